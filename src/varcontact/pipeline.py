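"""End-to-end run: parse -> translate -> map -> geometry -> annotate -> report.

The pipeline streams variants through the full chain and writes a
deterministic report (TSV, JSON, or both): one row per variant x
structure context, plus a structure-free row for variants no structure
covers.  Re-running with identical inputs and configuration produces
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from varcontact.alignment import DEFAULT_MIN_IDENTITY, align_chain
from varcontact.annotation import (
    AnnotationReportRow,
    AnnotationStore,
    RuleConfig,
    StructureContext,
    annotate_variant,
    load_annotation_tables,
)
from varcontact.structure3d import (
    DEFAULT_CUTOFF,
    parse_pdb,
    load_structure_index,
)
from varcontact.variant_mapping import (
    GenomicVariant,
    IsoformCatalog,
    ProteinSubstitution,
    ReferenceMismatchError,
    TranslationVerdict,
    load_genome,
    load_isoform_catalog,
    load_transcript_models,
    parse_variants,
    translate_genomic_variant,
)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "protein_id", "position", "ref_aa", "alt_aa",
    "structure_id", "source", "chain", "mapped_residue", "interface",
    "direct_features", "neighbor_features", "somatic", "predictions",
    "flags", "call", "evidence",
]


class PipelineError(RuntimeError):
    """Fatal pipeline problem (unreadable input, zero variants, ...)."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs; all knobs surfaced."""

    variants: str
    dialect: str = "protein_tsv"
    structure_index: Optional[str] = None
    features: Optional[str] = None
    somatic: Optional[str] = None
    predictions: Optional[str] = None
    isoforms: Optional[str] = None
    transcripts: Optional[str] = None
    genome: Optional[str] = None
    cutoff: float = DEFAULT_CUTOFF
    min_identity: float = DEFAULT_MIN_IDENTITY
    rule: RuleConfig = field(default_factory=RuleConfig)
    out: Optional[str] = None
    out_format: str = "tsv"  # tsv | json

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if not (0 < self.min_identity <= 1):
            raise ValueError(
                f"min identity must lie in (0, 1], got {self.min_identity}")
        if self.out_format not in ("tsv", "json"):
            raise ValueError(f"unknown output format {self.out_format!r}")


def build_structure_contexts(
    index_path: str,
    catalog: IsoformCatalog,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[StructureContext]:
    """Load every indexed structure and align each mapped chain against
    its isoform sequence.  PDB paths are taken relative to the index
    file's directory."""
    base = os.path.dirname(os.path.abspath(index_path))
    with open(index_path) as fh:
        entries = load_structure_index(fh)
    contexts: list[StructureContext] = []
    for entry in entries:
        pdb_path = entry.file
        if not os.path.isabs(pdb_path):
            pdb_path = os.path.join(base, pdb_path)
        with open(pdb_path) as fh:
            structure = parse_pdb(
                fh, entry.structure_id, entry.source, entry.chain_protein)
        maps = {}
        for chain_id, protein_id in entry.chain_protein.items():
            iso_seq = catalog.sequence_of(protein_id)
            if iso_seq is None:
                logger.warning(
                    "%s chain %s: protein %s not in isoform catalog; skipped",
                    entry.structure_id, chain_id, protein_id)
                continue
            if chain_id not in structure.chains:
                logger.warning(
                    "%s: indexed chain %s absent from file; skipped",
                    entry.structure_id, chain_id)
                continue
            chain_seq, rids = structure.chain_sequence(chain_id)
            pm = align_chain(
                iso_seq, chain_seq, rids,
                protein_id=protein_id,
                structure_id=entry.structure_id,
                chain_id=chain_id,
                min_identity=min_identity,
            )
            if not pm.accepted:
                logger.warning(
                    "%s chain %s: alignment identity %.2f below %.2f; "
                    "map rejected", entry.structure_id, chain_id,
                    pm.identity, min_identity)
            maps[chain_id] = pm
        contexts.append(StructureContext(structure=structure, maps=maps))
    return contexts


def _fmt_features(feats) -> str:
    return ";".join(
        f"{f.category}:{f.label}@{f.start}-{f.end}" for f in feats) or "."


def _fmt_neighbors(nfs) -> str:
    parts = []
    for nf in nfs:
        tag = nf.relation + (",seq_adjacent" if nf.sequence_adjacent else "")
        parts.append(
            f"{nf.feature.category}:{nf.feature.label}@{nf.residue_id}"
            f"({nf.distance:.2f}A,{tag})")
    return ";".join(parts) or "."


def _fmt_somatic(recs) -> str:
    return ";".join(
        f"{s.sample_id}@{s.position}({s.tumor_site}/{s.histology})"
        for s in recs) or "."


def _fmt_predictions(recs) -> str:
    return ";".join(f"{p.method}:{p.call}({p.score:g})" for p in recs) or "."


def row_to_tsv(row: AnnotationReportRow) -> str:
    sub = row.substitution
    fields = [
        sub.protein_id, str(sub.position), sub.ref_aa, sub.alt_aa,
        row.structure_id or ".", row.source or ".", row.chain_id or ".",
        str(row.mapped_residue) if row.mapped_residue else ".",
        "1" if row.interface_flag else "0",
        _fmt_features(row.direct_features),
        _fmt_neighbors(row.neighbor_features),
        _fmt_somatic(row.somatic_matches),
        _fmt_predictions(row.predictions),
        ";".join(row.flags) or ".",
        row.call,
        ";".join(row.evidence) or ".",
    ]
    return "\t".join(fields)


def row_to_dict(row: AnnotationReportRow) -> dict:
    sub = row.substitution
    return {
        "protein_id": sub.protein_id,
        "position": sub.position,
        "ref_aa": sub.ref_aa,
        "alt_aa": sub.alt_aa,
        "structure_id": row.structure_id,
        "source": row.source,
        "chain": row.chain_id,
        "mapped_residue": str(row.mapped_residue) if row.mapped_residue else None,
        "interface": row.interface_flag,
        "direct_features": [dataclasses.asdict(f) for f in row.direct_features],
        "neighbor_features": [
            {
                "feature": dataclasses.asdict(nf.feature),
                "residue": str(nf.residue_id),
                "distance": round(nf.distance, 4),
                "relation": nf.relation,
                "sequence_adjacent": nf.sequence_adjacent,
            }
            for nf in row.neighbor_features
        ],
        "somatic": [dataclasses.asdict(s) for s in row.somatic_matches],
        "predictions": [dataclasses.asdict(p) for p in row.predictions],
        "flags": list(row.flags),
        "call": row.call,
        "evidence": list(row.evidence),
    }


def render_report(rows: list[AnnotationReportRow], fmt: str) -> str:
    if fmt == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        lines += [row_to_tsv(r) for r in rows]
        return "\n".join(lines) + "\n"
    return json.dumps([row_to_dict(r) for r in rows], indent=2,
                      sort_keys=True) + "\n"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full annotation pipeline.

    Returns a run summary with counts: variants in, translated, mapped to
    at least one structure, rows out, damaging calls.  Unmapped variants
    are not errors — they appear as structure-free rows.
    """
    try:
        with open(cfg.variants) as fh:
            records = parse_variants(fh, cfg.dialect)
    except OSError as exc:
        raise PipelineError(f"cannot read variants: {exc}") from None
    if not records:
        raise PipelineError("zero variants parsed")

    n_in = len(records)
    subs: list[ProteinSubstitution] = []
    n_translated = 0
    if any(isinstance(r, GenomicVariant) for r in records):
        if not cfg.transcripts or not cfg.genome:
            raise PipelineError(
                "genomic variants require --transcripts and --genome")
        with open(cfg.transcripts) as fh:
            models = load_transcript_models(fh)
        genome = load_genome(cfg.genome)
        for rec in records:
            if isinstance(rec, ProteinSubstitution):
                subs.append(rec)
                continue
            model = next(
                (m for m in models if m.chrom == rec.chrom
                 and any(s <= rec.pos <= e for s, e in m.cds_exons)),
                None,
            )
            if model is None:
                logger.info("%s:%d: no transcript CDS covers it (non-coding)",
                            rec.chrom, rec.pos)
                continue
            try:
                result = translate_genomic_variant(rec, model, genome)
            except ReferenceMismatchError as exc:
                logger.warning("%s", exc)
                continue
            if isinstance(result, TranslationVerdict):
                logger.info("%s:%d: %s", rec.chrom, rec.pos, result.value)
                continue
            n_translated += 1
            subs.append(result)
    else:
        subs = [r for r in records if isinstance(r, ProteinSubstitution)]

    catalog = IsoformCatalog()
    if cfg.isoforms:
        with open(cfg.isoforms) as fh:
            catalog = load_isoform_catalog(fh)

    store: AnnotationStore = load_annotation_tables(
        cfg.features, cfg.somatic, cfg.predictions)

    contexts = []
    if cfg.structure_index:
        contexts = build_structure_contexts(
            cfg.structure_index, catalog, cfg.min_identity)

    rows: list[AnnotationReportRow] = []
    n_mapped = 0
    n_damaging = 0
    for sub in subs:
        variant_rows = annotate_variant(
            sub, store, contexts, cfg.cutoff, catalog, cfg.rule)
        if any(r.structure_id for r in variant_rows):
            n_mapped += 1
        n_damaging += sum(1 for r in variant_rows if r.call == "damaging")
        rows.extend(variant_rows)

    if cfg.out:
        with open(cfg.out, "w") as fh:
            fh.write(render_report(rows, cfg.out_format))

    summary = {
        "variants_in": n_in,
        "substitutions": len(subs),
        "translated": n_translated,
        "mapped_to_structure": n_mapped,
        "rows_out": len(rows),
        "damaging_calls": n_damaging,
    }
    logger.info(
        "pipeline: %d variants in, %d substitutions (%d translated), "
        "%d mapped to >=1 structure, %d rows, %d damaging calls",
        n_in, len(subs), n_translated, n_mapped, len(rows), n_damaging)
    summary["rows"] = rows
    return summary
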