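"""Joining variants against feature / somatic / prediction stores.

The engine takes a protein substitution plus the structures covering it,
collects the functional features at the mutated position and at every
residue in spatial contact with it (back-mapped to isoform coordinates
through each chain's own position map), flags interface membership, and
applies a configurable disjunctive rule to call the variant damaging.

The damaging-call rule mirrors the shape of evidence that drives driver
interpretation — direct functional site, site in spatial contact,
interface membership, somatic recurrence, predictor consensus — with
every clause individually toggleable, because no single published rule is
canonical here.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO, Union

from intervaltree import IntervalTree

from varcontact.alignment import PositionMap, map_position
from varcontact.structure3d import (
    DEFAULT_CUTOFF,
    ResidueId,
    Structure3D,
    interface_residues,
    spatial_neighbors,
)
from varcontact.variant_mapping import IsoformCatalog, ProteinSubstitution

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = frozenset({
    "ptm_site", "catalytic_site", "binding_site", "mutagenesis_site",
    "domain", "signal_peptide", "transmembrane", "secondary_structure",
})
#: single-residue functional-site categories that drive clauses d1/d2
SITE_CATEGORIES = frozenset({
    "ptm_site", "catalytic_site", "binding_site", "mutagenesis_site",
})
PREDICTION_METHODS = frozenset({
    "SIFT", "Polyphen2", "LRT", "MutationTaster", "MutationAssessor",
    "FATHMM", "VEST3", "CADD",
})
PREDICTION_CALLS = frozenset({"damaging", "tolerated", "unknown"})


class AnnotationLoadError(ValueError):
    """Malformed annotation table; message names the line."""


@dataclass(frozen=True)
class FeatureRecord:
    """A sequence feature: a single-residue site (start == end) or a
    range such as a Pfam domain, on 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    category: str
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature range must satisfy 1 <= start <= end, "
                f"got {self.start}-{self.end}"
            )
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")


@dataclass(frozen=True)
class SomaticRecord:
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    sample_id: str
    tumor_site: str = ""
    histology: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"somatic position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class PredictionRecord:
    protein_id: str
    position: int
    alt_aa: str
    method: str
    score: float
    call: str

    def __post_init__(self) -> None:
        if self.method not in PREDICTION_METHODS:
            raise ValueError(f"unknown prediction method {self.method!r}")
        if self.call not in PREDICTION_CALLS:
            raise ValueError(f"unknown prediction call {self.call!r}")


@dataclass
class AnnotationStore:
    """Feature / somatic / prediction records indexed for point lookup."""

    features: list[FeatureRecord] = field(default_factory=list)
    somatic: list[SomaticRecord] = field(default_factory=list)
    predictions: list[PredictionRecord] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _somatic_idx: dict[tuple[str, int], list[SomaticRecord]] = field(
        default_factory=dict, repr=False)
    _pred_idx: dict[tuple[str, int], list[PredictionRecord]] = field(
        default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for f in self.features:
            # intervaltree upper bounds are exclusive; feature ends inclusive
            self._trees.setdefault(f.protein_id, IntervalTree()).addi(
                f.start, f.end + 1, f)
        for s in self.somatic:
            self._somatic_idx.setdefault((s.protein_id, s.position), []).append(s)
        for p in self.predictions:
            self._pred_idx.setdefault((p.protein_id, p.position), []).append(p)

    def somatic_at(self, protein_id: str, position: int) -> list[SomaticRecord]:
        return list(self._somatic_idx.get((protein_id, position), []))

    def predictions_for(
        self, protein_id: str, position: int, alt_aa: str | None = None
    ) -> list[PredictionRecord]:
        recs = self._pred_idx.get((protein_id, position), [])
        if alt_aa is None:
            return list(recs)
        return [p for p in recs if p.alt_aa == alt_aa]


def features_at(
    store: AnnotationStore, protein_id: str, position: int
) -> list[FeatureRecord]:
    """All feature records whose [start, end] contains the position
    (inclusive at both ends), in load order."""
    tree = store._trees.get(protein_id)
    if tree is None:
        return []
    hits = [iv.data for iv in tree.at(position)]
    hits.sort(key=lambda f: (f.start, f.end, f.category, f.label))
    return hits


def _rows(stream: Union[str, TextIO, Iterable[str]]):
    if isinstance(stream, str):
        with open(stream) as fh:
            yield from enumerate(csv.reader(fh, delimiter="\t"), start=1)
    else:
        yield from enumerate(csv.reader(stream, delimiter="\t"), start=1)


def load_annotation_tables(
    feature_tsv: Union[str, TextIO, None],
    somatic_tsv: Union[str, TextIO, None] = None,
    prediction_tsv: Union[str, TextIO, None] = None,
) -> AnnotationStore:
    """Build an :class:`AnnotationStore` from the three TSV snapshots.

    Column contracts (tab-separated, one header line):

    * features: ``protein_id start end category label``
    * somatic:  ``protein_id position ref_aa alt_aa sample_id tumor_site histology``
    * predictions: ``protein_id position alt_aa method score call``

    Any ``None`` table is treated as empty.  Unknown category/method/call
    tokens raise :class:`AnnotationLoadError` naming the line.
    """
    features: list[FeatureRecord] = []
    somatic: list[SomaticRecord] = []
    predictions: list[PredictionRecord] = []

    if feature_tsv is not None:
        for lineno, row in _rows(feature_tsv):
            if not row or row[0] == "protein_id":
                continue
            if len(row) != 5:
                raise AnnotationLoadError(
                    f"features line {lineno}: expected 5 columns, got {len(row)}")
            try:
                features.append(FeatureRecord(
                    row[0], int(row[1]), int(row[2]), row[3], row[4]))
            except ValueError as exc:
                raise AnnotationLoadError(
                    f"features line {lineno}: {exc}") from None

    if somatic_tsv is not None:
        for lineno, row in _rows(somatic_tsv):
            if not row or row[0] == "protein_id":
                continue
            if len(row) != 7:
                raise AnnotationLoadError(
                    f"somatic line {lineno}: expected 7 columns, got {len(row)}")
            try:
                somatic.append(SomaticRecord(
                    row[0], int(row[1]), row[2], row[3], row[4], row[5], row[6]))
            except ValueError as exc:
                raise AnnotationLoadError(
                    f"somatic line {lineno}: {exc}") from None

    if prediction_tsv is not None:
        for lineno, row in _rows(prediction_tsv):
            if not row or row[0] == "protein_id":
                continue
            if len(row) != 6:
                raise AnnotationLoadError(
                    f"predictions line {lineno}: expected 6 columns, got {len(row)}")
            try:
                predictions.append(PredictionRecord(
                    row[0], int(row[1]), row[2], row[3], float(row[4]), row[5]))
            except ValueError as exc:
                raise AnnotationLoadError(
                    f"predictions line {lineno}: {exc}") from None

    logger.info(
        "annotation store: %d features, %d somatic, %d predictions",
        len(features), len(somatic), len(predictions))
    return AnnotationStore(features, somatic, predictions)


# ---------------------------------------------------------------------------
# report rows

@dataclass(frozen=True)
class NeighborFeature:
    """A feature found on a residue in spatial contact with the variant."""

    feature: FeatureRecord
    residue_id: ResidueId
    distance: float
    relation: str  # intra_chain | interface_partner
    sequence_adjacent: bool = False


@dataclass
class StructureContext:
    """One structure together with the position maps of its chains."""

    structure: Structure3D
    maps: dict[str, PositionMap]

    def chains_for(self, protein_id: str) -> list[str]:
        """Chain ids carrying this protein with an accepted map, sorted."""
        out = []
        for chain_id, pid in self.structure.chain_protein.items():
            pm = self.maps.get(chain_id)
            if pid == protein_id and pm is not None and pm.accepted:
                out.append(chain_id)
        return sorted(out)


@dataclass
class AnnotationReportRow:
    """One variant x one structure context (or the structure-free row)."""

    substitution: ProteinSubstitution
    structure_id: str | None = None
    source: str | None = None
    chain_id: str | None = None
    mapped_residue: ResidueId | None = None
    direct_features: list[FeatureRecord] = field(default_factory=list)
    neighbor_features: list[NeighborFeature] = field(default_factory=list)
    interface_flag: bool = False
    somatic_matches: list[SomaticRecord] = field(default_factory=list)
    predictions: list[PredictionRecord] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    call: str = "no_evidence"
    evidence: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RuleConfig:
    """Toggles for the disjunctive damaging-call rule.

    d1 direct functional site; d2 functional site in spatial contact
    (sequence-adjacent contacts excluded unless ``d2_sequence_adjacent``);
    d3 interface residue; d4 somatic recurrence; d5 strict majority of
    non-unknown predictor calls damaging (ties do not fire).
    """

    d1_direct_site: bool = True
    d2_neighbor_site: bool = True
    d3_interface: bool = True
    d4_somatic: bool = True
    d5_prediction_majority: bool = True
    d2_sequence_adjacent: bool = False

    @classmethod
    def none(cls) -> "RuleConfig":
        return cls(False, False, False, False, False)


def annotate_variant(
    sub: ProteinSubstitution,
    store: AnnotationStore,
    contexts: Sequence[StructureContext] = (),
    cutoff: float = DEFAULT_CUTOFF,
    catalog: IsoformCatalog | None = None,
    rule: "RuleConfig | None" = None,
) -> list[AnnotationReportRow]:
    """Annotate one substitution against every structure covering it.

    Emits one row per structure whose accepted position map covers the
    variant position (for homomeric structures the lowest covering chain
    id is used), plus exactly one structure-free row when no structure
    covers it.  Rows are ordered experimental before model, then by
    structure id.  A ref_aa disagreeing with the catalog sequence yields
    a single ``ref_mismatch``-flagged row without structural annotation.
    Each row is classified with ``rule`` (default :class:`RuleConfig`).
    """
    base_flags: list[str] = []
    if catalog is not None:
        seq = catalog.sequence_of(sub.protein_id)
        if seq is not None:
            if sub.position > len(seq) or seq[sub.position - 1] != sub.ref_aa:
                base_flags.append("ref_mismatch")
        principal = catalog.is_principal(sub.protein_id)
        if principal is False:
            base_flags.append("non_principal")

    direct = features_at(store, sub.protein_id, sub.position)
    somatic = store.somatic_at(sub.protein_id, sub.position)
    preds = store.predictions_for(sub.protein_id, sub.position, sub.alt_aa)

    rows: list[AnnotationReportRow] = []
    if "ref_mismatch" not in base_flags:
        ordered = sorted(
            contexts,
            key=lambda c: (c.structure.source != "experimental",
                           c.structure.structure_id),
        )
        for ctx in ordered:
            st = ctx.structure
            for chain_id in ctx.chains_for(sub.protein_id):
                pm = ctx.maps[chain_id]
                rid = map_position(pm, sub.position)
                if rid is None:
                    continue
                row = AnnotationReportRow(
                    substitution=sub,
                    structure_id=st.structure_id,
                    source=st.source,
                    chain_id=chain_id,
                    mapped_residue=rid,
                    direct_features=list(direct),
                    somatic_matches=list(somatic),
                    predictions=list(preds),
                    flags=list(base_flags),
                )
                if sub.position in pm.mismatches:
                    row.flags.append("mapped_mismatch")

                nset = spatial_neighbors(st, rid, cutoff)
                inverse_maps = {
                    cid: ctx.maps[cid].inverse()
                    for cid in ctx.maps
                    if ctx.maps[cid].accepted
                }
                for nb in nset.neighbors:
                    n_chain = nb.residue_id.chain_id
                    n_protein = st.chain_protein.get(n_chain)
                    inv = inverse_maps.get(n_chain)
                    if n_protein is None or inv is None:
                        continue
                    iso_pos = inv.get(nb.residue_id)
                    if iso_pos is None:
                        continue
                    for feat in features_at(store, n_protein, iso_pos):
                        row.neighbor_features.append(NeighborFeature(
                            feature=feat,
                            residue_id=nb.residue_id,
                            distance=nb.distance,
                            relation=nb.relation,
                            sequence_adjacent=nb.sequence_adjacent,
                        ))
                if st.is_complex:
                    chain_ids = sorted(st.chain_protein)
                    partner = (chain_ids[0] if chain_ids[1] == chain_id
                               else chain_ids[1])
                    iface = interface_residues(st, chain_id, partner, cutoff)
                    row.interface_flag = any(ra == rid for ra, _rb, _d in iface)
                rows.append(row)
                break  # one row per structure

    if not rows:
        rows.append(AnnotationReportRow(
            substitution=sub,
            direct_features=list(direct),
            somatic_matches=list(somatic),
            predictions=list(preds),
            flags=list(base_flags),
        ))

    cfg = rule if rule is not None else RuleConfig()
    for row in rows:
        row.call, row.evidence = classify_variant(row, cfg)
    return rows


def classify_variant(
    row: AnnotationReportRow, rule: RuleConfig | None = None
) -> tuple[str, list[str]]:
    """Apply the disjunctive damaging-call rule to an annotated row.

    Returns ``(call, evidence)``: damaging when any enabled clause fires
    (each fired clause appends a ``clause:detail`` string); neutral when
    nothing fires but at least one prediction record exists; no_evidence
    otherwise.
    """
    cfg = rule if rule is not None else RuleConfig()
    evidence: list[str] = []
    pos = row.substitution.position

    if cfg.d1_direct_site:
        for f in row.direct_features:
            if f.category in SITE_CATEGORIES:
                evidence.append(f"d1:{f.category}@{pos}")

    if cfg.d2_neighbor_site:
        for nf in row.neighbor_features:
            if nf.feature.category not in SITE_CATEGORIES:
                continue
            if nf.sequence_adjacent and not cfg.d2_sequence_adjacent:
                continue
            evidence.append(
                f"d2:{nf.feature.category}@{nf.residue_id}"
                f"({nf.distance:.2f}A,{nf.relation})"
            )

    if cfg.d3_interface and row.interface_flag:
        evidence.append(f"d3:interface@{row.mapped_residue}")

    if cfg.d4_somatic and row.somatic_matches:
        sites = sorted({s.tumor_site for s in row.somatic_matches if s.tumor_site})
        detail = ",".join(sites) if sites else "recurrent"
        evidence.append(f"d4:somatic@{pos}({len(row.somatic_matches)};{detail})")

    if cfg.d5_prediction_majority:
        voting = [p for p in row.predictions if p.call != "unknown"]
        dmg = sum(1 for p in voting if p.call == "damaging")
        if voting and dmg * 2 > len(voting):
            evidence.append(f"d5:predictions({dmg}/{len(voting)} damaging)")

    if evidence:
        return "damaging", evidence
    if row.predictions:
        return "neutral", []
    return "no_evidence", []


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary-classification counts with derived accuracy, precision,
    recall and Matthews correlation coefficient.

    Metrics with a zero denominator are NaN, never silently 0.  Values
    are stored at full precision; display rounds to 2 decimals.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    mcc: float

    def rounded(self) -> dict[str, float]:
        return {
            "accuracy": round(self.accuracy, 2),
            "precision": round(self.precision, 2),
            "recall": round(self.recall, 2),
            "mcc": round(self.mcc, 2),
        }

    def __str__(self) -> str:
        r = self.rounded()
        return (
            f"tp={self.tp} fp={self.fp} fn={self.fn} tn={self.tn} | "
            f"accuracy: {r['accuracy']:.2f}, recall: {r['recall']:.2f}, "
            f"precision: {r['precision']:.2f}, MCC: {r['mcc']:.2f}"
        )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.info("metric %s undefined (zero denominator); reporting NaN", name)
        return math.nan
    return num / den


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Confusion-matrix metrics; NaN for any zero-denominator metric."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = _ratio(tp + tn, total, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn))
    mcc = _ratio(tp * tn - fp * fn, denom, "mcc")
    return ConfusionMetrics(tp, fp, fn, tn, accuracy, precision, recall, mcc)


def evaluate(
    labelled_variants: Sequence[tuple[ProteinSubstitution, str]],
    calls: Mapping[ProteinSubstitution, str],
    *,
    no_evidence_negative: bool = True,
) -> ConfusionMetrics:
    """Score calls against pathogenic/neutral labels.

    ``calls`` maps each variant to its final call (a variant with several
    report rows counts as damaging if any row is).  ``no_evidence`` is a
    negative call by default.
    """
    tp = fp = fn = tn = 0
    for sub, label in labelled_variants:
        if label not in ("pathogenic", "neutral"):
            raise ValueError(f"unknown label {label!r} for {sub}")
        call = calls[sub]
        if call == "no_evidence" and not no_evidence_negative:
            raise ValueError(
                f"{sub}: no_evidence call present but not counted as negative")
        positive = call == "damaging"
        if positive and label == "pathogenic":
            tp += 1
        elif positive and label == "neutral":
            fp += 1
        elif not positive and label == "pathogenic":
            fn += 1
        else:
            tn += 1
    return compute_metrics(tp, fp, fn, tn)
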