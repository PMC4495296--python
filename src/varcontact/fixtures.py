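"""Deterministic synthetic inputs: structures, tables, validation sets.

Everything the pipeline consumes — PDB structures with engineered
contacts, annotation tables, isoform catalogs, transcript models and
labelled validation variants — can be generated here from a seed, so the
whole system is exercisable with no external downloads.

Geometry is deliberately schematic: chains are straight C-alpha/C-beta
traces with 3.8 A residue spacing, parallel chains separated well beyond
the contact cutoff, and individual partner residues repositioned to sit
at an exact requested minimum heavy-atom distance from a chosen residue
of the first chain.  That is enough to drive every distance-based code
path with hand-checkable expectations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.SeqUtils import seq3

from varcontact.annotation import FeatureRecord, PredictionRecord, SomaticRecord
from varcontact.variant_mapping import ProteinSubstitution, TranscriptModel

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CA_SPACING = 3.8   # A between consecutive residues along the chain axis
CB_OFFSET = 1.5    # A from CA to the pseudo C-beta
CHAIN_SEPARATION = 25.0  # A between the two chain axes (no stray contacts)


class FixtureError(ValueError):
    """Infeasible fixture specification."""


@dataclass(frozen=True)
class LabelPlant:
    """A labelled variant plus the rule clause its evidence should fire
    (``d1``..``d5``) or ``None`` for a deliberately evidence-free case."""

    variant: ProteinSubstitution
    label: str  # pathogenic | neutral
    evidence: Optional[str] = None


@dataclass
class FixtureSpec:
    """Full description of one synthetic scenario; seed-deterministic."""

    seed: int = 0
    n_residues_per_chain: tuple[int, int] = (80, 80)
    chain_ids: tuple[str, str] = ("A", "B")
    protein_ids: tuple[str, str] = ("P1", "P2")
    gene_ids: tuple[str, str] = ("G1", "G2")
    structure_id: str = "S1"
    source: str = "experimental"
    contact_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    feature_plants: list[FeatureRecord] = field(default_factory=list)
    somatic_plants: list[SomaticRecord] = field(default_factory=list)
    prediction_plants: list[PredictionRecord] = field(default_factory=list)
    label_plants: list[LabelPlant] = field(default_factory=list)


def chain_sequences(spec: FixtureSpec) -> tuple[str, str]:
    """Seed-deterministic random amino-acid sequences for the two chains."""
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.n_residues_per_chain
    seq_a = "".join(AA20[i] for i in rng.integers(0, 20, size=n_a))
    seq_b = "".join(AA20[i] for i in rng.integers(0, 20, size=n_b))
    return seq_a, seq_b


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resnum: int, xyz: tuple[float, float, float]) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d}  {name:<3s} {resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.00:>6.2f}"
        f"{20.00:>6.2f}          {name[0]:>2s}"
    )


def generate_structure(spec: FixtureSpec) -> str:
    """Emit fixed-column PDB text for the two-chain pseudo-structure.

    Chain A runs along the x axis at z = 0, chain B parallel at
    z = CHAIN_SEPARATION.  For each contact pair ``(res_a, res_b, d)``
    residue ``res_b`` of chain B is repositioned directly above
    ``res_a``'s C-alpha at height d, making the minimum heavy-atom
    distance between the pair exactly d.
    """
    n_a, n_b = spec.n_residues_per_chain
    seen_a: dict[int, float] = {}
    seen_b: dict[int, float] = {}
    for ra, rb, d in spec.contact_pairs:
        if d < 1.0:
            raise FixtureError(f"contact distance {d} < 1.0 A is infeasible")
        if not (1 <= ra <= n_a) or not (1 <= rb <= n_b):
            raise FixtureError(f"contact ({ra},{rb}) outside chain lengths")
        if ra in seen_a or rb in seen_b:
            raise FixtureError(
                f"residue reused in contact set at pair ({ra},{rb})")
        seen_a[ra] = d
        seen_b[rb] = d

    seq_a, seq_b = chain_sequences(spec)
    moved = {rb: (ra, d) for ra, rb, d in spec.contact_pairs}

    lines: list[str] = []
    serial = 1

    def emit(chain: str, seq: str, z_axis: float, repositioned: dict) -> None:
        nonlocal serial
        for i, aa in enumerate(seq, start=1):
            if i in repositioned:
                ra, d = repositioned[i]
                x0 = (ra - 1) * CA_SPACING
                ca = (x0, 0.0, d)
                cb = (x0, 0.0, d + CB_OFFSET)
            else:
                x0 = (i - 1) * CA_SPACING
                ca = (x0, 0.0, z_axis)
                cb = (x0, CB_OFFSET, z_axis)
            resname = seq3(aa).upper()
            lines.append(_pdb_atom_line(serial, "CA", resname, chain, i, ca))
            serial += 1
            if aa != "G":  # glycine has no C-beta
                lines.append(_pdb_atom_line(serial, "CB", resname, chain, i, cb))
                serial += 1
        lines.append("TER")

    emit(spec.chain_ids[0], seq_a, 0.0, {})
    emit(spec.chain_ids[1], seq_b, CHAIN_SEPARATION, moved)
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# labelled validation scenario

def _alt_for(ref: str) -> str:
    return "A" if ref != "A" else "V"


def default_validation_spec(seed: int = 0) -> FixtureSpec:
    """The default labelled scenario: 14 pathogenic and 10 neutral
    variants on a two-chain complex.

    Eleven pathogenic variants carry planted evidence — three on
    catalytic sites, two contacting a partner-chain binding site, two at
    bare interface contacts, two on recurrent somatic positions, two with
    a damaging predictor majority — and three are deliberately
    evidence-free (they model pathogenic mechanisms the annotation cannot
    see).  The ten neutral variants sit in feature-free regions; two of
    them carry all-tolerated predictions.  Under the default rule the
    implied confusion matrix is tp=11, fp=0, fn=3, tn=10.
    """
    spec = FixtureSpec(
        seed=seed,
        n_residues_per_chain=(120, 80),
        contact_pairs=[
            (30, 10, 4.5), (40, 20, 4.5),   # bare interface contacts (d3)
            (50, 30, 4.2), (60, 40, 4.2),   # contacts to partner sites (d2)
        ],
    )
    seq_a, _seq_b = chain_sequences(spec)
    p1, p2 = spec.protein_ids

    spec.feature_plants = [
        FeatureRecord(p1, 10, 110, "domain", "PFX1"),
        FeatureRecord(p1, 70, 70, "catalytic_site", "active"),
        FeatureRecord(p1, 72, 72, "catalytic_site", "active"),
        FeatureRecord(p1, 74, 74, "catalytic_site", "active"),
        FeatureRecord(p2, 30, 30, "binding_site", "ligand"),
        FeatureRecord(p2, 40, 40, "binding_site", "ligand"),
    ]

    def sub(pos: int) -> ProteinSubstitution:
        ref = seq_a[pos - 1]
        return ProteinSubstitution(p1, pos, ref, _alt_for(ref))

    plants: list[LabelPlant] = []
    for pos in (70, 72, 74):
        plants.append(LabelPlant(sub(pos), "pathogenic", "d1"))
    for pos in (50, 60):
        plants.append(LabelPlant(sub(pos), "pathogenic", "d2"))
    for pos in (30, 40):
        plants.append(LabelPlant(sub(pos), "pathogenic", "d3"))
    for pos in (80, 82):
        plants.append(LabelPlant(sub(pos), "pathogenic", "d4"))
    for pos in (90, 92):
        plants.append(LabelPlant(sub(pos), "pathogenic", "d5"))
    for pos in (100, 102, 104):
        plants.append(LabelPlant(sub(pos), "pathogenic", None))
    for pos in (5, 7, 9, 11, 13, 15, 17, 19, 21, 23):
        plants.append(LabelPlant(sub(pos), "neutral", None))
    spec.label_plants = plants

    for pos in (80, 82):
        v = sub(pos)
        spec.somatic_plants += [
            SomaticRecord(p1, pos, v.ref_aa, v.alt_aa, f"TCGA-{pos}-1",
                          "bladder", "carcinoma"),
            SomaticRecord(p1, pos, v.ref_aa, v.alt_aa, f"TCGA-{pos}-2",
                          "lung", "adenocarcinoma"),
        ]

    for pos in (90, 92):  # 3/4 non-unknown calls damaging -> majority fires
        v = sub(pos)
        spec.prediction_plants += [
            PredictionRecord(p1, pos, v.alt_aa, "SIFT", 0.01, "damaging"),
            PredictionRecord(p1, pos, v.alt_aa, "Polyphen2", 0.97, "damaging"),
            PredictionRecord(p1, pos, v.alt_aa, "LRT", 0.92, "damaging"),
            PredictionRecord(p1, pos, v.alt_aa, "MutationTaster", 0.40, "tolerated"),
            PredictionRecord(p1, pos, v.alt_aa, "CADD", 12.0, "unknown"),
        ]
    for pos in (5, 7):  # neutral variants with all-tolerated predictions
        v = sub(pos)
        spec.prediction_plants += [
            PredictionRecord(p1, pos, v.alt_aa, "SIFT", 0.60, "tolerated"),
            PredictionRecord(p1, pos, v.alt_aa, "Polyphen2", 0.02, "tolerated"),
            PredictionRecord(p1, pos, v.alt_aa, "FATHMM", 1.50, "tolerated"),
        ]
    return spec


def expected_confusion(spec: FixtureSpec) -> tuple[int, int, int, int]:
    """Confusion matrix (tp, fp, fn, tn) implied by the label plants:
    a variant is called damaging exactly when it has planted evidence."""
    tp = sum(1 for p in spec.label_plants
             if p.label == "pathogenic" and p.evidence is not None)
    fn = sum(1 for p in spec.label_plants
             if p.label == "pathogenic" and p.evidence is None)
    fp = sum(1 for p in spec.label_plants
             if p.label == "neutral" and p.evidence is not None)
    tn = sum(1 for p in spec.label_plants
             if p.label == "neutral" and p.evidence is None)
    return tp, fp, fn, tn


def generate_validation_set(spec: FixtureSpec, out_dir: str) -> dict[str, str]:
    """Write the complete input bundle for one scenario.

    Emits variants, labels, the three annotation tables, the isoform
    catalog, the structure index and the PDB file, all in the dialects
    the pipeline consumes.  Returns a name -> path dict.
    """
    os.makedirs(os.path.join(out_dir, "structures"), exist_ok=True)
    seq_a, seq_b = chain_sequences(spec)
    p1, p2 = spec.protein_ids
    g1, g2 = spec.gene_ids
    ch_a, ch_b = spec.chain_ids
    paths: dict[str, str] = {}

    def write(name: str, rel: str, text: str) -> None:
        path = os.path.join(out_dir, rel)
        with open(path, "w") as fh:
            fh.write(text)
        paths[name] = path

    pdb_rel = os.path.join("structures", f"{spec.structure_id}.pdb")
    write("structure", pdb_rel, generate_structure(spec))

    write("structure_index", "structure_index.tsv", "".join(
        ["structure_id\tfile\tsource\tchain\tprotein_id\n",
         f"{spec.structure_id}\t{pdb_rel}\t{spec.source}\t{ch_a}\t{p1}\n",
         f"{spec.structure_id}\t{pdb_rel}\t{spec.source}\t{ch_b}\t{p2}\n"]))

    write("isoforms", "isoforms.tsv", "".join(
        ["gene_id\tprotein_id\tsequence\tprincipal\n",
         f"{g1}\t{p1}\t{seq_a}\t1\n",
         f"{g2}\t{p2}\t{seq_b}\t1\n"]))

    lines = ["protein_id\tposition\tref_aa\talt_aa\n"]
    for plant in spec.label_plants:
        v = plant.variant
        lines.append(f"{v.protein_id}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\n")
    write("variants", "variants.tsv", "".join(lines))

    lines = ["protein_id\tposition\tref_aa\talt_aa\tlabel\n"]
    for plant in spec.label_plants:
        v = plant.variant
        lines.append(
            f"{v.protein_id}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\t{plant.label}\n")
    write("labels", "labels.tsv", "".join(lines))

    lines = ["protein_id\tstart\tend\tcategory\tlabel\n"]
    for f in spec.feature_plants:
        lines.append(f"{f.protein_id}\t{f.start}\t{f.end}\t{f.category}\t{f.label}\n")
    write("features", "features.tsv", "".join(lines))

    lines = ["protein_id\tposition\tref_aa\talt_aa\tsample_id\ttumor_site\thistology\n"]
    for s in spec.somatic_plants:
        lines.append(
            f"{s.protein_id}\t{s.position}\t{s.ref_aa}\t{s.alt_aa}\t"
            f"{s.sample_id}\t{s.tumor_site}\t{s.histology}\n")
    write("somatic", "somatic.tsv", "".join(lines))

    lines = ["protein_id\tposition\talt_aa\tmethod\tscore\tcall\n"]
    for pr in spec.prediction_plants:
        lines.append(
            f"{pr.protein_id}\t{pr.position}\t{pr.alt_aa}\t{pr.method}\t"
            f"{pr.score}\t{pr.call}\n")
    write("predictions", "predictions.tsv", "".join(lines))

    return paths


# ---------------------------------------------------------------------------
# transcript-model scenarios for the genomic path

def random_transcript_model(
    seed: int,
    n_codons: int = 20,
    n_exons: int = 2,
    strand: str = "+",
    chrom: str = "chrT",
    protein_id: str = "PT1",
) -> tuple[TranscriptModel, dict[str, str]]:
    """A random multi-exon coding transcript plus a matching genome.

    The CDS starts with ATG, contains no internal stop codon, and is
    split into ``n_exons`` pieces separated by random intron stretches;
    flanking sequence pads both ends.  Returns the model and a
    chromosome -> sequence dict ready for the translator.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in stops:
            codons.append(c)
    cds = "".join(codons)

    # split into exon pieces (each >= 1 base)
    if n_exons > len(cds):
        raise FixtureError("more exons than CDS bases")
    cut_points = sorted(rng.choice(
        np.arange(1, len(cds)), size=n_exons - 1, replace=False).tolist())
    pieces = [cds[a:b] for a, b in
              zip([0] + cut_points, cut_points + [len(cds)])]
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        pieces = [p.translate(comp)[::-1] for p in reversed(pieces)]

    genome_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cursor = 0

    def pad(n: int) -> None:
        nonlocal cursor
        genome_parts.append("".join(bases[i] for i in rng.integers(0, 4, size=n)))
        cursor += n

    pad(int(rng.integers(5, 15)))
    for piece in pieces:
        start = cursor + 1
        genome_parts.append(piece)
        cursor += len(piece)
        exons.append((start, cursor))
        pad(int(rng.integers(5, 15)))

    genome = {chrom: "".join(genome_parts)}
    tm = TranscriptModel(
        transcript_id=f"T{seed}",
        protein_id=protein_id,
        gene_id=f"G{seed}",
        chrom=chrom,
        strand=strand,
        cds_exons=tuple(exons),
    )
    return tm, genome
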