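"""Variant input parsing, genomic-to-protein translation and isoform choice.

Variants arrive either as protein-level substitutions (``protein_tsv``) or
as genomic SNVs (``vcf_lite``).  Genomic SNVs are translated to protein
substitutions through a transcript model (ordered CDS exons on a stated
strand) and a reference genome; the principal isoform of each gene is the
single reference sequence against which downstream annotation happens.

Coordinates are 1-based inclusive throughout: genomic positions, CDS
offsets (counted from the first base of the start codon) and protein
residue indices.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO, Union

from Bio.Seq import Seq
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: extended alphabet: 20 amino acids, unknown X, stop '*'
AA_ALPHABET = AMINO_ACIDS | {"X", "*"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class VariantParseError(ValueError):
    """Malformed variant input; message names the line number and field."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the reference sequence."""


class CatalogError(KeyError):
    """Lookup into the isoform catalog failed."""


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide substitution on a chromosome (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"genomic position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"ref/alt must be single nucleotides, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class ProteinSubstitution:
    """One amino-acid change on a specific protein isoform."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"protein position must be >= 1, got {self.position}")
        for name, aa in (("ref_aa", self.ref_aa), ("alt_aa", self.alt_aa)):
            if aa not in AA_ALPHABET:
                raise ValueError(f"{name} {aa!r} is not a valid one-letter residue")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"ref equals alt ({self.ref_aa}) at {self.protein_id}:{self.position}"
            )

    def __str__(self) -> str:  # e.g. ENSP000001:S427F
        return f"{self.protein_id}:{self.ref_aa}{self.position}{self.alt_aa}"


class TranslationVerdict(enum.Enum):
    """Outcome of a genomic SNV that does not yield a substitution."""

    NON_CODING = "non_coding"
    SYNONYMOUS = "synonymous"


@dataclass(frozen=True)
class TranscriptModel:
    """Protein-coding transcript: ordered CDS exons on one strand.

    ``cds_exons`` are 1-based inclusive genomic intervals, non-overlapping
    and sorted by genomic start regardless of strand.  The translation
    phase is assumed 0: the first CDS base (5' on the coding strand)
    begins the start codon, and the total CDS length must be divisible
    by 3.
    """

    transcript_id: str
    protein_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_exons:
            raise ValueError(f"{self.transcript_id}: no CDS exons")
        prev_end = 0
        for start, end in self.cds_exons:
            if start < 1 or end < start:
                raise ValueError(
                    f"{self.transcript_id}: bad exon interval {start}-{end}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted at "
                    f"{start}-{end}"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} is not a "
                "multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_exons)


@dataclass(frozen=True)
class IsoformEntry:
    gene_id: str
    protein_id: str
    sequence: str
    principal: bool

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - (AMINO_ACIDS | {"X"})
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)} in sequence"
            )


@dataclass
class IsoformCatalog:
    """Gene -> isoform entries, each with sequence and APPRIS-style flag."""

    entries: list[IsoformEntry] = field(default_factory=list)

    def by_gene(self, gene_id: str) -> list[IsoformEntry]:
        return [e for e in self.entries if e.gene_id == gene_id]

    def sequence_of(self, protein_id: str) -> str | None:
        for e in self.entries:
            if e.protein_id == protein_id:
                return e.sequence
        return None

    def is_principal(self, protein_id: str) -> bool | None:
        """True/False for known isoforms, None when the catalog lacks it."""
        for e in self.entries:
            if e.protein_id == protein_id:
                return e.principal
        return None


# ---------------------------------------------------------------------------
# parsing

def parse_variants(
    stream: Union[TextIO, Iterable[str]],
    dialect: str,
) -> list[Union[GenomicVariant, ProteinSubstitution]]:
    """Parse a variant file into typed records, preserving input order.

    ``protein_tsv``: tab-separated, header line
    ``protein_id  position  ref_aa  alt_aa``.

    ``vcf_lite``: the CHROM/POS/ID/REF/ALT columns of VCF v4 body lines;
    ``#``-prefixed header lines are ignored.  Multi-nucleotide REF or ALT
    alleles are skipped with a warning (scope is SNVs).

    Raises :class:`VariantParseError` naming the line number on any
    malformed data line.
    """
    if dialect not in ("protein_tsv", "vcf_lite"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[Union[GenomicVariant, ProteinSubstitution]] = []
    header_seen = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if dialect == "vcf_lite":
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise VariantParseError(
                    f"line {lineno}: expected >=5 tab-separated VCF columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1:
                logger.warning(
                    "line %d: skipping non-SNV record %s>%s (scope is SNVs)",
                    lineno, ref, alt,
                )
                continue
            try:
                pos = int(pos_s)
            except ValueError:
                raise VariantParseError(
                    f"line {lineno}: POS field {pos_s!r} is not an integer"
                ) from None
            try:
                records.append(GenomicVariant(chrom, pos, ref.upper(), alt.upper()))
            except ValueError as exc:
                raise VariantParseError(f"line {lineno}: {exc}") from None
        else:
            if not header_seen:
                header_seen = True
                if line.split("\t")[0] == "protein_id":
                    continue
                # fall through: headerless file, treat as data
            fields = line.split("\t")
            if len(fields) != 4:
                raise VariantParseError(
                    f"line {lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            protein_id, pos_s, ref_aa, alt_aa = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise VariantParseError(
                    f"line {lineno}: position field {pos_s!r} is not an integer"
                ) from None
            try:
                records.append(ProteinSubstitution(protein_id, pos, ref_aa, alt_aa))
            except ValueError as exc:
                raise VariantParseError(f"line {lineno}: {exc}") from None
    return records


def serialize_variants(
    records: Iterable[Union[GenomicVariant, ProteinSubstitution]],
    dialect: str,
) -> str:
    """Inverse of :func:`parse_variants` on well-formed records."""
    lines: list[str] = []
    if dialect == "protein_tsv":
        lines.append("protein_id\tposition\tref_aa\talt_aa")
        for r in records:
            assert isinstance(r, ProteinSubstitution)
            lines.append(f"{r.protein_id}\t{r.position}\t{r.ref_aa}\t{r.alt_aa}")
    elif dialect == "vcf_lite":
        lines.append("#CHROM\tPOS\tID\tREF\tALT")
        for r in records:
            assert isinstance(r, GenomicVariant)
            lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(lines) + "\n"


def load_transcript_models(stream: Union[TextIO, Iterable[str]]) -> list[TranscriptModel]:
    """Read the transcript-model TSV.

    Columns: ``transcript_id protein_id gene_id chrom strand cds_exons``
    with exons encoded ``start-end`` joined by ``;``.
    """
    models: list[TranscriptModel] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("transcript_id"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise VariantParseError(
                f"line {lineno}: expected 6 columns in transcript model, "
                f"got {len(fields)}"
            )
        tid, pid, gid, chrom, strand, exons_s = fields
        exons: list[tuple[int, int]] = []
        try:
            for chunk in exons_s.split(";"):
                a, b = chunk.split("-")
                exons.append((int(a), int(b)))
        except ValueError:
            raise VariantParseError(
                f"line {lineno}: malformed cds_exons field {exons_s!r}"
            ) from None
        try:
            models.append(TranscriptModel(tid, pid, gid, chrom, strand, tuple(exons)))
        except ValueError as exc:
            raise VariantParseError(f"line {lineno}: {exc}") from None
    return models


def load_isoform_catalog(stream: Union[TextIO, Iterable[str]]) -> IsoformCatalog:
    """Read the isoform catalog TSV.

    Columns: ``gene_id protein_id sequence principal`` (principal is
    0/1).  At most one principal isoform per gene is enforced.
    """
    entries: list[IsoformEntry] = []
    flagged: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("gene_id"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise VariantParseError(
                f"line {lineno}: expected 4 columns in isoform catalog, "
                f"got {len(fields)}"
            )
        gid, pid, seq, flag = fields
        principal = flag.strip() in ("1", "true", "True")
        if principal:
            if gid in flagged:
                raise VariantParseError(
                    f"line {lineno}: gene {gid} has more than one principal isoform"
                )
            flagged.add(gid)
        try:
            entries.append(IsoformEntry(gid, pid, seq, principal))
        except ValueError as exc:
            raise VariantParseError(f"line {lineno}: {exc}") from None
    return IsoformCatalog(entries)


def load_genome(path: str) -> dict[str, str]:
    """Read a FASTA reference into a chromosome-name -> sequence dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


# ---------------------------------------------------------------------------
# translation

def _cds_offset(tm: TranscriptModel, pos: int) -> int | None:
    """1-based offset of genomic ``pos`` within the CDS, or None if outside.

    On the minus strand the CDS reads 3'->5' along genomic coordinates,
    so the offset counts down from the genomically-last exon end.
    """
    hit = None
    for start, end in tm.cds_exons:
        if start <= pos <= end:
            hit = (start, end)
            break
    if hit is None:
        return None
    start, end = hit
    if tm.strand == "+":
        before = sum(e - s + 1 for s, e in tm.cds_exons if e < start)
        return before + (pos - start) + 1
    before = sum(e - s + 1 for s, e in tm.cds_exons if s > end)
    return before + (end - pos) + 1


def _cds_sequence(tm: TranscriptModel, genome: Mapping[str, str]) -> str:
    chrom_seq = genome[tm.chrom]
    parts = [chrom_seq[s - 1: e] for s, e in tm.cds_exons]
    cds = "".join(parts)
    if tm.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds


def translate_cds(cds: str) -> str:
    """Whole-CDS translation with the standard genetic code (stop = '*')."""
    return str(Seq(cds).translate(table=1))


def translate_genomic_variant(
    gv: GenomicVariant,
    tm: TranscriptModel,
    genome: Mapping[str, str],
) -> Union[ProteinSubstitution, TranslationVerdict]:
    """Map a genomic SNV onto the transcript's protein product.

    Returns a :class:`ProteinSubstitution` for missense and stop-gain
    (alt_aa ``'*'``) changes, :data:`TranslationVerdict.SYNONYMOUS` when
    the mutated codon translates identically, and
    :data:`TranslationVerdict.NON_CODING` when the position falls outside
    every CDS exon.

    Raises :class:`ReferenceMismatchError` when the stated ref allele
    disagrees with the reference genome, and ``KeyError`` when the genome
    lacks the chromosome.
    """
    if gv.chrom != tm.chrom:
        raise ValueError(
            f"variant chromosome {gv.chrom} does not match transcript "
            f"chromosome {tm.chrom}"
        )
    chrom_seq = genome[tm.chrom]
    if gv.pos > len(chrom_seq):
        raise ReferenceMismatchError(
            f"position {gv.pos} beyond end of {tm.chrom} ({len(chrom_seq)} bp)"
        )
    genome_base = chrom_seq[gv.pos - 1]
    if genome_base != gv.ref:
        raise ReferenceMismatchError(
            f"{gv.chrom}:{gv.pos}: stated ref {gv.ref} but reference "
            f"sequence has {genome_base}"
        )
    offset = _cds_offset(tm, gv.pos)
    if offset is None:
        return TranslationVerdict.NON_CODING

    cds = _cds_sequence(tm, genome)
    codon_index = (offset - 1) // 3  # 0-based
    within = (offset - 1) % 3
    codon = cds[codon_index * 3: codon_index * 3 + 3]
    alt_base = gv.alt if tm.strand == "+" else gv.alt.translate(_COMPLEMENT)
    mutated = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = translate_cds(codon)
    alt_aa = translate_cds(mutated)
    if ref_aa == alt_aa:
        return TranslationVerdict.SYNONYMOUS
    return ProteinSubstitution(tm.protein_id, codon_index + 1, ref_aa, alt_aa)


def select_principal_isoform(gene_id: str, catalog: IsoformCatalog) -> str:
    """Choose the single reference isoform of a gene.

    The APPRIS-style principal flag wins; absent a flag the longest
    sequence is taken, with remaining ties broken by lexicographically
    smallest protein_id so the choice is deterministic.
    """
    entries = catalog.by_gene(gene_id)
    if not entries:
        raise CatalogError(f"gene {gene_id!r} not in isoform catalog")
    flagged = [e for e in entries if e.principal]
    if flagged:
        return flagged[0].protein_id
    best = min(entries, key=lambda e: (-len(e.sequence), e.protein_id))
    return best.protein_id
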