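"""Local sequence alignment between isoforms and structure chains.

A structure chain's observed-residue sequence (derived from ATOM records,
so crystallographic gaps become alignment gaps) rarely matches the
isoform sequence exactly: tags, engineered mutations, disordered loops.
A Smith-Waterman local alignment with affine gaps reconciles the two, and
the aligned columns become a position map from isoform coordinates to
author-numbered structure residues.

Scoring defaults are the ubiquitous protein settings: BLOSUM62, gap open
11, gap extend 1, with a gap of length k costing open + k*extend.  The
unknown residue X scores 0 against everything.  Traceback ties are broken
diagonal > up > left (up = gap in the target) so outputs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "PositionMap",
    "smith_waterman",
    "build_position_map",
    "map_position",
    "align_chain",
    "load_matrix",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class AlphabetError(ValueError):
    """Sequence contains a character outside the 20 amino acids + X."""


def _matrix_to_dict(matrix) -> dict[tuple[str, str], float]:
    """Flatten a Bio.Align substitution matrix into a pair-keyed dict."""
    table: dict[tuple[str, str], float] = {}
    alphabet = matrix.alphabet
    for a in alphabet:
        for b in alphabet:
            table[(a, b)] = float(matrix[a, b])
    return table


def load_matrix(source: str) -> dict[tuple[str, str], float]:
    """Load a substitution matrix by name (e.g. ``BLOSUM62``) or from an
    NCBI-format matrix text file path."""
    try:
        mat = substitution_matrices.load(source)
    except FileNotFoundError:
        mat = substitution_matrices.read(source)
    return _matrix_to_dict(mat)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` and ``gap_extend`` are non-negative penalties; a gap of
    length k costs ``gap_open + k * gap_extend``.
    """

    matrix: dict[tuple[str, str], float] = field(
        default_factory=lambda: load_matrix("BLOSUM62")
    )
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def score(self, a: str, b: str) -> float:
        # X (unknown residue) is scored neutrally against everything
        if a == "X" or b == "X":
            return 0.0
        return self.matrix[(a, b)]


@dataclass(frozen=True)
class LocalAlignment:
    """Result of a Smith-Waterman alignment.

    ``aligned_columns`` lists 1-based (query_pos, target_pos) pairs with
    ``None`` marking a gap in that sequence; ``identity`` is the fraction
    of residue-paired columns whose residues are equal (0.0 for an empty
    alignment).
    """

    query: str
    target: str
    score: float
    aligned_columns: tuple[tuple[Optional[int], Optional[int]], ...]
    identity: float

    @property
    def is_empty(self) -> bool:
        return not self.aligned_columns


def _check_alphabet(seq: str, which: str) -> None:
    allowed = set(AA20) | {"X"}
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise AlphabetError(
                f"{which} sequence: illegal character {ch!r} at position {i}"
            )


def smith_waterman(
    query: str,
    target: str,
    scheme: ScoringScheme | None = None,
) -> LocalAlignment:
    """Optimal local alignment under affine-gap dynamic programming.

    Uses the Gotoh three-state recurrence.  When no residue pair scores
    positively the result is the empty alignment with score 0.  The
    maximal cell is the first one found scanning query-major, and
    traceback ties break diagonal > up > left, making the output
    deterministic.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(query, "query")
    _check_alphabet(target, "target")
    if scheme is None:
        scheme = ScoringScheme()

    m, n = len(query), len(target)
    NEG = -math.inf
    go = scheme.gap_open + scheme.gap_extend  # cost of opening a 1-gap
    ge = scheme.gap_extend

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (up)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (left)

    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - go, E[i - 1][j] - ge)
            F[i][j] = max(H[i][j - 1] - go, F[i][j - 1] - ge)
            diag = H[i - 1][j - 1] + scheme.score(qi, target[j - 1])
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j

    if best <= 0.0:
        return LocalAlignment(query, target, 0.0, (), 0.0)

    # traceback from (bi, bj) in state H; ties: diagonal > up > left
    cols: list[tuple[Optional[int], Optional[int]]] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0.0:
                break
            diag = H[i - 1][j - 1] + scheme.score(query[i - 1], target[j - 1])
            if h == diag:
                cols.append((i, j))
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append((i, None))
            # prefer closing the gap (return to H) on ties
            if E[i][j] == H[i - 1][j] - go:
                state = "H"
            i -= 1
        else:  # F
            cols.append((None, j))
            if F[i][j] == H[i][j - 1] - go:
                state = "H"
            j -= 1

    cols.reverse()
    paired = [(q, t) for q, t in cols if q is not None and t is not None]
    matches = sum(1 for q, t in paired if query[q - 1] == target[t - 1])
    identity = matches / len(paired) if paired else 0.0
    return LocalAlignment(query, target, best, tuple(cols), identity)


@dataclass(frozen=True)
class PositionMap:
    """Isoform position -> structure residue identifier for one chain.

    Built from the residue-paired columns of a local alignment; mismatch
    columns are mapped but recorded in ``mismatches``.  Maps whose
    alignment identity falls below the acceptance threshold carry
    ``accepted=False`` and are excluded from annotation.
    """

    protein_id: str
    structure_id: str
    chain_id: str
    mapping: dict[int, Hashable]
    mismatches: frozenset[int]
    identity: float
    accepted: bool

    def inverse(self) -> dict[Hashable, int]:
        return {rid: pos for pos, rid in self.mapping.items()}


DEFAULT_MIN_IDENTITY = 0.8


def build_position_map(
    aln: LocalAlignment,
    query_offset: int,
    structure_residues: Sequence[Hashable],
    *,
    protein_id: str = "",
    structure_id: str = "",
    chain_id: str = "",
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> PositionMap:
    """Turn aligned columns into an isoform -> residue-identifier map.

    ``query_offset`` is the 1-based isoform position of the first query
    character (1 when the whole isoform was aligned).
    ``structure_residues`` are the chain's observed residue identifiers in
    order; the alignment target must have been their one-letter sequence.
    """
    n_target = sum(1 for _, t in aln.aligned_columns if t is not None)
    if n_target > len(structure_residues):
        raise ValueError(
            f"alignment references {n_target} target positions but chain has "
            f"{len(structure_residues)} residues"
        )
    mapping: dict[int, Hashable] = {}
    mismatches: set[int] = set()
    for q, t in aln.aligned_columns:
        if q is None or t is None:
            continue
        iso_pos = q + query_offset - 1
        mapping[iso_pos] = structure_residues[t - 1]
        if aln.query[q - 1] != aln.target[t - 1]:
            mismatches.add(iso_pos)
    return PositionMap(
        protein_id=protein_id,
        structure_id=structure_id,
        chain_id=chain_id,
        mapping=mapping,
        mismatches=frozenset(mismatches),
        identity=aln.identity,
        accepted=aln.identity >= min_identity and bool(mapping),
    )


def map_position(pm: PositionMap, pos: int) -> Optional[Hashable]:
    """Mapped structure residue identifier, or ``None`` when the position
    lies in an alignment gap or outside the aligned region (never
    extrapolates)."""
    return pm.mapping.get(pos)


def align_chain(
    isoform_seq: str,
    chain_seq: str,
    chain_residues: Sequence[Hashable],
    *,
    protein_id: str = "",
    structure_id: str = "",
    chain_id: str = "",
    scheme: ScoringScheme | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> PositionMap:
    """Align a full isoform sequence against a chain's observed sequence
    and return the derived position map."""
    aln = smith_waterman(isoform_seq, chain_seq, scheme)
    return build_position_map(
        aln,
        1,
        chain_residues,
        protein_id=protein_id,
        structure_id=structure_id,
        chain_id=chain_id,
        min_identity=min_identity,
    )
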