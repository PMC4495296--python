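"""PDB structures, heavy-atom neighborhoods and interface residues.

Structures (experimental or homology models, monomers or binary
complexes) are consumed as PDB text.  Proximity is operationalized as the
minimum Euclidean distance over heavy-atom (non-hydrogen) pairs; waters
are dropped, alternate locations are resolved to the highest-occupancy
conformer, and HETATM ligands are excluded unless asked for.  Residues
keep their author numbering and insertion codes; no renumbering ever
happens, because position maps target author numbering.

Spatial queries run through a per-structure k-d tree over atom
coordinates; a quadratic brute-force scan over residue pairs would give
identical results (and does, in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, NamedTuple, TextIO, Union

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "ResidueId",
    "Structure3D",
    "Neighbor",
    "NeighborSet",
    "StructureIndexEntry",
    "parse_pdb",
    "residue_min_distance",
    "spatial_neighbors",
    "interface_residues",
    "load_structure_index",
]

DEFAULT_CUTOFF = 5.0  # Angstrom


class StructureError(ValueError):
    """Problem reading or querying a structure."""


class ResidueId(NamedTuple):
    """Author-numbered residue identity: chain, number, insertion code."""

    chain_id: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.number}{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "ResidueId":
        chain, rest = text.split("/", 1)
        num = ""
        i = 0
        if rest and rest[0] == "-":
            num, i = "-", 1
        while i < len(rest) and rest[i].isdigit():
            num += rest[i]
            i += 1
        return cls(chain, int(num), rest[i:])


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    occupancy: float
    alt_loc: str
    coords: tuple[float, float, float]


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    aa: str  # one-letter code, 'X' for non-tabulated residues
    name3: str
    atoms: list[Atom]
    is_hetatm: bool = False

    @property
    def rid(self) -> ResidueId:
        return ResidueId(self.chain_id, self.number, self.insertion_code)

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Structure3D:
    """Parsed structure: ordered chains of heavy-atom residues.

    ``chain_protein`` maps chain identifiers to protein accessions (from
    the structure index); in this scope a complex has exactly two mapped
    chains.
    """

    structure_id: str
    source: str  # "experimental" | "model"
    chains: dict[str, list[Residue]]
    chain_protein: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("experimental", "model"):
            raise StructureError(
                f"{self.structure_id}: source must be experimental|model, "
                f"got {self.source!r}"
            )
        if not self.chains:
            raise StructureError(f"{self.structure_id}: structure has no chains")

    @property
    def is_complex(self) -> bool:
        return len(self.chain_protein) == 2

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains.values():
            yield from chain

    @cached_property
    def _index(self) -> dict[ResidueId, Residue]:
        return {r.rid: r for r in self.residues()}

    def residue(self, rid: ResidueId) -> Residue:
        try:
            return self._index[rid]
        except KeyError:
            raise StructureError(
                f"{self.structure_id}: no residue {rid}"
            ) from None

    def chain_sequence(self, chain_id: str) -> tuple[str, list[ResidueId]]:
        """Observed-residue one-letter sequence and parallel identifiers.

        Derived from ATOM residues in file order, so unresolved stretches
        are simply absent (they become alignment gaps downstream).
        """
        if chain_id not in self.chains:
            raise StructureError(f"{self.structure_id}: no chain {chain_id!r}")
        residues = [r for r in self.chains[chain_id] if not r.is_hetatm]
        return "".join(r.aa for r in residues), [r.rid for r in residues]

    @cached_property
    def _atom_tree(self) -> tuple[cKDTree, np.ndarray, list[ResidueId]]:
        """k-d tree over every heavy atom, with atom -> residue lookup."""
        coords: list[tuple[float, float, float]] = []
        owner: list[int] = []
        rids: list[ResidueId] = []
        for res in self.residues():
            idx = len(rids)
            rids.append(res.rid)
            for atom in res.atoms:
                coords.append(atom.coords)
                owner.append(idx)
        arr = np.array(coords, dtype=float)
        return cKDTree(arr), np.array(owner, dtype=int), rids


def _one_letter(name3: str) -> str:
    info = gemmi.find_tabulated_residue(name3)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in by_name:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > by_name[atom.name].occupancy:
            by_name[atom.name] = atom
    return [by_name[n] for n in order]


def parse_pdb(
    stream: Union[str, TextIO],
    structure_id: str,
    source: str = "experimental",
    chain_protein: dict[str, str] | None = None,
    *,
    include_hetatm: bool = False,
) -> Structure3D:
    """Parse PDB-format text into a heavy-atom :class:`Structure3D`.

    Hydrogens (and deuterium) and waters are dropped; alternate locations
    collapse to the highest-occupancy conformer (ties keep the first
    listed); residues left with no atoms disappear.  Only the first MODEL
    of a multi-model file is read.  HETATM ligand residues are excluded
    unless ``include_hetatm`` is set.
    """
    text = stream if isinstance(stream, str) else stream.read()
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{structure_id}: unparseable PDB text: {exc}") from None
    if len(st) == 0:
        raise StructureError(f"{structure_id}: no ATOM records found")
    model = st[0]  # first MODEL only

    chains: dict[str, list[Residue]] = {}
    n_atoms = 0
    for g_chain in model:
        residues: list[Residue] = []
        for g_res in g_chain:
            if g_res.is_water():
                continue
            is_het = g_res.het_flag == "H"
            if is_het and not include_hetatm:
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    occupancy=float(a.occ),
                    alt_loc=(a.altloc if a.altloc != "\0" else ""),
                    coords=(float(a.pos.x), float(a.pos.y), float(a.pos.z)),
                )
                for a in g_res
                if not a.element.is_hydrogen
            ]
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue  # e.g. hydrogen-only residue after filtering
            n_atoms += len(atoms)
            icode = g_res.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=g_chain.name,
                    number=g_res.seqid.num,
                    insertion_code=icode,
                    aa=_one_letter(g_res.name),
                    name3=g_res.name,
                    atoms=atoms,
                    is_hetatm=is_het,
                )
            )
        if residues:
            chains[g_chain.name] = residues
    if n_atoms == 0:
        raise StructureError(f"{structure_id}: no ATOM records found")
    return Structure3D(
        structure_id=structure_id,
        source=source,
        chains=chains,
        chain_protein=dict(chain_protein or {}),
    )


def residue_min_distance(r1: Residue, r2: Residue) -> float:
    """Minimum Euclidean distance (A) over all heavy-atom pairs; symmetric."""
    if not r1.atoms or not r2.atoms:
        raise StructureError("residue without heavy atoms in distance query")
    a = r1.coord_array()
    b = r2.coord_array()
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


@dataclass(frozen=True)
class Neighbor:
    residue_id: ResidueId
    distance: float
    relation: str  # "intra_chain" | "interface_partner"
    sequence_adjacent: bool = False


@dataclass(frozen=True)
class NeighborSet:
    center: ResidueId
    cutoff: float
    neighbors: tuple[Neighbor, ...]

    def residue_ids(self) -> list[ResidueId]:
        return [n.residue_id for n in self.neighbors]


def spatial_neighbors(
    s: Structure3D,
    center: ResidueId,
    cutoff: float = DEFAULT_CUTOFF,
) -> NeighborSet:
    """All residues with a heavy atom within ``cutoff`` A of the center
    residue (minimum heavy-atom distance, boundary inclusive).

    Each neighbor is labeled ``intra_chain`` or ``interface_partner`` by
    chain membership; same-chain residues with author numbers differing
    by 1 are additionally flagged ``sequence_adjacent`` so downstream
    rules can discount trivial backbone contacts.  Sorted by distance,
    then residue identifier.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    center_res = s.residue(center)  # raises on unknown residue
    tree, owner, rids = s._atom_tree
    center_idx = rids.index(center)

    candidates: set[int] = set()
    for atom in center_res.atoms:
        for ai in tree.query_ball_point(atom.coords, cutoff):
            candidates.add(int(owner[ai]))
    candidates.discard(center_idx)

    neighbors: list[Neighbor] = []
    for idx in candidates:
        rid = rids[idx]
        d = residue_min_distance(center_res, s.residue(rid))
        if d > cutoff:
            continue
        same_chain = rid.chain_id == center.chain_id
        neighbors.append(
            Neighbor(
                residue_id=rid,
                distance=d,
                relation="intra_chain" if same_chain else "interface_partner",
                sequence_adjacent=same_chain and abs(rid.number - center.number) == 1,
            )
        )
    neighbors.sort(key=lambda n: (n.distance, n.residue_id))
    return NeighborSet(center=center, cutoff=cutoff, neighbors=tuple(neighbors))


def interface_residues(
    s: Structure3D,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[tuple[ResidueId, ResidueId, float]]:
    """Cross-chain residue pairs within ``cutoff`` A (min heavy-atom
    distance, inclusive), sorted by the pair of residue identifiers.

    The interface residue set of chain A is the projection onto first
    components; swapping the chains mirrors the pairs.
    """
    if chain_a == chain_b:
        raise ValueError("interface requires two distinct chains")
    for c in (chain_a, chain_b):
        if c not in s.chains:
            raise StructureError(f"{s.structure_id}: no chain {c!r}")

    res_b = [r for r in s.chains[chain_b] if not r.is_hetatm]
    coords_b = []
    owner_b = []
    for i, r in enumerate(res_b):
        for atom in r.atoms:
            coords_b.append(atom.coords)
            owner_b.append(i)
    tree_b = cKDTree(np.array(coords_b, dtype=float))
    owner_b = np.array(owner_b, dtype=int)

    pairs: dict[tuple[ResidueId, ResidueId], float] = {}
    for r_a in s.chains[chain_a]:
        if r_a.is_hetatm:
            continue
        cand: set[int] = set()
        for atom in r_a.atoms:
            for ai in tree_b.query_ball_point(atom.coords, cutoff):
                cand.add(int(owner_b[ai]))
        for i in cand:
            d = residue_min_distance(r_a, res_b[i])
            if d <= cutoff:
                pairs[(r_a.rid, res_b[i].rid)] = d
    return sorted((ra, rb, d) for (ra, rb), d in pairs.items())


@dataclass(frozen=True)
class StructureIndexEntry:
    structure_id: str
    file: str
    source: str
    chain_protein: dict[str, str]


def load_structure_index(
    stream: Union[TextIO, Iterable[str]],
) -> list[StructureIndexEntry]:
    """Read the structure index TSV.

    Columns: ``structure_id file source chain protein_id``, one row per
    mapped chain; rows of one structure share file and source.
    """
    rows: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("structure_id"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise StructureError(
                f"line {lineno}: expected 5 columns in structure index, "
                f"got {len(fields)}"
            )
        sid, path, source, chain, protein = fields
        if source not in ("experimental", "model"):
            raise StructureError(
                f"line {lineno}: source must be experimental|model, got {source!r}"
            )
        if sid not in rows:
            rows[sid] = {"file": path, "source": source, "chain_protein": {}}
            order.append(sid)
        elif rows[sid]["file"] != path or rows[sid]["source"] != source:
            raise StructureError(
                f"line {lineno}: structure {sid} has inconsistent file/source"
            )
        rows[sid]["chain_protein"][chain] = protein
    return [
        StructureIndexEntry(sid, rows[sid]["file"], rows[sid]["source"],
                            rows[sid]["chain_protein"])
        for sid in order
    ]
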