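"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use different algorithms / factorizations
than the package code: a match-state-centric affine-gap recurrence for
local alignment, a fully vectorized all-pairs distance matrix for
geometry, and Biopython whole-sequence splicing/translation for the
genomic path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from varcontact.alignment import ScoringScheme
from varcontact.structure3d import Atom, Residue, Structure3D


# ---------------------------------------------------------------------------
# local-alignment oracle: match-state recurrence, score only

def sw_oracle_score(query: str, target: str, scheme: ScoringScheme) -> float:
    """Optimal local affine-gap score by an exhaustive DP over match-ending
    alignments: M(i,j) is the best alignment ending with qi aligned to tj;
    gap states carry open + k*extend costs.  Independent of the package's
    Gotoh H/E/F formulation."""
    m, n = len(query), len(target)
    NEG = -math.inf
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Gq = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming query
    Gt = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming target
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            prev = max(0.0, M[i - 1][j - 1], Gq[i - 1][j - 1], Gt[i - 1][j - 1])
            M[i][j] = scheme.score(query[i - 1], target[j - 1]) + prev
            Gq[i][j] = max(M[i - 1][j] - go, Gq[i - 1][j] - ge)
            Gt[i][j] = max(M[i][j - 1] - go, Gt[i][j - 1] - ge)
            best = max(best, M[i][j])
    return best


def score_from_columns(aln, scheme: ScoringScheme) -> float:
    """Re-score an alignment from its column list: substitution scores for
    paired columns, open + len*extend per maximal same-sequence gap run."""
    total = 0.0
    run: str | None = None
    for q, t in aln.aligned_columns:
        if q is not None and t is not None:
            total += scheme.score(aln.query[q - 1], aln.target[t - 1])
            run = None
        else:
            kind = "q" if q is None else "t"
            if kind != run:
                total -= scheme.gap_open
                run = kind
            total -= scheme.gap_extend
    return total


# ---------------------------------------------------------------------------
# geometry oracle: vectorized all-pairs residue min-distance matrix

def residue_distance_matrix(s: Structure3D) -> tuple[np.ndarray, list]:
    """(n_res x n_res) matrix of minimum heavy-atom distances, brute force
    over the full atom-atom distance matrix, plus the residue-id order."""
    coords, owner, rids = [], [], []
    for res in s.residues():
        idx = len(rids)
        rids.append(res.rid)
        for atom in res.atoms:
            coords.append(atom.coords)
            owner.append(idx)
    arr = np.asarray(coords)
    owner = np.asarray(owner)
    diff = arr[:, None, :] - arr[None, :, :]
    d_atom = np.sqrt((diff ** 2).sum(axis=2))
    n = len(rids)
    out = np.full((n, n), np.inf)
    for i in range(n):
        rows = d_atom[owner == i]
        for j in range(n):
            out[i, j] = rows[:, owner == j].min()
    return out, rids


def random_structure(seed: int, n_residues: int, box: float | None = None,
                     two_chains: bool = True) -> Structure3D:
    """Random point-cloud structure: 1-3 heavy atoms per residue in a box
    sized for realistic contact density."""
    rng = np.random.default_rng(seed)
    if box is None:
        box = max(10.0, 4.0 * n_residues ** (1 / 3))
    chains: dict[str, list[Residue]] = {}
    chain_ids = ["A", "B"] if two_chains else ["A"]
    per_chain = n_residues // len(chain_ids)
    for chain_id in chain_ids:
        residues = []
        for num in range(1, per_chain + 1):
            center = rng.uniform(0, box, size=3)
            n_atoms = int(rng.integers(1, 4))
            atoms = []
            for k in range(n_atoms):
                xyz = center + rng.normal(0, 0.8, size=3)
                atoms.append(Atom(
                    name=f"C{k}", element="C", occupancy=1.0, alt_loc="",
                    coords=(float(xyz[0]), float(xyz[1]), float(xyz[2]))))
            residues.append(Residue(
                chain_id=chain_id, number=num, insertion_code="",
                aa="A", name3="ALA", atoms=atoms))
        chains[chain_id] = residues
    return Structure3D("RND", "experimental", chains,
                       {c: f"P_{c}" for c in chain_ids})


def transform_structure(s: Structure3D, rotation: np.ndarray,
                        translation: np.ndarray) -> Structure3D:
    chains = {}
    for cid, residues in s.chains.items():
        out = []
        for r in residues:
            atoms = [
                Atom(a.name, a.element, a.occupancy, a.alt_loc,
                     tuple((rotation @ np.asarray(a.coords) + translation)
                           .tolist()))
                for a in r.atoms
            ]
            out.append(Residue(r.chain_id, r.number, r.insertion_code,
                               r.aa, r.name3, atoms, r.is_hetatm))
        chains[cid] = out
    return Structure3D(s.structure_id, s.source, chains, dict(s.chain_protein))


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ---------------------------------------------------------------------------
# shared bundles

@pytest.fixture(scope="session")
def validation_bundle(tmp_path_factory):
    """Default labelled validation scenario written to disk once."""
    from varcontact.fixtures import default_validation_spec, generate_validation_set

    out_dir = tmp_path_factory.mktemp("valset")
    spec = default_validation_spec(seed=0)
    paths = generate_validation_set(spec, str(out_dir))
    return spec, paths


@pytest.fixture(scope="session")
def blosum_scheme():
    return ScoringScheme()
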