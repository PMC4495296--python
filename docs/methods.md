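# Methods

## Problem and model

`varcontact` interprets single-amino-acid variants in their 3D context.
A substitution is given directly (`protein_id, position, ref_aa, alt_aa`)
or derived from a genomic SNV through a transcript model; it is then
placed onto every available structure of the protein — experimental
crystal structures or homology models, monomers or binary complexes —
and annotated with (i) the sequence features at the mutated position,
(ii) the features of every residue in spatial contact with it, including
residues of the partner chain in a complex, (iii) whether the residue is
part of a protein–protein interface, (iv) recurrent somatic mutations at
the position, and (v) pre-computed damage predictions. A disjunctive
rule turns this evidence into a damaging/neutral/no-evidence call, and a
labelled set of variants is scored with a confusion matrix (accuracy,
precision, recall, MCC).

The underlying assumption is the standard driver-mutation heuristic:
variants that hit functional sites, or residues whose spatial
neighbourhood contains functional sites or interface contacts, are far
more likely to be damaging than variants in featureless regions.

## Coordinates, translation

All coordinates are 1-based inclusive: genomic positions, CDS offsets
(from the first base of the start codon; phase 0 assumed, CDS length must
be divisible by 3), and protein positions. On the minus strand the CDS
reads 3'→5' along genomic coordinates with complemented bases. Codons
are translated with the standard genetic code; stop codons are `*`, and
stop-gain substitutions are carried through flagged rather than dropped.
Intronic/UTR SNVs get an explicit non-coding verdict; synonymous changes
an explicit synonymous verdict. Reference-allele disagreements with the
genome raise an error naming the position.

Principal-isoform choice: the catalog's principal flag wins; otherwise
the longest sequence; remaining ties go to the lexicographically smallest
accession, so the choice is deterministic. Variants on non-principal
isoforms are annotated against the queried isoform and flagged
`non_principal`.

## Sequence–structure reconciliation

Structure chains rarely match isoform sequences exactly (tags, engineered
mutations, unresolved loops), so each mapped chain is reconciled with its
isoform by Smith–Waterman local alignment with affine gaps. The chain
sequence is taken from observed ATOM residues, so density gaps become
alignment gaps naturally.

Scoring defaults are the ubiquitous protein settings — BLOSUM62, gap open
11, gap extend 1 — all configurable; matrices can also be read from
NCBI-format text files. A gap of length k costs `open + k·extend`
(BLAST-style existence/extension). The unknown residue X scores 0
against everything. Traceback ties break diagonal > up > left and the
maximal cell is the first found scanning query-major, so outputs are
bit-reproducible.

Residue-paired alignment columns become the position map
(isoform position → author residue number + insertion code); mismatch
columns are mapped but flagged. Maps with identity below 0.8 (default)
are rejected and the structure is skipped with a logged reason — this
guards against annotating through spurious local hits. Positions in
gaps or outside the aligned region return an explicit unmapped verdict;
the map never extrapolates.

## Geometry

"Close physical proximity" is the minimum Euclidean distance over
heavy-atom (non-hydrogen) pairs, with the default cutoff 5.0 Å applied
inclusively (a contact at exactly 5.0 Å counts). Hydrogens and waters
are removed at parse time; alternate locations collapse to the
highest-occupancy conformer (ties keep the first listed); HETATM ligands
are excluded from neighbour sets unless explicitly included; only the
first MODEL of multi-model files is read. Author numbering is the
residue identity throughout.

Neighbour queries run through a per-structure k-d tree over atom
coordinates (scipy cKDTree) with exact min-distance confirmation per
candidate residue; the test suite verifies equality with a quadratic
all-pairs scan, plus neighbour symmetry, cutoff monotonicity and
rigid-motion invariance (1e-6 Å tolerance). Interface residues are the
cross-chain residue pairs within the cutoff; a residue's interface flag
is membership in the projection of that pair set. Same-chain neighbours
with |Δ author number| = 1 are kept but labelled `sequence_adjacent` so
the call rule can discount trivial backbone contacts.

## The damaging-call rule

No single published decision rule is canonical for this evidence shape,
so the default rule is an explicit, auditable disjunction with every
clause toggleable:

- **d1** — the position itself carries a site feature (ptm, catalytic,
  binding, mutagenesis site; domains and other ranges do not fire),
- **d2** — a residue in spatial contact carries a site feature
  (sequence-adjacent contacts excluded by default, to avoid rediscovering
  linear motifs as "spatial" evidence),
- **d3** — the mapped residue is an interface residue,
- **d4** — at least one somatic record at the position,
- **d5** — a strict majority of non-unknown predictor calls is damaging
  (ties do not fire; predictions join on protein, position and alt
  residue, somatic records on protein and position only).

Each fired clause appends a `clause:detail` evidence string; evidence is
non-empty exactly when the call is damaging. With no fired clause the
call is neutral if any prediction record exists, else no_evidence.
Evaluation counts no_evidence as a negative call (configurable). Metrics
are stored at full precision and displayed at 2 decimals; any metric
with a zero denominator is NaN, never 0.

## Synthetic data

The fixtures module generates everything the pipeline consumes.
Structures are deliberately schematic: straight Cα/Cβ traces with 3.8 Å
spacing, parallel chains 25 Å apart (beyond any cutoff in use), and
individually repositioned partner residues that sit at an exact requested
minimum heavy-atom distance from a chosen residue of the first chain.
This drives every distance code path with hand-checkable expectations; it
does **not** emulate realistic packing density, side chains, crystal
artefacts, or the alignment noise of real isoform/SEQRES discrepancies —
chain sequences equal isoform sequences in generated bundles, so the
alignment step is exercised at identity 1.0 there (lower-identity and
mismatch behaviour is covered by dedicated alignment tests instead).
Passing the end-to-end fixture therefore demonstrates the joining,
geometry and rule logic, not performance on real structures.

The default labelled scenario has 14 pathogenic and 10 neutral variants
on a two-chain complex. Eleven pathogenic variants carry planted
evidence (3 catalytic-site, 2 partner-chain binding-site contacts at
4.2 Å, 2 bare interface contacts at 4.5 Å, 2 recurrent somatic positions,
2 damaging predictor majorities) and three are deliberately evidence-free,
modelling pathogenic mechanisms invisible to annotation; the ten neutral
variants sit in feature-free regions, two with all-tolerated predictions.
The implied confusion matrix is tp=11, fp=0, fn=3, tn=10 — the unique
non-negative matrix on a 14/10 design consistent with accuracy 0.88,
recall 0.79, precision 1.00, MCC 0.78 — and the pipeline reproduces it
exactly. The generator is seed-deterministic (sequences change with the
seed; the planted design does not), and generated files are byte-identical
across runs with the same seed.

Transcript-model scenarios build a random multi-exon CDS (ATG start, no
internal stop) embedded in random flanking sequence, on either strand.

## Numerical and design choices

- Distances are exact (no squared-distance shortcuts in comparisons);
  the inclusive cutoff uses `<=`.
- Report rows are ordered experimental before model, then by structure
  id; neighbour lists by distance then residue id; all serialization is
  deterministic, so re-running a configuration is byte-identical.
- On homomeric complexes (one protein on both chains) one row per
  structure is emitted, from the lowest chain id whose accepted map
  covers the position.
- Problem sizes in the test suite — 500 random alignment pairs (length
  ≤ 12), 50 random structures of 40–200 residues, 20 random transcript
  models — were chosen to exercise the oracle-equivalence properties
  densely while keeping the suite fast.

## Known limitations

- Only SNV-scale substitutions; no indels, MNVs, or splice consequences.
- PDB format only; mmCIF, assemblies with more than two mapped chains,
  symmetry expansion, and solvent accessibility / ΔΔG are out of scope.
- The damaging-call rule is a documented stand-in, not a claim to
  replicate any published per-variant decision procedure.
- Damage predictor scores are consumed from tables, never computed.
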