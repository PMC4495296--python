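# varcontact

Structural annotation of single-amino-acid variants at protein–protein
interfaces.

Interpreting a missense variant from sequence features alone misses a
whole class of mechanism: a mutated residue may sit in, or right next to,
a catalytic site, a binding site, a post-translational modification site,
or the interface of a protein complex, even when nothing is annotated at
the position itself. `varcontact` is for computational biologists who
have variant calls (protein-level substitutions or genomic SNVs), local
snapshots of annotation tables, and PDB structures of the proteins and
their binary complexes, and who want per-variant structural context and
an auditable damaging/neutral call.

## What it computes

For a substitution on isoform *p* at position *i*:

1. **Translation** (genomic input only): the SNV is mapped through a
   transcript model, strand-aware, codon index ⌊(cds_offset−1)/3⌋+1,
   standard genetic code; the principal isoform per gene is selected by
   flag, then length, then accession.
2. **Sequence–structure reconciliation**: Smith–Waterman local alignment
   (affine gaps; BLOSUM62, open 11, extend 1 by default) between the
   isoform and each structure chain's observed residues gives a position
   map *i* → author residue number; maps below 80% identity are rejected.
3. **Geometry**: residues in spatial contact are those with minimum
   heavy-atom distance ≤ 5 Å (inclusive, configurable); interface
   residues are the cross-chain contact pairs of a complex. Contacted
   residues are mapped back to their own isoform coordinates and their
   features joined in.
4. **Call**: damaging iff any enabled clause fires — direct functional
   site (d1), site in spatial contact (d2), interface residue (d3),
   somatic recurrence (d4), strict damaging majority of predictor calls
   (d5) — each contributing an evidence string.
5. **Evaluation**: calls against pathogenic/neutral labels give a
   confusion matrix with accuracy, precision, recall and

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate the bundled synthetic validation scenario (a two-chain complex
with 14 pathogenic and 10 neutral labelled variants, with functional
sites, interface contacts, somatic records and predictions planted), run
the pipeline, and score it:

```
$ varcontact fixtures --out-dir demo/bundle --seed 0
$ varcontact annotate \
    --variants    demo/bundle/variants.tsv \
    --structures  demo/bundle/structure_index.tsv \
    --features    demo/bundle/features.tsv \
    --somatic     demo/bundle/somatic.tsv \
    --predictions demo/bundle/predictions.tsv \
    --isoforms    demo/bundle/isoforms.tsv \
    --out demo/report.tsv
variants: 24  substitutions: 24  mapped: 24  rows: 24  damaging: 11

$ varcontact evaluate --labels demo/bundle/labels.tsv --report demo/report.tsv
tp=11 fp=0 fn=3 tn=10 | accuracy: 0.88, recall: 0.79, precision: 1.00, MCC: 0.78
```

All 24 variants map onto the structure; 11 are called damaging — exactly
the pathogenic variants with visible structural/annotation evidence —
and the three pathogenic variants planted without evidence become false
negatives, so precision is perfect while recall is 11/14. One report row
(variant at a planted catalytic site):

```
P1  70  M  A  S1  experimental  A  A/70  0  domain:PFX1@10-110;catalytic_site:active@70-70  ...  damaging  d1:catalytic_site@70
```

Columns: variant, structure/chain/mapped residue, interface flag, direct
features, neighbour features with distances and chain relation, somatic
matches, predictions, flags, call, evidence. `--format json` writes the
same rows nested.

The library surface mirrors the CLI: `parse_variants`,
`translate_genomic_variant`, `smith_waterman`, `build_position_map`,
`parse_pdb`, `spatial_neighbors`, `interface_residues`,
`annotate_variant`, `classify_variant`, `compute_metrics`, `evaluate`,
and the generators in `varcontact.fixtures`.

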