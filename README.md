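# estcurate

Curation and digital-expression mining of clone-named EST catalogs.

Large EST collections are built by sequencing 96-well plates of cDNA clones,
and the deposited clone names (e.g. `CA48LN09IF-A9, 5'end`) encode the
physical workflow: library stem, batch, plate, well, and read direction.
`estcurate` reconstructs that geometry and uses it to curate and mine the
catalog:

- **est_catalog** (`estcurate.catalog`) — clone-name parsing, 96-well
  geometry, plate sheets (the ordered gene-ID vector of one plate +
  direction), and TSV/YAML catalog I/O.
- **redundancy_collapse** (`estcurate.collapse`) — groups re-sequenced reads
  of one clone (bidirectional or same-direction) so every clone is counted
  exactly once; resolves conflicting gene assignments by confidence; reports
  multiplicity histograms and disagreement rates.
- **plate_qc** (`estcurate.plateqc`) — a dot-plot algorithm over gene-ID
  plate sheets: diagonal runs in the binary match matrix reveal true plate
  pairings and their offsets. Detects well slips (piecewise offsets),
  duplicated/triplicated plates, swapped plate pairings, partial
  duplications, and plates copied across libraries, and emits a correction
  plan (merge / exclude / re-pair / realign) that restores true unique-clone
  counts.
- **frequency_profile** (`estcurate.frequency`) — per-gene frequencies in
  transcripts per 10,000, with size-weighted combination of same-type
  libraries (identical to pooling counts).
- **diff_expression** (`estcurate.detest`) — chi-squared goodness-of-fit
  across ≥2 groups (expected counts proportional to library sizes, df=g−1)
  and the exact conditional (Audic–Claverie) test for library pairs,
  computed in log space; filters, Bonferroni control, and enrichment
  direction calls.
- **downstream_stats** (`estcurate.downstream`) — hierarchical clustering of
  frequency profiles with (1 − Pearson) distance and average linkage
  (UPGMA), Newick export, log2-ratio tables, and directional-concordance
  reports (Spearman/Pearson + quadrant counts).
- **synthetic_data** (`estcurate.simulate`) — generators with exact ground
  truth: model transcriptomes (log-normal/Zipf, fold changes, normalization
  flattening), clone/plate sequencing plans, per-read misannotation, and
  literal injection of every plate-level error class, plus named end-to-end
  scenarios.

## CLI

```sh
estcurate simulate --scenario table2_mixed --seed 17 -o fixtures/
estcurate catalog validate fixtures/table2_mixed.catalog.tsv
estcurate qc fixtures/table2_mixed.catalog.tsv -o plan.json --report relations.tsv
estcurate collapse fixtures/table2_mixed.catalog.tsv --plan plan.json -o unique.tsv
estcurate freq unique.tsv --groups fixtures/table2_mixed.libraries.yaml -o freq.tsv
estcurate de freq.tsv --test chi2 -o de.tsv
estcurate de freq.tsv --test ac --m 3333 -o de_ac.tsv   # two-group tables
estcurate cluster freq.tsv -k 4 -o clusters.tsv --newick tree.nwk
estcurate concord ratios_a.tsv ratios_b.tsv -o concordance.tsv
```

Scenarios: `clean`, `table2_mixed` (every injected error class),
`root_vs_nonroot` (paper-scale enrichment power), `four_group_de`
(clusterable four-group profiles).

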