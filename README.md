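# phylopop

Phylogeographic analysis of aligned nucleotide sequence data, built as one
tested pipeline:

- **io**: FASTA alignment and population-map reading/validation, polymorphic
  and parsimony-informative site summaries.
- **distances**: Kimura two-parameter and raw-difference kernels, full
  distance matrices (pairwise deletion, saturation flagging), within/between
  population summaries.
- **haplotypes**: complete-deletion haplotype collapsing, unbiased gene
  diversity h with Nei's sampling variance, nucleotide diversity pi, and
  HS/HT/GST/NST differentiation with a permutation test of NST > GST.
- **structure**: two- and three-level AMOVA on squared molecular distances
  with level-appropriate permutation schemes, pairwise FST, a simulated-
  annealing SAMOVA search over Gabriel-graph-contiguous partitions, and the
  Mantel test.
- **network**: median-joining haplotype networks (minimum spanning network
  plus consensus median vectors, degree-pruned), with edge-list export.
- **demography**: Tajima's D and Fu's Fs with coalescent-simulation
  p-values, mismatch distributions, sudden-expansion model fitting (SSD
  minimization + parametric bootstrap, Harpending's raggedness), and
  expansion-time conversion t = tau/(2u) with u = mu * k * g.
- **barcode**: barcoding-gap analysis and leave-one-out identification with
  minimum-distance (MD) and best-close-match (BCM) classifiers, bootstrap-
  replicated success rates with 95% CIs.
- **simulate**: a structured-coalescent simulator (island model, two deme
  groups, instantaneous expansion, finite-sites K2P mutation) plus a
  23-deme two-refugium preset mirroring the bundled survey data.
- **datasets**: the published 23-population / 236-individual COI haplotype
  frequency survey used for desk-scale verification.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-count
diversity values, expansion-time endpoints, and property-based checks of
AMOVA/SAMOVA/neutrality statistics/median networks against independent
oracles at reduced replicate counts).

## CLI

```sh
phylopop simulate --seed 1 --outdir sim/          # two-refugium preset
phylopop collapse --alignment sim/alignment.fasta \
    --popmap sim/population_map.csv --out haplotypes.json
phylopop diversity ... | differentiation ... | structure ... | samova ... \
    | network ... | demography ... | barcode ...
phylopop run-all config.yaml                       # full pipeline
```

A pipeline config is a flat YAML mapping (`alignment`, `population_map`,
`outdir`, `seed`, `stages`, permutation/bootstrap counts, `mu`/`k_sites`/
`generation_time`); every stage writes self-describing JSON/TSV artifacts,
and all randomness derives from the single master seed.

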