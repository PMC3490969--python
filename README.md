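# kelppop

Population-genetic differentiation and mitochondrial recombination analysis
for kelp multilocus alignments.

## The problem

Morphologically drastic varieties of the kelp *Saccharina japonica* — the
typical (TYP), deep-water "longipes" (LON) and shallow-water (SHA) forms —
may be phenotypic plasticity or cryptic species. Resolving this takes a
multilocus genetic analysis: a concatenated alignment of plastid (rbcLS,
1,822 bp), mitochondrial (COI, 1,788 bp) and nuclear (ITS, 676 bp) gene
regions, a catalogue of lineage-diagnostic variation (fixed single-nucleotide
differences and fixed length polymorphisms), differentiation statistics with
permutation significance, sliding-window divergence, and neighbor-joining
trees with bootstrap support. A complication makes the standard 5'-COI
"barcode" unreliable here: interspecific recombination in COI, detectable as
segment-dependent divergence and phylogenetic discordance, with breakpoints
and parental lineages recoverable from informative-site scans.

`kelppop` implements this whole workflow as a tested Python package for
anyone analysing two-lineage differentiation or gene-internal recombination
in small multilocus datasets.

## The statistics at its core

* π, the mean pairwise per-site difference within a group, and
  D<sub>xy</sub>, the mean across groups, under pairwise deletion, with
  seeded site-bootstrap standard errors; p-distance by default, JC69 / K2P /
  T92 corrections optional.
* Hudson F<sub>st</sub> = 1 − H<sub>w</sub>/H<sub>b</sub> and
  K<sub>st</sub> = 1 − K<sub>s</sub>/K<sub>t</sub>, with label-permutation
  P-values of the form (1+k)/(1+N).
* Saitou–Nei neighbor joining with deterministic tie-breaking, bootstrap
  bipartition support, and Robinson–Foulds comparison.
* MaxChi: χ² = m(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)) over partitions of the
  informative sites of a (target, parent, parent) triplet, with permutation
  significance, exhaustive triplet search under Bonferroni control,
  two-changepoint breakpoint localisation, major/minor parent assignment,
  and a PHYLPRO-style correlation profile.
* A synthetic-data generator that plants fixed differences, indels and
  spliced recombinants with an exact, self-checked truth record.

See `docs/methods.md` for definitions, conventions and limitations.

## Worked example

Simulate the study-structured dataset (two lineages, 17 vs 8 samples, three
partitions, seven fixed indels) and analyse it:

```bash
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_site_catalogue.py
python analysis/03_divergence_profiles.py --seed 1
python analysis/04_differentiation_tests.py --seed 1
```

prints

```
segregating sites: 111
fixed differences between lineages: 109
indel events: 7, fixed between lineages: 7
pi TYP-lineage: 0.000055
pi SHA-lineage: 0.000000
Dxy concatenate: 0.0256 +- 0.0024
Dxy rbcLS: 0.0089 +- 0.0022
Dxy COI: 0.0481 +- 0.0052
Dxy ITS: 0.0106 +- 0.0041
Fst between lineages: 0.9982 (P = 0.000999)
Kst between lineages: 0.9968 (P = 0.000999)
Fst within TYP-lineage (control): -0.1250 (P = 0.955)
```

Read: the two lineages are separated by 109 fixed substitutions and 7 fixed
length polymorphisms while each is nearly monomorphic (π ≈ 1e-4) —
species-level structure (F<sub>st</sub> ≈ 1 at the permutation floor) — and
COI is the discriminating marker (D<sub>xy</sub> ≈ 4.8% vs ≈ 1% elsewhere).
The within-lineage control shows what no structure looks like.

The recombination analysis (`analysis/06_recombination_scan.py --seed 1`)
splices a 542-bp donor segment (columns 686–1227) between lineages diverged
~14% in COI and recovers it:

```
event: REC1 [678, 1231] (554 bp), major TYP03, minor SHA01, corrected P = 0.0434
PHYLPRO minimum: r = -0.999 at column 708
5' tree: recombinant's nearest neighbor is TYP01
3' tree: recombinant's nearest neighbor is SHA03
RF(5', 3') = 4
```

— one significant event with breakpoints within a few columns of truth, and
the recombinant switching lineages between the 5'-barcode tree and the
3'-segment tree: exactly why a 5'-only barcode can misplace taxa with
hybrid history. `analysis/07_segment_contrast.py` reproduces the aggregate
5'-vs-3' divergence contrasts (means 0.0380 vs 0.1579, ratio 4.2, paired-t
P = 0.0001 for the close-kelp comparisons) from the bundled per-pair table.

The same workflow runs end-to-end from a YAML config via the CLI:

```bash
kelppop run config.yaml      # or: kelppop simulate / sites / recomb / ...
```

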