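# Methods

`kelppop` re-implements, as a tested analysis pipeline, the population-genetic
and recombination toolkit used to resolve morphological forms of the kelp
*Saccharina japonica*: a concatenated three-partition alignment (plastid
rbcLS, mitochondrial COI, nuclear ITS), site-level catalogues of lineage
differences, differentiation statistics with permutation tests, sliding-window
divergence, neighbor-joining trees with bootstrap support, and a suite of
recombination detectors for the interspecific COI recombination signal.

## Data model and coordinates

Alignments are equal-length nucleotide rows over `A C G T`, gap `-`, `N` and
the IUPAC ambiguity letters. Coordinates are **1-based inclusive** in every
file, report and public signature, and 0-based half-open internally
(`start_internal = start_report − 1`). Gaps and ambiguity codes are missing
states throughout: they are never alleles, and all distance statistics use
**pairwise deletion** — a column enters a pair's comparison only when both
rows carry an unambiguous base. This matches the "ignoring indels" convention
of the classic intraspecific-analysis packages and is robust to comparator
sequences of unequal coverage.

## Variation catalogue

* **Segregating sites**: columns with ≥ 2 distinct non-missing bases among the
  analysed rows.
* **Fixed differences**: columns where each group is monomorphic (over its
  non-missing states) for a different base; columns where either group is
  entirely missing are skipped so coverage gaps cannot create artifact calls.
* **Indel events**: a maximal run of gap columns sharing an identical
  per-sample presence pattern is one event; adjacent runs with different
  patterns are separate events. This makes counts of "fixed length
  polymorphisms" (presence uniform within each group, different between
  groups) well-defined. Event kind (insertion/deletion) is read relative to a
  stated reference row.
* **Nucleotide diversity π**: the mean over unordered within-group pairs of
  (differences / comparable sites). A pair with zero comparable sites is an
  error naming the pair, never a silent NaN.

## Divergence

Pairwise distances report the raw proportion `p = P + Q` (transitions A↔G,
C↔T give `P`; the rest `Q`) and a model correction:

* JC69: `d = −(3/4)·ln(1 − 4p/3)`
* K2P: `d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q)`
* T92: `d = −h·ln(1 − P/h − Q) − ((1−h)/2)·ln(1 − 2Q)` with
  `h = 2θ(1−θ)`, θ the pooled GC content of the pair.

A correction whose logarithm argument is non-positive raises a saturation
error naming the pair and model. **Dxy** is the mean distance over all
cross-group pairs; its standard error is the standard deviation of Dxy over
seeded column-bootstrap replicates (default 1,000), implemented as multinomial
column weights so the whole bootstrap is a single matrix product. The
**default model for all reported Dxy is the uncorrected p-distance**: the
study-scale divergences (1–16%) are printed on the uncorrected scale, which
is also the convention of the DnaSP-style tools this analysis mirrors;
corrected models are options, and gamma rate-variation corrections are out of
scope. Sliding windows (defaults 100/1 at concatenate scale, 50/10 at gene
scale) report per-window Dxy at window midpoints; a pair without comparable
sites drops out of that window's mean and a window with no comparable pair is
NaN.

## Differentiation

Hudson-style `Fst = 1 − Hw/Hb`, with `Hw` the mean per-site difference over
all within-group pairs pooled (an alternative group-mean weighting is
available and named in outputs) and `Hb` the mean over cross pairs.
`Kst = 1 − Ks/Kt` with `Ks = (n₁K₁ + n₂K₂)/(n₁+n₂)` and `Kt` the pooled mean
pairwise difference. Note this is the plain (untransformed) Kst; tools that
report the log-transformed K\*st variant give smaller values on strongly
diverged data. Significance comes from shuffling group labels over the pooled
sample (sizes preserved) with `p = (1 + #{permuted ≥ observed})/(1 + N)` —
never zero, so reports print bounds when no permutation reaches the observed
value. Default 1,000 permutations, all seeded.

## Trees

Neighbor joining is authored in-package so its determinism is under test
control: Saitou–Nei Q-criterion, ties broken on the lowest row-major index
pair, negative branch lengths clamped to zero with the deficit moved to the
sibling branch (switchable). Bootstrap support is the percentage of
column-resampled replicate trees containing each bipartition of the point
tree (default 1,000 replicates; saturated replicates are skipped and counted,
with a warning above 1%). Robinson–Foulds distance is the symmetric
difference of non-trivial bipartitions. Trees are stored unrooted; rooting is
presentation only. Because within-lineage samples are nearly identical, RF
between region trees includes arbitrary resolution of zero-length branches —
the discordance analysis therefore also uses patristic (branch-length-aware)
nearest neighbors to read a taxon's placement, which resolves attachments at
the central trifurcation that topological sister sets cannot.

## Recombination detection

All detectors share one substrate: for a target and two candidate parents, an
**informative site** is a column where the parents differ and the target
matches exactly one (columns missing in any of the three are excluded).

* **MaxChi**: for every partition point of the informative-site order, the
  2×2 chi-square of parent-match counts left/right of the cut,
  `χ² = m(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, no continuity correction,
  zero-margin tables scored 0; the scan reports the maximum and its
  partition. Significance permutes the site order;
  `p = (1+k)/(1+N)`.
* **Triplet search** (Chimaera-style): every ordered target with every
  unordered parent pair; Bonferroni correction over the number of triplets
  actually evaluated (those with ≥ 4 informative sites). Permutations stop
  early once 30 permuted maxima reach the observed value — the p-value is
  then already orders of magnitude above any Bonferroni threshold — so null
  triplets cost ~100 permutations while candidates get the full budget
  (4,999 where the family is large). Events are merged per target (smallest
  raw p, then largest χ²); an event whose winning triplet used a
  better-supported event's recombinant as a parent is suppressed as an echo
  of that event.
* **Breakpoint pair**: the single-partition MaxChi statistic defines
  significance, but a spliced segment has two boundaries, so the reported
  `(begin, end)` comes from an exhaustive two-changepoint chi-square
  maximisation (O(m²), exact) over the informative sites; boundaries map to
  the midpoint between bracketing informative sites and degenerate cleanly
  to the single-breakpoint solution at vector edges. Intervals are linear
  alignment coordinates with the segment length stated explicitly — no
  circular wrap-around convention is guessed.
* **Parent assignment**: the minor parent minimises p-distance to the target
  inside the segment, the major parent outside (the major contributes the
  longer remainder); ties break on label order and are flagged.
* **PHYLPRO-style profile**: at each boundary between consecutive variable
  sites, the Pearson correlation between the target's distance vectors (to
  every other sequence) from the left and right windows of variable sites
  (default 20); zero-variance windows are NaN, not errors; deep minima flag
  breakpoints.

The study's other detector implementations (RDP, GENECONV, BOOTSCAN, SISCAN,
VisRD, EEEP) are not re-implemented: the three methods above have crisp
published definitions, share the informative-site substrate, and the original
finding was method-concordant.

## Synthetic data

The generator emulates the structure the analysis assumes, with an exact
truth record. Per partition, an ancestral sequence is uniform random;
lineage B's consensus differs at exactly `round(length × divergence)` planted
columns (deterministic count rather than a stochastic coalescent, so
truth-record comparisons are exact — appropriate for data showing
near-complete lineage sorting, ~109 fixed vs ~5 shared polymorphic sites);
individuals mutate off their consensus at per-site rate `π/2` (expected
pairwise diversity π), with mutation columns disjoint from planted columns
and indel spans by default, so planted positions stay fixed. Lineage-fixed
indels are gap runs applied to every member of one lineage. Recombinants are
spliced from the two lineage consensi at stated breakpoints with light
post-splice Jukes–Cantor noise (default 0.002) modelling post-hybridisation
divergence. The generator self-checks every planted feature against the
emitted alignment before returning; the same seed yields byte-identical
FASTA.

Defaults are the study conditions: partitions 1,822 / 1,788 / 676 bp at
between-lineage divergences 0.009 / 0.048 / 0.011, π = 1e-4, 17 vs 8
samples, and seven fixed length polymorphisms (13-, 4-, 8-bp deletions plus
four 1-bp events). These defaults plant 16 + 86 + 7 = 109 fixed differences.
What the generator does **not** emulate: recombination within lineages,
rate heterogeneity along sequences, coalescent genealogical noise, indel
evolution, and sequencing error — so green tests certify the statistics and
their calibration under the assumed structure, not robustness to every
feature of real data.

## Calibration and recovery conditions

The acceptance-level checks use: (a) null calibrations with 200 replicates
per test (one panmictic population split 5 vs 5 for Fst; a three-sequence
triplet with independent per-site mutations, π = 0.02 over 1,200 bp, for
MaxChi), where permutation validity follows from exchangeability; (b) 100
spliced-recombinant simulations with parent divergence drawn in [0.10, 0.15],
4 + 4 samples over a 1,788-bp region, and donor segments covering the
majority of the 3' segment (begin in [760, 900], end in [1600, 1750]) —
mirroring the observed event's geometry, where the donated segment dominates
the ~862-bp 3' coding tail; and (c) the default two-lineage emulation. These
problem sizes were chosen as the smallest at which the planted effects are
unambiguous.

## Pipeline

The `run` pipeline executes concatenation → site/indel catalogue → π →
Dxy/Fst/Kst with permutations → sliding windows → NJ + bootstrap per region
(5'-COI, 3'-COI, full COI, concatenate) → RF discordance → triplet
recombination search → segment contrast, writing a manifest with per-stage
status, wall time and seed. Stage seeds derive from one master seed via named
substreams, so permutation and bootstrap P-values reproduce exactly. The
recombination stage scans one representative per group plus all ungrouped
sequences: near-identical within-group samples add no signal but inflate the
Bonferroni family (the original analysis likewise scanned species-level
representatives). Stage errors are recorded and independent stages continue.

Configuration is YAML. The CLI (`kelppop concat|sites|diversity|
differentiate|windows|tree|recomb|contrast|simulate|run`) is a thin layer
over the library; the numbered scripts under `analysis/` are the narrative
drivers of the study workflow.

## Segment contrast

The 5'-vs-3' contrast feeds per-pair segment divergences to a paired t-test
and a Mann–Whitney U test (treated as unpaired, as is conventional in this
analysis style, and computed with the midrank normal approximation using the
plain variance — no continuity or tie correction — which is what the classic
packages report). The 3'/5' ratio is printed to one decimal; machine outputs
keep full precision. The 5'/3' split column defaults to 740 within the COI
region. A bundled 20-row table of printed per-pair COI segment divergences
(focal taxon vs close kelps, distant kelps, and Ectocarpales comparators)
drives the aggregate-contrast reproduction.

## Known limitations

* Maximum-likelihood and Bayesian tree inference, substitution-model
  selection, and gamma/invariant-site corrections are out of scope; the
  discordance analysis uses NJ throughout (the original topologies were
  method-congruent).
* Kst is the plain variant; comparisons with tools reporting K\*st require
  the log transform.
* Bonferroni over evaluated triplets is conservative; with many
  near-duplicate sequences the family should be reduced to representatives
  (the pipeline does this automatically).
* Breakpoint localisation is limited by informative-site density: with
  sparse sites the midpoint convention can be tens of columns off.
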