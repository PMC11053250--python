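# Methods

`eibalance` analyzes two-condition Visium-like spatial transcriptomics of
mouse hippocampus for excitatory/inhibitory (E/I) imbalance: it scores a
glutamatergic and a GABAergic synapse signature in every spot, classifies
spots by a median split of the two scores, compares the resulting
proportions and score distributions between conditions, and screens
hippocampal differential expression for receptor-like candidate genes
whose spatial pattern tracks the glutamatergic signature. Because the
kind of study it targets rarely deposits raw spot matrices, the package
ships a generative model of the design so every stage is testable from a
seed alone.

## Per-spot gene-set variation score

The central statistic is a rank-based single-sample enrichment score
(a GSVA-style statistic), built in three stages.

**Stage 1 — expression-level statistic.** For gene *i* and spot *j*,
`e[i,j]` is the averaged-tie rank of spot *j* among all *S* spots for
that gene, divided by *S* (values in (0, 1]). This is a discrete ECDF
evaluation; a Gaussian-kernel CDF estimate with bandwidth `sd/4` is
available (`ecdf_mode="gaussian-kernel"`) for users who prefer the
continuous variant. The rank form is the default because it is exactly
testable against enumeration.

**Stage 2 — within-spot ranking.** Within each spot, genes are ordered
by `e` descending; ties break by gene index ascending (determinism over
randomization). The gene at rank *R* (of *N*) carries weight
`w_R = |N/2 − R|`, emphasizing genes at the extremes of the spot's
expression profile.

**Stage 3 — weighted KS walk.** For a gene set with *m* members present
(1 ≤ m < N), the walk after the top-ℓ genes is

    ν(ℓ) = Σ_{r≤ℓ, in set} w_r^τ / Σ_{in set} w^τ  −  #{out-of-set ≤ ℓ} / (N − m)

with τ = 1 by default. The enrichment score is
`ES = max(ν, 0) + min(ν, 0)` (`es_mode="diff"`, default; both extrema
include the walk's 0 starting state, so a set concentrated entirely at
the top yields a minimum of 0 rather than a spurious negative), or the
single deviation of maximal magnitude (`es_mode="maxabs"`). |ES| ≤ 2 in
diff mode and ≤ 1 in maxabs mode.

Two properties of this statistic matter for interpretation:

- **It is relative.** Stage 1 ranks across all scored spots, so a
  condition that raises a signature in one group also lowers the other
  group's e-values. Absolute per-group mean scores are therefore not
  monotone in a planted effect; the between-group contrast is, and all
  group comparisons in the package use contrasts.
- **Within-spot ties are generic in rank mode** (e-values are ranks/S),
  so results can depend on gene order through the deterministic
  tie-break. The kernel mode is tie-free for continuous data.

`permutation_null` draws random gene sets of a given size to provide an
empirical null for the score; it is a calibration utility, not part of
the main pipeline.

## E/I classification

Per spot, each signature score is dichotomized at the **pooled** median
(both conditions together); ties at the median go low. High-glut/low-GABA
spots are excitatory, low-glut/high-GABA inhibitory, and the agreeing
cells mixed_high/mixed_low; the four categories partition the spots.
Pooling is essential: a per-group split would force every group to ~50%
high and erase the group contrast the analysis is about. Group score
distributions are compared with a two-sided Mann–Whitney test and the
high-glutamatergic, high-GABAergic and excitatory fractions with a
two-proportion chi-square with continuity correction (the study design
this mirrors used nonparametric two-group comparisons; it does not name
its proportion test).

## Differential expression and candidate ranking

Genes are tested spot-wise within the assigned hippocampus with a
two-sided Wilcoxon/Mann–Whitney rank-sum test on log-normalized
expression — a deliberate, assumption-light replacement for a
negative-binomial GLM fit, with the discovery gates kept at
|FC| ≥ 1.25 with BH-adjusted p < 0.05 and a top tier at FC ≥ 1.5. The
exact null is enumerated when n₁+n₂ ≤ 12 (correctly handling ties, which
permutation of averaged ranks does automatically); otherwise the
tie-corrected normal approximation with continuity correction is used.
Fold changes are ratios of group means of de-logged normalized
expression with pseudocount c = 0.01 (the FC scale is not standardized in
this literature; de-logged normalized means keep the gate interpretable
as a ratio of expression levels). Spatial similarity is the Spearman
correlation between a gene's per-spot expression and the glutamatergic
score over hippocampal spots of both groups; candidates are top-tier
genes inside the glutamatergic set ranked by similarity, then |FC|.

## Region assignment

The study design this automates selected hippocampal spots manually from
clusters and histology; without images that step is irreproducible, so
the package substitutes marker scoring: per region (CA1/CA3/DG), the
score of a spot is the mean gene-wise z-score (across spots, on
log-normalized values) of the region's marker genes; zero-variance genes
contribute 0. A spot is assigned to the argmax region if the best score
clears a threshold (default 0.25, conservative against background
spots), otherwise "other"; exact ties resolve CA1 > CA3 > DG. The marker
sets lead with the subfield markers this analysis is anchored on
(Itpka/Fibcd1/Spink8; Cabp7/Homer3/Hs3st4; C1ql2/Fam163b/Dsp).

## QC and normalization

Spots are kept with ≥ `min_features` detected genes (default 100) and a
mitochondrial count fraction ≤ `max_mito` (default 0.2; `mt-` prefix,
case-insensitive); genes must be detected in ≥ `min_spots` spots
(default 3). The source study reports these QC axes but not its
cut-offs, so the defaults are this package's. Normalization is
`ln(1 + count × 10⁴ / spot_total)` — the ecosystem convention; it is
exactly invariant to scaling a spot's counts.

## The synthetic data generator

`simulate.generate_dataset` emulates the study design at desk scale: two
one-section samples (control CON, colitis-like DSS) of 1000 spots on a
25×40 grid, 1000 genes, a centered 9-row hippocampal band split into
CA1/CA3/DG strips (~360 hippocampal spots/sample, inside the 300–400
range the emulated study reports). Counts are negative binomial with
variance μ + αμ² (α = 0.3), per-gene baseline mean 0.5 (≈500 UMI/spot
over 1000 genes — typical Visium depth scaled to the gene count),
lognormal spot library-size factors (CV 0.3), and ten `mt-` genes tuned
to a ~5% mitochondrial fraction. Ten markers per region (a realistic
signature size; the study names its top three) are subfield-enriched:
baseline × 0.1 outside every band and baseline × 4 inside their band
(~40× contrast, typical of subfield markers, which are chosen precisely
because they are near-exclusive).

The condition effect multiplies the 30 glutamatergic-signature genes by
`effect_glut` (default 1.5) in hippocampal spots of the affected group;
the 30 GABAergic genes stay at `effect_gaba` = 1. One receptor-like gene
(Grm1, the first glutamatergic gene) carries an additional 2× boost —
total fold 3 — so that it unambiguously carries the signature's spatial
pattern; it is the planted positive control for candidate
prioritization. Optional spiked DE genes (`n_de_spike`, fold
`de_spike_fold`) among the filler genes support power/FDR experiments.

Spots also draw a lognormal per-spot activity factor per synapse
program: CV 0 for the glutamatergic program (pyramidal content is dense
and laminar) and CV 0.3 for the GABAergic program (interneurons are
sparse and scattered, so per-spot GABAergic signal is patchy). Without
this heterogeneity the simulated spots are exchangeable within a region,
and the scoring statistic's intrinsic rank-displacement coupling —
inflating 3% of the transcriptome necessarily pushes other genes down
each affected spot's ranking — becomes statistically detectable as a
spurious GABA group difference. At a realistic transcriptome size the
signature is ~0.15% of genes and the coupling is an order of magnitude
smaller; the heterogeneity term restores a realistic signal-to-artifact
ratio at desk scale.

What the generator does **not** emulate: spatial autocorrelation beyond
the region bands, cell-type deconvolution mixtures, per-gene baseline
heterogeneity, batch/section effects, segmentation of the ~15
non-hippocampal clusters of a real section, or dropout beyond what the
NB model implies. Passing tests therefore demonstrate the pipeline's
operating characteristics under a clean NB world, not performance on
real tissue.

All randomness flows from one seed through named substreams (library
size, counts, program factors), so adding draws to one stage never
perturbs another, and two runs with the same config are byte-identical.

## Numerical and degenerate-input choices

- Constant genes: p = 1 in the DE screen, similarity 0 (with a warning),
  z-contribution 0 in marker scores, e = 0.5 everywhere in kernel mode.
- A gene set absent from the matrix, or covering every gene, is an error
  naming the set; sets partially present are scored on the present
  members, recorded in `set_sizes_used`.
- If every in-set gene sits at walk weight 0 (possible at even N), the
  in-set CDF falls back to the unweighted step function.
- Ties at the dichotomization median go low (strict >), making "high"
  calls conservative.
- BH adjustment uses the standard step-up with monotonicity enforcement;
  p-values outside [0, 1] are rejected.

## Problem sizes

Default analyses run two 1000-spot samples with 1000 genes; the test
suite's ensemble checks use 20 seeds at that scale and smaller
300-spot/400-gene simulations for score-level properties. These sizes
give stable operating characteristics (e.g., DE recall/FDR estimated
over 30 planted genes) while keeping a full run in a few seconds.

## Known limitations

- The rank-displacement coupling described above is intrinsic to
  single-sample enrichment scores; with very large signatures or small
  transcriptomes, a strong effect in one set will depress scores of
  disjoint sets.
- The Wilcoxon screen tests distributional shift, not an NB mean model;
  it is robust but can be conservative at very low counts.
- Marker-score region assignment requires markers strong enough to
  separate bands; it does not reproduce cluster-based parcellation.
- The chi-square proportion test treats spots as independent, as does
  the emulated analysis; spatial correlation in real data would make it
  anti-conservative.
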