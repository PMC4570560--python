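# Methods

`phosphosig` re-implements, as a tested library, the quantitative analysis
chain of a two-set triple-SILAC phosphoproteomics experiment comparing a
tumor-suppressor-proficient and -deficient cell pair under high serum and
serum starvation: log-ratio computation across the two labeling sets,
outlier-based differential phosphosite calling, serum-response
classification, residue-level kinase-target-set enrichment, and local
annotation/network context summaries. This note describes the models, the
parameters that matter, and the choices made where the design was open.

## Experiment model and ratio computation

Each phosphosite (gene symbol + S/T/Y residue position) carries up to six
intensities: light/medium/heavy channels in two labeling sets. An
`ExperimentDesign` maps each `(set, channel)` to a biological condition and
names an *anchor* condition measured in both sets (here: proficient cells
in normal serum, light label). A named comparison between two conditions is
*direct* when both live in one set — `log2(I_first / I_second)`, summed
intensity `I_first + I_second` — and *chained* otherwise, composed through
the anchor as `log2(first/anchor_1) − log2(second/anchor_2)`. A chained
ratio's summed intensity is the minimum of its two legs' sums, a
conservative weight reflecting that the noisier leg limits its precision.
Log-ratios are median-centered per comparison (median log2 = 0) before any
outlier scoring; the asymmetric-scale model below assumes a centered
distribution, and median centering is the standard normalization for
single-replicate SILAC ratio distributions.

The literature the channel layout derives from fixes only the shared light
anchor, not the remaining channel-to-condition assignment. The default
design assigns set 1 = {anchor, deficient/high serum, deficient/low serum}
and set 2 = {anchor, proficient/low serum, deficient/low serum}, which
makes all four standard comparisons (genotype under each serum level,
serum response in each genotype) direct. The design model is fully
configurable, and chained composition is exercised by tests using
alternative layouts.

Zero intensities are converted to missing at load time — a zero is a
non-detection, and propagating it into a log-ratio or an intensity bin
would corrupt both. Localization probability is carried but not filtered
on by default; a `min_localization` option enables the conventional ≥ 0.75
cut.

## Outlier significance (Significance A and B)

With a single quantified ratio per site, differential calling treats the
population of log-ratios as its own null and flags outliers. For ratios
with median `r0`, the right and left scales are the 84.13th and 15.87th
percentile distances from `r0` (the ±1σ quantiles of a normal), estimated
with linear interpolation between order statistics. Each ratio is scored
against its own side, `z = (r − r0)/s⁺` or `(r0 − r)/s⁻`, and

    p = ½ · erfc(z / √2) = 1 − Φ(z),

the one-sided normal tail probability: `p = 0.5` at the median, `p ≈ 0.159`
at one robust sigma. Note the calibration consequence: under a Gaussian
null, `p < α` flags a fraction `α` *per tail*, i.e. `2α` of all sites
(verified analytically and by simulation in the test suite). The
significance flag applies `α = 0.05` to this side-specific p directly,
which is the statistic's conventional use; BH adjustment is available but
off by default.

*Significance B* is the same statistic computed inside contiguous
equal-occupancy bins of sites ordered by summed intensity (ties broken by
site id so binning is reproducible). Bins hold `min_bin` sites (default
300, configurable; the defining description fixes no bin size), with the
remainder merged into the highest-intensity bin. Because MS ratio scatter
shrinks with intensity, binning judges intense sites against a tighter
null: a 1.5-log2 shift at high intensity that is invisible to the pooled
statistic becomes clearly significant. With fewer than `min_bin` sites the
statistic degrades to a single bin (≡ Significance A) with a warning.
Degenerate scales (zero spread on one side of a bin's median) raise a
statistic error rather than producing infinities.

## Serum-response classification

Sites quantified in both genotypes yield a pair `x, y` of
log2(high serum / starvation) ratios in proficient and deficient cells.
The partition rule, with thresholds `τ_change` (a real response; default
1.0 log2 units) and `τ_null` (still "no response"; default 0.5):

* **correlated** — same sign, `min(|x|,|y|) ≥ τ_null`, `|x − y| < τ_change`;
* **persistent_in_deficient** — `x ≥ τ_change` and `y ≤ τ_null`;
* **lost_in_deficient** — `y ≥ τ_change` and `x ≤ τ_null`;
* **unclassified** otherwise.

Rules are evaluated in that order, so labels are mutually exclusive and
exhaustive. The thresholds are artifact choices: the source analysis shows
a qualitative scatter partition without numeric cuts, so the cut is
surfaced as a tunable with documented defaults. Sites missing either ratio
are omitted rather than labeled — missingness is not evidence of an
ambiguous response. For the downstream network stage, labels are collapsed
to deduplicated protein sets.

## Kinase-target enrichment

Residue-level target sets (one per kinase, members keyed by
`(GENE, residue)`, species-filtered so both kinase and substrate match the
organism under study) are intersected with the ranked universe; sets below
`min_size = 3` members are dropped (the smallest reported set in the
emulated analysis has 3 residues). The pre-ranked list orders sites by
log2 genotype ratio with deterministic key tie-breaking; the default
orientation puts deficient-enriched (most negative) ratios first, so a
kinase hyperactive in deficient cells earns a positive score.

The enrichment score uses unweighted (classic Kolmogorov–Smirnov)
increments: `+1/k` at members, `−1/(N−k)` elsewhere; ES is the signed
maximum-magnitude excursion of the running sum (a positive value wins an
exact magnitude tie, a deterministic convention), and the leading edge is
the members at or before the positive extremum (at or after, for negative
ES). Weighted scoring is intentionally not offered: the emulated analysis
labels its score a KS test, which is the unweighted form.

The null is gene-set permutation — random member sets of equal effective
size drawn from the universe — because a single pre-ranked list offers no
sample labels to permute. With `n_perm` permutations (default 1000, seed
mandatory):

* `NES = ES / mean(|ES_null|)` over same-sign nulls;
* `p_perm = (1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign nulls)`;
* FDR pools each set's nulls (normalized by that set's own same-sign mean)
  and takes the ratio of null to observed tail fractions at the observed
  |NES|, clipped to [0, 1] and made monotone non-increasing in |NES| by a
  cumulative minimum from the weakest score upward. A single scored set
  falls back to its permutation p-value, flagged as such.

Same seed gives bit-identical results; per-set null streams are spawned
from the root seed in sorted-kinase order so results are independent of
caller-supplied set order.

## Annotation enrichment and network context

Annotation enrichment is the plain hypergeometric upper tail: for a query
of `n` proteins in a background of `M`, a term with `K` members and `k`
hits scores `p = P(X ≥ k)`, BH-corrected across the tested terms; `k = 0`
terms are omitted. This deliberately replaces the original web-service
statistic with an exact, testable equivalent; its p-values are therefore
not replication targets. The high-confidence subnetwork keeps edges
*strictly above* the confidence threshold (default 0.9) with both
endpoints in the query set, and reports connected components sorted by
size (ties by lexicographically smallest member). Component-wise
enrichment composes the two; components below 2 nodes are skipped and
component members outside the annotation background are ignored.

## Synthetic data and what it does (not) emulate

The generator produces all four input tables with planted truth under one
seed; the three table families draw from independent spawned substreams,
so regenerating one table never perturbs another.

Default scale mirrors the emulated study: 3655 proteins at ~2.9 sites each
(~10,700 sites). Base log2 intensities are N(23, 2²). Channel noise is
additive on the log2 scale with sd `σ(I)/√2` where

    σ(I) = a + b·exp(−c·(I − I_min)),   a = 0.15, b = 1.2, c = 0.4,

and `I_min = μ − 3σ` — ratio noise (the difference of two channel draws)
then has the intensity-decaying sd `σ(I)` that intensity-binned outlier
calling assumes, from ≈1.35 log2 units for faint sites to ≈0.15 for
intense ones. Missingness is 5% per channel. Planted fractions follow the
emulated study's reported significant fractions: genotype-differential
sites 1.9% (both serum levels) + 6.4% (high only) + 3.8% (low only), with
effect magnitudes |N(2.0, 0.5²)| clipped at 0.75; serum-response classes
25% correlated, 3% persistent-in-deficient, 3% lost-in-deficient with
responses ≥ 1.5 log2 units; one planted kinase set of 10 sites shifted by
δ = −2 in the low-serum comparison among 20 size-10 decoys.

A structural constraint shapes the planting: the four condition means per
site leave only three free contrasts, so genotype effects, serum classes
and kinase shifts cannot be planted independently on one site. The three
kinds of truth are therefore planted on disjoint site populations, keeping
every recovery test against its own clean truth. Network/annotation truth
is three 8-protein modules whose internal edges score > 0.9 (each pair
present with probability 0.9) and which each carry a dedicated term;
background edges score below 0.9.

What the generator does *not* emulate: peptide-to-site rollup and shared
peptides, label-incorporation artifacts, non-Gaussian (heavy-tailed) ratio
noise, correlated missingness (censoring at low intensity), and
compositional effects between channels. Passing recovery tests therefore
demonstrate correctness of the statistical machinery under its stated
assumptions, not robustness to every pathology of real MS data.

## Numerical and reproducibility choices

* Percentiles: linear interpolation between order statistics
  (`np.percentile` default); binning order tie-broken by site id.
* ES magnitude ties between the positive and negative extremum resolve to
  the positive one, in both the running-sum and the closed-form
  position-based evaluation, so the two paths agree exactly.
* Permutation p-values use the add-one convention, bounded away from zero;
  a set with no same-sign nulls gets `p = 1` and a flagged fallback
  normalizer.
* All randomness flows from `numpy` `SeedSequence` spawning; identical
  seeds give byte-identical written tables.
* Problem sizes in the test and acceptance runs (universes of ~1,200–3,655
  proteins, 120–1,000 permutations) are chosen to exercise every code path
  at statistically meaningful scale while keeping a full run in seconds.

## Known limitations

* The side-specific outlier p-value is not uniform on (0, 1) under the
  null (it is uniform on (0, 0.5] per side); users wanting a familiar
  two-sided scale should double it or enable BH adjustment.
* Chained ratios inherit noise from both legs but are scored in the same
  pooled/binned null as direct ratios; no per-comparison variance model is
  attempted.
* The annotation test ignores term hierarchy (no parent–child correction)
  and uses a single background; protein-level rollup of site ratios is out
  of scope.
* Replaying the emulated study's printed counts requires its supplementary
  site tables, which are not redistributable here; the replay code path
  accepts any site table in the documented TSV dialect.
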