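# Methods

`oxiswitch` implements a consensus analysis of five-stage developmental
bulk-transcriptome data measured on Affymetrix-style PM/MM probe chips,
together with the two companion assays used to corroborate it (NADH-TR
histology histograms and qRT-PCR mean normalized expression).  This note
documents the models, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Study design being modelled

*Longissimus dorsi* muscle from sheep at five stages of development — 80,
100 and 120 d fetal, 150 d (1–3 d postpartum) and 230 d (young lamb) —
three animals per stage, profiled on a chip of probe sets each holding ~11
perfect-match/mismatch (PM/MM) 25-mer probe pairs.  The scientific question
is which genes switch expression between adjacent stages, dominated by the
late-fetal → postnatal transition.

## Probe-set summarization

Three independent routes from raw probe intensities to probe-set × array
log2 expression:

**MAS5.** 4×4 chip zones; the dimmest 2% of probes per zone give a zone
background mean and noise sd; each probe is corrected by the
1/(d²+100)-distance-weighted average over zones, floored at
max(0.5, 0.5·local noise) and capped at the raw value (the cap keeps the
correction a genuine reduction even for sub-floor inputs).  The probe-set
signal is the one-step Tukey biweight (c = 5, ε = 1e-4) of
log2(PM − IM), where the ideal mismatch IM is MM when MM < PM and otherwise
a surrogate derived from the probe set's specific background (contrast
τ = 0.03, scale τ = 10) so PM − IM stays positive.  Arrays are scaled so
the 2%-trimmed antilog mean is 200.  Detection calls use a one-sided
Wilcoxon signed-rank test of the discrimination scores
R = (PM−MM)/(PM+MM) against τ = 0.015, with an exact null tail computed by
dynamic programming (midranks for ties, zeros dropped); P below 0.04, M
below 0.06, A otherwise.

**RMA.** PM-only. The observed intensity is modelled as
O = B + S, B ~ N(μ, σ²), S ~ Exp(α).  Parameters are fit per array by
maximum likelihood of the convolution density (the kernel-density mode,
left-half rms and right-tail mean seed the optimizer).  We use the ML fit
rather than the kernel-mode point estimates alone because on simulated
N(100,10) + Exp(1/200) data the kernel mode overestimates μ enough to bias
the corrected mean by >10%, while the ML fit recovers (μ, σ, α) almost
exactly.  Each probe becomes E[S|O] (computed with a log-space Mills ratio),
clipped to (0, O].  Arrays are then quantile normalized (ties get the mean
of tied rank means) and probe sets summarized by median polish (row sweeps
first, tol 0.01, ≤10 iterations; expression = overall + array effect).

**Reduced GCRMA.** Nonspecific binding is predicted per array by a
quadratic regression of log MM on probe GC count — the affinity model
reduced to its GC component, which is the only sequence feature the
synthetic chips carry.  The prediction is subtracted from PM (floored at
0.5) and the RMA normalization/summarization tail follows.  A constant-GC
chip degenerates gracefully to a global nonspecific-binding estimate.

## Differential expression

Each gene gets a cell-means one-way fit over the k = 5 stages: stage means,
pooled within-stage variance s² on d = N − k = 10 df.  Variances are
moderated by the standard empirical-Bayes scaled-inverse-χ² prior: the
posterior variance is s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²)
estimated from the marginal distribution of log s² by digamma/trigamma
moment matching (d₀ = ∞ — and s₀² = the pooled mean variance — when the
spread of log s² is within pure χ² sampling noise).  The moderated t for an
adjacent-stage contrast is the stage-mean difference over s̃·√(2/n) on
d₀ + d df; the per-contrast moderated F is t² (identical p).  An omnibus
(k−1)-df moderated F is provided but is not the default decision statistic,
because the trajectory codes need per-interval decisions.  Log2 fold
changes are always computed from the raw replicate means, not fitted
values.  Benjamini–Hochberg adjustment runs within each contrast × method
at a target FDR of 0.01 (a switch pools contrasts).

## Consensus filter and trajectory codes

For each gene × contrast, convergence = share of the three methods calling
it significant (0/33.3/66.7/100%).  A pair is consensus-DE when
convergence > 50% (i.e. ≥ 2 of 3 methods) **and** the gene is MAS5-Present
in at least ⌈N/2⌉ of all arrays.  Marginal calls do not count toward that
filter by default.  Each consensus gene receives a four-letter code over
{F, U, D} — per interval, F if not consensus-DE, else the direction of the
MAS5 stage-mean change (exact ties carry no direction evidence and resolve
to F).  Directions use MAS5 intensities only because the three methods'
scales are not comparable.  With four intervals the code space holds
3⁴ = 81 clusters; clusters with ≥ 50 members are flagged reported.  The
"expressed" universe for reporting percentages is genes Present or Marginal
in ≥ 1 stage, a stage-level call being a majority of its replicates.

## Over-representation analysis

Gene sets come from GMT files (identifiers uppercased, deduplicated,
intersected with the background universe).  A cluster of n genes from a
universe of N against a set of K members overlapping in k is scored by the
hypergeometric upper tail P(X ≥ k); EASE mode discounts one overlapping
gene (tail at k − 1), the conservative DAVID variant, and is the default
for term enrichment; Fisher mode is the default for motif target sets.
Bonferroni and Benjamini–Hochberg corrections run over the tested
collection; motif reports keep Bonferroni p < 0.05.  Enriched terms are
grouped into functional annotation groups by greedy seeding in p-value
order over pairwise Cohen's kappa (threshold 0.5, seed size 3) of their
gene-membership vectors, groups sharing a majority of members merged; each
group is scored by the geometric mean of its members' Benjamini p
(significant at ≤ 0.05).  The kappa/seed parameters are documented package
defaults — the upstream tool never published its exact values.

## Histology histograms

NADH-TR-stained fields are 8-bit grayscale; the analysis is pixel-global by
design (no fibre segmentation): per image an exact 256-bin intensity
histogram, per animal the mean over its fields (≥ 10 recommended; fewer
warns), per stage the mean over animals, plus summary statistics (median
intensity, peak intensity, interquartile width).  Note the histogram has
256 bins, 0–255: descriptions of 8-bit data as "0–256" are off by one.
The synthetic fixture packs jittered circles ("fibres") with per-fibre
intensities from a configurable normal distribution over a dark rim and
background, covering most of the frame so histogram medians reflect fibre
staining rather than background.

## qPCR mean normalized expression

MNE = E_ref^Ct̄_ref / E_target^Ct̄_target, with technical replicates
averaged on the Ct scale first (a switch averages per-replicate ratios
instead); E = 2 is perfect doubling, and efficiencies must lie in (1, 2].
Biological replicates (n = 3 animals) are summarized as mean ± sample sd;
a single replicate reports no dispersion.  Only the MNE quantity is
computed — randomization-test machinery of relative-expression software is
out of scope.

## Synthetic data generator

Per probe i (of gene g) on array j:

    PM_ij = O_ij + NSB_ij + s_gj · φ_i · ε_ij
    MM_ij = O_ij + NSB_ij + crosstalk · s_gj · φ_i · ε′_ij

* optical background O ~ N(40, 4²) clipped at 1;
* nonspecific binding NSB lognormal, log-scale mean log 30 + 0.08·(GC − 12.5),
  sd 0.35, shared within a PM/MM pair (same target sequence) — sharing makes
  the zero-noise identity PM − MM = s exact;
* probe affinity φ lognormal (log-sd 0.3, shared within a pair) so median
  polish and the biweight have real work;
* measurement noise ε lognormal with CV 0.15 and unit mean;
* MM crosstalk 0.05, so MM occasionally exceeds PM and the ideal-mismatch
  logic is exercised;
* specific signal: log2 s follows the planted trajectory from a baseline,
  plus a per-gene-per-array biological deviation N(0, 0.25²) — each array
  is a different animal, and without this term within-stage variance is
  purely technical and unrealistically small;
* baselines: changing genes are always expressed (log2 base ~ N(6.5, 1.5²));
  flat genes are expressed with probability 0.55 and otherwise sit at
  background level (log2 base ~ N(−2, 1²)).  These values were calibrated
  once so the MAS5 Present rate lands in the realistic 60–70% band.

Planted codes default to a mix dominated by the birth-interval switch
(7% FFUF, 7% FFDF, 2% FFFU, 2% FFFD, 82% FFFF).  Up and down movements are
deliberately balanced within each interval: trimmed-mean scaling and
quantile normalization assume globally balanced differential expression,
and a strongly unbalanced mix shifts every flat gene at the affected stage —
a real normalization artefact that the generator can reproduce (set the
frequencies asymmetric) but does not impose by default.  Planted effect
magnitudes are |N(2.5, 0.4²)| floored at 2 log2 units, signed by the code
letter.

What the generator does **not** emulate: spatial chip artefacts, batch
effects, probe-level sequence structure beyond GC count, cross-species
probe mismatch loss, saturation, and array-wide intensity drift.  Passing
truth-recovery tests therefore demonstrates the pipeline's statistical
behaviour under its own assumptions, not robustness to those artefacts.

## Numerical choices and degenerate inputs

* Positive floor after any background subtraction: 0.5 on the raw scale.
* Quantile-normalization ties: mean of tied rank means (via midrank
  interpolation into the mean-sorted vector).
* Median polish: row sweeps first, overall medians of the effect vectors
  redistributed each sweep; defaults tol 0.01 / 10 iterations, and the
  routine accepts tighter settings (tests run it to 1e-12 against a scalar
  oracle).
* Signed-rank p-values: exact dynamic-programming tail per effective n;
  all-tied probe sets return p = 0.5, call A.
* Biweight with zero MAD and all-zero weights falls back to the median.
* d₀ estimation drops non-positive variances; all-zero variances raise.
* Direction ties in code assignment resolve to F.
* Empty zones, single-replicate stages, inconsistent contingency counts and
  malformed GMT lines raise informative errors.

## Simulation sizes used by the shipped checks

The acceptance script and test suite run the full pipeline at 5,000 probe
sets (5 stages × 3 replicates), calibration checks at 10,000 genes × 5–20
seeds, enrichment calibration at 200 trials, and histology at 3 animals ×
10 fields per stage.  These sizes give stable estimates of every reported
rate while keeping a full run in the minutes range on one core; the
generator scales to chip-sized experiments (15,000–24,000 probe sets) with
the same interfaces.

## Known limitations

* The GCRMA reduction to a GC-count affinity model is intentional; it
  cannot capture position-specific base effects.
* Per-contrast moderated t assumes within-stage homoskedasticity on the
  log2 scale; strongly background-dominated genes violate it (they are
  largely removed by the Present filter).
* The consensus filter inherits any systematic bias shared by all three
  summarization routes (e.g. compositional normalization shifts under
  heavily unbalanced differential expression).
* Identifier namespaces of clusters and gene-set collections must already
  match; the loader only uppercases and warns on low overlap.
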