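# Methods

## Study design

The package models a batch-culture stress experiment on a thermoacidophilic
archaeon (*Saccharolobus islandicus* REY15A-type design): an optimal control
(pH 3.4, 76 °C), an acid stress condition (pH 2.4, 76 °C) and a cold stress
condition (pH 3.4, 66 °C), each harvested at mid-log and early stationary
phase in biological triplicate — 18 samples. Every differential analysis
contrasts one stress against the optimal control at the same growth phase,
giving four contrasts.

## Growth kinetics

Cultures are described by the logistic model
`OD(t) = K·OD0·e^{μt} / (K + OD0·(e^{μt} − 1))` with specific growth rate μ
(1/h), carrying capacity K (OD600 units) and inoculum OD0. Doubling time is
`Td = ln 2 / μ`. Two estimators are provided:

- **`logistic`** (default): nonlinear least squares on the full trajectory
  (`scipy.optimize.curve_fit`, bounds μ ∈ [1e-6, 10], K ∈ [1e-6, 100]).
  Exact on noise-free logistic data and stable at realistic OD noise.
- **`window`**: ordinary least squares on ln(OD) versus time over the
  contiguous run of at least `min_points` (default 4) observations inside
  `od_bounds` (default 0.04 to half the observed maximum) that maximizes
  r², ties broken toward the earlier window. This mirrors the common
  practice of log-linear fitting over a chosen exponential window. Because
  OD is never far below K inside those bounds, the method carries a small
  (few percent) saturation bias toward slower rates; it is kept for
  comparability and exposed, but is not the default.

Maximum density is the per-replicate maximum observed OD, summarized as
mean ± SE. Throughout the package "±" is the standard error `sd/√n` across
biological replicates (the convention is stated here because "±" is
ambiguous in much of the literature). Conditions are compared by one-way
ANOVA with Tukey HSD post-hoc tests at α = 0.05; groups with zero
within-group variance short-circuit to p = 1 (equal means) or p = 0
(different means) rather than propagating NaN from degenerate fixtures.

## GDGT lipid profiling

GDGTs carry 0–8 cyclopentane rings. Peak areas of late-eluting isomers
(GDGT-3′/4′/5′) are summed into their major components *before* any other
computation; total area is conserved exactly. Relative abundances are
`f_n = area_n / Σ area`, and the Ring Index is the abundance-weighted mean
ring number `RI = Σ n·f_n / Σ f_n ∈ [0, 8]`. GDGT-8 is carried through all
code paths even though cultured profiles rarely contain it, so the full
ring range remains representable. Group comparisons (RI and each f_n) use
a two-sample t-test — Welch by default, pooled-variance behind a flag —
flagged at p < 0.05, with the same degenerate zero-variance rules as above.

## Transcript differential expression

Replicate QC computes Pearson correlations between libraries on *raw*
counts (log-CPM optional). Per library, `r_in` is the best correlation to
a replicate-group partner and `r_out` the best to any outside library. A
library passes at `r_in > 0.9`; below that it is retained with a warning
unless an outside library correlates better by more than 0.05
(`r_out > r_in + 0.05`), in which case it is excluded. The retention rule
generalizes an ad-hoc single-library precedent into a symmetric criterion;
that formalization is this package's choice.

The DE engine is an explicitly labelled **stand-in**: Welch's t-test on
`log2(CPM + 0.5)` with Benjamini–Hochberg adjustment, not a
negative-binomial framework with dispersion shrinkage. Real-data users are
expected to supply an externally produced DE table (`--de-table`); the
package's contribution is everything downstream of the per-gene statistics.
Genes whose mean raw count across a contrast's samples falls below a floor
(default 5) receive NA p-values, mirroring independent filtering.

The transcript sign convention is **negative log2FC = increased expression
under stress** (log2FC = mean(optimal) − mean(stress)); it is inverted
relative to common defaults and is reconciled explicitly during
integration. A DEG requires |log2FC| ≥ 1 and adjusted p < 0.05, with
direction `up_in_stress` at log2FC ≤ −1 and `down_in_stress` at ≥ +1.
Cross-stress Venn partitions key on (gene, direction), so a gene moving in
opposite directions under the two stresses is never "common"; the partition
asserts `unique + common = total` per stress and direction on every run.

CPM normalization absorbs a small composition offset when many genes shift
in one direction; the fold-change gate keeps that offset from producing
spurious calls, but estimated log2FC of strongly asymmetric datasets can be
displaced by a few tenths of a unit.

## Differential protein abundance (layered-uncertainty Z)

Inputs are per-protein, per-sample log2 ratios against a common internal
standard, each with the within-sample SE across quantified spectra. For a
condition × phase group:

- `m` — mean log2 ratio across the (≥ 2) biological replicates;
- `sd_between` — their sample SD;
- `se_within` — the mean within-sample spectral SE;
- `u = √(sd_between² + se_within²)` — the total uncertainty.

The "root-square sum" combination is read as quadrature; the literal
additive reading `u = sd_between + se_within` is implemented behind
`--uncertainty-combine additive` because the phrase is genuinely ambiguous.
The test statistic is

    Z = (m_stress − m_optimal) / (u_stress + u_optimal)

with the **plain sum** of the two uncertainties in the denominator — kept
exactly as defined even though quadrature would be conventional for a
difference. The plain sum inflates the denominator by up to √2, making the
procedure deliberately conservative; the null-calibration experiment below
quantifies the effect (essentially zero false positives). Z maps to a
two-sided standard-normal p-value (one-sided available), BH adjustment is
applied within each contrast, and a protein is significant when adjusted
p < 0.1 **and** |log2FC| ≥ 1. Protein log2FC is positive when abundance
rises under stress. Proteins quantified in fewer than two replicates of
either condition are reported with NA statistics, never silently dropped.

Proteome coverage is `100 · n_detected / n_predicted`, reported raw and
rounded to the nearest integer percent.

## Transcript–protein concordance

Each significant protein change is matched by exact locus tag to a DEG
call at the same stress and phase (no homology mapping). After reconciling
the two inverted sign conventions, the pair is `consistent` when both move
the same way in stress, `opposite` when they disagree, and
`no_transcript_change` when no DEG exists at that contrast. Tallies are
conserved against the number of significant protein changes on every run.
A curated 27-row reference table of published significant protein changes
with matched transcript directions ships with the package and anchors this
bookkeeping (18 distinct acid-stress proteins; 6 consistent and 9 opposite
pairs).

## Synthetic data generator

The generator emulates the full 18-sample design with known ground truth;
every output is a pure function of (config, seed), with the global seed
fanned out to per-stage streams as `seed + stage index` (OD 1, GDGT 2,
counts 3, proteins 4).

- **Growth**: logistic trajectories from the printed doubling times
  (6.8 / 9.8 / 14.0 h), maximum densities (1.48 / 0.75 / 1.69) and
  inoculum 0.02, sampled every 2 h over 168 h (long enough for the slowest
  culture to plateau), plus additive Gaussian noise (sd 0.02 OD units,
  truncated at zero). The logistic form is a stand-in — the real
  experiment's rate-fitting model is not constrained by the data design —
  chosen as the simplest shape with an exponential phase and a plateau.
- **Lipids**: per condition × phase, a fixed true composition on the
  9-simplex whose RI equals the reported target exactly
  (3.65 / 1.59 / 2.83 at mid-log; 3.93 / 2.08 / 3.67 at early stationary);
  templates encode the qualitative profile differences (acid enriched in
  rings 0–2 with GDGT-4 depleted; cold depleted above ring 4; GDGT-7 < 1%,
  GDGT-8 absent) and are blended toward GDGT-0 or GDGT-6 to hit the target.
  Samples are Dirichlet draws (concentration 500) scaled to a total area,
  with isomer shares split off GDGT-3/4/5 (U[0, 0.10] under acid,
  U[0, 0.02] otherwise).
- **Counts**: negative-binomial (Gamma–Poisson) with dispersion 0.05,
  log-normal baseline means and ±30% library-size jitter. Per phase, 10%
  of genes are differential, split 40/20/40 into acid-unique, cold-unique
  and common responses; common genes share sign and magnitude across
  stresses. Effect magnitudes are U[1, 3] on the log2 scale with random
  sign; stress means are scaled by `2^(−log2FC)` so the transcript sign
  convention holds end-to-end. `dispersion` interpolates down to Poisson
  (< 1e-12) and, at exactly 0, to deterministic expectation counts — the
  idealization used for exact-recovery tests.
- **Proteins**: per cell, `n_spectra ~ 1 + Poisson(5)` (a realistic
  spectra-per-protein load), spectrum-level values
  `Normal(truth + replicate effect, 0.5)` with replicate effects
  `Normal(0, 0.25)`; the reported value is the spectrum mean and the
  reported SE the sample SD/√n (zero when a single spectrum leaves the SD
  undefined). The two noise SDs place the Z procedure in a regime where
  both uncertainty layers matter. A configurable subset of proteins
  (default 10%, magnitude 2 log2 units) carries true shifts, either in one
  random contrast or in all four (`protein_shift_mode`), the latter used
  for power experiments.

What the generator does **not** emulate: raw reads or spectra,
peptide-to-protein inference, chromatographic drift, batch effects,
count-matrix correlation structure between genes, or annotation content.
Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed noise model, not robustness to every
real-data artifact.

## Validation experiments and problem sizes

The shipped test suite and `scripts/acceptance.py` run, at package-chosen
scales:

- growth recovery: noise-free exactness (< 1% Td error) plus 100 noisy
  datasets (median relative Td error < 10%, stress ordering
  cold > acid > optimal);
- ring index and BH adjustment against independent brute-force oracles
  (1000 random inputs each, agreement to 1e-12);
- protein Z null calibration (100 datasets × 500 proteins, no true shifts:
  flagged fraction ≤ 0.02) and power (50 datasets, 2-log2-unit shifts in
  every contrast: ≥ 90% detected);
- DEG false-call calibration (50 datasets × 1000 null genes) and exact
  planted-set recovery of the Venn partition in the degenerate count limit;
- byte-identical reruns of the full pipeline at a fixed seed.

## Known limitations

- The stand-in DE test is underpowered relative to negative-binomial
  frameworks at n = 3; it exists to exercise the downstream bookkeeping.
- The window growth estimator's saturation bias is inherent to log-linear
  fitting near the carrying capacity; prefer the logistic fit.
- BH is applied per contrast; pooling across contrasts would change
  borderline calls.
- The maximum-density estimate takes the maximum of noisy observations and
  is therefore biased upward by roughly two noise SDs.
- Zero-variance degenerate rules (p = 0/1) are pragmatic conventions for
  synthetic fixtures, not inferential statements.
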