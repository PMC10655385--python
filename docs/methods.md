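# Methods

This note documents the models implemented in `mbscreen`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Plate model and normalization

Screening plates are 384-well (rows A–P × columns 1–24). In the default
layout the external columns 1, 2, 23 and 24 carry controls — negative
(DMSO, vehicle) and positive (bortezomib, kill control) alternating by
row, 32 wells each — and columns 3–22 carry the 320 test compounds. The
per-well arrangement of the two control types inside the control
columns is a package choice (only the columns are fixed by the assay
description); it is configurable through a `well,role` CSV.

Raw fluorescence is normalized per plate to percent-of-negative-control
viability, `100·raw/median(DMSO wells)`. The plate-wise DMSO median was
chosen over positive-control-anchored scaling because it is robust,
standard for resazurin screens, and leaves the kill control free to
serve QC. Plate quality is summarized by the Z′-factor
`1 − 3(σ₊+σ₋)/|µ₊−µ₋|` (fail below 0.5, configurable); coincident
control means yield Z′ = −∞ and an automatic fail.

## Robust-Z scoring and hit calling

Within each plate, test wells are standardized as
`z = (v − median)/(1.4826·MAD)`, center and scale computed on the
plate's *test wells* (sample-based scoring, as in cellHTS2's default):
the dedicated control columns would otherwise bias the spread estimate.
More negative z means stronger growth inhibition. Replicate plates are
scored separately and z averaged per compound, preserving per-plate
normalization. Per cell model, compounds are ranked ascending by mean z
(stable tie-break on compound id) and the top `ceil(p·n)` selected
(default p = 0.05; the ceiling guarantees a non-empty cut for small
libraries). The screen's deliverable is the cross-model union with
per-model provenance.

Two rates summarize performance on simulated screens: *recall*, the
fraction of spiked actives present in the cross-model union, and the
*false-positive rate*, the fraction of inert compounds selected per
model (averaged over models). The per-model rate is the meaningful
calibration of the calling procedure: a union over several independent
5% cuts mechanically exceeds 5% unless compound ranks were identical
across models, so the union's inert fraction measures cross-model
concordance of the library's background activity, not the caller.

## Dose–response and selectivity

Viability curves use the four-parameter logistic on log dose,
`v(d) = bottom + (top − bottom)/(1 + (d/m)^h)` with box constraints
bottom ∈ [0, 100], top ∈ [50, 120], h ∈ (0, 10], fitted by bounded
least squares with multi-start on log₁₀ m (7 starts spanning the tested
range ± 0.5 log, crossed with shallow/steep hill starts); the best RSS
wins. On noise-free data the fit recovers generating parameters to
< 0.1% (checked against a brute-force grid oracle).

GI₅₀ is the *absolute* 50%-of-control crossing
`m·((top−50)/(50−bottom))^(1/h)`, not the curve midpoint, because the
censoring rule is absolute: when the fitted curve stays above 50%
viability at the highest tested dose, no GI₅₀ is reported and the value
is censored at `> top dose`. The default confirmation design is 6
points, fivefold from 5 µM (5, 1, 0.2, 0.04, 0.008, 0.0016 µM) in
triplicate — the replicate count is unprinted in the source campaign;
triplicate is the standard resazurin design, and a single-replicate
fivefold series is information-limited (~10–12% median GI₅₀ error at
σ = 5 regardless of fitting).

Two directional ratios are kept distinct: the resistance fold-shift
GI₅₀(R)/GI₅₀(S) (how resistant the selected model became to a
chemotherapeutic) and the compound selectivity ratio GI₅₀(S)/GI₅₀(R)
(> 2 on at least one model pair ⇒ resistant-selective; symmetric for
sensitive-selective). A censored sensitive arm with a finite resistant
GI₅₀ contributes the conservative lower bound `top_dose/GI₅₀(R)`;
doubly censored pairs are "inactive". If a compound crosses the
threshold in both directions on different models, the larger fold wins,
keeping the two calls mutually exclusive. Summary percentages are
rounded half-up to two decimals.

The VECC composite is dosed in units: `x U` puts each of the four
drugs at `x` times its own GI₅₀, so the cocktail enters checkerboards
as a single axis.

## HSA synergy

For a checkerboard with single-agent margins, the per-cell excess over
the highest-single-agent reference is
`Δ(i,j) = inh(aᵢ,bⱼ) − max(inh(aᵢ,0), inh(0,bⱼ))`, with inhibition
clipped to [0, 100] so Δ is bounded in percentage points. The HSA score
is the mean Δ over combination cells only (the margins define the
reference, they are not evidence). Calls: synergistic at score ≥ +10,
antagonistic at ≤ −10, non-interactive between. The source legend
prints "antagonistic when HSA ≤ 10", which contradicts its own
non-interactive interval `10 > HSA > −10`; the only consistent reading,
≤ −10, is implemented. The matrix mean is used rather than a
most-synergistic-area mean (both exist in common synergy tools); a
window-based variant would be a straightforward extension. Replicate
matrices are averaged cell-wise before scoring. Note that clipping
combination inhibition at 100% slightly shrinks recovered positive
excesses when single agents already approach full kill (the +15
recovery sits near +13.5 on the default grids).

## Limiting dilution

Under the single-hit Poisson model a well seeded with d cells stays
sphere-free with probability `exp(−F·d)`; F is estimated by least
squares on observed negative fractions (log₁₀ F line search after a
coarse grid), with a profile-style 95% CI from the RSS acceptance
region. Saturated designs return bounds with flags instead of point
estimates. Two groups are compared by the extra sum-of-squares F test —
shared-F versus separate-F fits, `F = (RSS_sh − RSS_sep)/(RSS_sep/df)`
with df = n_points − 2 — matching the test named in the source rather
than the ELDA complementary-log-log GLM (a known alternative backend).

A caveat the test suite documents: on binomial well counts this
least-squares F test is *anticonservative* relative to an
exchangeable-null permutation of well outcomes (binomial fractions are
heteroscedastic and the residual df are few). Decisions agree for
clearly separated frequencies, and power at the default design
(frequencies 0.01 vs 0.05, 24 wells/dose, doses 10–1000) is essentially
complete, but borderline p-values near 0.05 should be read with this
bias in mind.

## Cohort stratification and survival

Differential features between matched sensitive/resistant models are
selected by a paired t-test across models on per-model medians
(features first intersected across all models), with a Z score that
standardizes each feature's median R−S difference against the
distribution over all features; selection at p < 0.05.

Patients are projected onto reference (resistant-model) samples by
Spearman correlation over the differential gene set — computed as
Pearson on average ranks, vectorised over the whole patients ×
references matrix and verified against both `scipy.stats.spearmanr`
and the closed-form `1 − 6Σd²/(n(n²−1))` on tie-free vectors. The
similarity matrix is clustered by k-means (Euclidean, k-means++ with 50
restarts, fixed seed) for k = 1..8; k is chosen as the maximizer of the
WSS second difference `WSS(k−1) − 2·WSS(k) + WSS(k+1)`. Because second
differences can never select k = 1 while k-means reduces WSS smoothly
even on unclustered data (a 1-D Gaussian loses at most 1 − 2/π ≈ 36%
of WSS to the best 2-split), a k > 1 is accepted only if it removes at
least half the total WSS; genuinely separated clusters in this
pipeline remove ≥ 70%.

Survival is compared with the Kaplan–Meier product-limit estimator per
cluster and the multivariate log-rank (Mantel–Cox) test (lifelines).
With zero events the p-value is reported as NA. For permutation
checks, a vectorised numpy implementation of the same chi-square
statistic is first verified to replicate lifelines' value on the
observed data, then evaluated over label permutations.

## Synthetic-data generators

All generators are pure functions of (configuration, seed) and emit
the same containers the analysis stages consume.

**Screen** (`simulate_screen`): 3533 compounds at 5 µM across 4 cell
models in duplicate; raw signal = plate gain (lognormal σ = 0.05) ×
10 000 a.u. × viability × (1 + ε), ε ~ N(0, CV = 0.10); DMSO wells at
0% inhibition, bortezomib at 95%. A compound's true inhibition is a
compound property shared across models: 40 actives drawn uniform
(50–95% inhibition by default) and an inert background with half-normal
nonspecific toxicity (scale 15 viability points). The background scale
is calibrated so the cross-model union of top-5% cuts lands near the
~300 compounds the real 4-model campaign funnelled into confirmation;
with fully inert backgrounds the union would inflate toward 4× the
per-model cut, which real screens do not show.

**Dose–response** (`simulate_drc`): Gaussian viability noise (default
σ = 5 points) around a true 4PL curve, clipped to [−5, 130], triplicate
fivefold design. The recovery experiment draws truth from
`draw_drc_truth`: confirmation-grade actives with GI₅₀ log-uniform over
the central tested doses (0.008–1 µM), hill 1–2.5, bottom 0–15, top
95–105 — the population a confirmation range is designed to straddle;
curves with GI₅₀ at or beyond the design edge are the censoring rule's
territory instead.

**Synergy** (`simulate_synergy`): HSA-null surface from two 4PL single
agents, a planted uniform excess δ on combination cells (clipped at
100% inhibition), and Gaussian viability noise (σ = 3) on every
measured cell.

**Limiting dilution** (`simulate_lda`): n_negative ~ Binomial(n_wells,
exp(−F·d)) at doses 10–1000 cells/well, 24 wells/dose (dose schedules
are unprinted in the source; these are conventional neurosphere LDA
settings).

**Cohort** (`simulate_cohort`): 763 patients, 962 signature genes, 12
reference samples over 3 reference models. Expression is built from a
shared resistant-signature core plus one latent profile per reference
model; each of the 3 patient clusters (proportions 0.35/0.42/0.23,
mirroring the reported low/intermediate/high-similarity subgroup
sizes) loads on the core and on one model profile, scaled by `sep`
(sep = 0 collapses the structure into one blob). Survival is
exponential with cluster hazards 0.03/0.06/0.15 per year under
independent exponential censoring tuned to ~30% censoring — the real
cohort's hazards are unpublished; these values merely realize "the
high-similarity cluster does worst" at a plausible pediatric scale.

What the generators deliberately do **not** emulate: spatial plate
artifacts (edge effects, gradients), plate-order drift, realistic
transcriptome covariance (genes are independent given the latent
profiles), cross-platform scaling between reference and cohort arrays,
competing risks, or informative censoring. Passing tests therefore
demonstrate correctness of the estimators under their stated models,
not robustness to those real-data pathologies.

## Problem sizes and determinism

The validation experiments use the study-scale defaults where cheap
(full 3533 × 4 × 2 screen, 763-patient cohort) and 100–200 Monte-Carlo
repeats for recovery/power experiments (200 dose–response curves, 200
limiting-dilution comparisons, 100 checkerboards per planted excess,
10⁴ label permutations for the log-rank check). All randomness is
funneled through explicit seeds (numpy `default_rng`; sub-seeds via
`SeedSequence`), so every table and summary regenerates bit-identically
from the same configuration.
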