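# Methods

## Task model

Each trial offers a smaller-sooner (SS) and a larger-later (LL) coin.
Distances are integers in grid squares; the avatar travels at
`seconds_per_square` = 1.3 s/square, so the delay of an option is its
distance × 1.3 s. Rewards are integer units 1–10 with 1 unit = 0.005 €, so
coins span 0.005–0.05 €; loot points accrue at 20 points per eurocent
(10 points per unit). The published reward-difference statistic
"5.0 (2.8) cents" is interpreted as 5.0 (2.8) *reward units*, since a mean
difference of 5 cents is impossible inside a 0.5–5 cent coin range.

Sessions are 3 blocks of 480 s. A new trial starts only while block time
remains; a started trial always completes and scores. Trial duration =
reaction time + travel time of the chosen option + a 0.8 s feedback
interval.

**Optimality.** Because total time, not trial count, is fixed, the option
with the higher reward per second of travel maximizes expected total
earnings. `label_optimal` compares r/t exactly (integer cross-products in
the generator, so ties are exact); the generator never emits ties, but
ingested logs are re-labelled and tie trials are excluded from optimality
and SDT scoring.

## Trial generation and calibration

Per trial the generator samples the distance difference Δd (uniform on
{1, 2, 4, 7}) and reward difference Δr (uniform on {1, 3, 5, 7, 9}), draws
the optimal-side label, and then places the SS option — absolute distance
d_SS ∈ {2..6} and reward r_SS ∈ {1..10−Δr} — uniformly within the region
of the offer space consistent with that label. Cells whose offer space
admits only one label (e.g. Δr = 9 forces LL-optimal; Δd = 7, Δr = 1
forces SS-optimal) are forced, so the Δ marginals are exactly the
configured ones: delay difference mean 4.55 s, SD 2.98 s; reward
difference mean 5.0, SD 2.83 units.

The overall LL-optimal rate is P(LL forced) + P(both feasible) × p, where
p is the label probability on two-sided cells. `calibrate_generator`
solves this analytically (p = 0.30 for the defaults, hitting the 60%
design rate) and verifies by pilot simulation; targets outside the
reachable range `[P(LL forced), P(LL forced) + P(both)]` (= [0.45, 0.95]
for the defaults) raise a calibration error. Absolute SS distances are a
design choice (not published); {2..6} squares was chosen jointly with the
reaction-time model so the default mean trial duration is ≈10 s, which
yields ≈143 completed trials per session.

## Agent model

Choice is logistic in the subjective-value difference:
P(LL) = σ(τ·(V_LL − V_SS − b)), with hyperbolic V = A/(1 + kD) and an
additive SS bias b ≥ 0. **Delays enter relative to the SS arrival**: the
SS reward is the temporal reference (D = 0) and the LL reward is
discounted by the delay difference Δ. This matches the indifference-point
definition (indexed by the LL−SS delay difference), so at indifference
r_SS/r_LL = 1/(1 + kΔ) exactly and parameter recovery is unbiased. With
absolute-delay discounting instead, the Δ-based estimator would be biased
low by ≈(1 + k·t_SS).

Reaction times are lognormal (meanlog = log 1.4 s, sdlog = 0.35), clamped
to [0.3, 15] s — the same bounds as the analysis-side validity filter, so
the filter removes nothing on simulated data, mirroring the empirical
report. The defaults k ~ LogNormal(log 0.15, 0.5) and
τ ~ LogNormal(log 2.0, 0.4) give discounting in the middle of the offered
value-ratio range (θ between ≈0.9 and ≈0.4 across delay levels), a
balanced SS/LL mix, and the ≈10 s mean trial duration above.

**Cohorts.** Two groups of 80 agents. Covariate distributions follow the
demographic profile of an acutely underweight anorexia nervosa (AN) sample
and age-matched healthy controls (HC): age ≈16.3 (2.5) y truncated to
[12, 26]; BMI-SDS 0.05 (0.64) vs −3.24 (1.07); BDI-II 4.6 (5.1) vs
26.3 (10.6), floored at 0; EDI-2 132.8 (25.4) vs 221.9 (44.2). Discounting
parameters are drawn identically in both groups; the AN group receives an
SS bias with mean 0.30 units, SD 0.15, linked −0.10/SD to BMI-SDS and
+0.10/SD to BDI-II (direction-only emulation of the reported clinical
associations; magnitudes are free parameters of the generator, not
empirical claims).

## Estimators

**Validity filter.** Keep 0.3 ≤ RT ≤ 15 s (inclusive; the exclusion rule
is "< 0.3 s" and "exceeding 15 s"). Idempotent.

**Indifference points.** Per delay-difference level (unique values rounded
to 0.1 s; {1.3, 2.6, 5.2, 9.1} s for generated data), P(choose SS) is fit
as a logistic function of the value ratio v = r_SS/r_LL by maximum
likelihood with the slope constrained non-negative; θ is the ratio at
fitted P = 0.5. Constant responses clip to the endpoints — always-SS means
indifference below every observed ratio (extreme discounting, θ = 0);
always-LL means θ = 1 — and crossings outside the observed ratio range are
clipped into [0, 1]; both cases set the `clipped` flag. Levels with fewer
than 4 trials are flagged low-n. Because the offered ratios form a
discrete grid (max 0.9), very shallow discounters (k ≲ 0.02/s) saturate at
θ = 1 for short delays; this floors their recovered k, a resolution limit
of the design, not of the fit.

**Hyperbolic k.** Least squares of θ(Δ) = 1/(1 + kΔ) over k ∈ [0, 10]/s:
2000-point log-spaced grid plus k = 0, then bounded scalar refinement
(tolerance 1e-6) between the neighbouring grid points. log k uses a floor
of 1e-4/s so k = 0 maps to ln(1e-4) ≈ −9.21.

**AUC.** Trapezoid area under (Δ/Δ_max, θ) with the anchor (0, 1)
prepended: at zero delay difference the options differ only in reward, so
the normative indifference ratio is 1. Result in [0, 1].

**SDT.** Signal = LL-optimal, yes = chose LL (the convention is symmetric;
the criterion location c = −(z_H + z_F)/2 is emitted alongside β for
robustness). Extreme rates are corrected by the standard 1/(2N) rule
before the z-transform. Note that a *value-maximizing* agent is not a
*rate-maximizing* observer: even with zero SS bias its criterion in
reward-rate space is liberal toward LL (β < 1), and its proportion of
optimal choices is strictly below 1 at any noise level. β is therefore
informative as a *contrast* between groups or bias levels, not against an
absolute β = 1 baseline; an injected SS bias raises β markedly while
moving d′ by <10% at matched τ — the dissociation the analysis relies on.
A τ = 0 (random) agent does sit at d′ ≈ 0, β ≈ 1.

**Group statistics.** Welch t from summary statistics with
Welch–Satterthwaite df; power via the noncentral t (one-sided α = 0.05 by
default — the only setting consistent with the published power statements
93/60/35% at d = 0.5/0.3/0.2, n = 80/group); Benjamini–Hochberg FDR over
the co-reported family of eight outcome contrasts; binomial models on
per-subject success/total counts (subject-level aggregation avoids
unmodelled within-subject correlation) and OLS for continuous outcomes,
both with age as covariate; case–control age matching by the Hungarian
algorithm on |age difference|.

## What the synthetic cohort does and does not show

The generator reproduces the task's design statistics and the direction of
the reported group pattern: with a positive injected SS bias the AN group
shows a higher SS proportion, higher optimality, and a higher SS rate when
SS is optimal. Passing tests demonstrate that the estimators recover known
parameters and effect directions from data generated by this model — not
that the model captures real AN decision-making. Two leakage properties
are worth noting when interpreting synthetic runs: an additive SS bias
shifts measured indifference points by ≈b/r_LL, so large injected biases
produce apparent group differences in log k and AUC that the empirical
study did not show; and the additive bias shifts both side-conditional
proportions, whereas the empirical effect appeared only when SS was
optimal. Real-data features not emulated: within-session learning or
fatigue, RT dependence on choice difficulty, the tutorial block, and any
subtype structure within the patient group.

## Problem sizes

Statistical checks use 100,000 generated trials (design moments), 160
simulated sessions (session length), 4,000-trial agent runs (SDT
dissociation), and 16 full sessions across a 4-point k grid (parameter
recovery). The full default pipeline (160 subjects, ≈23k trials) runs in
well under a minute.
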