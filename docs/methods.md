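# Methods

## The population model

`lrckit.simulate` models an intravenous transplant of `n_injected` leukemia
cells into a recipient animal. Each cell independently lodges in the bone
marrow with probability `homing_prob` (homing is sample-specific and can
span 10⁻⁴–10⁻¹ across leukemia samples). Homed cells then evolve in discrete
time steps of `dt` days (default 1):

1. **Division.** An active cell divides with probability
   `r·dt·(1 − N/K)`, floored at 0 — a logistic slow-down in which the niche
   capacity `K` throttles the division *rate*, consistent with
   nutrient/niche limitation. Both daughters inherit the parent's division
   count plus one. Dormant cells divide with `dormant_div_rate·dt`
   (default 0).
2. **Death.** Every cell dies with the per-step equivalent of the daily
   probability `d`.
3. **Compartment switching.** Dormant cells wake with `p_wake` per day,
   active cells fall dormant with `p_sleep` per day; both are memoryless.
   At engraftment a cell starts dormant with probability `p_dormant_seed`.
4. **Treatment.** On scheduled days, cells that divided within the
   preceding day die with `kill_prob_divided`, others with
   `kill_prob_undivided` (`kill_prob_divided ≥ kill_prob_undivided`:
   proliferation-dependent kill is what makes dormant cells drug-resistant
   here).

Division, death and switching are binomial thinning operations on the whole
population, so the simulator is exact for the stated per-step probabilities
(no tau-leaping approximation error beyond the chosen step). A configurable
`hard_cap` (default 2×10⁷ cells) aborts runaway configurations with an
explicit error rather than exhausting memory.

**Label arithmetic.** Each cell carries a dye intensity `m0·2^−k`, where `k`
is its division count and `m0` the true post-bleaching intensity at day 3.
The first `lag_days` (default 3) are division-free, so a day-3 flow sample
is a clean zero-division reference — matching the calibration protocol in
which the day-3 MFI defines "0 divisions". Measurement noise is lognormal
and median-preserving: `measured = true·exp(σZ)` with `σ² = ln(1+cv²)`, so
the geometric mean is a consistent estimator of the true intensity and
`cv_mfi = 0` yields an exact readout. Bleaching itself is not simulated;
`m0` is *defined* as the post-bleaching value.

**Reversibility.** Dormancy is an environment-dependent state, not a
lineage property. `retransplant` re-randomizes compartment membership with
`p_dormant_seed` and resets the label, so re-transplanting sorted
fully-diluted cells regenerates the same dormant fraction as a bulk
transplant — the model's implementation of reversible dormancy, asserted as
a statistical property in the tests.

### Default study conditions

| parameter | default | units | rationale |
|---|---|---|---|
| `n_injected` | 10⁵ | cells | desk-scale stand-in for 10⁷-cell injections |
| `homing_prob` | 0.005 | — | middle of the >2-decade sample-to-sample range |
| `r` | 0.9 | /day | early log-linear burden growth over ~2 weeks |
| `K` | 10⁶ | cells | marrow capacity; saturation within 3 weeks |
| `d` | 0 | /day | death folded into net growth unless studied |
| `p_dormant_seed` | 0.01 | — | rare dormant compartment |
| `p_wake`, `p_sleep` | 0 | /day | long-term dormancy over the 21-day horizon |
| `dormant_div_rate` | 0 | /day | label-retaining by construction |
| `m0` | 1000 | MFI units | arbitrary scale; all gating is ratio-based |
| `cv_mfi` | 0.2 | — | realistic flow CV |
| `detection_threshold` | 5×10⁵ | photons/s | imaging engraftment call |
| `n_days`, `lag_days` | 21, 3 | days | three-week experiment, day-3 reference |

The burden readout `pct_blasts = 100·N/K` reads `K` as the accessible
marrow cellularity; MRD calls use it directly.

## Gating

The reference statistic is the geometric mean by default (consistent under
the lognormal noise model); median, KDE-mode and maximum are available but
the maximum is noise-fragile. Division counts are `round(log2(ref/mfi))`
clipped at 0. Class boundaries operate on raw MFI thresholds
(`ref·2^−3`, `ref·2^−7`, both inclusive): LRC means *at most three*
bisections, non-LRC *seven or more*. Because a rounded count crosses an
integer exactly where the MFI crosses the corresponding threshold, counted
divisions and gate classes can never disagree at a boundary. The source
phrasing of the boundary conventions is ambiguous at exactly 3 and exactly
7; both bounds are `GateConfig`-overridable.

## Growth fitting and selection

Both models are fitted to log burden (multiplicative noise): exponential by
OLS (the lognormal MLE), logistic by Levenberg–Marquardt least squares on
log-scale parameters `(ln N0, ln r, ln K)` with multi-start initialization —
`N0` from the first observation, `r` from the early log-slope,
`K ∈ {2, 10, 100}×max(burden)`. Wald standard errors come from the Jacobian;
the capacity is flagged unidentifiable when `se(ln K) ≥ 2` (early-phase
data). Zero burdens are left-censored at half a user-supplied detection
limit, with a warning. Model choice uses AICc with the residual variance
counted as a parameter (k = 3 exponential, 4 logistic); ΔAICc < 2 is
reported as *equivocal*, never forced. BIC is available via a flag. Wald
intervals on `r` are mildly anticonservative under sparse sampling; with
daily observations (the simulator's native cadence) their empirical
coverage is ~91–95%.

## Limiting dilution

The single-hit model `P(engraft|d) = 1 − (1−f)^d` is fitted by bounded
scalar maximization of the binomial log-likelihood over `ln f`
(`xatol 10⁻¹²`); tests verify agreement with a 10⁴-point grid-search oracle.
The 95% CI inverts the profile likelihood at χ²₁(0.95)/2 = 1.921 via Brent
root-finding on each side. All-negative tables return `f = 0` with the
closed-form one-sided bound `1 − exp(−1.921/Σ nᵢdᵢ)`; all-positive tables
return `f = 1` with a one-sided lower bound; both are flagged, never raised.
Goodness of fit is a likelihood ratio against the saturated per-dose model
(df = doses − 1). Two assays are compared by a 1-df LRT against the pooled
fit, with a warning when a boundary MLE degrades the χ² reference. A Wald
interval on `ln f` (`fit_wald`) exists for comparison only. Frequencies are
also reported in the conventional "1/n cells" form by rounding `1/f`.

## Treatment statistics

Survival per gate class is the treated/control count ratio with a
conditional-binomial (Wilson-transformed) Poisson-ratio CI; zero-control
classes are excluded with a warning. The relative drug effect is the
elimination ratio scaled to non-LRC = 100%; it is scale-free in the counts.
Enrichment folds get a delta-method CI on the log fold when sample sizes
are supplied. MRD is strictly `< 1%` blasts with a molecular-remission-like
tier below 0.1%; both thresholds are arguments. Where several animals per
arm are analyzed, per-animal estimates are computed first and then averaged
(the package's default aggregation, applied in the acceptance script).

## Expression and signatures

The generator draws NB2 counts (`var = μ + φμ²`, default dispersion
φ = 0.5) with lognormal baseline means; planted genes shift the group-A
mean by the specified log2 fold-change and a global library factor < 1
emulates the reduced RNA content of dormant cells. The differential test is
a counts-per-median-depth-normalized two-sided Mann-Whitney test with BH
adjustment and pseudocount-1 fold-changes — a self-contained substitute for
read-level single-cell pipelines, adequate for synthetic counts; all-zero
genes are carried neutrally (p = FDR = 1, log2FC = 0). Signatures take
FDR ≤ 0.05 and |log2FC| > 1 (symmetric in direction), ranked by p-value
with |log2FC| as tie-break. The overlap test is the exact hypergeometric
upper tail; the directional variant counts same-direction overlap against
the same null and is therefore conservative for discordant sets. Rank
enrichment is a weighted running sum (hits weighted by |statistic|, misses
by a uniform decrement, ES = signed maximum deviation) with a gene-label
permutation null, calibrated against the same-sign half of the permutation
distribution with the usual +1 correction — this keeps null p-values
uniform, which the tests check by KS. Gene-label (not phenotype)
permutation keeps the null deterministic under a seed at desk scale.

## What the generator does and does not emulate

It reproduces the statistical structure the inference assumes:
sample-specific homing, logistic burden growth, a rare long-term dormant
compartment, 10–100-fold differential drug kill, single-hit engraftment,
reversibility on re-transplant, and planted transcriptomic separations with
reduced RNA content. It does **not** model spatial niche geometry,
pharmacokinetics, clonal genetics, bleaching kinetics, flow spillover or
doublets, or read-level sequencing noise — so green tests certify the
inference machinery on data satisfying the model's assumptions, not the
biology of any particular sample.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make Monte-Carlo
bands tight relative to the assertions: 500-replicate CI coverage for the
limiting-dilution fit (doses {3, 10, 30}, 20 mice/dose, f = 1/50),
200-replicate model-selection arms, 100 random tables for the MLE/grid
oracle, cohorts of 10⁴–10⁶ cells for truth-recovery checks, and
2000-gene × 40–100-cell matrices for expression power and FDR checks.

## Known limitations

- The discrete-day logistic map recovers `ln(1 + r)` rather than `r` when
  continuous-time fits are applied to simulator output; use finer `dt` when
  that distinction matters.
- Profile CIs assume the single-hit model; heterogeneous initiator
  frequencies (multi-hit) are out of scope.
- The Mann-Whitney DE test is underpowered at very small cell numbers and
  ignores batch structure; it is a pipeline stage, not a methods
  contribution.
- The directional overlap p-value is conservative by construction.
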