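# lrckit

Simulation and inference toolkit for **label-retaining cell (LRC) dormancy
studies** in leukemia xenografts.

## The problem

In acute lymphoblastic leukemia (ALL), a rare subpopulation of tumor cells
divides slowly or not at all. These dormant cells survive chemotherapy —
which targets proliferation — persist as minimal residual disease (MRD,
< 1% blasts in bone marrow), and can re-initiate the disease. Experimentally
they are found by staining patient-derived xenograft (PDX) cells with a
proliferation-sensitive dye (CFSE): every division halves the dye, so cells
that retain a bright label after weeks of leukemic growth are the dormant
candidates.

`lrckit` packages the quantitative machinery of such a study:

- **`lrckit.simulate`** — a stochastic, discrete-time birth-death simulator
  of label-diluting, niche-limited leukemia growth with a rare reversible
  dormant compartment, proliferation-dependent drug kill, limiting-dilution
  assays, and negative-binomial expression matrices with planted signatures.
  It is the fully tested stand-in for all animal data.
- **`lrckit.gating`** — day-3 reference calibration and division counting:
  `k = round(log2(M0 / MFI))`; cells with `k <= 3` gate as LRC, `k >= 7` as
  non-LRC, the rest as "others".
- **`lrckit.growth`** — homing efficiency with Wilson intervals, and
  exponential vs logistic fits, `N(t) = K / (1 + (K/N0 - 1) e^{-rt})`, on
  log burden with AICc model selection.
- **`lrckit.lda`** — single-hit Poisson limiting dilution:
  `P(engraft | dose d) = 1 - (1 - f)^d`, maximum likelihood over `log f`,
  profile-likelihood 95% CIs, goodness of fit, and likelihood-ratio
  comparison of two assays. Engraftment is called from bioluminescence flux
  at the 5×10⁵ photons/s detection threshold.
- **`lrckit.treatment`** — per-class survival fractions, the *relative drug
  effect* `100 × (1 - S_LRC) / (1 - S_nonLRC)` (non-LRC = 100%), LRC
  enrichment folds, and MRD calls at the 1% burden threshold.
- **`lrckit.signature`** — rank-sum differential expression with BH-FDR,
  signature derivation (FDR ≤ 0.05, |log2FC| > 1), exact hypergeometric
  overlap tests, fold-change sign concordance, and a weighted running-sum
  rank enrichment with a gene-permutation null.

Model-fitting stages follow the model/results convention: build a model from
data, call `.fit()`, read estimates, standard errors and diagnostics off the
results object (`GrowthResults.summary()`, `LDAResult.summary()`).

## Worked example

```python
import lrckit as lk

cfg = lk.SimConfig(n_injected=100_000, homing_prob=0.005, r=0.9, K=1e6,
                   p_dormant_seed=0.01, cv_mfi=0.2, n_days=21, seed=42)

# calibrate the reference from a day-3 experiment (before proliferation)
day3, _ = lk.simulate_engraftment(cfg.with_(n_days=3))
reference = lk.calibrate_reference(lk.measure_flow(day3, cv_mfi=0.2, seed=1))

# three-week experiment: gate the final flow sample
cohort, burden = lk.simulate_engraftment(cfg)
gated = lk.classify_cells(lk.measure_flow(cohort, cv_mfi=0.2, seed=2), reference)
print(f"day-3 reference MFI: {reference:.1f}")
print(f"gate counts: {gated.counts}")
print(f"LRC fraction: {gated.lrc_fraction:.2e} "
      f"(95% CI {gated.lrc_ci[0]:.2e}-{gated.lrc_ci[1]:.2e})")

# which growth law? (post-lag phase)
growth_phase = burden[burden["day"] >= 3]
sel = lk.select_model([lk.ExponentialGrowth(growth_phase).fit(),
                       lk.LogisticGrowth(growth_phase).fit()])
print(sel)

# limiting-dilution assay at a true initiating-cell frequency of 1/50
table = lk.simulate_lda(f_true=1/50, doses=[3, 10, 30], mice_per_dose=20, seed=3)
print(lk.SingleHitModel(table).fit().summary())
```

Output:

```text
day-3 reference MFI: 991.7
gate counts: {'LRC': 2, 'others': 704, 'nonLRC': 999290}
LRC fraction: 2.00e-06 (95% CI 5.48e-07-7.29e-06)
model selection (aicc): logistic
         model       aicc      delta
0     logistic -45.598245   0.000000
1  exponential  46.974464  92.572709
Single-hit limiting dilution fit on 3 dose(s), 60 mice
  frequency f = 0.01526 (1/66 cells)
  95% CI [0.007927, 0.02611] (1/38 to 1/126 cells)
  log-likelihood -22.88
  single-hit goodness-of-fit p = 0.38
```

Reading it: the day-3 calibration recovers the true post-bleaching label
intensity (1000 units) to within 1%; after 21 days of logistic growth the
dormant compartment is a ~2-per-million rarity among fully label-diluted
cells; AICc decisively prefers the logistic law on the saturating burden
series; and the single-hit fit brackets the simulated frequency 1/50
(= 0.02) inside its profile-likelihood interval, with no evidence against
the single-hit dose-response.

A console script exposes the same stages:
`lrckit simulate|gate|growth-fit|lda|drug-effect|signature --help`.

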