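# Methods

## Signals: from RR series to deceleration capacity

The unit of input is a per-patient sequence of beat-to-beat RR intervals
with onset times.  Analysis proceeds in three stages.

**NN filtering.**  A beat enters the normal-to-normal (NN) series when it is
labelled `normal`, its interval lies inside physiologic bounds (default
300–2000 ms), and it differs from the last accepted interval by at most 20%.
Defaults follow standard Holter practice.  The last-accepted reference can
deadlock when the first accepted beat is itself aberrant (e.g. a
compensatory pause opening the record): every subsequent normal beat is then
>20% away.  The filter therefore resets its reference after 10 consecutive
rejections and re-seeds on the next in-bounds normal beat.  Every removal
sets a gap flag on the following kept beat; nothing is removed silently.

**Anchor selection.**  Beat *i* is a deceleration anchor when
RR(i) > RR(i−1), the relative increase is ≤ `max_relative_increase`
(default 5%, the conventional artifact guard — larger jumps are more likely
ectopy than vagal activity), and the full window [i−L, i+L−1] exists
without crossing a gap (phase coherence across gaps is meaningless).
L defaults to 2, the minimum housing the four wavelet indices.

**PRSA profile and DC.**  X(k) is the mean RR at offset k over all anchors;

    DC = [X(0) + X(1) − X(−1) − X(−2)] / 4  (ms).

This is the Haar-wavelet contrast at scale 2 centred on the anchor.  Some
clinical reports print the formula with four plus signs; that expression
evaluates to ≈ mean RR (hundreds of ms), not a capacity in the 0–10 ms
range, so the signed form is the default and the all-plus form is retained
only behind `formula_convention="as_printed"` for auditing printed numbers.
A regression test asserts the two differ by two orders of magnitude on
stationary series.

Risk stratification uses the conventional cutoffs: DC > 4.5 ms low risk,
2.5 < DC ≤ 4.5 ms intermediate, DC ≤ 2.5 ms high (boundaries belong to the
lower band).

## HRV panel

Time domain: SDNN (sample SD of all NN), SDANN (sample SD of 5-min segment
means, grid anchored at the first beat, incomplete tail dropped — making the
estimate deterministic and order-independent), rMSSD and pNN50 (successive
differences, pairs spanning a gap excluded; pNN50 uses |Δ| > 50 ms), and
mean HR = 60000 / mean NN (robust to gaps, unlike beats-per-elapsed-time).

Frequency domain: LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) band powers in
ms² of the NN tachogram *as a function of beat time* — a Lomb–Scargle
periodogram of the irregularly sampled series, no interpolation.  Each
5-minute segment's raw periodogram (4× oversampled natural resolution, up
to 0.5 Hz) is rescaled so its integral equals the segment variance; band
powers are the corresponding variance shares, and segment powers are
averaged over the record.  This construction makes the Parseval identity
exact by design: a single in-band sinusoid of amplitude A yields A²/2
(tested at 10%).  Segment averaging is the conventional way 24-h spectral
indices are produced and keeps the estimator O(beats × segment-resolution);
a 24-h single periodogram at natural resolution would cost ~10¹⁰
evaluations per patient.  Mean removal per segment makes the powers
invariant to interval offsets.  HF = 0 reports the LF/HF ratio as missing,
never infinite.

## Outcome models

**Logistic regression** (the probability source for reclassification
statistics) is fitted by IRLS with step halving, which guarantees a
monotone log-likelihood trace (stored on the fit object); convergence is a
relative log-likelihood change < 1e-10 or 100 iterations.  Perfect
separation is detected (diverging linear predictor with vanishing weights)
and raised, never silently returned.  The implementation is cross-checked
against statsmodels in the test suite.

**Cox proportional hazards**, Kaplan–Meier curves and the k-group log-rank
test are delegated to lifelines (Efron tie handling; Breslow is not
offered).  Hazard ratios carry Wald 95% CIs exp(β ± 1.96 SE) throughout —
no profile likelihood — and Harrell's C over comparable pairs.

**Categorical tests** come in both flavours — Pearson χ² and the
likelihood-ratio G = 2 Σ O ln(O/E) — because clinical tables rarely state
which variant produced a printed statistic; the baseline table reports
both for every categorical row.  Continuous variables are gated by
per-group Shapiro–Wilk at α = 0.05 into ANOVA (mean ± SD) or
Kruskal–Wallis (median, IQR); the gate decision is recorded per variable.

## Incremental value of an added marker

Given nested logistic fits (base: GRACE score; updated: GRACE + DC or
GRACE + LF/HF) on the same patients:

- **LRT**: χ² = 2(llₑₓₜ − llᵦₐₛₑ), df = difference in parameter count.
- **AICc**: −2 ll + 2k + 2k(k+1)/(n−k−1); ΔAICc, relative likelihood
  exp(−Δ/2) and Akaike weights (normalised), sorted by AICc.
- **Continuous NRI**: any risk increase is "up", any decrease "down",
  exact ties stay in the denominators; NRIₑ = (upₑ−downₑ)/nₑ,
  NRIₙₑ = (downₙₑ−upₙₑ)/nₙₑ, NRI = NRIₑ + NRIₙₑ.  The asymptotic SE is the
  binomial form √((up+down)/n² − (up−down)²/n³) per class, combined in
  quadrature; z = NRI/SE.  A percentile bootstrap (2000 resamples) is
  available as an option.  The reclassification count table is always
  emitted so NRI is auditable from counts.
- **IDI**: gain in discrimination slope, computed both as the component sum
  and as the slope difference; the two must agree to 1e-12 (asserted at
  runtime).  SE = √(var(d)ₑ/nₑ + var(d)ₙₑ/nₙₑ) with d = p_new − p_old.
- **ROC**: AUC via the tie-corrected Mann–Whitney statistic (identical to
  trapezoidal integration; asserted against scikit-learn), SE/CI by DeLong
  (Hanley–McNeil behind a flag), Youden-optimal cutoff (ties → lowest
  threshold), Harrell's C attached when survival times are supplied.

Two calibration caveats, measured rather than assumed.  First, for
*in-sample* nested fits with a pure-noise added marker the NRI point
estimate is optimistically biased (mean ≈ +0.10 at n = 323, event rate
0.127) because the refitted noise coefficient aligns with in-sample
accidents; the z-tests nevertheless hold size approximately (measured
rejection ≈ 4–7% at α = 0.05 for both NRI and IDI; the NRI test is the
borderline-anticonservative one).  Second, the asymptotic NRI p-value can
differ substantially from published values computed with unstated methods;
the count table lets readers recompute under any convention.

## Study pipeline

`run_study` executes: per-patient DC + HRV → DC-group stratification →
baseline table → KM/log-rank across the three DC groups → univariate Cox
screen over the configured covariates → multivariate Cox on the p < 0.05
survivors (threshold configurable) → enrichment comparison of GRACE-only
vs GRACE+DC vs GRACE+LF/HF → optional STEMI / NSTE-ACS subgroup screens
when a `presentation` column exists → JSON report plus CSV tables.  The
GRACE score is always an input column, never computed.  The composite
endpoint is first-event (death or non-fatal MI); reports contain no
timestamps so reruns are byte-identical.  No multiple-testing correction
is applied (flagged in report metadata).  The report structure is checked
by a bundled schema validator on every write.

## Synthetic cohorts and what they do (not) show

The generator builds each beat as

    RR = base·(1 + circadian) + LF·sin(2π·0.10·t) + HF·sin(2π·0.25·t) + ε,

with defaults base 800 ms, circadian amplitude 8%, LF 6 ms, noise σ 4 ms,
ectopy 0.5%/beat (premature beat at 0.6× plus compensatory pause), duration
24 h.  The HF amplitude is the vagal-tone dial: per patient it is
11·exp(0.8·tone) ms, capped at 40 ms because beyond that the 5% anchor
guard rejects the oscillation itself and DC saturates (the dial is
monotone over the working range, Spearman ρ > 0.8 by test).  GRACE scores
are drawn N(97, 26²) with a Gaussian-copula correlation of −0.3 to the
tone; through the lognormal amplitude map the realised corr(DC, GRACE) is
≈ −0.25.  Event times follow a Weibull baseline (shape 1.2 — mild aging
hazard, closed-form sampling; scale 400 months) multiplied by
exp(ln 1.020·(GRACE−97) + ln 0.885·(DC−mean DC)), administratively
censored at 60 months; these defaults give an event rate of ~12–14%
(matching a 41/323 study), split 9/41 death vs non-fatal MI.

Deliberately, the hazard uses the **pipeline-computed DC**, not the latent
tone, so parameter-recovery experiments close the loop through the signal
chain: Cox fits on 200 generated cohorts (n = 500) recover HR_DC and
HR_GRACE within a few percent with ~93–98% Wald CI coverage.  Because the
regressor in the hazard and in the fit are the same quantity, recovery is
exact in expectation even for short records; 10-minute records are used in
the recovery experiments and 2-hour records in the end-to-end summary run
purely to keep simulation sizes proportionate — the estimand does not
change with duration.

What the generator does *not* emulate: real respiratory non-stationarity,
atrial fibrillation or other non-sinus rhythm (excluded populations),
autonomic drift linking tone to the circadian profile, covariate-dependent
censoring, and any dependence of death-vs-MI type on covariates.  Passing
tests therefore demonstrate correctness of the estimators and the pipeline
plumbing under a proportional-hazards world, not clinical validity on real
Holter data.

## Numerical choices

- 0-based beat indexing; anchors index the filtered NN series.
- Anchor windows never span gaps; a gap *before* the window's first beat is
  allowed (it lies outside the window).
- DC is shift-invariant and scale-equivariant on series where the anchor
  set coincides (property-tested).
- Youden ties resolve to the lowest threshold; ROC thresholds sweep the
  unique score values.
- AICc requires n − k − 1 > 0 and raises otherwise.
- Kruskal–Wallis on all-identical data returns H = 0, p = 1 with a
  degenerate flag (midrank convention) instead of raising.
- Seeds: every stochastic routine takes an explicit integer seed and is
  bit-reproducible; per-patient RR seeds are spawned from the cohort seed.

## Known limitations

- LF/HF from the generator is only loosely controlled by the tone (the
  ratio involves both bands), so the LF/HF enrichment arm behaves as a
  weak marker — intentionally mirroring its clinical behaviour.
- The NRI/IDI z-tests are asymptotic and slightly anticonservative for
  in-sample nested comparisons (see above); the bootstrap option is the
  conservative alternative.
- Single-run study summaries at n = 323 (41 events) carry large sampling
  noise in every headline statistic; only the replicated experiments are
  stable.
- Efron is the only tie-handling method for Cox fits.
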