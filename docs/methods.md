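# Methods

## Cross-correlogram construction

For an ordered pair (pyramidal reference, interneuron target) restricted to
an analysis interval, every spike pair contributes a lag
`Δ = t_int − t_pyr`. Lags are histogrammed on a fixed lattice of 101 bins of
1 ms width with centers at integer milliseconds from −50 to +50 and
half-open edges at half-integers, `[c − 0.5, c + 0.5)` ms. This makes the
0.5–2.5 ms monosynaptic window exactly the two bins centered at +1 and
+2 ms, and the ±10–50 ms flanks exactly 41 bins per side. Counts are
normalized by the number of reference spikes `n_ref` in the interval, so a
bin value is the probability of an interneuron spike at that lag per
pyramidal spike. A pair with `n_ref = 0` in an interval has no CCG there;
downstream metrics report missing rather than zero. When the two trains are
the same unit, zero-lag self-pairs are excluded.

The histogram is computed with a sorted two-pointer sweep
(`searchsorted` bounds per reference spike); unit tests pin it bin-exactly
to a quadratic all-pairs oracle up to 10⁴ spikes per train.

## Detection and spike-transmission probability

* Chance level: mean normalized CCG over the 82 flank bins.
* Peak statistic: `z = (max of the two peak-bin raw counts − flank mean) /
  flank SD`, computed on raw counts; a pair is significant at `z ≥ 3`.
  A zero flank SD leaves detection undefined (reported not-significant with
  a flagged `nan` z) rather than inventing an infinite score.
* Transmission probability: sum over both peak bins of
  `(bin probability − chance)`. Units: extra interneuron spikes per
  pyramidal spike. Values can be slightly negative for independent pairs —
  legitimate sampling noise around zero — and are retained unclamped;
  bounded change scores clamp at zero only when forming `(b−a)/(b+a)`.
* Detection runs on the whole-recording CCG; per-session CCGs supply the
  per-session transmission values.
* Quality filters: a pair must have ≥ 1000 total coincidences within
  ±50 ms in FAM1 or FAM2, and in a qualifying session the bin-value SD must
  be below one third of the mean. The dispersion test is evaluated on the
  flank bins by default so a genuine large peak cannot disqualify its own
  pair; a switch (`dispersion_on_flanks=False`) evaluates all 101 bins
  instead.

Two bins were chosen for the transmission sum because a 1–2 ms-wide peak at
1–2 ms latency spans both lattice bins; using the max bin alone would
undercount broad peaks, and wider windows dilute the estimate with chance
mass.

## Light-response PSTH

Spike probability in 20 ms bins over a (−0.1 s, +0.6 s) window around
pulse onsets, normalized by the number of pulses. A cell is classified
`suppressed` / `activated` when its mean in-pulse bin value falls below
(1−θ) or above (1+θ) times the pre-pulse baseline (θ = 0.5 by default);
otherwise `unmodulated`. θ trades misclassification of noisy low-rate cells
against sensitivity to weak modulation; 0.5 cleanly separates the simulated
suppression (×0.1–0.3) and disinhibition (×2–2.5) regimes.

## Session metrics

* Session rate: spike count / interval length, also over interval unions
  (used for in-light rates and split halves).
* Change score `c = (b − a)/(b + a)`: bounded in [−1, 1], antisymmetric,
  missing when both terms are zero. Applied identically to rates,
  transmission probabilities, and pairing counts.
* Alternating split: consecutive 5 s blocks numbered from the session
  start; odd- vs even-numbered blocks give two interleaved half-sessions.
  The across-pairs correlation of a metric between halves is the
  within-session stability ceiling; cross-session correlations are compared
  against it with the Fisher-Z two-correlation test.
* Pairing counts: all (pyramidal, interneuron) spike pairs with
  `0 < |lag| ≤ W` for `W ∈ {10, 20, 50, 100}` ms, tallied separately for
  pyramidal-leading ("+", causal direction) and interneuron-leading ("−")
  order plus their sum. Zero-lag ties are directionless and counted in
  neither; every pair counts, so one spike can enter several pairs. For
  independent Poisson trains `E[count_all] = 2 W r_pyr r_int T`, a property
  test of the implementation and the basis for rate-predicts-pairing
  analyses.

## Statistical layer

All models that enter likelihood comparisons are fit by maximum likelihood
(not REML). The animal random intercept is tested by a likelihood-ratio
test against the plain linear model with a χ²(1) reference; testing a
variance on its boundary makes this conservative, which is accepted and
documented rather than corrected. When the optimizer collapses the
random-intercept variance to zero (statsmodels reports an infinite profile
likelihood there), the boundary ML solution is the OLS fit and is used
directly, giving an LRT statistic of exactly zero.

Independent contributions of fixed predictors ("does NOV still predict FAM2
once FAM1 is in the model?") are single-term F-tests on the full ML fit,
equivalent to a full-vs-drop-one comparison for one-degree terms. Missing
metric values are removed listwise per model with the per-model n logged.
Partial correlations residualize both variables on the controls (with
intercept) and correlate the residuals; a variable fully explained by its
controls has partial correlation 0, while a constant input yields missing.
Holm–Bonferroni step-down controls the family-wise error across pairing
windows. R² confidence intervals use a seeded 1000-resample bootstrap
percentile interval.

## Synthetic data generator

The generator emulates a recording day: exploration sessions FAM1, NOV,
FAML, FAM2 of 1500 s each, then a 1080 s rest session tiled with 500 ms
light pulses every 3 s (the pulse period is a free knob; 3 s leaves ample
pre-pulse baseline for the PSTH). Within a session each cell is a
homogeneous Poisson process; base rates are log-normal (defaults put
pyramidal cells at ~0.3–3 Hz and interneurons ~5–30 Hz), multiplied by a
per-animal log-normal offset (SD 0.15 in log rate) that the mixed models
should absorb.

During FAML, light is delivered in alternating 10 s epochs at 50% duty
cycle — a surrogate for position-triggered illumination of a fixed sector
of the arena, which would require simulating trajectories. Light multiplies
the rate of suppressed cells by `suppression_factor` (default 0.3) and of
disinhibited pyramidal cells by `enhancement_factor` (default 2.0); the
same cells respond to the rest-session pulses, which is what the PSTH
classifier recovers.

Connections are planted additively: each presynaptic spike triggers, with
session-specific probability `p_trans`, one extra postsynaptic spike at a
truncated-normal latency (mean 1.4 ms, SD 0.3 ms, truncated to
[0.5, 2.5] ms so planted peaks land wholly inside the detection window).
Background is not thinned — the detection statistic assumes an additive
peak over a chance floor, and the planted probability is then exactly the
expected excess probability the estimator measures. Postsynaptic spikes
closer than 0.1 ms are merged; at the simulated rates this removes ≲0.3% of
transmission spikes (a negligible downward bias ≪ the ±0.01 recovery
tolerance). Identical config and seed give identical spike trains.

What the generator does **not** emulate: place-field spatial structure,
theta rhythmicity, bursting, refractory dynamics, common-input
correlations, and non-stationary rates within a session. Consequently,
passing recovery tests show that the estimator is calibrated and unbiased
when the CCG flanks are flat in expectation; on real data, slow co-rate
fluctuations raise the flanks and the chance subtraction is precisely the
mechanism that compensates. The null-calibration result (false-positive
rate ≤ 2%) is for independent Poisson pairs and will degrade under strong
common drive; that is a property of the 3 SD rule itself, not of this
implementation.

A second, table-level generator (`simulate_transmission_table`) emits
standardized per-pair transmission values with a planted linear generative
model (FAM2 from FAM1 and FAML, NOV correlated with FAM1 but carrying no
independent signal, optional animal intercepts). It exercises the
statistical layer at population scale without paying spike-simulation cost,
and is the basis of the model-comparison and LRT calibration checks.

## Problem sizes and numerical choices

Desk-scale defaults keep every check cheap: calibration uses 200
independent pairs and sensitivity 100 planted pairs of 25 min each;
estimator recovery averages 20 seeds per planted probability; the
statistical-layer checks use 78-pair, 4-animal tables with 50–100
replicates. File round-trips write CSV with full float precision and read
with round-trip parsing, so tables survive write→read bit-exactly.
Klusters-dialect spike files are integer samples at a configurable rate
(default 20 kHz); cluster ids 0 and 1 are treated as noise/artifact by
convention, exposed as an option.

## Known limitations

* Inhibitory (trough) connections and jitter/convolution-based significance
  methods are out of scope; the 3 SD flank rule is the single detector.
* The χ²(1) reference for the variance LRT is conservative; a 50:50 mixture
  reference would be sharper.
* The Wald F-test for independent contributions relies on the mixed model's
  estimated covariance; at very small group counts it can be mildly
  anti-conservative relative to a full refit comparison.
* The pairing-direction labels ("+" = pyramidal leads) are presentational;
  both directions and their sum are always reported.
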