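# Methods

This note documents the models, defaults and design choices behind
`startlekit`, and what the synthetic-data tests do and do not show.

## Startle-magnitude metrics

Raw triaxial acceleration **A** (default 320 Hz sampling, ±6 g =
±58.8 m s⁻² dynamic range, 16 bit) is high-pass filtered at 2 Hz to
remove the static gravity component and slow swimming movement before
any metric is computed. The filter is a windowed-sinc (Hamming) FIR
whose order is chosen for a ≤ 1 Hz transition band (1057 taps at
320 Hz); it is applied zero-phase by compensating the integer group
delay of the linear-phase kernel, so flinch timing is preserved
(a causal mode is available). DC attenuation exceeds 50 dB; a 15 Hz
flinch carrier passes within 5%.

Within a 1-s analysis window starting at stimulus onset:

- **p–p VeDBA** = √(x² + y² + z²) where x, y, z are the per-axis
  max − min spans, computed independently per axis before the
  root-sum-square (this specific construction is deliberate; it is not
  the same as the norm of the largest excursion).
- **max norm jerk** = max over samples of the Euclidean norm of the
  per-axis first differences scaled by the sampling rate (m s⁻³). No
  smoothing is applied before differentiation.
- **latency** is the first sample whose norm jerk exceeds k × MAD of
  the baseline norm jerk (k = 8 by default). This detector is a
  pragmatic addition for the simulator round-trips; reported startle
  latencies in stationing odontocetes fall within 100–200 ms of onset.

No-sound control baselines average the metric over five non-overlapping
pseudorandom 1-s windows of a control record (caller-supplied seed).
Samples at the dynamic-range limit mark the trial as clipped, and
clipped trials are excluded from model fitting.

## Acoustics

Received levels use SPL = |Tₓ| − Gain + 20 log₁₀(V) with the
hydrophone voltage sensitivity looked up nearest-neighbour between
sparse calibration points (−211.63, −211.55, −211.0, −211.3 dB re
1 V µPa⁻¹ at 1, 10, 25, 32 kHz in the bundled reference values). V is
the RMS over the central 90%-cumulative-energy window by default
(configurable to full duration; the averaging window of the original
measurements is not documented, so both are exposed). Compensation to
the animal's acoustic window assumes spherical spreading,
+20 log₁₀(d_hydrophone/d_ear), or applies a fixed per-animal offset
(+0.6 … +1.95 dB in the reference table). SEL integrates the squared
pressure over the pulse.

Stimuli are white noise band-filtered (4th-order Butterworth, zero
phase) to a third-octave around the centre frequency, or broadband with
−20 dB points near 6.8 and 19 kHz, then shaped by raised-cosine
rise/plateau/fall ramps ("mild tapering" is not otherwise specified).
The digital-to-pressure convention maps amplitude 1.0 to 180 dB re
1 µPa; it only matters for synthesis/measurement round-trips and is an
explicit parameter.

Click attribution labels a hoop/projector event pair as the focal
animal's only if (1) the projector-hydrophone peak is ≥ 30 dB above the
hoop peak, (2) the hoop waveform has off-axis character, quantified as
−10 dB duration ≥ 40 µs (the original criterion is qualitative, so the
threshold is configurable), and (3) the observed TDOA matches the
geometry within 0.2 ms. Unpaired events are ambiguous.

## Dose–response models

Startle magnitude is strictly positive and right-skewed, so gamma GLMs
are used with log, inverse (hyperbolic) or — for rise-time data —
identity links; binary video scores use a logistic GLM. Fitting is
IRLS via statsmodels. Identity-link gamma fits with non-positive fitted
values are rejected. Logistic fits are checked for (quasi-)complete
separation — no finite MLE exists there, so such fits raise instead of
returning arbitrarily large coefficients; recovery studies exclude and
count them.

The gamma log-likelihood is evaluated at the deviance-based dispersion
(shape = n/deviance), the convention R's `logLik.glm` uses, which makes
AICc values directly comparable to the R/MuMIn ecosystem (verified to
4 decimals against R on shared data). The parameter count k includes
the gamma dispersion (+1). AICc = AIC + 2k(k+1)/(n−k−1); models with
n ≤ k+1 are excluded. Candidate models are all admissible subsets of
{session factor, trial or ln trial (never both), focal-animal clicks,
other-animal clicks} on top of the always-included primary predictor;
echolocation covariates require ≥ 2 sessions with full records
(focal clicks additionally > 2 click trials). Ties within 0.01 AICc go
to the smaller model. Non-significant terms in the winner are retained.
Dispersion is reported from the Pearson χ²/(n−p) estimator; Wald 95%
intervals are β ± 1.96 SE.

Predictions are computed on a 0.1-step grid with other covariates held
fixed (trial at the intermediate 6.5 when a trial term is in the
model), with 95% bounds η ± t(n−k, 0.975)·SE(η) back-transformed
through the inverse link. This analytic t-quantile construction is
equivalent in distribution to sampling t deviates on the link scale; a
seeded Monte-Carlo mode is provided and agrees within sampling error.
An inverse-link linear predictor that touches zero on the grid is an
error (singular mean), which the pipeline converts to an invalid
threshold rather than a crash. Nagelkerke pseudo-R² uses
[1 − (L0/L1)^(2/n)] / [1 − L0^(2/n)], clamped to [0, 1].

## Thresholds

The startle threshold is the smallest grid level whose fitted response
exceeds the no-sound baseline — pooled across sessions, or, when the
session factor is retained, computed per session against that session's
own control and reported as the arithmetic mean. No threshold is
reported when the primary predictor's p-value is ≥ 0.05. The search
grid spans the observed levels ± 10 dB. Binary-response thresholds are
the 50% probability point and require an increasing curve. Rise-time
thresholds are where the (decreasing) curve drops below baseline; the
grid extends to 5× the largest tested rise time and values beyond the
tested range are flagged as extrapolated.

Sensation level subtracts the audiogram threshold, interpolated
linearly in log₂-frequency (audiograms are conventionally drawn on
log-frequency axes; a linear-in-kHz flag exists). Queries outside the
audiogram span are errors, not extrapolations.

The threshold-versus-frequency trend fits gamma GLMs with frequency in
kHz as the single predictor under log and inverse links, selects by
AICc, and reports the fitted difference between two query frequencies.
On the seven bundled p–p VeDBA thresholds the log link wins and the
fitted 1→32 kHz decrease is 19.6 dB, consistent with the published
18.2 dB given that the exact threshold subset and link behind that
figure are not documented (a log₂-frequency predictor would give
15.4 dB; the literal frequency-as-predictor reading is used).

## Synthetic data

The generator emulates the playback protocol: sessions of 12 sound
exposures whose level descends in 6 dB steps from trial 1 to 6, rises
3 dB, then ascends in 6 dB steps (default start 157 dB → range
127–160 dB), plus one no-sound control per session. Response metrics
are drawn from a gamma distribution (default shape 5) whose mean
follows the configured link function of level, rise time and ln trial;
binary video scores are Bernoulli draws from a logistic model. Bundled
presets encode published effect sizes with intercepts anchored so the
truth curve crosses the baseline at the corresponding published
threshold (e.g. VeDBA multiplier 1.094/dB crossing a 2 m s⁻² baseline
at 139.1 dB; jerk 1.126/dB at 138.1 dB; rise-time multiplier 0.989/ms
crossing at 141 ms; identity slope −0.135 m s⁻² ms⁻¹ at 220 ms). The
habituation preset multiplies in 0.693 per ln trial. Where a preset
needs a magnitude the sources do not pin down, values are chosen to
match reported scales (peak jerks ≈ 10³ m s⁻³ near 160 dB; baselines of
1–2 m s⁻²).

Accelerometer-level simulation superimposes, on quiet stationary
sensor/tissue noise (σ = 0.01 m s⁻²) and a 9.81 m s⁻² gravity offset on
one axis, a damped-sinusoid flinch (15 Hz carrier, 100 ms decay,
fixed 3-axis direction) whose amplitude is calibrated so the windowed
metric of the noiseless flinch equals the gamma draw, with onset
latency 200 ms − 2 ms/dB above 130 dB (floor 80 ms) and clipping at
±58.8 m s⁻². Baseline movement is modelled as sporadic bursts (about
one per second, amplitudes gamma-distributed around the nominal
baseline) placed in the per-session no-sound control records, not in
stimulus windows. This two-component structure is deliberate: a single
stationary noise floor strong enough to produce realistic control
baselines would put a hard lower bound on window-maximum metrics above
the truth curve's sub-threshold range, which contradicts the defining
feature of the threshold analysis — fitted curves crossing *below* the
control baseline at sub-threshold levels (stationing animals are
typically quieter during stimulus anticipation than in random control
windows). The jerk-unit baseline is derived from the same waveform
family (unit-flinch jerk/VeDBA ratio), keeping the two metrics
consistent.

Synthetic audio embeds calibrated pulses at scheduled levels
(round-trip through the SPL formula within 0.2 dB) on two channels;
synthetic click recordings construct focal clicks satisfying all three
attribution criteria and non-focal clicks violating the amplitude and
TDOA criteria. All generators are bit-reproducible from their seed.

What the synthetic data does **not** emulate: real tissue/tag transfer
functions, snapping-shrimp noise, tag-position effects across sessions,
session-to-session responsiveness drift, or animal decision processes
(e.g. breaking station). Passing tests therefore demonstrate that the
analysis recovers known truth under the model's own assumptions — not
that those assumptions capture every property of wild recordings.

## Recovery studies and problem sizes

Coefficient-recovery studies generate 200 replicate datasets per
published effect size at the study's trial counts (36 trials for the
level and habituation studies; 24 for rise time; two 12-trial sessions
for the second subject) and refit the matching GLM. Replicate
multipliers are averaged on the link scale and exponentiated (a
geometric mean): fitted coefficients are approximately normal on the
link scale, and the arithmetic mean of exponentiated logistic
estimates at n = 36 is badly right-skewed. Even so, the logistic
recovery remains a few percent above truth — the familiar upward bias
of small-sample logistic MLEs — while sitting comfortably inside the
published interval; the gamma recoveries are unbiased to ~0.2%. The
jerk study runs the full record-level pipeline (raw records → filter →
window → metric → GLM). The level studies draw RL uniformly over the
tested 120–160 dB range where the protocol schedule is not prescribed,
and follow the schedule where it is (habituation, video).

Model-selection behaviour was cross-checked against an R `glm` +
MuMIn-convention AICc oracle: with a pure level effect the selected
model is exactly {RL} in roughly three quarters of replicates (AICc
admits a chance extra term in the remainder — an inherent property of
the criterion, reproduced by both implementations), and strong ln-trial
habituation is retained in roughly half to two thirds. Test thresholds
are set two binomial standard deviations below these measured rates.

## Known limitations

- The inverse-link gamma fit inherits statsmodels' IRLS behaviour: it
  can fail to converge on strongly exponential data; such candidates
  are dropped from selection with a note in the candidate table.
- Per-session thresholds reuse the pooled fit with the session factor
  shifting the curve; fully separate per-session fits (used for one
  poorly behaved subject/frequency in the original analysis) are
  supported by filtering the trial table per session before fitting.
- Click attribution assumes one stationing animal and a fixed geometry;
  it does not track moving animals.
- Latency detection (k·MAD) is not part of the threshold analysis and
  is only validated against the generator's ground truth.
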