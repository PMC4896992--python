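# Methods

This note records the models, conventions and design choices behind
`cortstate`, in the order data flows through the package.

## Spectral features (`cortstate.spectral`)

Windows are rectangular (no taper) by default — the method is defined on a
plain FFT — with a Hann option for users who want reduced leakage. A window
of length `w` seconds gives a frequency resolution of `1/w` Hz (0.1 Hz for
the 10 s classification window, 0.25 Hz for the 4 s initialisation window).
A bin belongs to a band iff `lo ≤ f ≤ hi`; the gaps between the published
band edges (3–4, 7–8, 12–13, 30–31 Hz) stay unassigned. Windows are indexed
by their **start** time, and all window counts follow
`floor((n − w)/step) + 1` with trailing partial data dropped.

Channel handling: band powers are computed per channel and averaged **after**
the power computation, so antiphase channels do not cancel. The default
channel subset is the four deepest contacts (ids 13–16 on a 16-channel
laminar probe), where low-frequency power is strongest.

**Normalisation.** Whether band powers should enter the coding step raw or
relative to total power is genuinely open; both modes are implemented and
recorded in every output and trained model. `"relative"` (each window's
band powers divided by its total 0.5–80 Hz power) is the default for two
reasons: the automatic upper bound is rounded to one decimal place, which
presumes O(1) values, and relative powers make the classifier exactly
invariant to overall amplitude scaling (electrode gain, impedance drift).
A model trained in one mode refuses features computed in the other.

## Coded-vector classifier (`cortstate.classifier`)

The 10 pairwise band differences are taken over unordered pairs in a fixed
canonical order (δθ, δα, δβ, δγ, θα, θβ, θγ, αβ, αγ, βγ), absolute values
taken, and coded against bounds `UB = mean_k |mean_t Err_k|` (rounded to
`rounding_precision` decimals, default 1) and `LB = 0.5·UB` (not
independently rounded, so `LB/UB = 0.5` exactly). Both boundary values code
to the middle level. Bounds are set once, from the state with the smaller
mean per-pair `Err` variance — selected automatically, with an override —
and frozen in the model so codes stay comparable across recordings.

Training keeps the `l = 5` most frequent distinct coded vectors per state
(ties broken by first occurrence, stable sort). "Variance explained" is
operationalised as **occurrence coverage**: the fraction of a state's
training windows whose coded vector is one of its model vectors. Coded
vectors are categorical, so no literal variance exists; coverage is the
natural analogue and is reported per state.

Classification assigns the state of the globally nearest model vector (L1).
Ties between states at equal minimal distance keep the previous window's
label (temporal continuity — states persist for tens of seconds, so the
previous label is the best available prior); a tie on the very first window
defaults to synchronised. Every window is labelled; there is no
"unclassifiable" outcome.

**Trial classification.** Windows whose time stamp falls within
`[onset − 0.001 s, onset + 16.432 s]` of any trial are excluded, and each
trial takes the majority state over windows stamped in
`[onset − prestim, onset)`; a majority tie takes the window nearest the
onset. Exclusion is by window *time stamp*, not window extent: with 10 s
windows stamped at their start, every pre-stimulus window's data extends
into the stimulation period, so excluding by overlap would leave no
pre-stimulus windows at all. Stamp-based exclusion keeps the pre-stimulus
look-back usable while dropping every window attributed to the stimulation
period itself.

## RMS power-threshold baseline (`cortstate.baselines`)

Same windows, raw LFP: per-window RMS per channel, averaged across the
subset; the experiment-mean RMS is the threshold (recomputed per recording,
never shared). RMS above threshold → synchronised; below → desynchronised;
exact equality → synchronised (the published rule leaves equality open, and
the high side is the natural reading of "higher → synchronised"). A
degenerate recording whose windows all equal the threshold warns. Because
the threshold tracks mean amplitude it is biased toward whichever state
dominates the recording — the failure mode the coded-vector method avoids.

## Haemodynamic partitioning (`cortstate.hemodynamics`)

Stable periods are maximal runs of identical window labels, converted to
`[t_first, t_first + n·step)` and kept when **strictly** longer than 30 s
(transition ramps and noise dominate shorter stretches). State means pool
across periods duration-weighted — equivalent to concatenating the labelled
samples. Evoked trials are interpolated onto a common grid around onset,
the pre-stimulus mean subtracted per trial, averaged per state, and
summarised as the mean over 0–10 s post-onset; a state with fewer than 5
trials in an experiment is flagged for exclusion from cross-experiment
grand averages.

**Permutation control.** State labels of the analysis units (stable
periods or trials) are permuted 50 times with values and weights staying
attached to their units (period durations are preserved). The true
desynchronised−synchronised difference is pooled with the 50 null
differences; quartiles use linear interpolation, and a value is an outlier
iff it falls outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`. The lower fence is
`Q1 − 1.5·IQR`; a printed form of this rule sometimes appears with a plus
sign, which would mark nearly everything below Q3 an outlier and cannot be
intended. Calibration measured by simulation: with the default effect the
true difference is flagged in ≳95 % of replicates and with zero effect in
≲5 %; note that among 50 permuted differences a borderline *null* lands
outside the fences in roughly a quarter of replicates (for any number of
units — it is a property of the Tukey rule at n = 51), so the true
difference is the *unique* outlier in only ~60–80 % of replicates.

## Evaluation (`cortstate.evaluation`)

Windows are scored against the reference label at the window's **start**
time (consistent with window stamping). Three percentages per experiment:
correct among classified windows, unclassified, and total accuracy
(unclassified counts as wrong), with
`total = correct × fraction_classified` exactly. Methods are aggregated by
unweighted mean ± SD across experiments; wall time is reported as
information only and never asserted.

## Synthetic generator (`cortstate.simulate`)

**State sequence.** Alternating visits with exponential dwells of mean
120 s per state, shifted by a 35 s floor (mean preserved) so that >30 s
stable periods always exist; a `fixed` dwell option gives deterministic
schedules. The first state is drawn from the seed unless pinned.

**LFP.** Per channel and state, five white-noise traces are band-pass
filtered (4th-order Butterworth per EEG band), scaled so band `b` has RMS
`rms_state · sqrt(w_b)` with `w` the normalised band profile, and summed;
the realised trace switches between the two state processes per sample.
Defaults: synchronised profile (0.57, 0.16, 0.08, 0.13, 0.06) at RMS 1.0
(a.u.), desynchronised (0.08, 0.10, 0.12, 0.30, 0.40) at RMS 0.5. The
amplitude ratio (2:1) and profiles are conventions chosen so that (a) an
amplitude-based expert criterion separates the states, (b) the
desynchronised/synchronised **absolute** gamma-power ratio exceeds 1 — the
power in the upper bands rises during desynchronisation even though the
overall amplitude falls — and (c) relative band values are O(0.1–0.5), so
the one-decimal bound rounding lands at a usable UB ≈ 0.2. A shared
log-normal amplitude envelope (σ = 0.2, 60 s timescale) models within-state
amplitude nonstationarity; it moves window RMS but cancels exactly in
relative band powers. Deeper channels get a mild low-frequency (δ, θ) gain
(0.9→1.1 across the array), motivating the deep-channel subset.

**Haemodynamics.** Sampled at 8 Hz (a 32 Hz camera cycling four
wavelengths). While desynchronised the baseline targets are
+8.56 µM Hbo, −5.56 µM Hbr, +2.00 µM Hbt (the canonical state-difference
magnitudes for this preparation); the series approach their targets
through a first-order lag, τ = 5 s — ramps of a few seconds are visible in
such data but no time constant is published, so τ is a convention.
Additive white noise, σ = 0.5 µM per species. The three species are
simulated independently; measured Hbt need not equal Hbo + Hbr exactly,
and the analysis code only relies on that identity when the input
satisfies it.

**Stimulation.** Trials default to the standard protocol: 30 trials of
70 s, stimulus 10 s into each trial, 16 s pulse train at 5 Hz (80 pulses;
last onset 2040 s, requiring ≥2100 s of recording). Evoked haemodynamic
responses are gamma-variate kernels: synchronised — peak 5 s post-onset,
amplitudes (+4.0, −1.5, +2.5) µM for (Hbo, Hbr, Hbt); desynchronised —
peak 16 s, 0.4× amplitude. Evoked LFP deflections are brief biphasic
pulses whose amplitude adapts over the train: synchronised, large first
response decaying to a plateau; desynchronised, small first response
growing to a plateau.

**What the generator does not emulate.** No biophysical neuron or vascular
dynamics, no 1/f spectral background, no movement or cardiac artefacts, no
pixel-space optical imaging, no blood-pressure or CO₂ covariates.
Consequently, passing tests certify the pipeline's arithmetic and its
behaviour under controlled spectral contrasts — not classification
performance on animal recordings, where state boundaries are fuzzier and
spectra are broadband.

## Problem sizes used in tests

The test suite trains on a 400 s, 4-channel recording and classifies
independent 400–480 s recordings (batteries of 3–10 experiments for the
comparative and recovery checks); the permutation-control calibration uses
2400 s state sequences with haemodynamics only (~20 stable periods each,
30 replicates per condition). These sizes give stable statistics for every
assertion while keeping the full suite around a minute of compute.

## Degenerate inputs and numerical conventions

All-zero windows stay all-zero in relative mode (no 0/0). `UB = 0` (all
`Err` below any bound) yields `LB = 0` and every window codes to the
middle level — training on such data fails loudly when fewer than `l`
distinct vectors exist. Equal per-state profiles with equal RMS are
accepted by the generator (classifiers then perform at chance); a
synchronised RMS *below* the desynchronised RMS is rejected as
contradicting the states' definitions. Quartiles, filtering and FFTs use
scipy/numpy defaults noted inline; every stochastic component (generator,
permutation control, fuzzed tests) takes an explicit seed or Generator.
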