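# Methods

This note records the models, parameter defaults, and numerical choices
behind `resplock`, and what the synthetic experiments do and do not show
about real recordings.

## Synthetic session model

A session is a sequence of non-overlapping 1.8 s action windows (225 samples
at 125 Hz) tied to the moves of a simulated agent whose per-action error
probability is 0.2 (independent Bernoulli draws), matching the ~4:1
non-error:error imbalance of the paradigm. Every epoch is a sum of
independent components, in microvolts:

**Background noise.** Per-channel pink (1/f-power) noise, generated by
shaping white Gaussian noise with a 1/sqrt(f) amplitude profile in the
frequency domain and rescaling to `noise_sigma` RMS (default 4 µV). At that
default the 11–16 Hz band-power SNR at O1 is near 0 dB. An explicit
common-mode alpha component is not modelled; the pink spectrum already
places substantial power in the alpha range.

**SSVEP.** The flicker drive is modelled by its fundamental: a sinusoid at
`flicker_hz` (12.5 Hz), active only while the flicker is on, scaled by a
per-channel gain map peaking at O1/O2 (1.5 µV) and declining toward frontal
sites. The screen's on/off flicker is a square-wave luminance signal, but
the cross-correlation model is derived for the sinusoidal form, so the
fundamental is the right simulator primitive; harmonics are deliberately
omitted. The response carries the stimulus with the phase term *added* —
`sin(2πF₀t + Φ̄)`, `phase_lag_rad` default 4.05 — which places
cross-correlation maxima on the lattice τ = n/F₀ − δ, and its envelope is
delayed by `response_delay_s` (default 0.27 s, the lattice point with
n = 4). Since delay + active duration (0.27 + 1.6 s) exceeds the window, the
tail of each response spills 70 ms into the following window; the simulator
generates that spill (as the continuation of the previous window's
sinusoid), because truncating the response at the window boundary would
systematically shift the global correlation maximum to the n = 3 lattice
point. The flicker restarts at each action onset (phase-locked); setting
`flicker_phase_locked=False` randomizes the stimulus phase per window,
emulating free-running flicker designs.

**ErrP.** On error trials a biphasic transient is added over fronto-central
channels: a 6 Hz cosine carrier under a Gaussian envelope (σ = 55 ms), with
the trough at 250 ms and the compensating positive peak ~330 ms after the
action onset, so the dominant spectral energy lies in the 4–8 Hz theta
band. The per-channel gain map peaks at Cz (7 µV) and Fz (6 µV) — typical
single-trial ErrP amplitudes — and is exactly zero over O1/O2/P3/P4, so
that without coupling the parieto-occipital narrowband configuration
carries no class information by construction. The published record
constrains only the band and approximate latency, not the waveform; this
template is an explicit modelling assumption.

**Coupling.** The paradigm's "differential interaction" is modelled as a
multiplicative attenuation of the SSVEP amplitude on error trials
(`coupling_effect`, default 0.2 → 20% attenuation) plus a small Gaussian
phase jitter (σ = 0.5 × coupling_effect rad). No mechanism is claimed; the
knob exists so the headline contrast — coupled cohorts separable in the
E3F3 cell, uncoupled cohorts at chance there — is reproducible and tunable.

**Artifacts.** With per-trial probability `artifact_rate` (default 0), an
epoch receives either a 3-sample rectangular spike of 80–130 µV on a random
channel or a 300 ms blink-shaped positive lobe (~100 µV) over the frontal
channels. These exist solely to exercise the threshold rejection rule.

All randomness flows from integer seeds through `numpy.random.SeedSequence`
spawning: identical (config, seed) pairs give bit-identical sessions, and
per-trial generators draw the same counts regardless of the label so that
error/non-error epochs with equal trial seeds share their noise exactly.

## Preprocessing

Band-passes are Butterworth designs of order 4 applied forward–backward
(`sosfiltfilt`), so event latencies are not shifted; the two-pass
application squares the magnitude response and doubles the effective
roll-off. Epochs are filtered individually with even (reflection) padding of
up to one window length. The three bands are F1 = 1–40 Hz, F2 = 10–40 Hz,
F3 = 11–16 Hz; the three electrode subsets are E1 (all twelve), E2
(fronto-central 7) and E3 (parieto-occipital 5), a disjoint partition.

Artifact rejection flags a trial when any channel's absolute deviation from
its own epoch mean exceeds 75 µV (the "spike" rule — deviation from the
epoch mean rather than from zero, so DC offsets do not trigger it) or any
channel's peak-to-peak range exceeds 125 µV, with OR-aggregation across
channels. Rejection is applied after broadband filtering by default; both
the ordering and the thresholds are arguments.

## Phase-locking analysis

Analytic signals come from `scipy.signal.hilbert`; phases are wrapped to
(−π, π]. The instantaneous stimulus–response phase lag is the wrapped
difference of the two phase series (the phasor-quotient argument), and the
PLV is the modulus of the mean unit phasor. Sliding PLV uses 0.5 s windows
(62 samples at 125 Hz) with stride 1 and excludes the first 200 ms of each
window, where SSVEP activity has not yet built up; the exclusion is a
parameter (`onset_exclude_s`).

Cross-correlation is the unnormalized sliding inner product of the stimulus
template *advanced* by the delay against the response,
C[k] = Σⱼ template[j]·response[j+k]: amplitude constants scale C but never
move its maxima, so templates default to A₀ = 1 and the analysis is
scale-free. For per-window analysis, the occipital (O1/O2 by default,
configurable) average of the **continuous** concatenated recording is
filtered to F3 and correlated once; the full correlogram is then sliced at
each action onset. Filtering the continuous trace rather than individual
epochs matters: per-epoch filtering disrupts the response tail at window
boundaries and biases the peak toward the preceding lattice point.

Each window's global maximum is refined by a parabolic fit through its two
neighbours, giving sub-sample delay resolution (the correlogram is locally a
sampled cosine, which a parabola approximates well near its peak; the
correction is clipped to ±half a sample). Without this refinement the 8 ms
sample grid aliases into ±0.6 rad of phase error per window. Local-maxima
detection admits peaks above 0.5 × the global maximum by default; window
endpoints are counted only when no interior peak exists, since a window
boundary cutting through a correlation lobe is an artifact of the
restriction. Delay histograms default to one-sample (8 ms) bins, resolving
the 80 ms lattice; ties for the modal bin break toward the earliest delay.

The mean phase lag is estimated by inverting the maxima condition
2πF₀τ + Φ̄ = 2nπ at each observed peak delay and aggregating with a
circular mean, reported in [0, 2π) (values within 1e-9 of 2π wrap to 0).
On noiseless sessions the injected lag is recovered to < 0.01 rad; at 5 µV
noise, to < 0.05 rad.

## Fidelity score

The published description of the score — a discrepancy between observed
cross-correlation maxima latencies and an ideal fixed-delay scenario — does
not pin down a functional form, so two interpretations are implemented and
labelled as such:

* `in_zone` (default): the fraction of analyzable windows whose global peak
  delay lies within ± `tolerance_s` of the modal zone. The tolerance
  defaults to half an SSVEP period (40 ms), half the lattice spacing, so a
  window is "in zone" exactly when its peak chose the modal lattice point.
  The ideal scenario scores 1; scores live in [0, 1].
* `mad`: one minus the mean absolute deviation of peak delays from the
  modal zone, rescaled by half the window length and clipped to [0, 1].

The modal zone defaults to the cohort-level delay-histogram mode
(`cohort_modal_zone`), with per-user override. For template repetition r,
window i correlates the r-window template anchored at its own onset (the
template is re-anchored per window, the natural reading for phase-locked
flicker); the last r − 1 windows of a session are unanalyzable, so a sweep
to r = 150 needs more than 150 windows. For pure-noise data the in-zone
score sits near the chance level 2·tolerance/window (≈ 0.09 at the one-period
tolerance used in the chance-level test), slightly depressed by
window-slicing edge effects that concentrate peaks at slice boundaries.

The score never reads trial labels — the unsupervised contract is asserted
in the tests by relabeling sessions and checking bitwise-equal scores.
Fidelity–accuracy association uses Pearson correlation with two-sided
t-test p-values per repetition count; zero-variance cases report NaN.

## Detection model

The detector is xDAWN + Riemannian tangent space + elastic-net logistic
regression, built as sklearn transformers composing in a `Pipeline`:

* **xDAWN** (`XdawnFilter`): per class, the evoked prototype is the
  class-mean epoch — the least-squares estimate for non-overlapping
  fixed-length windows — and the filters solve the generalized symmetric
  eigenproblem Σ_evoked w = λ Σ_total w (`scipy.linalg.eigh`), keeping the
  top `n_filters` (default 4, a conventional choice; the source does not
  state one) unit-norm vectors per class. A small ridge (1e-9 of the mean
  eigenvalue) keeps Σ_total well conditioned. The tests cross-check the
  filters against mne's independent xDAWN estimator and a dense
  inv(Σ_total)·Σ_evoked eigendecomposition.
* **Augmented covariances** (`XdawnCovariances`): each epoch is stacked
  with the filtered class prototypes (a "super-trial" of 4·n_filters rows)
  and its covariance estimated with Ledoit–Wolf shrinkage toward scaled
  identity (`sklearn.covariance.LedoitWolf`, assume_centered), guaranteeing
  positive-definiteness at the resulting 16×16 dimension.
* **Tangent space** (`TangentSpace`): the affine-invariant Riemannian mean
  of the training covariances is computed by fixed-point iteration
  (tolerance 1e-10 on the Frobenius norm of the tangent-space mean, at most
  100 iterations); epochs map to upper-triangular vectorizations of
  log(M^{-1/2} C M^{-1/2}) with √2-weighted off-diagonals, so Euclidean
  norms equal Riemannian distances to M.
* **Classifier head**: elastic-net logistic regression, mixing parameter
  0.5, with the regularization strength chosen by inner 3-fold CV over
  C ∈ {0.05, 0.5, 5} (`inner_cv=True`), or fixed C = 1 for speed
  (`inner_cv=False`). These hyperparameters are this package's defaults,
  not a replication of unreported originals.

Balanced accuracy is 100·(TPR + TNR)/2 via sklearn. The within-user
protocol is stratified 5-fold CV repeated 4 times (20 runs per user), with
the whole procedure repeated 10 times for a mean and standard deviation;
all three counts are `CVProtocol` fields. Zero-shot generalization
evaluates every ordered train/test user pair (1-v-1) or each held-out user
against the pooled rest (1-v-rest), on broadband (F1) full-montage (E1)
data. Deep-learning detectors are out of scope; the classical model is the
pipeline's representative detector.

## Problem sizes in the test and acceptance runs

The shipped tests exercise the full study protocol shape at reduced sizes
chosen as this package's own desk-scale defaults: cohorts of 3–12 users,
sessions of 40–300 windows, single outer repeats with the fast classifier
head for grid sweeps, and a six-user noise ramp (1–20 µV) with 300-window
sessions for the joint fidelity/accuracy experiment. The repetition sweep
uses r ∈ {1, 5, 20, 60, 100, 150}. On this cohort the fidelity–accuracy
correlation rises from r = 1 to an interior maximum before declining — the
qualitative shape of the published sweep — but its peak location depends on
the noise ramp and is not a quantitative reproduction.

## Limitations

The generator emulates the *statistical signatures* the analysis consumes —
spectral peaks, phase locking, class imbalance, envelope delays, amplitude
topographies — not the physiology behind them. It omits volume-conducted
correlations between channels, non-stationarity within sessions, SSVEP
harmonics, alpha rhythms distinct from the pink background, eye-movement
spectra, and inter-subject topography variability. Tests passing on this
cohort therefore validate the *pipeline* (formulas, conventions,
invariances, qualitative contrasts), and the analytic constants (cycle
counts, lattice spacing, closed-form delays) transfer exactly; detection
accuracies and correlation peak locations on real recordings will differ.
Real-data ingestion (EDF via mne, or delimited matrices + event tables) is
provided but EDF *export* requires an optional writer backend (`edfio`).
Per-trial or per-episode fidelity-based rejection is out of scope.
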