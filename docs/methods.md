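# Methods

`awarelfp` implements the analysis chain of a report-independent visual
awareness experiment recorded with stereo-EEG (sEEG) depth electrodes,
together with a synthetic task-and-LFP generator that makes every stage
testable without patient data. This note describes the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish about real recordings.

## The task and the behavioral model

Each trial: 600 ms fixation, a 50 ms Gabor grating at 7° eccentricity, a
650 ms delay, then a fixation-point color change that cues a saccade to one
of two targets at ±10°. The saccade direction jointly encodes cue color and
the subject's awareness report, so report behavior is matched between seen
and unseen trials. A session holds 180 trials: 70% near threshold (contrast
driven by a 1-up/1-down staircase with step 0.39% or 0.78%), 10% clearly
visible, 20% stimulus absent. Class counts are enforced exactly
(126/18/36), not drawn multinomially, so scheduler behavior is
deterministic given the proportions.

The simulated observer reports "aware" with probability

    AP(SC) = a + b / (1 + exp(-d (SC - c)))

with guess floor `a` (default 0.02), range `b` (0.96), threshold `c` (10%
contrast) and slope `d` (1.5 /%). The 1-up/1-down rule converges to the 50%
point of this curve; the staircase updates only on near-class trials
(whether the original procedure also updated on control trials is not
stated anywhere; near-only is the conventional choice). The default
starting contrast is `c + 5 steps`.

Psychometric fitting is weighted nonlinear least squares on per-level aware
fractions with multi-start over threshold and slope, bounds
`0 ≤ a, b ≤ 1, d > 0`. For population fits adjacent contrast levels are
pooled to 8 per session. Contrast levels are classed low/near/high by their
aware fraction (<25%, 25–75%, >75%) and trials labeled LU/NU/NA/HA;
low-aware and high-unaware combinations are rare and excluded.

Saccade latency: position and speed are smoothed with centered 20 ms
windows stepped 1 ms; onset is the first time the smoothed speed exceeds
30°/s for more than 20 ms (≥ 21 consecutive samples at 1 kHz — the strict
reading of "more than"). Trials are excluded when fixation leaves the 4°
half-width window for more than 40 consecutive ms or the latency exceeds
the 2000 ms response window. d′ contrasts the aware rate on high-contrast
(signal) vs catch (noise) trials with the 1/(2N) correction for extreme
rates. The paired aware-vs-unaware latency comparison uses a Wilcoxon
signed-rank test whose null distribution is enumerated exactly (dynamic
programming over midranks) for n ≤ 25; both sidednesses are reported, with
the one-sided (aware faster) alternative as the headline.

### Synthetic gaze and the latency convention

Gaze jitter is Gaussian noise smoothed with a 50 ms kernel and rescaled to
0.3° SD, so fixational drift velocity stays far below the saccade
threshold. Saccades follow a raised-cosine velocity pulse (40 ms, peak
≈ 500°/s). Because the detector's mandated smoothing shifts the apparent
threshold crossing, the generator defines its `latency` parameter
operationally: the pulse is placed so that the smoothed-speed criterion
applied to the noise-free profile fires exactly at `latency`. Recovery over
1000 synthetic saccades then shows |bias| < 1 ms and SD < 1 ms; without
this convention the round trip would carry a constant ≈ 6 ms offset that
says nothing about real data.

## The synthetic LFP

Each channel × trial is 1/f-amplitude (pink) noise, built by spectral
shaping of white noise and scaled exactly (via Parseval) to 10 µV SD, over
the standard epoch −490..1299 ms at 1 kHz. Stimulus-present trials add a
contrast-saturating evoked transient from ~100 ms. Channels designated
"awareness-related" additionally carry, in aware trials only:

- **ERP effect** — a 5 Hz burst (50 ms raised-cosine rise, ~500 ms total,
  area-cancelled) of amplitude `erp_gain` (default 50 µV = 5× noise SD)
  starting at `erp_dot` (250 ms), with a per-channel carrier phase. Two
  deliberate choices: the burst's energy lies inside the 1–250 Hz passband,
  because any sustained DC-like deflection is smeared backward by the
  zero-phase 1 Hz high-pass (a 550 ms box leaks ~45% of its amplitude into
  the pre-onset window; the burst leaks < 4%); and the per-channel phases
  keep the montage-wide effect from vanishing at carrier zero crossings,
  which would notch the decoding time course.
- **High-gamma effect** — 60–150 Hz band-limited noise gated from `hg_dot`
  (230 ms), scaled to `hg_gain` (5×) times the pink noise's in-band RMS
  (computed analytically from the shaping spectrum).
- **Connectivity effect** — a 4 Hz oscillation (10 µV) from `plv_onset`
  (250 ms) whose inter-channel phase lags are fixed across aware trials
  (`plv_lag`, 0.7 rad) and random in unaware trials. The amplitude must
  rival the ~9 µV of pink noise inside 1–8 Hz for the phase to be
  recoverable; weaker oscillations leave the PLV contrast invisible, which
  is an SNR statement about the generator, not about the estimator.

Per-shaft common pink noise (5 µV) emulates the shared white-matter
reference; the bipolar step removes it. One RNG stream per session, keyed
by `(seed, session index)`; identical seeds give bit-identical sessions.

What the generator does *not* emulate: epileptiform transients and
artifacts, non-stationary noise spectra, volume-conducted dipole geometry,
latency jitter of the neural effects, correlated noise between shafts, or
any relationship between behavior and single-trial effect amplitude beyond
the aware/unaware dichotomy. Passing tests therefore demonstrate that the
statistics recover programmed effects under realistic noise levels and
trial counts — not that real recordings satisfy the models.

## Preprocessing

Filtering follows standard intracranial practice: zero-phase FIR, 1–250 Hz
band-pass with notches at 50/100/150/200/250 Hz. A single Hamming-window
`firwin2` design realizes the whole magnitude response (3301 taps at 1 kHz
for ~1 Hz transitions, notch stop bands ±2 Hz); epochs are odd-reflection
padded before the symmetric convolution. Measured response: −70 dB at the
notches, 1.000 at 20 Hz, −62 dB at DC. Known artifact, shared with any
zero-phase high-pass: effects with energy near the 1 Hz edge are spread
symmetrically in time, so apparent onsets of strongly sustained responses
can precede their true onsets; onset-recovery tests therefore run on
unfiltered epochs, and the pipeline's filtered DOTs should be read with
this caveat.

Channel screening (an automated surrogate for the visual inspection used
with clinical data) drops flat channels, line-dominated channels (48–52 Hz
over 1–45 Hz PSD ratio > 1), and broadband-power outliers (> 5 scaled MADs
from the montage median, MAD floored at 0.1 dex). Metrics use pre-stimulus
samples only so genuine task responses never count against a channel.

Bipolar re-referencing subtracts each contact's direct within-segment
neighbor; pairs never span the 10 mm segment gap, inherit midpoint
coordinates and the deeper contact's region label (the assignment rule for
real data is not documented; deeper-contact inheritance is one defensible
convention).

## Divergence-onset statistics

At every millisecond in 0–650 ms (stimulus onset to cue), NA and NU trials
are compared with a two-sided Welch t-test (the unequal-variance form is
the robust default; the equal-variance choice is unverifiable). The
uncorrected p matrix is Benjamini–Hochberg corrected jointly across
channels × time points at q = 0.01, and a channel is awareness-related iff
some significant run lasts strictly longer than 20 ms (≥ 21 samples). DOT
is the first sample of the earliest qualifying run; DA the mean NA−NU
difference over that run (raw units); Td = 650 − DOT; normDOT min-max
normalizes Td within a subject (degenerate range ⇒ 0.5, the midpoint
avoiding an arbitrary extremal rank). Population time courses rectify each
channel's difference before averaging, because LFP polarity is not
physiologically interpretable; SEM is across channels. A 350 ms cutoff
splits early from late DOTs.

Calibration facts established by the test suite: with all effects zero the
mean flagged fraction over 100 seeded 20-channel sessions stays ≤ 5%;
with a 5×SD effect the median recovered DOT sits 13–17 ms after the true
onset (the detection delay of a ramped effect crossing the significance
threshold) and within the ±30 ms recovery band for onsets 200–300 ms.
Limitation: BH over pointwise tests does not control *run-level* false
positives under temporally correlated noise, and ~1–2% of channels per
seed show a spurious qualifying run; conclusions should rest on medians
and population counts, not a single channel's DOT.

## High-gamma analysis

Each trial's own-condition mean (the evoked response) is subtracted before
time-frequency analysis, so only induced activity remains. Morlet wavelets
(7 cycles, 60–150 Hz in 10 Hz steps, via `mne.time_frequency`) yield
magnitudes; the HG magnitude is the average across the grid, computed in
trial chunks so the full channel × frequency × time × trial array is never
materialized. Results are only valid inside −200..800 ms (the longest
wavelet half-length, ~58 ms at 60 Hz, fits comfortably inside the epoch
margins; enforced by assertion). Baseline normalization: (x−μ)/σ·100 with
μ, σ pooled over the −200..0 ms samples of all trials per channel (the
per-trial vs pooled choice is not documented for the original analysis;
pooled is the lower-variance estimate). Spectrograms for display use
10·log10(x/μ). The divergence machinery is then applied to the normalized
magnitude unchanged; programmed 230 ms HG onsets are recovered within
[200, 260] ms — wavelet smoothing makes HG onsets ~20 ms blurry in both
directions.

## Decoding

Features at each time point are instantaneous channel vectors, z-scored
per channel with training-set statistics (toggleable). Trials are class
balanced by undersampling, assigned to 10 folds per class, sub-averaged in
disjoint groups of 4 (remainders dropped, keeping pseudo-trial noise
homogeneous), and scored leave-one-fold-out; the fold assignment is
redrawn 5 times, so each time point averages 50 fold tests. The classifier
is a two-class LDA with Ledoit–Wolf shrinkage of the pooled covariance —
plain LDA is singular whenever channels outnumber pseudo-trials. Temporal
generalization trains at t and tests at every t′ with the same folds;
cross-condition generalization trains on all NA/NU pseudo-trials and tests
on HA/LU pseudo-trials (aware ↔ HA), which needs no fold bookkeeping since
the test trials are disjoint.

Calibration: the permutation null (mean over 20 label shuffles of a
zero-effect subject) stays within 0.50 ± 0.03 at every time point. Two
fine-print effects worth knowing: label permutation on data *with* strong
effects sits slightly above 0.5 at informative times, because the random
overlap between shuffled and true labels is a whole-dataset quantity that
survives pseudo-trial averaging and fold splitting; and single-run
pointwise accuracies at uninformative times fluctuate by ±0.05 at ~300
trials/class, so pre-onset calibration is asserted on the window mean.

## Connectivity

Low-frequency phases come from zero-phase FIR band-passes into [1–4] and
[4–8] Hz sub-bands followed by the analytic signal — instantaneous phase
is only meaningful for near-narrowband signals, so the 1–8 Hz range is
split rather than filtered whole. The time-across PLV is
`|mean_trials exp(i(φ_i − φ_j))|` per time point, computed per sub-band
and averaged, then baseline-corrected by subtracting each pair's mean over
−200..0 ms. The first/last 500 ms of the epoch are excluded from validity
for the 1 Hz edge; the reported window is −200..800 ms. Region-level
matrices average corrected PLV over all pairs joining two regions (equal
subject weights when pooling); network displays keep the strongest 15% of
edges (`ceil`, ties broken by stable order). Site-to-rest curves average a
site's corrected PLV to all other channels, computed separately for NA and
NU.

## Topographic display

Contact values project to surface vertices by Shepard interpolation with
weights 1/d², ignoring contacts beyond 15 mm; a vertex with no contact in
range is undefined, and a vertex coincident with a contact takes its value
exactly. A 12-vertex icosphere ships as a synthetic stand-in surface for
testing; real meshes are user-supplied.

## Problem sizes and determinism

Default test-suite sizes: 20–45 channels, 180–900 trials per subject, 25 ms
decoding grids, 20–100 seeds for calibration studies — sizes at which every
stage's behavior (convergence, false-positive rate, recovery bias) is
measurable while a full run of the suite stays practical on a single core.
The pipeline driver records every stage's parameters, seed and config hash
in a line-delimited JSON provenance log; identical configs and seeds
reproduce stage outputs byte-for-byte.
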