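# Methods

This note documents the models, parameter choices and numerical details
behind `vrdistress`, and what the synthetic-data validation does and does
not establish about real recordings.

## Study protocol being modeled

Each subject contributes three 4-minute sessions recorded simultaneously
by a chest ECG device ("faros", 500 Hz) and a wrist PPG device ("e4",
64 Hz BVP): a seated resting **baseline**, a calm non-interactive VR scene
(**NIS**), and an interactive VR scene (**IS**) in which the subject
solves a manual puzzle while being startled at fixed times — a falling box
at 120 s, a second box preceded by a suspense sound at 180 s, and a
monster attack at 240 s that ends the scene. Recordings are aligned on
wall-clock timestamps and re-expressed in scene-relative time (t = 0 at
scene start).

## Signal chains

**ECG.** Zero-phase FIR bandpass, 3–45 Hz, Hamming window, order
`round(0.3·fs)` forced even so the filter is linear-phase; applied
forward–backward with even reflection padding of 3× the tap count. At
this order the Hamming transition band is wide enough that DC leaks
through (single-pass DC gain ≈ 0.21), so the taps are mean-corrected to
place an exact null at 0 Hz; this perturbs the rest of the response by
under 1 %. QRS detection follows Hamilton's adaptive scheme with the
open-source defaults: rectified-derivative envelope over 80 ms, running
8-peak QRS/noise averages, detection threshold
`noise + 0.3125·(qrs − noise)`, 200 ms refractory, search-back at 1.5×
the running mean RR, and R localisation at the signal maximum within
±40 ms. Template correction builds the mean −100…+100 ms beat window and
shifts each beat to the lag in ±50 ms maximising normalized
cross-correlation; beats whose centered window would run off the
recording are left untouched, and conflicting shifts are resolved by
keeping the better-correlated beat. The ±50 ms search and 200 ms template
width are this package's choices.

**BVP.** Zero-phase 4th-order Butterworth bandpass 1–8 Hz (the effective
attenuation is that of an 8-pole filter since it is applied twice).
Beat detection uses Elgendi's two-moving-averages method on the
clipped-squared signal with the published constants (W1 = 111 ms,
W2 = 667 ms, β = 0.02): contiguous blocks where the short average exceeds
the long average plus β·mean(squared), at least W1 wide, each yield one
beat at the block's systolic maximum. Two implementation details are
ours: blocks whose peak is below one third of the upper-quartile block
height are discarded (they are bandpass rebound between slow beats, which
can rival true beats in number at 50 bpm), and the reported onset is the
global minimum of the window between the previous systolic peak and the
current one (capped at 350 ms), which is robust to noise micro-minima.
Onsets anchor the heart rate by default; systolic peaks are available via
`ppg_use_peaks`.

## HR features and the distress rule

HR is 60/RR at the later beat of each pair, boxcar-smoothed over
3 samples in the beat domain with reflective padding (3 samples span
nominally 6 ms at 500 Hz and 46.88 ms at 64 Hz). Both devices are then
linearly interpolated onto the identical 4 Hz grid anchored at scene
start, held at the edge values outside the beat span, and segmented into
non-overlapping 10 s windows (24 per full scene; a trailing partial
window is dropped).

RMSSD is deliberately computed on the successive 4 Hz HR samples (bpm)
within each window — the ultra-short-term variant used throughout this
pipeline — not on NN intervals in milliseconds. Baseline personalization
uses the minimum of the subject's processed baseline 4 Hz HR (so it is
artifact-sensitive exactly as the rest of the pipeline is) and the median
of the baseline per-window RMSSD values (even counts average the two
central values). Flags are strict inequalities at 1.3× and 0.5×; a
window exactly at threshold is not flagged, and a degenerate RMSSD
threshold of zero can never flag (a warning is emitted). Levels are the
flag sums; a window "detects distress" at level ≥ 1.

For event coincidence, the three inspected windows are those covering
`[t−10, t)`, `[t, t+10)` and `[t+10, t+20)`. Windows beyond the recorded
span are marked absent; they count as non-detecting but remain in the
denominator of three. The 240 s event therefore has only its preceding
window available — detection of that event hinges on arousal persisting
from earlier in the scene (see the generator below).

## Agreement and cohort statistics

SNR is defined on the HR series itself, `10·log10(mean(x²)/popvar(x))`
with the population (divide-by-N) variance as noise power; a constant
series maps to +∞ with a warning. Device agreement on the shared 4 Hz
grid over the full scene span, with no outlier exclusion: Pearson r,
Spearman ρ, MAE/RMSE with the chest device as reference, and Bland–Altman
bias ± 1.96·sd (sample sd, differences taken wrist − chest). Cohort
comparisons of per-level distress counts are paired Wilcoxon signed-rank
tests — zeros dropped, average ranks for ties, statistic `min(W⁺, W⁻)`,
exact two-sided p by subset-sum dynamic programming over doubled ranks
for n ≤ 25, tie-corrected normal approximation beyond — with Cliff's
delta (order: wrist, chest) and magnitude labels at |0.147|/|0.33|/|0.474|.

## The synthetic-data generator

The generator defines the validation conditions; its defaults were chosen
once as a plausible rendition of the study population and hardware.

**RR process.** Log-RR follows a stationary unit-variance AR(1)
(coefficient 0.9) scaled to a relative sd of `hrv_sd_ms / resting RR`,
i.e. `hrv_sd_ms` is the stationary RR jitter scale. Cohort subjects draw
resting HR from N(70, 8) bpm clipped to [55, 90] and `hrv_sd_ms` from
N(40, 8) ms clipped to [20, 60] — healthy adults in their early twenties.

**Distress response.** Each IS event multiplies the local mean HR by
`1 + g(t)·0.4` and the RR jitter by `1 − g(t)·0.7` (defaults equal to the
rule system's design points, so threshold crossings are decisive rather
than marginal). The envelope `g` is a phasic trapezoid — 2 s linear rise,
hold until 20 s after onset, 2 s fall — plus a tonic sensitization term:
each event leaves a residue of height 0.6 decaying with τ = 180 s,
clipped so g ≤ 1. The tonic term models the observation that startled
subjects do not return to baseline between scares; it is also what makes
the final event (whose post-event windows do not exist) detectable in the
window that precedes it. The per-event response magnitudes are modeling
choices, not estimates of any measured effect.

**Waveforms.** ECG: a fixed sum-of-Gaussians PQRST template (R apex
exactly at the beat time) plus 0.3 Hz baseline wander (amp 0.05 of R),
50 Hz powerline (0.01) and white noise (sd 0.02). Generation refuses
RR < 0.3 s, where templates would overlap nonphysically. BVP: a
gamma-shaped systolic wave (foot at 0, peak at 0.18 s) with a small
dicrotic bump, placed at beat time + 250 ms transit delay; because the
1–8 Hz bandpass that every consumer applies advances the apparent foot by
≈ 18 ms, templates are placed that much late so the *filtered* onset
falls exactly at the nominal delay.

**Wrist artifacts.** Three mechanisms, all logged as metadata:
band-limited 1–8 Hz noise (sd 0.12 of pulse amplitude) — residual motion
coupling inside the cardiac band, the steady contributor to wrist-HR
noise; biphasic motion spikes at a Poisson rate of 1/min (amp ≈ 4× pulse);
and contact-loss stretches (10 % chance per minute, 3–8 s, signal
replaced by a noise floor of sd 0.02). These defaults were calibrated so
that the cohort-mean chest-vs-wrist HR SNR gap lands in the 4–6 dB range
that motivates the device comparison; per-subject gaps are strongly
heavy-tailed (a single mis-detected beat stretch can dominate a scene's
variance), which mirrors the qualitative behavior of real wrist data.

**What passing tests do and do not show.** The generator's beats are
template-perfect and its noise is stationary and additive; real ECG
morphology varies beat to beat, electrode artifacts are structured, and
real PPG artifacts correlate with motion in ways a Poisson model does
not capture. Clean-signal recovery (ECG window HR within 1.5 bpm of
truth, PPG within 3 bpm; beat recall/precision 1.0 at ±25 ms) validates
the implementation of the chain, not its field accuracy; the
sensitivity/specificity results say the rule system behaves as designed
when effects of the stated size are present, not that humans produce such
effects.

## Numerical and design details

* Even-count medians average the two central values everywhere.
* Resampling grids are `start + k·0.25 s` with the end point exclusive;
  segmentation restarts at each scene's t = 0.
* Recording spans are cropped to the timestamp intersection before
  analysis; cropping never alters sampling rates or kept samples.
* The EDF codec writes 16-bit samples in 1 s records with per-channel
  physical scaling; start times quantize to whole seconds and recordings
  pad to whole records by repeating the final sample.
* A subject without a baseline scene is a fatal error (thresholds are
  undefined); any other scene whose streams fail to process is skipped
  with a logged reason.
* Determinism: every stochastic component consumes an explicit seed, and
  session seeds are derived per (subject, scene) via `SeedSequence`, so
  identical inputs reproduce recordings bit for bit.

## Known limitations

* Single-lead, upright-R ECG only; no arrhythmia handling.
* RMSSD here is not the classical NN-interval RMSSD; values are in bpm
  and not comparable to ms-scale HRV literature.
* Pulse-rate variability vs HRV discrepancies are out of scope; the wrist
  chain is only used for the same HR features as the chest chain.
* Threshold multipliers (1.3/0.5) are fixed inputs, not fitted; no
  fine-tuning machinery is provided.
* The problem sizes used in the validation suite (8–16 subjects, 240 s
  sessions) were chosen as the smallest cohorts at which the cohort-level
  contrasts are stable.
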