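# Methods

## Background and model

Respiratory inductance plethysmography (RIP) measures breathing with two
elastic transducer bands, one around the rib cage (RC) and one around the
abdomen (AB). Under the Konno–Mead two-compartment model of chest-wall
motion, each band's displacement approximates that compartment's volume
excursion, and the *sum* of the two signals is an (uncalibrated) proxy for
tidal volume. ripwob computes four work-of-breathing (WOB) indices from
these two channels:

* **Phase angle (Φ)** — synchrony between the compartments. On an N-sample
  window, with x = RC and y = AB each mean-subtracted,

  Φ = arccos( Σₙ x(n)·y(n) / √(Σₙ x(n)² · Σₙ y(n)²) )

  in degrees. Φ = 0° is perfect synchrony, Φ = 180° paradoxical (opposed)
  motion. The arccos argument is clamped to [−1, 1] so rounding can never
  produce a domain error. The angle is *unsigned*: the inner product cannot
  distinguish RC-leads from AB-leads; only the magnitude of asynchrony is
  reported. Mean subtraction is essential — DC offsets from band tension
  would otherwise dominate the inner product.

* **RC%** — the rib-cage contribution to tidal volume,
  100·A_rc/(A_rc + A_ab), where A_c is the compartment excursion
  (see below). RC% + AB% = 100 by construction.

* **LBI** (labored breathing index) — (A_rc + A_ab)/A_sum, the ratio of the
  maximal compartmental amplitude (the tidal excursion the compartments
  would produce breathing in unison) to the excursion of the recorded sum
  rc + ab. Peak-to-peak is sub-additive, so LBI ≥ 1, with equality at
  perfect synchrony. For equal-amplitude sinusoids at lag θ the
  continuous-limit value is 1/cos(θ/2), which diverges as θ → 180°: with
  equal amplitudes at total paradox the summed signal cancels entirely and
  the index is undefined. Such windows are emitted as invalid rather than
  as unbounded values (threshold: summed excursion below 1e−6 of the
  combined compartmental excursion).

* **BPM** — breathing rate from the FFT of the whole record. Each channel
  is mean-subtracted and zero-padded to the next power of two (rectangular
  window); the two magnitude spectra are averaged per bin and restricted to
  a physiological band, 0.3–3.0 Hz by default (18–180 breaths/min, wide
  enough for anaesthetised rodents while excluding drift and motion
  harmonics). The largest magnitude is found, every bin within 20% of it is
  kept, and the rate is 60 times the amplitude-weighted mean of the
  selected bin frequencies — a reading that reduces exactly to the peak
  frequency for a single spectral line. If the peak does not stand at least
  3× above the median in-band magnitude, the record has no convincing
  respiratory line (e.g. pure sensor noise) and the estimate is flagged
  invalid; measured margins are wide (white noise peaks at ≈ 2.1–2.5× the
  median, clean breathing records at ≈ 300×).

Synchrony classification uses the conventional thresholds for humans and
most mammals: *synchronous* requires Φ < 30° **and** LBI < 1.05;
Φ ≥ 150° is labelled *paradoxical* (strictly only 180° is paradox, but a
strict-equality class would be empty under any noise; the threshold is
configurable); everything else is *asynchronous*.

## The analysis window and excursion estimator

All three per-window indices use the same N = 20-sample right-aligned
(causal) window, advanced by a 1-sample stride. At the 10 Hz output cadence
this covers about two breaths of a rat breathing at 0.943 Hz and emits ten
index samples per second. N is configurable; values below 4 are rejected
as meaningless for amplitude or phase estimation.

The compartment excursion A_c is the peak-to-peak (max − min) of the
window after removing the straight line through the window's first and
last samples. This estimator was chosen over a least-squares line fit
deliberately: a least-squares line fitted to a pure whole-period sinusoid
has a substantial spurious slope (−6A/π per period), which biases the
peak-to-peak by several percent and breaks the closed-form LBI = 1/cos(θ/2)
relationship that anchors the test suite. The endpoint-anchored line

* removes any *common* linear baseline drift exactly (drift adds the same
  line to both channels and to their sum, so LBI and RC% are strictly
  drift-invariant), and
* is a no-op on windows spanning whole periods of a stationary oscillation.

Its cost is sensitivity to noise at the two endpoint samples, which tilts
the window by an O(noise) line; at the 5% noise level used throughout,
this contributes well under 1% to the index means.

Degenerate windows — flat channels (no excursion), zero-variance channels
(phase undefined), or a vanishing summed excursion (unbounded LBI) — are
emitted as samples with `valid=False` and NaN estimates, never as
exceptions: one flat stretch must not abort a 3.5-minute analysis. Invalid
samples are excluded from summaries and histograms but counted, and every
summary reports per-subject valid fractions so data loss is visible.

## Summaries

Cohort tables report mean ± SEM with *subjects* as the unit of
replication: subject-level means are computed first over each recording's
valid samples, then the mean and SEM (sample SD/√n) are taken across
subjects, so a long recording cannot dominate the table. With a single
subject the SEM is reported as not applicable (NaN / JSON null).
Histograms pool valid samples across subjects into fixed-width bins
anchored on the bin-width grid at or below the data minimum (defaults: 2°
for phase, 0.01 for LBI); percent-in-range uses inclusive-low /
exclusive-high intervals.

## The synthetic generator

Real band recordings from anaesthetised rodents are rarely shareable, so
`ripwob.synthetic` generates two-compartment quasi-sinusoidal breathing
with every ground truth set explicitly. Breath periods are drawn i.i.d.
with a stated coefficient of variation around the base period, each breath
gets an amplitude scale with its own CV, a continuous instantaneous phase
is built by linear interpolation across breath boundaries, and the RC
channel is the AB sinusoid advanced by a constant phase lag and scaled by
the amplitude ratio. Additive white Gaussian noise (per channel,
independent) and optional common linear drift complete the signal.
Identical parameters and seed give bit-identical recordings; cohort
subjects draw from independent child streams keyed by (seed, subject
index), so subject i is reproducible regardless of cohort size.

Defaults describe a healthy anaesthetised young adult rat: 0.943 Hz
(56.6 breaths/min), amplitude ratio 1.13 (RC% ≈ 53), 5% period and
amplitude jitter, 5% noise, 210 s at 10 Hz. Presets cover the phenotypes
of interest: `healthy_synchronous` (lag 10°), `mild_async` (45°),
`paradoxical` (175°), and `anesthesia_deep` (amplitudes ×0.3, period CV
0.25, noise 0.15 — shallow, irregular breathing with poor SNR). Cohort
metadata (weight ≈ 246 g, HR ≈ 345 bpm, SpO2 ≈ 96%, ETCO2 ≈ 27 mmHg) are
Gaussian draws that exercise the pass-through path only; they are not a
physiological simulation.

What the generator does **not** emulate: waveform asymmetry between
inspiration and expiration, time-varying asynchrony within a recording,
band slippage or motion artifacts, correlated (non-white) sensor noise,
and cardiogenic oscillations. Passing tests therefore demonstrate correct
recovery of the model's ground truths, not robustness to every artifact of
real recordings.

## Numerical behaviour and known limitations

* **Small-angle noise bias.** Independent channel noise attenuates the
  window cosine by ρ = 1/(1 + σ_n²/σ_s²); because arccos has divergent
  slope at ±1, this inflates near-0° angles (and deflates near-180° ones)
  by up to arccos(ρ) ≈ 5.7° at the 5% noise level. Recovery tests
  acknowledge this floor at the lag-grid endpoints; interior lags recover
  within fractions of a degree. Estimator variance also biases small-lag
  means upward (arccos concavity), worth remembering when interpreting
  per-window Φ near zero.
* **Whole-record BPM.** The rate estimator is a whole-record average by
  default (FFT resolution ≈ 0.0049 Hz at 210 s / 10 Hz before padding).
  Breath-to-breath rate variability broadens the spectral line — at 5%
  period CV the 20%-of-peak band spans ~19 bins — so bin-level agreement
  with the generator frequency is only meaningful for steady rhythms;
  under jitter the estimate tracks the line centroid to ~1.5 bins.
* **arccos rounding.** Near perfect (anti)correlation, a cosine
  perturbation ε maps to an angle error ~√(2ε); float64 rounding therefore
  limits phase reproducibility to ~1e−4 degrees at the scale endpoints,
  which is far below any physiological signal.
* **Uncalibrated volumes.** No isovolume or other calibration is applied;
  RC%, LBI and Φ are ratio/angle quantities that do not require it, but
  absolute tidal volume in mL is out of scope.
* **Problem sizes.** Tests and the acceptance script run on 210-s
  recordings at 10 Hz (2100 samples, 2081 windows) and cohorts of 3–5
  subjects — the scale of a typical small-rodent feasibility study — with
  a 600-run seeded sweep for rate-recovery statistics.
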