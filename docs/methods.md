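# Methods

## Signal model

A subject at range `r` reflects the radar pulse; the chest surface moves by

```
d(t) = A_b Σ_k w_k sin(2π k f_b t + φ_b) + A_h sin(2π f_h t + φ_h) + RBM(t),
```

with `w_1 = 1`, breathing fundamental `f_b` (10–30 cycles/min), heartbeat
`f_h` (48–120 beats/min) and `RBM(t)` a bounded random walk active only
inside declared motion events. Chest motion is not sinusoidal, which is why
the harmonics `k ≥ 2` exist; their in-band images at `k·f_b` are the reason
magnitude-only HR pickers fail. The simulator renders each frame as an
amplitude-only Gaussian-derivative pulse evaluated on the fast-time range
axis at `r + d(t)`, plus a static per-bin clutter profile and white noise.
Carrier, antenna and propagation effects are not modelled: every downstream
algorithm consumes only the magnitude variation over slow time.

Displacement amplitudes are configuration, not measured facts: defaults are
5 mm breathing, 0.5 mm heartbeat — representative of seated adults at
sub-metre range. Harmonic weights default to (1, 0.5, 0.25, 0.12) for
k = 1..4. The harmonic-confusion scenario HC-1 raises w₃/w₄ to 0.4/0.3 so
that the 54 and 72 cpm harmonics outweigh the 70 bpm heartbeat — the regime
the voting selector exists for. The back-aspect geometry multiplies the
breathing amplitude by 0.06, small enough that the heartbeat becomes the
tallest spectral peak, as observed when a radar faces a person's back.

The pulse is a 5th-order Gaussian derivative (width parameter 0.03 m,
bins 4 mm apart). An odd order is deliberate: its single dominant
maximum-slope lobe sits at the pulse centre, so the most
displacement-sensitive fast-time sample — the one the variance scan should
find — coincides with the nominal subject range. Even orders have two equal
slope lobes and the selected bin would be bistable under noise. Echoes are
shifted so that maximum-slope point lands exactly at `r`; the ground-truth
bin is `round(r / bin_spacing)`.

Motion events come in three classes parameterised as bounded random walks
(step scale mm/√s, excursion bound mm): speaking (25, 4), head (20, 20),
whole body (400, 15). The constants were chosen so the three classes
reproduce the qualitative signature of real RBM: normalized correlation
widths around 0.64 / 0.40 / 0.02 of baseline respectively, and detection
latency ordered body < head < speaking. The walk is folded at the bound and
cosine-tapered over 0.5 s at event edges.

## Processing chain

**Clutter removal.** `c_m = α c_{m−1} + (1−α) r_m`, `c_0 = r_0`, output
`r_m − c_m`, vectorised over range bins with `scipy.signal.lfilter`. The
default α = 0.995 at 92.71 frames/s gives a ~2 s settling time and a
high-pass corner near 0.07 Hz, leaving ≥ 10 cpm breathing essentially
untouched. (α = 0.97 would put the corner at ~0.44 Hz and cost roughly
two-thirds of the 18 cpm breathing variance.) The filter is linear, so
clutter subtraction and subject echo superpose exactly.

**Range-bin selection.** Per-column sample variance over the current
sliding window only — a whole-recording variance would smear across bins if
the subject shifted. Ties break to the smallest index; an all-constant
matrix raises rather than returning an arbitrary bin.

**Kalman smoothing.** Scalar random-walk state, q = 1e-4, r = 1e-2,
initialised at the first observation with prior variance r. This is a
~1.4 Hz one-pole low-pass at steady state: strong on white noise, mild
(≈ 0.8 gain) on a 70 bpm heartbeat. It runs after bin selection, per
analysis window.

**Spectrum.** Zero-padded rFFT (pad factor 8) of the mean-removed window,
no taper. The rectangular window is a deliberate choice: its main lobe is
half the width of Hann's, and resolving a heartbeat 2 bpm from a breathing
harmonic is exactly a resolution problem. Mean removal prevents the padding
from smearing the DC level into the respiration band. Peak locations are
quantised to integer beats/min.

**HR voting.** Per window: up to 3 strongest strict local maxima in
48–120 bpm; discard candidates within 1 bpm of `k·RR`, k ≥ 2; add the
survivors to a tally that always reflects the last 20 windows (the oldest
window's votes retire as new ones arrive). Selection merges votes in
adjacent 1 bpm bins into the stronger bin — spectral jitter otherwise
splits one heartbeat line across two bins — then takes the highest count,
breaking ties by mean magnitude, then by the lower location. The first 20
updates are flagged provisional while the tally fills. No reset logic
exists for abrupt HR changes; the sliding window re-converges on its own,
which is the intended behaviour for a monitor whose subject's rate drifts
rather than jumps.

**Motion detection.** Normalized biased autocorrelation of the last 6 s of
the *unsmoothed* selected-bin signal; width = first lag below 0.5 (a pure
sinusoid of period P crosses at P/6; white noise at lag 1). 6 s covers a
full breathing period down to 10 cpm, keeping the stationary width stable.
The Kalman-smoothed signal is deliberately not used here: the smoother is a
low-pass that re-correlates the broadband fluctuation which distinguishes
violent motion, and with it whole-body motion measures *wider* than head
motion. The baseline width comes from the first segment after startup
(assumed stationary) unless configured. Motion is declared below 0.85 of
baseline — stationary subjects sit near 1.0 and even mild speaking motion
reaches ~0.7 — with two consecutive agreeing segments required to flip
state in either direction.

**Gating.** While motion is flagged, RR/HR outputs repeat the last valid
values with `held=True`, and the hold persists until the sliding spectral
window no longer overlaps any motion-flagged instant: the first resumed
spectra would otherwise be computed on contaminated frames and emit exactly
the invalid estimates gating exists to prevent. An estimate is graded valid
against a reference when |HR − reference| ≤ 3 beats/min (strict above 3);
validity is defined for HR, and RR is reported ungraded.

## Defaults and units

| parameter | default | unit | why |
|---|---|---|---|
| frame rate | 92.71 | frames/s | modelled acquisition rate |
| bin spacing | 0.004 | m | radar spatial resolution |
| α (clutter) | 0.995 | — | ~2 s settling, passes ≥ 10 cpm |
| q, r (Kalman) | 1e-4, 1e-2 | signal² | ~1.4 Hz smoothing corner |
| window | 40 | s | 1.5 cpm Rayleigh resolution, resolves HR vs harmonic 2 bpm apart |
| update period | 1 | s | output cadence |
| RR band | 10–30 | cycles/min | physiological breathing range |
| HR band | 48–120 | beats/min | 0.8–2 Hz heart range |
| K peaks | 3 | — | candidates per window |
| N windows | 20 | — | vote depth |
| harmonic tol | 1 | bpm | discard radius around k·RR |
| pad factor | 8 | — | integer-bpm peak quantisation |
| ACF segment | 6 | s | ≥ one breathing period at 10 cpm |
| ACF level | 0.5 | — | half-maximum width |
| width threshold | 0.85 | × baseline | between stationary (1.0) and speaking (~0.7) |
| hysteresis | 2 | segments | debounce near threshold |

The 40 s window is the resolution/responsiveness trade-off pushed toward
resolution: at 20 s (3 cpm resolution) the 70 bpm heartbeat and a 72 cpm
fourth harmonic fuse into a single peak and no algorithm downstream can
separate what the spectrum never resolved. RR estimation alone is fine at
20 s, and the acceptance script measures it there.

## What the simulator does and does not establish

The generator reproduces the structural features the chain is designed
around: a dominant breathing fundamental with controllable harmonics, a
weak heartbeat line, clutter identical across frames, white measurement
noise at roughly 10–15 dB slow-time SNR at the subject bin, and motion
events that decorrelate the slow-time signal at class-dependent rates. It
does not model: carrier/phase effects, antenna patterns, multipath,
through-wall attenuation, range migration, multiple subjects,
physiological rate drift within a recording, or the amplitude
nonstationarity of real breathing. Passing tests therefore demonstrate
that the algorithms do what they claim under the stated signal model —
harmonic-robust HR recovery, motion gating, bin selection — not that the
printed accuracies of any hardware study are reproduced. Hardware-bound
quantities (absolute SNR tables, per-subject invalid-estimate counts,
absolute detection latencies) are checked only as directions and
orderings on synthetic data.

## Numerical notes and edge cases

- All randomness flows through `numpy.random.default_rng(seed)`; fixed
  seeds give bit-identical frames and estimate streams.
- Generation refuses frame rates at or below twice the heartbeat frequency
  (slow-time Nyquist) and subjects whose excursion leaves the observable
  range span.
- Zero-variance inputs raise (`no motion found`, `zero-variance segment`)
  rather than returning arbitrary answers; an empty vote tally raises
  rather than guessing an HR.
- The biased ACF estimator guarantees `acf[0] = 1 ≥ |acf[l]|`, at the cost
  of a (1 − l/L) shrinkage that cancels in the width ratio.
- A correlation width that never crosses the level is capped at the last
  available lag.
- Estimates during motion repeat the last valid values; if motion starts
  before any valid estimate exists, held outputs are NaN until the first
  clean window.
- Update timestamps advance by `round(update_period · frame_rate)` frames
  (93 at the defaults), so nominal 1 s updates drift by ~3 ms each.

## Known limitations

- The voting tally needs `N` clean windows after startup (~60 s at
  defaults) before HR leaves the provisional state; the window length adds
  a further `window_s` of latency before the first estimate.
- Events much shorter than the vote depth barely perturb the converged
  tally, so the gating's benefit shows on motion lasting a substantial
  fraction of `N` updates; brief twitches are absorbed either way.
- Harmonic rejection removes only integer multiples of RR; intermodulation
  products (`f_h ± k f_b`) survive as candidates and are suppressed
  statistically by the vote, not deterministically.
- A true HR within 1 bpm of a breathing harmonic is discarded with it; the
  tally then settles on the nearest surviving recurrent peak.
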