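# Methods

## The model

An electrically evoked compound action potential (eCAP) recorded through a
cochlear implant is treated as the superposition of many identical
single-fiber contributions. Each auditory-nerve fiber that fires
contributes one stereotyped **unitary response (UR)** to the recording
electrode, and the firing times of the population are summarized by the
**compound discharge latency distribution (CDLD)**, a non-negative
function of time. The forward model is the convolution

    eCAP(t) = (CDLD * UR)(t)

so the CDLD's shape encodes firing synchronicity and its area the number
of excited fibers.

**UR model.** A five-parameter biphasic pulse: two Gabor-like half-waves
joined at a transition time `t0`, with negative-phase magnitude `u_n` and
width `sigma_n` (for t < t0) and positive-phase magnitude `u_p` and width
`sigma_p` (for t ≥ t0):

    UR(t) = U · e^{1/2} · ((t − t0)/σ) · exp(−(t − t0)² / (2σ²)),

with `(U, σ) = (u_n, sigma_n)` before `t0` and `(u_p, sigma_p)` after.
The `e^{1/2}/σ` normalization makes the parameterization
*peak-normalized*: the trough value is exactly `−u_n` at `t0 − sigma_n`
and the peak exactly `+u_p` at `t0 + sigma_p`. This is a deliberate
reading of a dimensionally ambiguous printed form: with magnitudes
defined as peak values, the published human UR
(`u_n = 0.155 µV, sigma_n = 0.038 ms, u_p = 0.022 µV, sigma_p = 0.155 ms,
t0 = −0.128 ms`, shipped as `PUBLISHED_HUMAN_UR`) reads directly as peak
amplitudes.

**CDLD model.** A mixture of K unit-peak Gaussians,
`Σ_k alpha_k · exp(−(t − mu_k)²/(2 sigma_k²))` with `alpha_k ≥ 0`, so the
CDLD is non-negative by construction. `alpha` is a *peak* amplitude, not
a component area. K = 2 in routine use (an early and a late neural
response component); components are always reported sorted by ascending
latency, which fixes the label-switching ambiguity of mixture fits.

## The two-step fitting procedure (DMR)

Both steps minimize `‖eCAP_c − forward(CDLD, UR)‖₂` with bounded
trust-region nonlinear least squares (`scipy.optimize.least_squares`,
method `trf`, ftol = xtol = 1e-10, at most 2000 residual evaluations).
`eCAP_c` is the preprocessed recording: the mean of the tail window
(default ≥ 1.5 ms, where the neural response has died out) is subtracted,
and 50 samples are added at each end by linear extrapolation to baseline
(the k-th added sample counting inward from the outer edge equals
`edge · k/(n_extend + 1)`, i.e. the ramp reaches zero one virtual sample
beyond the block) so that the convolution is not distorted at the window
edges.

* **Step one** frees all 11 parameters (5 UR + 6 CDLD) inside published
  bounds. Because an amplitude factor can move freely between the UR and
  the CDLD (`forward(c·CDLD, UR/c)` is identical — asserted as a test),
  step-one CDLDs are not interpreted; only the URs are kept and averaged
  parameter-wise over a series of eCAPs to give a unified human UR.
* **Step two** fixes the UR and refits only the 3·K CDLD parameters, so
  all temporal structure is forced into the CDLD.

**Starting values.** The default starts are the published ones. The
original workflow additionally tuned starting values by hand "when
needed"; a batch tool cannot do that, so the package automates the
trigger and the tuning: when the default-start fit's NRMSE index stays at
or below 0.9 (the conventional accuracy threshold), the fit is retried
from a deterministic ladder of starting vectors whose latencies run over
combinations of {0.3, 0.55, 0.8, 1.05, 1.3} ms, and the lowest-residual
result is kept. This refinement is deterministic and on by default
(`FitConfig.refine_on_poor_fit`); seeded uniform random restarts inside
the bounds exist behind `FitConfig.n_random_starts` but are off by
default.

**Model-order sweep.** Step two is repeated for K = 1…6 with nested
initialization: the K-component start is the (K−1)-component optimum plus
one extra component with amplitude 0, placed where the smaller model
underfits. An unmodeled CDLD component at latency `mu` leaves a residual
trough near `mu + t0 − sigma_n` (the UR's dominant negative lobe), so the
pad latency is read off the deepest residual trough. Starting the pad at
zero amplitude makes the K-model's initial objective equal the
(K−1)-model's optimum, so under a monotone-descent solver the residual
norm is non-increasing in K by construction rather than by luck.

**Numerical details.** The discrete convolution is multiplied by dt by
default (`conv_scale="dt"`), making the forward model a grid-independent
approximation of the continuous integral (halving dt changes the output
by < 0.5% of peak; asserted). The UR is sampled on
`[t0 − 6·sigma_n, t0 + 6·sigma_p]` snapped to the recording lattice
(truncation below 1e-8 of peak). Width parameters whose printed lower
bound is 0 are floored at 1e-9 ms during evaluation so a boundary
evaluation stays finite; fitted vectors are clipped to the bounds to
absorb last-digit solver overshoot. Degenerate (constant) input waveforms
are rejected before fitting. A component fitted to `alpha = 0` is
retained: the printed domain includes 0.

## Direct spectral deconvolution (comparison path)

`fft_deconvolve` computes `F⁻¹[F(eCAP)/F(UR)]` with the UR zero-padded to
the eCAP length (circular division; the output time axis starts at
`ecap.t0_start − ur.t0_start`). Near-null UR spectral bins amplify noise,
so bins with `|F(UR)|` below `eps · max|F(UR)|` are floored at that
magnitude with phase preserved (`eps = 1e-6` by default; 0 reproduces the
plain division). On noiseless, window-contained input the round trip
inverts the forward model to ~1e-14; with 2% noise the raw quotient goes
negative — the unphysical behavior that motivates the iterative method.
The classical post-processing (`strahl_postprocess`) applies a zero-phase
Butterworth low-pass (order 4, applied forward and backward by
`filtfilt`, so a 5 kHz tone is attenuated far beyond 20 dB at the 2.5 kHz
default cutoff) and, if the filtered curve still dips below zero, shifts
it up so its minimum is exactly zero. The source describing this
post-processing does not specify the filter design or the shift rule;
both choices here are this package's reading, are recorded in the run
manifest, and results depending on them should be treated as comparative.

## Synthetic data

The generator emulates the structure of clinical single-pulse eCAPs under
the model's own assumptions: ground-truth two-component CDLDs drawn
uniformly inside the published step-two bounds, convolved with the
published human UR on a 0–2.2 ms window at dt = 0.005 ms (440 samples;
grids are half-open `[start, end)`), plus an optional constant baseline
offset and white Gaussian noise with SD equal to `noise_sd_rel` (default
1%) of each waveform's noiseless peak.

Raw uniform draws over the full bound box frequently produce waveforms
unlike recordings — response energy before the window or still present
after 1.5 ms — which breaks tail-based baseline estimation and the edge
extension. Draws are therefore rejection-resampled until three realism
constraints hold, all configurable on `CdldSampler`:

* every `alpha ≥ 0.05` (no degenerate component),
* `|mu_i − mu_j| ≥ 2 · (sigma_i + sigma_j)` (genuinely bimodal),
* the noiseless eCAP is *contained in the recording window*: its
  amplitude before the window start and after 1.5 ms stays below 2% of
  its peak (N1/P1 inside the window, flat tail).

One `numpy` generator seeded with `spec.seed` drives both the parameter
draws and the noise, so batches are bit-reproducible; all seeds are
plain integers below 2³¹.

**What the generator does not emulate:** stimulus artifact and its
residue, alternating-polarity paradigms, correlated or non-Gaussian
recording noise (the noise spectrum of CI telemetry is not characterized
here), amplitude growth with stimulus level, and any violation of the
identical-UR assumption. Passing tests therefore show that the estimator
inverts its own generative model under realistic noise — not that the
model is correct for any particular clinical recording.

## Problem sizes used in validation

The recorded-data experiments behind the headline numbers used thousands
of clinical eCAPs, which are not public. The package's validation uses
seeded synthetic stand-ins at desk scale: 100 waveforms for the fit
accuracy rate, the first 20 of those for the model-order sweep, and 50
noiseless draws for parameter recovery. `scripts/acceptance.py` recomputes
these quantities from scratch for any seed.

## Known limitations

* The step-one UR estimate inherits the scale/shift degeneracy of the
  joint fit; it is constrained only by the printed bounds, exactly as in
  the original procedure. Averaging is over UR *parameters*; averaging UR
  waveforms would differ slightly because the model is nonlinear in its
  parameters.
* Whether the original implementation scaled its convolution by the
  sample interval is unknown; absolute `alpha` magnitudes are therefore
  comparable only within a fixed `conv_scale` convention.
* The start-refinement ladder removes most, not all, local-minimum
  failures; a small fraction of fits (≈2% at 1% noise) can converge to a
  plausible but wrong CDLD with a fit index above 0.9.
* The per-eCAP inclusion rule before UR averaging (whether poorly fit
  eCAPs should be excluded) is not specified by the source procedure;
  `fit-step1` averages all successfully fitted waveforms.
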