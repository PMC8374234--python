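# ecapdeconv

Iterative deconvolution of cochlear-implant eCAPs: estimate the human
unitary response and extract the temporal firing pattern of the auditory
nerve.

## The problem

The electrically evoked compound action potential (eCAP) recorded through
a cochlear implant is the summed response of many auditory-nerve fibers
to an electrical pulse. Clinically it is read off by its main peaks (the
N1 trough and P1 peak), which says little about *when* the individual
fibers fired. Under the standard assumption that every fiber contributes
the same stereotyped **unitary response (UR)**, the eCAP is the
convolution of that UR with the **compound discharge latency
distribution (CDLD)** — a non-negative function of time whose shape
encodes neural synchronicity and whose area reflects the number of
excited fibers:

    eCAP(t) = (CDLD * UR)(t)

Naively inverting this by spectral division,
`CDLD = F⁻¹[F(eCAP)/F(UR)]`, produces negative phases and
high-frequency ripple on noisy recordings. This package implements the
iterative alternative: model the UR as a five-parameter biphasic pulse
(`u_n, sigma_n, u_p, sigma_p, t0`) and the CDLD as a mixture of K
unit-peak Gaussians (`alpha_k, mu_k, sigma_k`; K = 2 in routine use), and
fit the convolution forward model to the recording with bounded nonlinear
least squares — the deconvolution fitting-error minimization routine
(DMR):

* **step one** fits UR and CDLD jointly per eCAP and averages the URs
  over a series of recordings into a unified human UR (the published
  estimate, `u_n = 0.155 µV, sigma_n = 0.038 ms, u_p = 0.022 µV,
  sigma_p = 0.155 ms, t0 = −0.128 ms`, ships as `PUBLISHED_HUMAN_UR`);
* **step two** fixes that UR and refits only the CDLD, which then
  carries all the temporal information, is non-negative by construction,
  and needs no post-processing.

Goodness of fit is the NRMSE index
`1 − ‖ref − pred‖ / ‖ref − mean(ref)‖` (1 = perfect; > 0.9 counts as
accurate). The direct spectral route and its classical low-pass-and-shift
post-processing are included as a comparison path, and a seeded synthetic
generator stands in for clinical recordings, with ground truth retained
for recovery scoring.

The package is for auditory electrophysiologists and CI researchers who
have eCAP waveforms (delimited text, ms / µV) and want CDLDs, a UR
estimate, or a model-order analysis out of them.

## Worked example

Simulate three synthetic eCAPs (known two-component CDLDs, published
human UR, 1% noise) and deconvolve them with step two:

```
$ ecapdeconv simulate --n 3 --seed 5 --out sim
$ ecapdeconv fit-step2 --input sim/waveforms.csv --ur published-human --out fits
INFO ecapdeconv: ecap0001: fit_index=0.9585 converged=True
INFO ecapdeconv: ecap0002: fit_index=0.9623 converged=True
INFO ecapdeconv: ecap0003: fit_index=0.9610 converged=True
```

`fits/fits.csv` is a long-format table (one row per fitted parameter,
with the fit metrics repeated). Pivoted, with the ground truth from
`sim/truth.csv` alongside:

```
fitted (step two)                      truth
waveform   alpha1  mu1    sigma1       alpha1  mu1    sigma1
ecap0001   0.1141  0.694  0.0772       0.1140  0.6936 0.0772
ecap0002   0.3402  0.4061 0.0780       0.3411  0.4063 0.0779
ecap0003   0.0960  0.2399 0.0089       0.1019  0.2398 0.0084
```

All three fits exceed the 0.9 accuracy threshold, and the recovered
component amplitudes (`alpha`, CDLD peak height), latencies (`mu`, ms)
and widths (`sigma`, ms) match the generating values to a few percent at
1% noise — e.g. for `ecap0002` the early component is recovered as a
burst of firing centred at 0.406 ms (truth 0.406 ms) with spread
0.078 ms. The second component of each waveform is recovered in the same
way; components are always sorted by latency, so `1` is the early and
`2` the late neural response component.

Other subcommands: `preprocess` (baseline correction from the ≥ 1.5 ms
tail plus 50-sample edge extension — applied automatically by the fit
commands), `fit-step1` (joint fits plus the averaged UR in
`ur_mean.csv`), `model-order` (K = 1…6 sweep with nested
initialization), and `fft-deconv` (the spectral comparison path, raw and
post-processed). Every run writes a `manifest.json` with the effective
configuration, input digests and package version; rerunning with the
same inputs and seed reproduces outputs bitwise.

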