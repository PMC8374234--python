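"""Direct frequency-domain deconvolution and its classical post-processing.

Dividing the eCAP spectrum by the UR spectrum recovers the CDLD in one
shot, but on recorded data the quotient blows up wherever the UR spectrum
is small: the raw result shows negative phases and high-frequency ripple,
which is unphysical for a latency distribution.  The classical remedy —
low-pass filtering at 2.5 kHz and shifting the curve up until it is
non-negative — is implemented here for comparison; the iterative DMR
(:mod:`.fitting`) avoids the problem by construction.  Results that depend
on the post-processing filter choice are comparative, not canonical.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .waveforms import SampledWaveform

__all__ = ["fft_deconvolve", "strahl_postprocess", "POSTPROCESS_FILTER_ORDER"]

#: Butterworth order of the zero-phase post-processing low-pass (applied
#: forward and backward, so the effective roll-off is doubled).
POSTPROCESS_FILTER_ORDER = 4


def fft_deconvolve(
    ecap: SampledWaveform,
    ur: SampledWaveform,
    eps: float = 1e-6,
    scale: str = "dt",
) -> SampledWaveform:
    """Spectral division ``CDLD = F^{-1}[F(eCAP) / F(UR)]``.

    The UR is zero-padded to the eCAP length and the division is circular.
    Spectral bins where ``|F(UR)|`` falls below ``eps`` times its maximum are
    floored at that magnitude with phase preserved, to keep near-null bins
    from amplifying noise; ``eps = 0`` reproduces the plain division.  With
    ``scale="dt"`` the quotient is divided by dt, inverting the dt-scaled
    convolution convention of :func:`.models.forward_ecap`.

    The output grid starts at ``ecap.t0_start - ur.t0_start`` (convolution
    adds time axes; deconvolution subtracts them) with the eCAP's length.
    """
    if abs(ecap.dt - ur.dt) > 1e-9 * ecap.dt:
        raise ValueError("eCAP and UR must share dt")
    if not np.any(ur.values):
        raise ValueError("UR is identically zero")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if scale not in ("dt", "none"):
        raise ValueError("scale must be 'dt' or 'none'")
    n = ecap.n
    if ur.n > n:
        raise ValueError("UR longer than eCAP; record a longer eCAP window")
    h = np.fft.rfft(ur.values, n)
    if eps > 0:
        floor = eps * np.max(np.abs(h))
        small = np.abs(h) < floor
        if np.any(small):
            phase = np.where(h[small] == 0, 1.0, h[small] / np.abs(h[small]).clip(min=1e-300))
            h = h.copy()
            h[small] = floor * phase
    q = np.fft.irfft(np.fft.rfft(ecap.values) / h, n)
    if scale == "dt":
        q = q / ecap.dt
    return SampledWaveform(ecap.t0_start - ur.t0_start, ecap.dt, q, f"{ecap.label}:cdld")


def strahl_postprocess(
    cdld: SampledWaveform,
    cutoff_khz: float = 2.5,
    order: int = POSTPROCESS_FILTER_ORDER,
) -> SampledWaveform:
    """Low-pass the spectrally deconvolved CDLD and shift it non-negative.

    A zero-phase Butterworth low-pass at ``cutoff_khz`` removes the
    high-frequency ripple; if the filtered curve still dips below zero it
    is shifted upward so its minimum is exactly zero.  The sampling rate is
    ``1 / dt`` kHz (dt in ms); the cutoff must lie below Nyquist.
    """
    fs_khz = 1.0 / cdld.dt
    nyq = fs_khz / 2.0
    if not (0 < cutoff_khz < nyq):
        raise ValueError(f"cutoff {cutoff_khz} kHz must lie in (0, Nyquist={nyq:g} kHz)")
    b, a = butter(order, cutoff_khz / nyq)
    y = filtfilt(b, a, cdld.values)
    m = float(np.min(y))
    if m < 0:
        y = y - m
    return cdld.with_values(y, label=f"{cdld.label}:post")
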