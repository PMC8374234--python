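"""Parametric UR and CDLD models and the forward eCAP convolution.

The eCAP is modeled as the convolution of a unitary response (UR) — the
stereotyped contribution of a single auditory-nerve fiber's action potential
to the recording electrode — with a compound discharge latency distribution
(CDLD), the non-negative function weighting fiber firings over time:

    eCAP(t) = (CDLD * UR)(t)

The UR is a biphasic pulse built from two Gabor-like half-waves joined at a
transition time ``t0``: a negative phase (depolarization seen at the
electrode) of magnitude ``u_n`` and width ``sigma_n`` for t < t0, and a
positive phase of magnitude ``u_p`` and width ``sigma_p`` for t >= t0.  The
parameterization is peak-normalized: the trough value is exactly ``-u_n``
(at ``t0 - sigma_n``) and the peak exactly ``+u_p`` (at ``t0 + sigma_p``),
so published magnitudes read directly as peak amplitudes in µV.

The CDLD is a mixture of K unit-peak Gaussians (alpha = peak amplitude, not
component area); K = 2 in routine use, matching the early and late neural
response components seen in eCAPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .waveforms import SampledWaveform, TimeGrid

__all__ = [
    "URParams",
    "GaussComponent",
    "CDLDParams",
    "PUBLISHED_HUMAN_UR",
    "STEP1_START_UR",
    "UR_SUPPORT_WIDTHS",
    "eval_ur",
    "eval_cdld",
    "ur_support_grid",
    "convolve_sampled",
    "forward_ecap",
]

#: UR support is truncated at this many phase widths either side of t0;
#: the discarded tail is below 1e-8 of the peak amplitude.
UR_SUPPORT_WIDTHS = 6.0


@dataclass(frozen=True)
class URParams:
    """Five-parameter biphasic unitary response.

    u_n, u_p : peak magnitudes of the negative / positive phase (µV);
    sigma_n, sigma_p : phase widths (ms); t0 : transition time (ms).
    """

    u_n: float
    sigma_n: float
    u_p: float
    sigma_p: float
    t0: float

    def __post_init__(self) -> None:
        if not (self.u_n > 0):
            raise ValueError("u_n must be > 0")
        if self.u_p < 0:
            raise ValueError("u_p must be >= 0")
        if not (self.sigma_n > 0 and self.sigma_p > 0):
            raise ValueError("UR widths must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.u_n, self.sigma_n, self.u_p, self.sigma_p, self.t0])


#: Human UR estimated from a large clinical eCAP corpus (step-one average).
PUBLISHED_HUMAN_UR = URParams(u_n=0.155, sigma_n=0.038, u_p=0.022, sigma_p=0.155, t0=-0.128)

#: Step-one starting UR, patterned on the guinea-pig UR morphology.
STEP1_START_UR = URParams(u_n=0.12, sigma_n=0.045, u_p=0.06, sigma_p=0.12, t0=-0.06)


@dataclass(frozen=True)
class GaussComponent:
    """One CDLD component: peak amplitude ``alpha`` (>= 0), latency ``mu``
    (ms) and width ``sigma`` (ms, > 0)."""

    alpha: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class CDLDParams:
    """Ordered Gaussian mixture describing the discharge latency distribution.

    Components are stored sorted by ascending latency (ties broken by
    ascending width), which pins down the "early"/"late" labeling that is
    otherwise ambiguous in mixture fits.
    """

    components: tuple[GaussComponent, ...]

    def __init__(self, components: Sequence[GaussComponent]):
        components = tuple(components)
        if len(components) < 1:
            raise ValueError("CDLD needs at least one component")
        components = tuple(sorted(components, key=lambda c: (c.mu, c.sigma)))
        object.__setattr__(self, "components", components)

    @property
    def k(self) -> int:
        return len(self.components)

    def as_array(self) -> np.ndarray:
        """Flat parameter vector [alpha1, mu1, sigma1, alpha2, ...]."""
        return np.array([v for c in self.components for v in (c.alpha, c.mu, c.sigma)])

    @staticmethod
    def from_array(x: Sequence[float]) -> "CDLDParams":
        x = np.asarray(x, dtype=float)
        if x.size % 3 != 0 or x.size == 0:
            raise ValueError("CDLD vector length must be a positive multiple of 3")
        return CDLDParams(
            [GaussComponent(*x[3 * i : 3 * i + 3]) for i in range(x.size // 3)]
        )


# ---------------------------------------------------------------------------
# Evaluators
# ---------------------------------------------------------------------------


def _ur_values(p: URParams, t: np.ndarray) -> np.ndarray:
    x = t - p.t0
    u = np.where(x < 0, p.u_n, p.u_p)
    sigma = np.where(x < 0, p.sigma_n, p.sigma_p)
    return u * math.sqrt(math.e) * (x / sigma) * np.exp(-(x**2) / (2 * sigma**2))


def eval_ur(p: URParams, grid: TimeGrid) -> SampledWaveform:
    """Sample the biphasic UR on a time grid.

    The value at ``t0`` is exactly 0; the minimum ``-u_n`` sits at
    ``t0 - sigma_n`` and the maximum ``+u_p`` at ``t0 + sigma_p``.  The grid
    should cover ``[t0 - 6 sigma_n, t0 + 6 sigma_p]`` to capture the full
    support (see :func:`ur_support_grid`).
    """
    return SampledWaveform(grid.start, grid.dt, _ur_values(p, grid.times), "UR")


def _cdld_values(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a flat [alpha, mu, sigma]*K vector; widths floored to keep
    a degenerate component finite (it then contributes ~nothing)."""
    out = np.zeros_like(t)
    for i in range(x.size // 3):
        alpha, mu, sigma = x[3 * i : 3 * i + 3]
        sigma = max(sigma, 1e-9)
        out += alpha * np.exp(-((t - mu) ** 2) / (2 * sigma**2))
    return out


def eval_cdld(p: CDLDParams, grid: TimeGrid) -> SampledWaveform:
    """Sample the Gaussian-mixture CDLD; non-negative everywhere."""
    return SampledWaveform(grid.start, grid.dt, _cdld_values(p.as_array(), grid.times), "CDLD")


def ur_support_grid(p: URParams, dt: float) -> TimeGrid:
    """Grid spanning the UR's effective support, snapped to multiples of dt.

    Snapping keeps the UR samples on the same lattice as any eCAP grid with
    the same dt, so convolution output times land on the recording grid.
    """
    i0 = math.floor((p.t0 - UR_SUPPORT_WIDTHS * p.sigma_n) / dt)
    i1 = math.ceil((p.t0 + UR_SUPPORT_WIDTHS * p.sigma_p) / dt)
    return TimeGrid(i0 * dt, (i1 + 1) * dt, dt)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------


def convolve_sampled(
    a: SampledWaveform, b: SampledWaveform, scale: str = "dt"
) -> SampledWaveform:
    """Full discrete convolution of two waveforms on the same dt.

    Output time of sample (i, j) is ``a.t[i] + b.t[j]``, so the result
    starts at ``a.t0_start + b.t0_start`` with ``len(a) + len(b) - 1``
    samples.  With ``scale="dt"`` the sum is multiplied by dt, making it a
    grid-resolution-independent approximation of the continuous convolution
    integral; ``scale="none"`` leaves the raw discrete sum.
    """
    if scale not in ("dt", "none"):
        raise ValueError("scale must be 'dt' or 'none'")
    if abs(a.dt - b.dt) > 1e-9 * a.dt:
        raise ValueError("convolution operands must share dt")
    vals = np.convolve(a.values, b.values)
    if scale == "dt":
        vals = vals * a.dt
    return SampledWaveform(a.t0_start + b.t0_start, a.dt, vals, a.label)


def forward_ecap(
    cdld: CDLDParams, ur: URParams, grid: TimeGrid, scale: str = "dt"
) -> SampledWaveform:
    """Predict an eCAP on ``grid`` by convolving the CDLD with the UR.

    The UR is sampled on its own support (``ur_support_grid``) at the same
    dt; the CDLD is evaluated on an enlarged lattice so that after the
    convolution the requested window is fully covered, then the result is
    cropped to ``grid``.  The UR's negative ``t0`` shifts response energy
    earlier, which is why the predicted eCAP can be non-zero slightly
    before the earliest CDLD latency.
    """
    vals = _forward_values(cdld.as_array(), ur, grid, scale)
    return SampledWaveform(grid.start, grid.dt, vals, "eCAP_p")


def _forward_values(
    cdld_vec: np.ndarray, ur: URParams, grid: TimeGrid, scale: str = "dt"
) -> np.ndarray:
    """Forward model on a flat CDLD vector (hot path for fitting)."""
    dt = grid.dt
    ug = ur_support_grid(ur, dt)
    ur_vals = _ur_values(ur, ug.times)
    n_u = ug.n
    # CDLD lattice offsets chosen so conv output indices 0..n-1 hit the grid.
    i0 = int(round(ug.start / dt))
    i1 = i0 + n_u - 1
    c_times = grid.start + dt * np.arange(-i1, grid.n - i0)
    c_vals = _cdld_values(cdld_vec, c_times)
    full = np.convolve(c_vals, ur_vals)
    out = full[n_u - 1 : n_u - 1 + grid.n]
    if scale == "dt":
        out = out * dt
    elif scale != "none":
        raise ValueError("scale must be 'dt' or 'none'")
    return out
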