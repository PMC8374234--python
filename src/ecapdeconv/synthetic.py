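"""Seeded synthetic eCAP generator.

Emulates the structure of clinical single-pulse eCAP recordings under the
model's own generative assumptions: a ground-truth two-component CDLD drawn
inside the step-two fitting bounds, convolved with a known UR (the published
human UR by default), plus a constant baseline offset and additive white
Gaussian recording noise scaled to the waveform's peak.  Ground truth is
retained for parameter-recovery scoring, which the clinical data cannot
provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    CDLDParams,
    GaussComponent,
    PUBLISHED_HUMAN_UR,
    URParams,
    forward_ecap,
)
from .waveforms import SampledWaveform, TimeGrid, write_waveforms

__all__ = [
    "CdldSampler",
    "SyntheticSpec",
    "sample_cdld_params",
    "simulate_ecap",
    "simulate_batch",
    "write_batch",
]


@dataclass(frozen=True)
class CdldSampler:
    """Uniform per-parameter ranges and realism constraints for CDLD draws.

    Defaults are the published step-two bounds.  Draws are rejected until
    every amplitude reaches ``min_alpha`` (so no component degenerates),
    every pair of latencies is separated by at least ``min_separation``
    times the pair's summed widths (so the mixture is genuinely multimodal,
    like the early/late neural response components), and the noiseless
    eCAP is contained in the recording window: its amplitude before the
    window start and after ``tail_start`` ms stays below ``max_tail_rel``
    of its peak.  The containment constraint matches recorded single-pulse
    eCAPs — N1 trough and P1 peak inside the window, response decayed by
    ~1.5 ms — and is what makes tail-based baseline estimation valid on
    the simulated data.
    """

    alpha_range: tuple[float, float] = (0.0, 0.35)
    mu_range: tuple[float, float] = (0.15, 1.35)
    sigma_range: tuple[float, float] = (0.0, 0.45)
    n_components: int = 2
    min_alpha: float = 0.05
    min_separation: float = 2.0
    tail_start: float = 1.5
    max_tail_rel: float = 0.02
    max_rejections: int = 10_000

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        for lo, hi in (self.alpha_range, self.mu_range, self.sigma_range):
            if not (hi > lo):
                raise ValueError("sampler ranges must have hi > lo")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic eCAP batch.

    Default grid: 0–2.2 ms at dt = 0.005 ms (440 samples), covering the
    N1/P1 complex and a flat tail beyond 1.5 ms.  ``noise_sd_rel`` scales
    the white-noise SD to each waveform's peak absolute amplitude (default
    1%); ``baseline_offset`` is a constant µV added before preprocessing.
    """

    ur: URParams = PUBLISHED_HUMAN_UR
    n_waveforms: int = 100
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(0.0, 2.2, 0.005))
    sampler: CdldSampler = field(default_factory=CdldSampler)
    noise_sd_rel: float = 0.01
    baseline_offset: float = 0.0
    conv_scale: str = "dt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if self.n_waveforms < 0:
            raise ValueError("n_waveforms must be >= 0")


def sample_cdld_params(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> CDLDParams:
    """Draw one ground-truth CDLD; deterministic given the spec seed.

    Uniform draws within the sampler ranges, rejection-resampled until the
    amplitude, separation and tail-flatness constraints hold.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    s = spec.sampler
    g = spec.grid
    # Evaluate containment on a grid widened by the UR support so that
    # response energy falling before the recording window is also caught.
    lead = 6.0 * abs(spec.ur.t0) + 6.0 * spec.ur.sigma_n
    wide = TimeGrid(g.start - g.dt * np.ceil(lead / g.dt), g.end, g.dt)
    outside = (wide.times < g.start) | (wide.times >= s.tail_start)
    for _ in range(s.max_rejections):
        comps = [
            GaussComponent(
                alpha=rng.uniform(*s.alpha_range),
                mu=rng.uniform(*s.mu_range),
                # sigma's printed lower bound is 0; keep the draw a valid width
                sigma=max(rng.uniform(*s.sigma_range), 1e-6),
            )
            for _ in range(s.n_components)
        ]
        if any(c.alpha < s.min_alpha for c in comps):
            continue
        ok = all(
            abs(a.mu - b.mu) >= s.min_separation * (a.sigma + b.sigma)
            for i, a in enumerate(comps)
            for b in comps[i + 1 :]
        )
        if not ok:
            continue
        cdld = CDLDParams(comps)
        clean = forward_ecap(cdld, spec.ur, wide, spec.conv_scale).values
        peak = np.max(np.abs(clean))
        if np.max(np.abs(clean[outside]), initial=0.0) > s.max_tail_rel * peak:
            continue
        return cdld
    raise ValueError(
        f"CDLD constraints unsatisfiable within the ranges after "
        f"{s.max_rejections} rejections"
    )


def simulate_ecap(
    cdld: CDLDParams, spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> SampledWaveform:
    """Forward-convolve one CDLD and add baseline offset and noise.

    Noise SD = ``noise_sd_rel`` times the peak absolute amplitude of the
    noiseless trace; with ``noise_sd_rel = 0`` and zero offset the output
    equals :func:`.models.forward_ecap` exactly.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    clean = forward_ecap(cdld, spec.ur, spec.grid, spec.conv_scale)
    vals = clean.values + spec.baseline_offset
    if spec.noise_sd_rel > 0:
        sd = spec.noise_sd_rel * float(np.max(np.abs(clean.values)))
        vals = vals + rng.normal(0.0, sd, size=vals.size)
    return clean.with_values(vals, label="ecap")


def simulate_batch(
    spec: SyntheticSpec,
) -> list[tuple[SampledWaveform, CDLDParams]]:
    """Generate ``n_waveforms`` independent (waveform, ground truth) pairs.

    A single generator seeded with ``spec.seed`` drives both the parameter
    draws and the noise, so the whole batch is reproducible end-to-end.
    Waveforms are labeled ``ecap0001, ecap0002, ...``.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_waveforms):
        truth = sample_cdld_params(spec, rng)
        w = simulate_ecap(truth, spec, rng)
        out.append((w.with_values(w.values, label=f"ecap{i + 1:04d}"), truth))
    return out


def write_batch(
    batch: list[tuple[SampledWaveform, CDLDParams]],
    waveform_path: str | Path,
    truth_path: str | Path,
    spec: SyntheticSpec | None = None,
) -> None:
    """Write a batch as a long-format waveform table plus a truth table.

    Truth rows: one per component (waveform_id, component, alpha, mu,
    sigma) plus the generating UR parameters and seed when ``spec`` is
    given.
    """
    write_waveforms([w for w, _ in batch], waveform_path, dialect="long")
    rows = []
    for w, truth in batch:
        for j, c in enumerate(truth.components, start=1):
            row = {
                "waveform_id": w.label,
                "component": j,
                "alpha": c.alpha,
                "mu": c.mu,
                "sigma": c.sigma,
            }
            if spec is not None:
                row.update(
                    u_n=spec.ur.u_n,
                    sigma_n=spec.ur.sigma_n,
                    u_p=spec.ur.u_p,
                    sigma_p=spec.ur.sigma_p,
                    t0=spec.ur.t0,
                    seed=spec.seed,
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(truth_path, index=False)
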