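"""Sampled-waveform container, text I/O, preprocessing and the NRMSE fit index.

Every waveform in this package — recorded or predicted eCAPs, unitary
responses (URs) and compound discharge latency distributions (CDLDs) — lives
on a uniform time grid in milliseconds with amplitudes in microvolts.
Preprocessing mirrors the standard eCAP workflow: the baseline is estimated
from the flat tail of the recording (neural activity has died out roughly
1.5 ms after the stimulus artifact) and subtracted, and the waveform is
linearly extrapolated to baseline on both ends so that the finite recording
window does not distort the convolution model near its edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SampledWaveform",
    "TimeGrid",
    "PreprocessConfig",
    "read_waveforms",
    "write_waveforms",
    "baseline_correct",
    "extend_signal",
    "preprocess",
    "nrmse_fit_index",
]

#: Relative tolerance on successive time steps when verifying grid uniformity.
GRID_UNIFORMITY_RTOL = 1e-6


@dataclass(frozen=True)
class SampledWaveform:
    """A uniformly sampled time series (time in ms, amplitude in µV).

    Parameters
    ----------
    t0_start:
        Time of the first sample in milliseconds.
    dt:
        Sampling interval in milliseconds; strictly positive.
    values:
        Sample amplitudes in microvolts; at least two finite samples.
    label:
        Free-text identifier carried through I/O and batch tables.
    """

    t0_start: float
    dt: float
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.isfinite(self.t0_start):
            raise ValueError("t0_start must be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite amplitude in waveform {self.label!r}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms: ``t0_start + i * dt``."""
        return self.t0_start + self.dt * np.arange(self.n)

    @property
    def t_end(self) -> float:
        """Time of the last sample (ms)."""
        return self.t0_start + self.dt * (self.n - 1)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "SampledWaveform":
        """Copy of this waveform with new amplitudes on the same grid."""
        return SampledWaveform(
            self.t0_start, self.dt, values, self.label if label is None else label
        )

    def same_grid(self, other: "SampledWaveform", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and abs(self.dt - other.dt) <= rtol * self.dt
            and abs(self.t0_start - other.t0_start) <= rtol * max(self.dt, 1.0)
        )


@dataclass(frozen=True)
class TimeGrid:
    """Half-open uniform time grid ``[start, end)`` with step ``dt`` (all ms).

    ``n = round((end - start) / dt)`` samples at ``start + i * dt``; the default
    recording window 0–2.2 ms at dt = 0.005 ms therefore holds 440 samples.
    """

    start: float
    end: float
    dt: float

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if not (self.end > self.start):
            raise ValueError("end must exceed start")

    @property
    def n(self) -> int:
        return int(round((self.end - self.start) / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n)

    @staticmethod
    def of(w: SampledWaveform) -> "TimeGrid":
        """The grid a waveform is sampled on."""
        return TimeGrid(w.t0_start, w.t0_start + w.n * w.dt, w.dt)


@dataclass(frozen=True)
class PreprocessConfig:
    """Baseline and signal-extension settings.

    tail_start:
        Time (ms) after which the recording is treated as baseline; the
        neural response has decayed roughly 1.5 ms post-stimulus, so the
        default tail window is [1.5 ms, end of recording].
    n_extend:
        Number of samples linearly extrapolated to baseline at each end
        of the waveform before fitting (default 50).
    """

    tail_start: float = 1.5
    n_extend: int = 50

    def __post_init__(self) -> None:
        if not (self.tail_start > 0):
            raise ValueError("tail_start must be > 0")
        if self.n_extend < 0:
            raise ValueError("n_extend must be >= 0")


# ---------------------------------------------------------------------------
# File I/O (delimited text, wide or long dialect)
# ---------------------------------------------------------------------------

_WIDE_COLS = ("time_ms", "amplitude_uV")
_LONG_COLS = ("waveform_id", "time_ms", "amplitude_uV")


def _grid_from_times(times: np.ndarray, label: str) -> tuple[float, float]:
    """Validate uniform spacing and return (t0_start, dt)."""
    if times.size < 2:
        raise ValueError(f"waveform {label!r} has fewer than 2 samples")
    steps = np.diff(times)
    dt = float(np.median(steps))
    if dt <= 0:
        raise ValueError(f"non-increasing time axis in waveform {label!r}")
    if np.max(np.abs(steps - dt)) >= GRID_UNIFORMITY_RTOL * dt:
        raise ValueError(f"non-uniform grid in waveform {label!r}")
    return float(times[0]), dt


def read_waveforms(path: str | Path, dialect: str = "wide") -> list[SampledWaveform]:
    """Read waveforms from a delimited text file.

    ``wide``: one waveform per file, columns ``time_ms, amplitude_uV``.
    ``long``: many waveforms, columns ``waveform_id, time_ms, amplitude_uV``;
    waveforms are returned in order of first appearance of their id.
    Comma and tab separators are auto-detected from the file extension
    (``.tsv``/``.tab`` → tab, otherwise comma).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if dialect == "wide":
        missing = [c for c in _WIDE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"format error: missing columns {missing} in {path.name}")
        t = df["time_ms"].to_numpy(dtype=float)
        t0, dt = _grid_from_times(t, path.stem)
        return [SampledWaveform(t0, dt, df["amplitude_uV"].to_numpy(dtype=float), path.stem)]
    if dialect == "long":
        missing = [c for c in _LONG_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"format error: missing columns {missing} in {path.name}")
        out = []
        for wid, grp in df.groupby("waveform_id", sort=False):
            t = grp["time_ms"].to_numpy(dtype=float)
            t0, dt = _grid_from_times(t, str(wid))
            out.append(SampledWaveform(t0, dt, grp["amplitude_uV"].to_numpy(dtype=float), str(wid)))
        return out
    raise ValueError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")


def write_waveforms(
    waveforms: SampledWaveform | Iterable[SampledWaveform],
    path: str | Path,
    dialect: str = "long",
) -> None:
    """Write waveforms as delimited text in the wide or long dialect."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if isinstance(waveforms, SampledWaveform):
        waveforms = [waveforms]
    waveforms = list(waveforms)
    if dialect == "wide":
        if len(waveforms) != 1:
            raise ValueError("wide dialect holds exactly one waveform per file")
        w = waveforms[0]
        pd.DataFrame({"time_ms": w.times, "amplitude_uV": w.values}).to_csv(
            path, sep=sep, index=False
        )
        return
    if dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "waveform_id": w.label or str(i),
                    "time_ms": w.times,
                    "amplitude_uV": w.values,
                }
            )
            for i, w in enumerate(waveforms)
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def baseline_correct(
    w: SampledWaveform, cfg: PreprocessConfig = PreprocessConfig()
) -> SampledWaveform:
    """Subtract the mean amplitude of the tail section (times >= tail_start).

    The tail of an eCAP recording carries neither neural response nor
    stimulus artifact, so its average estimates the recording baseline.
    Idempotent: the corrected waveform has zero tail mean.
    """
    tail = w.times >= cfg.tail_start
    if not np.any(tail):
        raise ValueError(
            f"tail window empty: waveform {w.label!r} ends at {w.t_end:.4g} ms "
            f"before tail_start={cfg.tail_start:g} ms"
        )
    return w.with_values(w.values - float(np.mean(w.values[tail])))


def extend_signal(
    w: SampledWaveform, cfg: PreprocessConfig = PreprocessConfig()
) -> SampledWaveform:
    """Linearly extrapolate the waveform to baseline at both ends.

    Adds ``n_extend`` samples before the first and after the last sample.
    The extrapolation reaches zero exactly one virtual sample beyond the
    added block, so counting inward from the outer edge the k-th added
    sample (k = 1..n_extend) equals ``edge_value * k / (n_extend + 1)``.
    Expects a baseline-corrected input (baseline = 0); the original samples
    are preserved exactly, and ``t0_start`` moves earlier by
    ``n_extend * dt``.
    """
    m = cfg.n_extend
    if m == 0:
        return w
    ramp = np.arange(1, m + 1) / (m + 1)
    lead = w.values[0] * ramp
    trail = w.values[-1] * ramp[::-1]
    return SampledWaveform(
        w.t0_start - m * w.dt, w.dt, np.concatenate([lead, w.values, trail]), w.label
    )


def preprocess(
    w: SampledWaveform, cfg: PreprocessConfig = PreprocessConfig()
) -> SampledWaveform:
    """Baseline-correct then extend: the standard pipeline before fitting."""
    return extend_signal(baseline_correct(w, cfg), cfg)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def nrmse_fit_index(pred: SampledWaveform, ref: SampledWaveform) -> float:
    """NRMSE goodness-of-fit index: ``1 - ||ref - pred|| / ||ref - mean(ref)||``.

    1 means a perfect fit; predicting the reference mean scores 0; worse
    predictions go negative. Fits above 0.9 are conventionally regarded as
    accurate for eCAP modeling. Requires identical grids and a non-constant
    reference.
    """
    if not ref.same_grid(pred):
        raise ValueError("pred and ref must share the same time grid")
    denom = float(np.linalg.norm(ref.values - np.mean(ref.values)))
    if denom == 0.0:
        raise ValueError("reference has no variance")
    return 1.0 - float(np.linalg.norm(ref.values - pred.values)) / denom
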