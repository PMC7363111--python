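"""Slice-wise physiological noise regressors (RETROICOR-style).

Cardiac and respiratory cycles corrupt BOLD series at frequencies far
above the volume sampling rate, so they cannot be filtered out in the
frequency domain; instead each slice's acquisition times are assigned a
cardiac phase (position within the beat) and a respiratory phase
(position within the breathing cycle, histogram-equalised amplitude with
inspiration/expiration sign), and low-order Fourier expansions of these
phases enter the GLM as slice-specific confounds.

With the study configuration — 3 cardiac harmonics, 4 respiratory
harmonics and 1 multiplicative cardiac x respiratory interaction — the
expansion yields 2*3 + 2*4 + 4 = 18 regressors per slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PhysioTrace:
    """Recorded cardiac trigger times and a respiratory waveform.

    ``cardiac_triggers`` are the detected beat times in seconds (strictly
    increasing, at least two). ``resp_samples`` is a uniformly sampled
    respiratory bellows trace at ``resp_rate_hz``; ``resp_t0`` is the
    time of its first sample.
    """

    cardiac_triggers: np.ndarray
    resp_samples: np.ndarray
    resp_rate_hz: float
    resp_t0: float = 0.0

    def __post_init__(self) -> None:
        self.cardiac_triggers = np.asarray(self.cardiac_triggers, dtype=float)
        self.resp_samples = np.asarray(self.resp_samples, dtype=float)
        if self.cardiac_triggers.size < 2:
            raise ValueError("need at least 2 cardiac triggers")
        if not np.all(np.diff(self.cardiac_triggers) > 0):
            raise ValueError("cardiac triggers must be strictly increasing")
        if not self.resp_rate_hz > 0:
            raise ValueError("resp_rate_hz must be positive")
        if self.resp_samples.size < 3:
            raise ValueError("respiratory waveform too short")

    @property
    def resp_times(self) -> np.ndarray:
        return self.resp_t0 + np.arange(self.resp_samples.size) / self.resp_rate_hz


@dataclass
class SliceTiming:
    """Per-slice acquisition offsets within the TR, in seconds."""

    offsets: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if np.any(self.offsets < 0) or np.any(self.offsets >= self.tr):
            raise ValueError("slice offsets must lie in [0, TR)")

    @property
    def n_slices(self) -> int:
        return int(self.offsets.size)


@dataclass
class PnmRegressors:
    """Per-slice physiological regressor matrices.

    ``values`` has shape ``(n_slices, nt, n_cols)``; ``names`` labels the
    columns (identical across slices, values differ because each slice is
    sampled at its own acquisition times).
    """

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_slices, nt, n_cols)")
        if self.values.shape[2] != len(self.names):
            raise ValueError("column names do not match value columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")
        if self.values.size and (np.max(np.abs(self.values)) > 1 + 1e-9):
            raise ValueError("regressor values must lie in [-1, 1]")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    def slice_matrix(self, s: int) -> np.ndarray:
        return self.values[s]


def cardiac_phase(triggers: np.ndarray, eval_times: np.ndarray) -> np.ndarray:
    """Cardiac phase in [0, 2*pi): linear position within the beat.

    Between consecutive triggers ``phase = 2*pi*(t - t_prev)/(t_next - t_prev)``.
    Times before the first or after the last trigger are handled by
    extending the nearest inter-beat interval outward.
    """
    triggers = np.asarray(triggers, dtype=float)
    if triggers.size < 2:
        raise ValueError("need at least 2 cardiac triggers")
    t = np.asarray(eval_times, dtype=float)
    intervals = np.diff(triggers)
    # virtual triggers extend the first/last interval far enough to cover t
    lo, hi = t.min(), t.max()
    pre: list[float] = []
    tt = triggers[0]
    while tt > lo:
        tt -= intervals[0]
        pre.append(tt)
    post: list[float] = []
    tt = triggers[-1]
    while tt <= hi:
        tt += intervals[-1]
        post.append(tt)
    grid = np.concatenate([pre[::-1], triggers, post])
    idx = np.searchsorted(grid, t, side="right") - 1
    idx = np.clip(idx, 0, grid.size - 2)
    frac = (t - grid[idx]) / (grid[idx + 1] - grid[idx])
    return (2 * np.pi * frac) % (2 * np.pi)


def respiratory_phase(
    resp_samples: np.ndarray,
    resp_rate_hz: float,
    eval_times: np.ndarray,
    t0: float = 0.0,
    n_bins: int = 100,
) -> np.ndarray:
    """Signed respiratory phase in (-pi, pi] (histogram-equalised amplitude).

    The centred waveform's absolute amplitude is ranked through its
    cumulative histogram: magnitude ``pi * H(|x(t)|)``, where ``H`` is the
    cumulative fraction of samples at or below that amplitude. The sign
    is the sign of the waveform slope at ``t`` (rising = inspiration =
    positive), estimated by central difference over one sample step.
    """
    x = np.asarray(resp_samples, dtype=float)
    if not resp_rate_hz > 0:
        raise ValueError("resp_rate_hz must be positive")
    x = x - x.mean()
    if np.ptp(x) == 0:
        raise ValueError("constant respiratory waveform: phase undefined")
    times = t0 + np.arange(x.size) / resp_rate_hz
    t = np.clip(np.asarray(eval_times, dtype=float), times[0], times[-1])

    absx = np.abs(x)
    hist, edges = np.histogram(absx, bins=n_bins)
    cum = np.concatenate([[0.0], np.cumsum(hist)]) / absx.size

    amp = np.interp(t, times, x)
    magnitude = np.pi * np.interp(np.abs(amp), edges, cum)

    dt = 1.0 / resp_rate_hz
    slope = (np.interp(t + dt, times, x) - np.interp(t - dt, times, x)) / (2 * dt)
    sign = np.where(slope >= 0, 1.0, -1.0)
    return sign * magnitude


def build_pnm_regressors(
    trace: PhysioTrace,
    slice_timing: SliceTiming,
    volume_times: np.ndarray,
    n_cardiac: int = 3,
    n_resp: int = 4,
    n_interact: int = 1,
    n_bins: int = 100,
) -> PnmRegressors:
    """Fourier expansion of cardiac/respiratory phase at each slice's times.

    For harmonic ``m`` each process contributes ``sin(m*phi)`` and
    ``cos(m*phi)`` columns; each interaction order ``i`` contributes the
    four products ``sin/cos(i*phi_card) * sin/cos(i*phi_resp)``, so the
    column count is ``2*n_cardiac + 2*n_resp + 4*n_interact``.
    """
    for name, n in (("n_cardiac", n_cardiac), ("n_resp", n_resp), ("n_interact", n_interact)):
        if n < 0:
            raise ValueError(f"{name} must be non-negative")
    volume_times = np.asarray(volume_times, dtype=float)
    nt = volume_times.size
    names: list[str] = []
    for m in range(1, n_cardiac + 1):
        names += [f"card_sin{m}", f"card_cos{m}"]
    for m in range(1, n_resp + 1):
        names += [f"resp_sin{m}", f"resp_cos{m}"]
    for i in range(1, n_interact + 1):
        suffix = "" if i == 1 else str(i)
        names += [f"int_ss{suffix}", f"int_sc{suffix}", f"int_cs{suffix}", f"int_cc{suffix}"]

    n_cols = 2 * n_cardiac + 2 * n_resp + 4 * n_interact
    values = np.empty((slice_timing.n_slices, nt, n_cols))
    for s in range(slice_timing.n_slices):
        t_s = volume_times + slice_timing.offsets[s]
        cols = []
        need_card = n_cardiac > 0 or n_interact > 0
        need_resp = n_resp > 0 or n_interact > 0
        phi_c = cardiac_phase(trace.cardiac_triggers, t_s) if need_card else None
        phi_r = (
            respiratory_phase(trace.resp_samples, trace.resp_rate_hz, t_s, trace.resp_t0, n_bins)
            if need_resp
            else None
        )
        for m in range(1, n_cardiac + 1):
            cols += [np.sin(m * phi_c), np.cos(m * phi_c)]
        for m in range(1, n_resp + 1):
            cols += [np.sin(m * phi_r), np.cos(m * phi_r)]
        for i in range(1, n_interact + 1):
            sc, cc = np.sin(i * phi_c), np.cos(i * phi_c)
            sr, cr = np.sin(i * phi_r), np.cos(i * phi_r)
            cols += [sc * sr, sc * cr, cc * sr, cc * cr]
        values[s] = np.column_stack(cols) if cols else np.empty((nt, 0))
    return PnmRegressors(values=values, names=names)


# ---------------------------------------------------------------------------
# plain-text physio I/O


def write_physio_trace(trace: PhysioTrace, triggers_path: str | Path, resp_path: str | Path) -> None:
    """Write triggers (one time per line) and respiration (two-column TSV)."""
    np.savetxt(triggers_path, trace.cardiac_triggers, fmt="%.6f")
    resp = np.column_stack([trace.resp_times, trace.resp_samples])
    np.savetxt(resp_path, resp, fmt="%.6f", header="time\tvalue", delimiter="\t", comments="")


def read_physio_trace(triggers_path: str | Path, resp_path: str | Path) -> PhysioTrace:
    triggers = np.loadtxt(triggers_path, ndmin=1)
    resp = pd.read_csv(resp_path, sep="\t")
    times = resp["time"].to_numpy(dtype=float)
    dt = np.diff(times)
    if times.size < 3 or np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError(f"{resp_path}: respiration must be uniformly sampled")
    return PhysioTrace(
        cardiac_triggers=triggers,
        resp_samples=resp["value"].to_numpy(dtype=float),
        resp_rate_hz=1.0 / dt.mean(),
        resp_t0=float(times[0]),
    )


def write_pnm_tsv(pnm: PnmRegressors, out_dir: str | Path, stem: str = "pnm") -> list[Path]:
    """Write one regressor TSV per slice; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(pnm.n_slices):
        p = out_dir / f"{stem}_slice{s:03d}.tsv"
        pd.DataFrame(pnm.values[s], columns=pnm.names).to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
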