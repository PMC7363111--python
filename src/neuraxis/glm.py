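"""Seed-based GLM functional connectivity.

Each spinal ROI's mean time course (plus its temporal derivative, to
absorb haemodynamic latency differences) is the regressor of interest in
a voxel-wise GLM over the brain, with slice-specific physiological
regressors, six motion parameters and mean white-matter/CSF series as
confounds. Voxel-wise AR(1) prewhitening makes the t statistics valid
under temporally autocorrelated noise; group inference is a voxel-wise
one-sample t on subject beta maps, z-transformed.

An "exclusive-variance" two-seed model enters both hemicord seeds into
one design so that each seed's map reflects only the variance unique to
that seed (shared variance is attributed to neither).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.fft import dct, idct

from .io_core import VolumeSeries, MaskVolume

Z_CAP = 8.0


@dataclass
class DesignMatrix:
    """An ``nt x p`` design with named columns and interest flags."""

    values: np.ndarray
    names: list[str]
    interest_flags: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.interest_flags = np.asarray(self.interest_flags, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("design must be 2D")
        if self.values.shape[1] != len(self.names) or len(self.names) != self.interest_flags.size:
            raise ValueError("names/flags do not match design columns")
        if not self.interest_flags.any():
            raise ValueError("design needs at least one regressor of interest")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def nt(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def interest_names(self) -> list[str]:
        return [n for n, f in zip(self.names, self.interest_flags) if f]


@dataclass
class GlmFit:
    """Per-interest-column maps from a voxel-wise GLM fit.

    Arrays are ``(n_voxels, n_interest)``; ``residuals`` is
    ``(nt, n_voxels)`` in the original (unwhitened) data space, retained
    for spatial smoothness estimation.
    """

    beta: np.ndarray
    stderr: np.ndarray
    tmap: np.ndarray
    zmap: np.ndarray
    dof: int
    residuals: np.ndarray
    interest_names: list[str]


@dataclass
class GroupResult:
    """Voxel-wise one-sample group test over subject betas."""

    zmap: np.ndarray
    tmap: np.ndarray
    subject_betas: np.ndarray  # (n_sub, n_voxels)
    n_sub: int
    dof: int


def hp_filter_array(ts: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    """High-pass a time-major array via a DCT basis projection.

    Removes the DCT-II components with frequency below ``cutoff_hz``
    (including the mean), i.e. components ``k`` with
    ``k / (2 * nt * tr) < cutoff``. Zero-phase by construction.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    ts = np.asarray(ts, dtype=float)
    nt = ts.shape[0]
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {nyquist} Hz")
    coeffs = dct(ts, axis=0, norm="ortho")
    freqs = np.arange(nt) / (2 * nt * tr)
    coeffs[freqs < cutoff_hz] = 0.0
    return idct(coeffs, axis=0, norm="ortho")


def highpass_filter(series: VolumeSeries, cutoff_hz: float) -> VolumeSeries:
    """Voxel-wise DCT high-pass of a :class:`VolumeSeries`."""
    flat = series.timeseries()
    filtered = hp_filter_array(flat, series.tr, cutoff_hz)
    data = filtered.T.reshape(series.data.shape)
    return replace(series, data=data)


def extract_roi_timeseries(series: VolumeSeries, mask: MaskVolume) -> np.ndarray:
    """Unweighted mean BOLD signal over the mask, per time point."""
    if mask.data.shape != series.shape:
        raise ValueError(f"mask shape {mask.data.shape} != series shape {series.shape}")
    return series.data[mask.data].mean(axis=0)


def temporal_derivative(ts: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Central-difference derivative (one-sided at the ends), same length."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    return np.gradient(ts, dt, axis=0)


def build_design(
    seeds: list[np.ndarray],
    pnm_slice: np.ndarray | None,
    motion: np.ndarray | None,
    wm_ts: np.ndarray | None,
    csf_ts: np.ndarray | None,
    tr: float = 1.0,
    seed_names: list[str] | None = None,
) -> DesignMatrix:
    """Assemble one slice's design: seeds + derivatives, then confounds.

    Interest columns are each seed and its temporal derivative; confound
    columns are the slice's physiological regressors, the six motion
    series and the WM/CSF means. Every column is mean-centred. Raises on
    rank deficiency.
    """
    if not seeds:
        raise ValueError("need at least one seed series")
    if seed_names is None:
        seed_names = [f"seed{i + 1}" for i in range(len(seeds))]
    nt = np.asarray(seeds[0]).shape[0]
    cols, names, flags = [], [], []
    for name, s in zip(seed_names, seeds):
        s = np.asarray(s, dtype=float)
        if s.shape[0] != nt:
            raise ValueError("seed series length mismatch")
        cols += [s, temporal_derivative(s, tr)]
        names += [name, f"{name}_derivative"]
        flags += [True, True]
    if pnm_slice is not None and np.asarray(pnm_slice).shape[1] > 0:
        pnm_slice = np.asarray(pnm_slice, dtype=float)
        if pnm_slice.shape[0] != nt:
            raise ValueError("PNM regressor length mismatch")
        for j in range(pnm_slice.shape[1]):
            cols.append(pnm_slice[:, j])
            names.append(f"pnm{j + 1}")
            flags.append(False)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (nt, 6):
            raise ValueError(f"motion must be (nt, 6), got {motion.shape}")
        for j in range(6):
            cols.append(motion[:, j])
            names.append(f"motion{j + 1}")
            flags.append(False)
    for name, ts in (("wm", wm_ts), ("csf", csf_ts)):
        if ts is not None:
            ts = np.asarray(ts, dtype=float)
            if ts.shape[0] != nt:
                raise ValueError(f"{name} series length mismatch")
            cols.append(ts)
            names.append(name)
            flags.append(False)
    X = np.column_stack(cols)
    X = X - X.mean(axis=0)
    return DesignMatrix(values=X, names=names, interest_flags=np.array(flags))


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles, preserving sign."""
    t = np.asarray(t, dtype=float)
    sf = stats.t.sf(np.abs(t), dof)
    sf = np.clip(sf, 1e-300, 1.0)
    z = stats.norm.isf(sf)
    return np.sign(t) * np.minimum(z, 40.0)


def _prewhiten_rows(X: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) whitening transform (full-sample variant, keeps all rows)."""
    out = np.empty_like(X)
    out[0] = np.sqrt(1 - rho**2) * X[0]
    out[1:] = X[1:] - rho * X[:-1]
    return out


def fit_glm(
    series: VolumeSeries | np.ndarray,
    design: DesignMatrix,
    ar1: bool = True,
    rho_grid: float = 0.01,
) -> GlmFit:
    """Voxel-wise prewhitened least squares.

    An OLS pass estimates each voxel's residual lag-1 autocorrelation;
    voxels are grouped on a ``rho_grid`` lattice and both data and design
    are AR(1)-whitened per group before the final OLS. With ``ar1=False``
    (or an estimated rho of 0) the fit is exactly OLS. ``t = beta/stderr``
    with ``dof = nt - p``; z maps come from the t -> normal quantile
    transform. Voxels with (numerically) zero residual variance get their
    z capped at +/-8.
    """
    if isinstance(series, VolumeSeries):
        Y = series.timeseries()
    else:
        Y = np.asarray(series, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
    nt, nv = Y.shape
    if nt != design.nt:
        raise ValueError(f"data has {nt} time points but design has {design.nt}")
    X = design.values
    p = design.p
    dof = nt - p
    if dof <= 0:
        raise ValueError(f"non-positive residual dof: nt={nt}, p={p}")
    Y = Y - Y.mean(axis=0)

    pinv = np.linalg.pinv(X)
    beta_all = pinv @ Y
    resid = Y - X @ beta_all

    if ar1:
        denom = np.einsum("tv,tv->v", resid, resid)
        num = np.einsum("tv,tv->v", resid[1:], resid[:-1])
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        rho = np.clip(rho, -0.95, 0.95)
        rho_binned = np.round(rho / rho_grid) * rho_grid
    else:
        rho_binned = np.zeros(nv)

    beta_w = np.empty_like(beta_all)
    sigma2 = np.empty(nv)
    var_scale = np.empty((p, nv))
    for r in np.unique(rho_binned):
        cols = np.where(rho_binned == r)[0]
        if r == 0.0:
            Xw, Yw = X, Y[:, cols]
        else:
            Xw = _prewhiten_rows(X, r)
            Yw = _prewhiten_rows(Y[:, cols], r)
        pinv_w = np.linalg.pinv(Xw)
        b = pinv_w @ Yw
        rw = Yw - Xw @ b
        beta_w[:, cols] = b
        sigma2[cols] = np.einsum("tv,tv->v", rw, rw) / dof
        xtx_inv_diag = np.sum(pinv_w**2, axis=1)
        var_scale[:, cols] = xtx_inv_diag[:, None]

    interest = np.where(design.interest_flags)[0]
    beta_i = beta_w[interest].T  # (nv, n_interest)
    var = var_scale[interest].T * sigma2[:, None]
    stderr = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(stderr > 0, beta_i / np.where(stderr > 0, stderr, 1.0), 0.0)
    z = _t_to_z(t, dof)
    # degenerate voxels: zero residual variance but nonzero effect
    degenerate = (stderr <= 1e-12) & (np.abs(beta_i) > 1e-12)
    if degenerate.any():
        z = np.where(degenerate, np.sign(beta_i) * Z_CAP, z)
        t = np.where(degenerate, np.sign(beta_i) * Z_CAP, t)
    z = np.clip(z, -Z_CAP * 5, Z_CAP * 5)

    resid_final = Y - X @ beta_w
    return GlmFit(
        beta=beta_i,
        stderr=stderr,
        tmap=t,
        zmap=z,
        dof=dof,
        residuals=resid_final,
        interest_names=design.interest_names,
    )


def fit_glm_exclusive(
    series: VolumeSeries | np.ndarray,
    seed_a: np.ndarray,
    seed_b: np.ndarray,
    pnm_slice: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    wm_ts: np.ndarray | None = None,
    csf_ts: np.ndarray | None = None,
    tr: float = 1.0,
    ar1: bool = True,
) -> GlmFit:
    """Two-seed exclusive-variance model.

    Both seeds (and their derivatives) enter a single design, so each
    seed's beta reflects only its unique variance. Near-collinear seeds
    (|r| > 0.999) are rejected.
    """
    a = np.asarray(seed_a, float) - np.mean(seed_a)
    b = np.asarray(seed_b, float) - np.mean(seed_b)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0 or abs(float(a @ b) / denom) > 0.999:
        raise ValueError("seed time series are collinear; exclusive model undefined")
    design = build_design(
        [seed_a, seed_b], pnm_slice, motion, wm_ts, csf_ts, tr, seed_names=["seed_a", "seed_b"]
    )
    return fit_glm(series, design, ar1=ar1)


def group_onesample(subject_betas: np.ndarray) -> GroupResult:
    """Voxel-wise one-sample t across subjects, z-transformed.

    A summary-statistics group model: subject beta maps are the inputs,
    and the group z map tests their mean against zero. Voxels with zero
    between-subject variance but nonzero mean are capped at z = +/-8 with
    a warning.
    """
    B = np.asarray(subject_betas, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    n_sub = B.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    dof = n_sub - 1
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    se = sd / np.sqrt(n_sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
    z = _t_to_z(t, dof)
    degenerate = (se <= 1e-12) & (np.abs(mean) > 1e-12)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxels have zero between-subject variance; z capped",
            RuntimeWarning,
        )
        z = np.where(degenerate, np.sign(mean) * Z_CAP, z)
        t = np.where(degenerate, np.sign(mean) * Z_CAP, t)
    return GroupResult(zmap=z, tmap=t, subject_betas=B, n_sub=n_sub, dof=dof)
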