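"""Gaussian-random-field cluster-level inference on z maps.

Suprathreshold clusters (26-connectivity, the common neuroimaging
default) are assigned family-wise corrected p-values from stationary
Gaussian random field theory: the expected number of clusters comes from
the 3D Euler-characteristic density at the cluster-forming threshold,
and cluster extent follows the classical exponential model
``P(n >= k) = exp(-beta * k^(2/3))``, giving
``p_FWE = 1 - exp(-E[clusters] * P(n >= k))``.

Field smoothness (per-axis FWHM in voxels) is estimated from the spatial
autocorrelation of standardised model residuals: for a Gaussian
autocorrelation function, the variance of normalised first differences
determines the kernel width per axis, and the mask volume in FWHM units
gives the resel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import gamma as gamma_fn

from .io_core import CLUSTER_COLUMNS, sort_cluster_table

FWHM_PER_SIGMA = np.sqrt(8 * np.log(2))
FWHM_FLOOR = 0.5


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM (in voxels) and resel count over the analysis mask."""

    fwhm_voxels: np.ndarray
    resel_count: float

    def __post_init__(self) -> None:
        self.fwhm_voxels = np.asarray(self.fwhm_voxels, dtype=float)
        if np.any(self.fwhm_voxels < FWHM_FLOOR):
            raise ValueError("fwhm below floor of 0.5 voxel")
        if not self.resel_count > 0:
            raise ValueError("resel count must be positive")


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray) -> SmoothnessEstimate:
    """Estimate field smoothness from 4D residuals over a mask.

    Residual series are standardised voxel-wise; along each axis the mean
    squared first difference ``v`` between neighbouring in-mask voxels
    gives the lag-1 spatial correlation ``rho = 1 - v/2``. For white
    noise convolved with a Gaussian kernel of width ``sigma_k`` the field
    autocorrelation is ``exp(-d^2 / (4 sigma_k^2))``, so
    ``sigma_k = sqrt(-1 / (4 ln rho))`` and the (kernel-convention)
    ``FWHM = sqrt(8 ln 2) * sigma_k``. Resels = in-mask voxel count /
    product of per-axis FWHMs.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 4:
        raise ValueError("residuals must be 4D (x, y, z, t)")
    if R.shape[3] < 10:
        raise ValueError("need at least 10 residual time points")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != R.shape[:3]:
        raise ValueError("mask shape does not match residuals")

    sd = R.std(axis=3)
    valid = mask & (sd > 0)
    if valid.sum() < 8:
        raise ValueError("residual field is (near-)constant; smoothness undefined")
    Z = np.where(valid[..., None], R / np.where(sd[..., None] > 0, sd[..., None], 1.0), np.nan)

    fwhm = np.empty(3)
    for ax in range(3):
        d = np.diff(Z, axis=ax)
        v = np.nanmean(d**2)
        if not np.isfinite(v) or v <= 0:
            raise ValueError("cannot estimate smoothness along axis %d" % ax)
        rho = 1.0 - v / 2.0
        if rho <= 0:
            f = FWHM_FLOOR  # rougher than the voxel grid resolves: clamp
        else:
            f = FWHM_PER_SIGMA * np.sqrt(-1.0 / (4.0 * np.log(rho)))
        fwhm[ax] = max(f, FWHM_FLOOR)
    resels = float(mask.sum()) / float(np.prod(fwhm))
    return SmoothnessEstimate(fwhm_voxels=fwhm, resel_count=resels)


def _ec_density_3d(t: float) -> float:
    """3D Euler-characteristic density of a unit Gaussian field (resel units)."""
    return (
        (4 * np.log(2)) ** 1.5 / (2 * np.pi) ** 2 * (t**2 - 1.0) * np.exp(-(t**2) / 2.0)
    )


def expected_clusters(resels: float, z_thresh: float) -> float:
    """Expected number of suprathreshold clusters over the mask."""
    return max(resels * _ec_density_3d(z_thresh), 1e-12)


def cluster_p_fwe(k_voxels: float, n_mask_voxels: int, resels: float, z_thresh: float) -> float:
    """Corrected p for one cluster of ``k_voxels`` suprathreshold voxels."""
    if k_voxels <= 0:
        return 1.0
    Em = expected_clusters(resels, z_thresh)
    En = max(n_mask_voxels * stats.norm.sf(z_thresh) / Em, 1e-12)
    beta = (gamma_fn(2.5) / En) ** (2.0 / 3.0)
    p_tail = np.exp(-beta * k_voxels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-Em * p_tail))


def label_clusters(zmap: np.ndarray, mask: np.ndarray, z_thresh: float) -> tuple[np.ndarray, int]:
    """26-connected components of ``z > z_thresh`` within the mask."""
    supra = (np.asarray(zmap) > z_thresh) & np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(supra, structure=structure)
    return labels, int(n)


def grf_cluster_correct(
    zmap: np.ndarray,
    mask: np.ndarray,
    z_thresh: float,
    smoothness: SmoothnessEstimate,
    p_thresh: float = 0.05,
    voxel_size=(1.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Threshold a z map and keep clusters surviving GRF correction.

    Returns the cluster table (only surviving clusters, canonical order)
    and the thresholded map with non-surviving clusters zeroed.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    if smoothness is None:
        raise ValueError("smoothness estimate required for GRF correction")
    zmap = np.asarray(zmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    labels, n = label_clusters(zmap, mask, z_thresh)
    voxel_cm3 = float(np.prod(voxel_size)) / 1000.0
    n_mask = int(mask.sum())

    rows = []
    keep = np.zeros_like(mask)
    for cid in range(1, n + 1):
        in_cluster = labels == cid
        k = int(in_cluster.sum())
        p = cluster_p_fwe(k, n_mask, smoothness.resel_count, z_thresh)
        if p >= p_thresh:
            continue
        vals = np.where(in_cluster, zmap, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), zmap.shape)
        rows.append(
            {
                "cluster_id": 0,
                "n_voxels": k,
                "volume_cm3": k * voxel_cm3,
                "peak_z": float(zmap[peak]),
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
                "p_corrected": p,
            }
        )
        keep |= in_cluster

    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    table = sort_cluster_table(table)
    table["cluster_id"] = np.arange(1, len(table) + 1)
    thresholded = np.where(keep, zmap, 0.0)
    return table, thresholded
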