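"""Activation-volume accounting, laterality index, and group statistics.

For each subject and spinal seed, the brain voxels whose connectivity z
exceeds the one-sided p < 0.01 threshold are counted inside each
hemisphere mask and converted to cm^3. The laterality index
``(L - R) / (L + R)`` summarises the hemispheric balance: +1 is fully
left-lateralised, -1 fully right-lateralised. Group tests are paired and
one-sample t tests; the side-of-cord x side-of-brain interaction is the
per-subject contrast of (L - R) volumes between the two hemicord seeds.

Hemisphere masks are the caller's responsibility (in the study design
they exclude the cerebellum); percent-volume profiles use the same
threshold within anatomical parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MaskVolume


@dataclass
class LateralityRecord:
    subject: str
    seed: str
    left_volume_cm3: float
    right_volume_cm3: float
    index: float


@dataclass
class PairedTestResult:
    t: float
    dof: int
    p: float
    mean_difference: float


def activation_volume(
    zmap: np.ndarray,
    mask: MaskVolume | np.ndarray,
    p_cutoff: float,
    voxel_size,
    tail: str = "positive",
) -> float:
    """Active volume (cm^3) within a mask at a per-voxel p threshold.

    A voxel is active when its z exceeds ``Phi^-1(1 - p_cutoff)``
    (one-sided positive by default; ``tail="both"`` also counts the
    negative tail, ``tail="negative"`` only it).
    """
    mask_data = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask, dtype=bool)
    zmap = np.asarray(zmap, dtype=float)
    if zmap.shape != mask_data.shape:
        raise ValueError(f"zmap shape {zmap.shape} != mask shape {mask_data.shape}")
    z_crit = stats.norm.isf(p_cutoff)
    if tail == "positive":
        active = zmap > z_crit
    elif tail == "negative":
        active = zmap < -z_crit
    elif tail == "both":
        active = np.abs(zmap) > z_crit
    else:
        raise ValueError(f"unknown tail {tail!r}")
    n = int((active & mask_data).sum())
    return n * float(np.prod(voxel_size)) / 1000.0


def laterality_index(left_volume: float, right_volume: float, scale: float = 1.0) -> float:
    """``(L - R) / (L + R)``; ``scale=100`` gives a percent-style display."""
    if left_volume < 0 or right_volume < 0:
        raise ValueError("volumes must be non-negative")
    total = left_volume + right_volume
    if total == 0:
        raise ValueError("laterality index undefined: both volumes are zero")
    return scale * (left_volume - right_volume) / total


def percent_volume(
    zmap: np.ndarray, parcel: MaskVolume | np.ndarray, p_cutoff: float, tail: str = "positive"
) -> float:
    """Percent of parcel voxels active at the per-voxel threshold."""
    parcel_data = parcel.data if isinstance(parcel, MaskVolume) else np.asarray(parcel, dtype=bool)
    n_parcel = int(parcel_data.sum())
    if n_parcel == 0:
        raise ValueError("empty parcel")
    zmap = np.asarray(zmap, dtype=float)
    if zmap.shape != parcel_data.shape:
        raise ValueError("zmap/parcel shape mismatch")
    z_crit = stats.norm.isf(p_cutoff)
    if tail == "positive":
        active = zmap > z_crit
    elif tail == "both":
        active = np.abs(zmap) > z_crit
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return 100.0 * int((active & parcel_data).sum()) / n_parcel


def paired_ttest(values_a: np.ndarray, values_b: np.ndarray) -> PairedTestResult:
    """Two-sided paired t test (a vs b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d, d[0]) and d.std(ddof=1) == 0:
        if d[0] == 0:
            return PairedTestResult(t=0.0, dof=n - 1, p=1.0, mean_difference=0.0)
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        t=float(res.statistic), dof=n - 1, p=float(res.pvalue), mean_difference=float(d.mean())
    )


def one_sample_test(values: np.ndarray, popmean: float = 0.0) -> PairedTestResult:
    """Two-sided one-sample t test against ``popmean``."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if x.std(ddof=1) == 0:
        if np.isclose(x.mean(), popmean):
            return PairedTestResult(t=0.0, dof=n - 1, p=1.0, mean_difference=0.0)
        raise ValueError("zero-variance sample away from the null: t undefined")
    res = stats.ttest_1samp(x, popmean)
    return PairedTestResult(
        t=float(res.statistic), dof=n - 1, p=float(res.pvalue), mean_difference=float(x.mean() - popmean)
    )


def side_by_hemisphere_interaction(records: list[LateralityRecord]) -> PairedTestResult:
    """Interaction between cord side and brain side.

    Requires both hemicord seeds for every subject. The per-subject
    contrast is ``(L - R volume | left seed) - (L - R volume | right
    seed)``; under contralateral organisation it is negative. Tested
    against zero with a one-sample t.
    """
    by_subject: dict[str, dict[str, LateralityRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject, {})[r.seed] = r
    contrasts = []
    for subject, seeds in sorted(by_subject.items()):
        if not {"left", "right"} <= set(seeds):
            raise ValueError(f"subject {subject!r} is missing a seed for the interaction")
        left_seed, right_seed = seeds["left"], seeds["right"]
        contrasts.append(
            (left_seed.left_volume_cm3 - left_seed.right_volume_cm3)
            - (right_seed.left_volume_cm3 - right_seed.right_volume_cm3)
        )
    return one_sample_test(np.asarray(contrasts))


def records_to_frame(records: list[LateralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": r.subject,
                "seed": r.seed,
                "left_volume_cm3": r.left_volume_cm3,
                "right_volume_cm3": r.right_volume_cm3,
                "laterality_index": r.index,
            }
            for r in records
        ]
    )
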