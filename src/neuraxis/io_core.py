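"""Core containers, NIfTI/TSV readers and writers, and run configuration.

The package keeps brain and cervical-cord acquisitions as two separate
:class:`VolumeSeries` objects throughout: the two fields of view are
acquired simultaneously but live on different grids with different voxel
sizes, so they are never resampled onto a common lattice here.

Coordinate convention: voxel indices are 0-based everywhere, and
left/right is *never* inferred from the orientation of an axis — sidedness
is an explicit attribute of :class:`MaskVolume`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

STRUCTURES = ("brain", "cord")
SIDES = ("left", "right", "none")

#: column order of an on-disk cluster table
CLUSTER_COLUMNS = [
    "cluster_id",
    "n_voxels",
    "volume_cm3",
    "peak_z",
    "peak_i",
    "peak_j",
    "peak_k",
    "p_corrected",
]


@dataclass
class VolumeSeries:
    """A 4D BOLD series on a regular grid.

    Parameters
    ----------
    data:
        Real-valued array of shape ``(nx, ny, nz, nt)``.
    voxel_size:
        Voxel edge lengths in mm, one per spatial axis.
    tr:
        Repetition time (volume sampling interval) in seconds.
    structure:
        Which field of view this series covers, ``"brain"`` or ``"cord"``.
    space_label:
        Free-text description of the grid (e.g. ``"synthetic-brain"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    structure: str
    space_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] < 3:
            raise ValueError(
                "VolumeSeries needs a time axis with at least 3 volumes; "
                f"got shape {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeSeries data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nt(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def timeseries(self) -> np.ndarray:
        """Return the data as an ``(nt, n_voxels)`` matrix (C voxel order)."""
        return self.data.reshape(-1, self.nt).T


@dataclass
class MaskVolume:
    """A boolean 3D mask with an explicit label and side attribute."""

    data: np.ndarray
    label: str
    side: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if not self.data.any():
            raise ValueError(f"mask {self.label!r} has no true voxels")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, with study defaults.

    The defaults mirror the analysis this package implements: a 0.01 Hz
    high-pass, per-subject activation threshold p < 0.01, cluster-forming
    z > 2.3 for seed maps and z > 3.1 for ICA maps with cluster-level
    p < 0.05, the 0.01-0.1 Hz resting-state band with a 4x in/out band
    power criterion, 40 principal and 40 independent components, and a
    0.15 cm^3 small-cord-cluster bound.
    """

    highpass_hz: float = 0.01
    subject_p: float = 0.01
    cluster_z_seed: float = 2.3
    cluster_z_ica: float = 3.1
    cluster_p: float = 0.05
    band_lo: float = 0.01
    band_hi: float = 0.1
    power_ratio_min: float = 4.0
    n_pca: int = 40
    n_ica: int = 40
    pca_var_target: float = 0.90
    small_cord_volume_cm3: float = 0.15
    n_cardiac: int = 3
    n_resp: int = 4
    n_interact: int = 1
    drop_volumes: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("need 0 < band_lo < band_hi")
        for name in (
            "highpass_hz",
            "subject_p",
            "cluster_z_seed",
            "cluster_z_ica",
            "cluster_p",
            "power_ratio_min",
            "small_cord_volume_cm3",
            "pca_var_target",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_pca", "n_ica"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        for name in ("n_cardiac", "n_resp", "n_interact", "drop_volumes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat ``key = value`` text configuration file."""
        values: dict[str, object] = {}
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = int if known[key] in ("int", int) else float
            values[key] = caster(val.strip())
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def read_volume_series(path: str | Path, structure: str) -> VolumeSeries:
    """Load a 4D NIfTI image as a :class:`VolumeSeries`.

    Voxel sizes and the TR are taken from the header zooms. 3D-only
    images and non-positive header TRs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 4 or img.shape[3] < 3:
        raise ValueError(f"{path} needs a time axis with at least 3 volumes (shape {img.shape})")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        raise ValueError(f"{path}: header TR must be positive, got {tr}")
    data = np.asarray(img.get_fdata(), dtype=float)
    return VolumeSeries(
        data=data,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=tr,
        structure=structure,
        space_label=path.stem,
    )


def write_volume_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a :class:`VolumeSeries` as a 4D NIfTI-1 image (float64)."""
    img = nib.Nifti1Image(series.data.astype(np.float64), _affine(series.voxel_size))
    img.header.set_zooms(series.voxel_size + (series.tr,))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str, side: str = "none") -> MaskVolume:
    """Load a 3D NIfTI mask; nonzero voxels are true.

    ``label`` and ``side`` are caller-supplied: sidedness never comes
    from the image orientation.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path} must be a 3D mask image (shape {img.shape})")
    return MaskVolume(data=np.asarray(img.get_fdata()) != 0, label=label, side=side)


def write_mask(mask: MaskVolume, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(tuple(voxel_size)))
    nib.save(img, str(path))


def write_stat_map(data: np.ndarray, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D statistic map as NIfTI."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"stat map must be 3D, got shape {data.shape}")
    img = nib.Nifti1Image(data.astype(np.float64), _affine(tuple(voxel_size)))
    nib.save(img, str(path))


def read_stat_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path} must be a 3D map (shape {img.shape})")
    return np.asarray(img.get_fdata(), dtype=float)


def drop_initial_volumes(series: VolumeSeries, n: int) -> VolumeSeries:
    """Remove the first ``n`` volumes (pre-equilibrium frames).

    All other metadata is preserved. ``n`` must leave at least 3 volumes'
    worth of headroom (``n < nt``); an empty result is forbidden.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= series.nt:
        raise ValueError(f"cannot drop {n} of {series.nt} volumes")
    if n == 0:
        return dataclasses.replace(series, data=series.data.copy())
    return dataclasses.replace(series, data=series.data[..., n:].copy())


def sort_cluster_table(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic cluster row order.

    Descending size, ties broken by descending peak z, then lexicographic
    (ascending) peak voxel coordinates.
    """
    if len(table) == 0:
        return table.copy()
    out = table.sort_values(
        by=["n_voxels", "peak_z", "peak_i", "peak_j", "peak_k"],
        ascending=[False, False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def write_cluster_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cluster table as TSV in the canonical column and row order."""
    if not set(CLUSTER_COLUMNS) <= set(table.columns):
        missing = set(CLUSTER_COLUMNS) - set(table.columns)
        raise ValueError(f"cluster table missing columns: {sorted(missing)}")
    out = sort_cluster_table(table)[CLUSTER_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_timeseries_tsv(values: np.ndarray, names: list[str], path: str | Path) -> None:
    """Write an ``(nt, k)`` matrix of named time series as TSV."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    pd.DataFrame(values, columns=names).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
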