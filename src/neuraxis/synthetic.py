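"""Synthetic paired brain / cervical-cord resting-state cohorts.

Emulates, at desk scale, simultaneous two-FOV acquisitions: 24 subjects,
TR 3.05 s, 155 acquired volumes (the first two discarded downstream), a
20x20x12 brain grid at 2 mm and a 6x6x10 cord grid at 1.2 x 1.2 x 5 mm.
Ground-truth networks span both structures with contralateral
brain-hemicord coupling and dorsal/ventral segregation; nuisance terms
are cardiac (~1 Hz) and respiratory (~0.3 Hz) artifacts phase-locked to
an emitted physiological trace, AR(1) noise, linear drift and leakage of
six motion parameters.

Every quantity a downstream stage should recover (network maps,
per-subject loadings, masks) is stored alongside the data, so pipeline
results can be scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import MaskVolume, VolumeSeries, write_mask, write_volume_series
from .physio import PhysioTrace, SliceTiming, cardiac_phase, write_physio_trace

# study-scale acquisition defaults
DEFAULT_BRAIN_SHAPE = (20, 20, 12)
DEFAULT_CORD_SHAPE = (6, 6, 10)
BRAIN_VOXEL_MM = (2.0, 2.0, 2.0)
CORD_VOXEL_MM = (1.2, 1.2, 5.0)
DEFAULT_TR = 3.05
DEFAULT_NT = 155
DEFAULT_N_SUB = 24

#: default planted network amplitude, in units of the voxel noise sd
DEFAULT_AMPLITUDE = 1.5

PARCEL_NAMES = [
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "insula",
    "putamen",
    "caudate",
    "thalamus",
    "cerebellum",
]


@dataclass
class NetworkSpec:
    """One planted network: spatial maps on both grids plus a band.

    Maps are non-negative and max-normalised to 1 when nonzero; either
    may be all-zero (e.g. a brain-only network). The time course of the
    network is band-limited Gaussian noise in ``band`` (Hz).
    """

    name: str
    brain_map: np.ndarray
    cord_map: np.ndarray
    amplitude: float = DEFAULT_AMPLITUDE
    band: tuple[float, float] = (0.01, 0.1)

    def __post_init__(self) -> None:
        self.brain_map = np.asarray(self.brain_map, dtype=float)
        self.cord_map = np.asarray(self.cord_map, dtype=float)
        for m in (self.brain_map, self.cord_map):
            if np.any(m < 0):
                raise ValueError(f"network {self.name!r}: maps must be non-negative")
            peak = m.max() if m.size else 0.0
            if peak > 0 and abs(peak - 1.0) > 1e-9:
                raise ValueError(f"network {self.name!r}: nonzero map must be max-normalised to 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class NoiseSpec:
    """Nuisance model parameters (all in voxel-noise sd units)."""

    ar1_coeff: float = 0.3
    sigma: float = 1.0
    cardiac_amp: float = 0.5
    resp_amp: float = 0.5
    drift_amp: float = 0.5
    motion_leak: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coeff < 1:
            raise ValueError("ar1_coeff must be in [0, 1)")
        for name in ("sigma", "cardiac_amp", "resp_amp", "drift_amp", "motion_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SubjectData:
    brain: VolumeSeries
    cord: VolumeSeries
    physio: PhysioTrace
    motion: np.ndarray  # (nt, 6)


@dataclass
class CohortDataset:
    """A simulated cohort plus its ground truth."""

    subjects: list[SubjectData]
    networks: list[NetworkSpec]
    loadings: np.ndarray  # (n_sub, n_networks)
    tr: float
    brain_slice_timing: SliceTiming
    cord_slice_timing: SliceTiming

    @property
    def n_sub(self) -> int:
        return len(self.subjects)


def _blob(shape, center, sigma) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma))
    return np.exp(-0.5 * d2)


def _norm(m: np.ndarray) -> np.ndarray:
    peak = m.max()
    return m / peak if peak > 0 else m


def default_network_suite(
    brain_shape=DEFAULT_BRAIN_SHAPE,
    cord_shape=DEFAULT_CORD_SHAPE,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> list[NetworkSpec]:
    """The six planted networks of a default cohort.

    Two contralateral hemicord-hemisphere pairs, a ventral-cord "motor"
    network and a dorsal-cord "thalamus" network (both with bilaterally
    symmetric brain maps), a brain-only network with zero cord map, and a
    high-frequency artifact source whose 0.25-0.45 Hz band lies entirely
    outside the 0.01-0.1 Hz resting-state band.

    Left means the lower-index half of axis 0 by construction here; the
    corresponding masks carry that side attribute explicitly.
    """
    bx, by, bz = brain_shape
    cx, cy, cz = cord_shape
    if bx < 8 or by < 8 or bz < 4 or cx < 4 or cy < 4 or cz < 4:
        raise ValueError("grids too small to place disjoint network blobs")

    bxi = np.arange(bx)[:, None, None]
    cxi = np.arange(cx)[:, None, None]
    cyi = np.arange(cy)[None, :, None]
    left_b = bxi < bx // 2
    right_b = ~left_b
    left_c = cxi < cx // 2
    right_c = ~left_c
    ventral_c = cyi < cy // 2
    dorsal_c = ~ventral_c

    def cord_blob(center, sigma, mask3) -> np.ndarray:
        # compact blob hard-masked to its half: the cord is mostly noise,
        # with signal confined to a quadrant-scale cluster
        return _norm(_blob(cord_shape, center, sigma) * np.broadcast_to(mask3, cord_shape))

    cord_left = cord_blob((cx * 0.2, (cy - 1) / 2, (cz - 1) / 2), (cx * 0.17, cy * 0.3, cz * 0.35), left_c)
    cord_right = cord_blob((cx * 0.8, (cy - 1) / 2, (cz - 1) / 2), (cx * 0.17, cy * 0.3, cz * 0.35), right_c)
    cord_ventral = cord_blob(((cx - 1) / 2, cy * 0.2, (cz - 1) / 2), (cx * 0.3, cy * 0.17, cz * 0.35), ventral_c)
    cord_dorsal = cord_blob(((cx - 1) / 2, cy * 0.8, (cz - 1) / 2), (cx * 0.3, cy * 0.17, cz * 0.35), dorsal_c)

    # lateralised brain blobs sit off-centre within one hemisphere
    lat_sigma = (bx * 0.10, by * 0.12, bz * 0.16)
    brain_left = _norm(_blob(brain_shape, (bx * 0.25, by * 0.5, bz * 0.55), lat_sigma) * left_b)
    brain_right = _norm(_blob(brain_shape, (bx * 0.75, by * 0.5, bz * 0.55), lat_sigma) * right_b)

    # bilaterally symmetric blobs for the ventral/dorsal networks
    motor = _blob(brain_shape, ((bx - 1) / 2, by * 0.35, bz * 0.8), (bx * 0.14, by * 0.12, bz * 0.15))
    thalamus = _blob(brain_shape, ((bx - 1) / 2, by * 0.6, bz * 0.45), (bx * 0.12, by * 0.10, bz * 0.16))
    occipital = _blob(brain_shape, ((bx - 1) / 2, by * 0.9, bz * 0.4), (bx * 0.18, by * 0.1, bz * 0.2))

    # edge shell: the classic rim pattern of motion/scanner artifact sources
    centre_dist = _blob(brain_shape, ((bx - 1) / 2, (by - 1) / 2, (bz - 1) / 2), (bx * 0.35, by * 0.35, bz * 0.35))
    rim_brain = _norm(np.clip(0.35 - centre_dist, 0, None))
    cord_centre = _blob(cord_shape, ((cx - 1) / 2, (cy - 1) / 2, (cz - 1) / 2), (cx * 0.4, cy * 0.4, cz * 0.4))
    rim_cord = _norm(np.clip(0.5 - cord_centre, 0, None))

    return [
        NetworkSpec("left_hemicord__right_brain", brain_right, cord_left, amplitude),
        NetworkSpec("right_hemicord__left_brain", brain_left, cord_right, amplitude),
        NetworkSpec("ventral_cord__motor", _norm(motor), cord_ventral, amplitude),
        NetworkSpec("dorsal_cord__thalamus", _norm(thalamus), cord_dorsal, amplitude),
        NetworkSpec("brain_only", _norm(occipital), np.zeros(cord_shape), amplitude),
        NetworkSpec("hf_artifact", rim_brain, rim_cord, amplitude, band=(0.25, 0.45)),
    ]


def band_limited_fine_course(
    rng: np.random.Generator,
    nt: int,
    tr: float,
    band: tuple[float, float],
    oversample: int = 16,
) -> tuple[np.ndarray, float]:
    """Band-limited unit-variance Gaussian noise on a fine time grid.

    Returns the fine series and its sampling step ``tr / oversample``.
    The fine grid lets fast processes be sampled at arbitrary slice
    acquisition times, so above-Nyquist bands alias exactly as a real
    oscillation would.
    """
    n_fine = nt * oversample
    dt = tr / oversample
    white = rng.standard_normal(n_fine)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_fine, d=dt)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(f"band {band} resolves no frequencies at nt={nt}, tr={tr}")
    spec[~keep] = 0.0
    fine = np.fft.irfft(spec, n=n_fine)
    sd = fine.std()
    if sd == 0:
        raise ValueError("degenerate band-limited time course")
    return (fine - fine.mean()) / sd, dt


def band_limited_timecourse(
    rng: np.random.Generator,
    nt: int,
    tr: float,
    band: tuple[float, float],
    oversample: int = 16,
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise sampled at volume times."""
    fine, _ = band_limited_fine_course(rng, nt, tr, band, oversample)
    ts = fine[::oversample]
    sd = ts.std()
    if sd == 0:
        raise ValueError("degenerate band-limited time course")
    return (ts - ts.mean()) / sd


def default_slice_timings(
    brain_shape=DEFAULT_BRAIN_SHAPE, cord_shape=DEFAULT_CORD_SHAPE, tr: float = DEFAULT_TR
) -> tuple[SliceTiming, SliceTiming]:
    """Ascending acquisition: brain slices first, cord slices after."""
    n_total = brain_shape[2] + cord_shape[2]
    offsets = np.arange(n_total) * tr / n_total
    return (
        SliceTiming(offsets[: brain_shape[2]], tr),
        SliceTiming(offsets[brain_shape[2]:], tr),
    )


def _simulate_physio(rng: np.random.Generator, duration: float) -> PhysioTrace:
    """~1 Hz jittered cardiac triggers and a ~0.3 Hz respiratory trace."""
    heart_rate = rng.normal(1.0, 0.05)
    n_beats = int((duration + 20) * heart_rate) + 4
    intervals = 1.0 / heart_rate + rng.normal(0, 0.03, size=n_beats)
    intervals = np.clip(intervals, 0.4, 2.0)
    triggers = -5.0 + np.cumsum(intervals)
    resp_rate = rng.normal(0.3, 0.02)
    fs = 10.0
    t = np.arange(-5.0, duration + 5.0, 1.0 / fs)
    resp = np.sin(2 * np.pi * resp_rate * t + rng.uniform(0, 2 * np.pi))
    resp = resp * (1.0 + 0.1 * np.sin(2 * np.pi * 0.01 * t)) + rng.normal(0, 0.02, size=t.size)
    return PhysioTrace(cardiac_triggers=triggers, resp_samples=resp, resp_rate_hz=fs, resp_t0=-5.0)


def _structure_signal(
    rng: np.random.Generator,
    shape,
    slice_timing: SliceTiming,
    networks,
    loadings,
    timecourses,
    noise: NoiseSpec,
    physio: PhysioTrace,
    motion: np.ndarray,
    nt: int,
    tr: float,
    structure: str,
) -> np.ndarray:
    nx, ny, nz = shape
    data = np.zeros((nx, ny, nz, nt))

    key = "brain_map" if structure == "brain" else "cord_map"
    nyquist = 0.5 / tr
    volume_times = np.arange(nt) * tr
    for net, loading, tc in zip(networks, loadings, timecourses):
        m = getattr(net, key)
        if m.max() == 0:
            continue
        if net.band[0] >= nyquist:
            # above-Nyquist source: one common fast process, but each
            # slice samples it at its own acquisition time within the TR
            # (as the scanner does), so slice phases are staggered and
            # volume-rate averages of the artifact largely cancel
            fine, dt = tc
            fine_times = np.arange(fine.size) * dt
            for s in range(nz):
                tc_s = np.interp(volume_times + slice_timing.offsets[s], fine_times, fine)
                data[:, :, s, :] += loading * net.amplitude * m[:, :, s, None] * tc_s[None, None, :]
        else:
            data += loading * net.amplitude * m[..., None] * tc[None, None, None, :]

    # physiological artifacts: evaluated at each slice's acquisition times,
    # phase-locked to the emitted trace, with smooth voxelwise gain
    volume_times = np.arange(nt) * tr
    card_gain = 0.5 + rng.random((nx, ny, nz))
    resp_gain = 0.5 + rng.random((nx, ny, nz))
    resp_interp_t = physio.resp_times
    for s in range(nz):
        t_s = volume_times + slice_timing.offsets[s]
        if noise.cardiac_amp > 0:
            phi = cardiac_phase(physio.cardiac_triggers, t_s)
            data[:, :, s, :] += noise.cardiac_amp * card_gain[:, :, s, None] * np.cos(phi)[None, None, :]
        if noise.resp_amp > 0:
            w = np.interp(t_s, resp_interp_t, physio.resp_samples)
            data[:, :, s, :] += noise.resp_amp * resp_gain[:, :, s, None] * w[None, None, :]

    # AR(1) noise with stationary sd = sigma
    if noise.sigma > 0:
        innov_sd = noise.sigma * np.sqrt(1 - noise.ar1_coeff**2)
        e = rng.normal(0, innov_sd, size=(nx, ny, nz, nt))
        ar = np.empty_like(e)
        ar[..., 0] = e[..., 0] / np.sqrt(1 - noise.ar1_coeff**2)
        for t in range(1, nt):
            ar[..., t] = noise.ar1_coeff * ar[..., t - 1] + e[..., t]
        data += ar

    # slow confounds: linear drift and motion leakage
    if noise.drift_amp > 0:
        ramp = np.linspace(-1, 1, nt)
        slope = rng.normal(0, noise.drift_amp, size=(nx, ny, nz))
        data += slope[..., None] * ramp[None, None, None, :]
    if noise.motion_leak > 0:
        mstd = motion.std(axis=0)
        mstd[mstd == 0] = 1.0
        mz = (motion - motion.mean(axis=0)) / mstd
        coupling = rng.normal(0, noise.motion_leak, size=(nx, ny, nz, 6))
        data += np.einsum("xyzk,tk->xyzt", coupling, mz)

    return data


def simulate_subject(
    networks: list[NetworkSpec],
    noise: NoiseSpec,
    nt: int = DEFAULT_NT,
    tr: float = DEFAULT_TR,
    seed: int = 0,
    brain_shape=DEFAULT_BRAIN_SHAPE,
    cord_shape=DEFAULT_CORD_SHAPE,
    loadings: np.ndarray | None = None,
) -> SubjectData:
    """Simulate one subject's paired brain/cord acquisition.

    Voxel signal is the loading-weighted sum of network maps times their
    band-limited time courses, plus slice-dependent cardiac/respiratory
    artifacts, AR(1) noise, linear drift and motion leakage. Deterministic
    given ``seed``.
    """
    if nt < 50:
        raise ValueError("need nt >= 50")
    rng = np.random.default_rng(seed)
    if loadings is None:
        loadings = np.ones(len(networks))
    loadings = np.asarray(loadings, dtype=float)

    duration = nt * tr
    physio = _simulate_physio(rng, duration)
    # motion: smooth random walks (3 translations, 3 rotations)
    steps = rng.normal(0, 1, size=(nt, 6)) * np.array([0.01, 0.01, 0.01, 2e-4, 2e-4, 2e-4])
    motion = np.cumsum(steps, axis=0)

    nyquist = 0.5 / tr
    tcs: list = []
    for net in networks:
        if net.band[0] >= nyquist:
            # fast artifact: keep the fine-grid course so each slice can
            # sample it at its own acquisition time
            tcs.append(band_limited_fine_course(rng, nt, tr, net.band, oversample=64))
        else:
            tcs.append(band_limited_timecourse(rng, nt, tr, net.band))
    bst, cst = default_slice_timings(brain_shape, cord_shape, tr)

    brain = _structure_signal(
        rng, brain_shape, bst, networks, loadings, tcs, noise, physio, motion, nt, tr, "brain"
    )
    cord = _structure_signal(
        rng, cord_shape, cst, networks, loadings, tcs, noise, physio, motion, nt, tr, "cord"
    )
    return SubjectData(
        brain=VolumeSeries(brain, BRAIN_VOXEL_MM, tr, "brain", "synthetic-brain"),
        cord=VolumeSeries(cord, CORD_VOXEL_MM, tr, "cord", "synthetic-cord"),
        physio=physio,
        motion=motion,
    )


def simulate_cohort(
    n_sub: int = DEFAULT_N_SUB,
    networks: list[NetworkSpec] | None = None,
    noise: NoiseSpec | None = None,
    nt: int = DEFAULT_NT,
    tr: float = DEFAULT_TR,
    seed: int = 0,
    brain_shape=DEFAULT_BRAIN_SHAPE,
    cord_shape=DEFAULT_CORD_SHAPE,
) -> CohortDataset:
    """Simulate a cohort with per-subject lognormal network loadings.

    Loadings are lognormal with mean 1 and sd 0.3 (every subject
    expresses every network, with realistic between-subject variation in
    strength) and are recorded in the ground truth. Per-subject seeds are
    derived deterministically from the master seed.
    """
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if networks is None:
        networks = default_network_suite(brain_shape, cord_shape)
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(seed)
    # lognormal with E=1, sd=0.3
    s2 = np.log(1 + 0.3**2)
    loadings = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=(n_sub, len(networks)))
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_sub)

    subjects = [
        simulate_subject(
            networks, noise, nt, tr, int(subject_seeds[i]), brain_shape, cord_shape, loadings[i]
        )
        for i in range(n_sub)
    ]
    bst, cst = default_slice_timings(brain_shape, cord_shape, tr)
    return CohortDataset(
        subjects=subjects,
        networks=networks,
        loadings=loadings,
        tr=tr,
        brain_slice_timing=bst,
        cord_slice_timing=cst,
    )


# ---------------------------------------------------------------------------
# ground-truth masks


def hemicord_masks(cord_shape=DEFAULT_CORD_SHAPE) -> dict[str, MaskVolume]:
    cx = cord_shape[0]
    idx = np.arange(cx)[:, None, None]
    left = np.broadcast_to(idx < cx // 2, cord_shape)
    return {
        "left_hemicord": MaskVolume(left.copy(), "left_hemicord", "left"),
        "right_hemicord": MaskVolume(~left, "right_hemicord", "right"),
    }


def horn_masks(cord_shape=DEFAULT_CORD_SHAPE) -> dict[str, MaskVolume]:
    cy = cord_shape[1]
    idx = np.arange(cy)[None, :, None]
    ventral = np.broadcast_to(idx < cy // 2, cord_shape)
    return {
        "ventral_horn": MaskVolume(ventral.copy(), "ventral_horn", "none"),
        "dorsal_horn": MaskVolume(~ventral, "dorsal_horn", "none"),
    }


def hemisphere_masks(brain_shape=DEFAULT_BRAIN_SHAPE) -> dict[str, MaskVolume]:
    bx = brain_shape[0]
    idx = np.arange(bx)[:, None, None]
    left = np.broadcast_to(idx < bx // 2, brain_shape)
    return {
        "left_hemisphere": MaskVolume(left.copy(), "left_hemisphere", "left"),
        "right_hemisphere": MaskVolume(~left, "right_hemisphere", "right"),
    }


def parcel_masks(brain_shape=DEFAULT_BRAIN_SHAPE) -> dict[str, MaskVolume]:
    """Nine disjoint synthetic parcels standing in for the key brain areas.

    A 3x3 in-plane partition of the grid, each parcel spanning all
    slices; purely geometric stand-ins, not anatomy.
    """
    bx, by, _ = brain_shape
    xs = np.linspace(0, bx, 4).astype(int)
    ys = np.linspace(0, by, 4).astype(int)
    masks: dict[str, MaskVolume] = {}
    for k, name in enumerate(PARCEL_NAMES):
        i, j = divmod(k, 3)
        m = np.zeros(brain_shape, dtype=bool)
        m[xs[i]: xs[i + 1], ys[j]: ys[j + 1], :] = True
        masks[name] = MaskVolume(m, name, "none")
    return masks


def nuisance_masks(brain_shape=DEFAULT_BRAIN_SHAPE) -> dict[str, MaskVolume]:
    """Synthetic stand-ins for white-matter and CSF reference regions.

    Two small corner boxes away from the planted network blobs; their
    mask means serve as the WM/CSF confound series.
    """
    bx, by, bz = brain_shape
    wm = np.zeros(brain_shape, dtype=bool)
    wm[: max(2, bx // 8), : max(2, by // 8), : max(2, bz // 4)] = True
    csf = np.zeros(brain_shape, dtype=bool)
    csf[-max(2, bx // 8):, : max(2, by // 8), : max(2, bz // 4)] = True
    return {
        "white_matter": MaskVolume(wm, "white_matter", "none"),
        "csf": MaskVolume(csf, "csf", "none"),
    }


def network_joint_maps(networks: list[NetworkSpec], brain_mask: np.ndarray, cord_mask: np.ndarray) -> np.ndarray:
    """Ground-truth maps flattened to joint (brain then cord) voxel order."""
    rows = []
    for net in networks:
        rows.append(np.concatenate([net.brain_map[brain_mask], net.cord_map[cord_mask]]))
    return np.asarray(rows)


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> None:
    """Write a cohort to disk: NIfTI pairs, physio text, motion TSVs, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sub in enumerate(cohort.subjects):
        stem = out / f"sub-{i + 1:02d}"
        write_volume_series(sub.brain, f"{stem}_brain.nii")
        write_volume_series(sub.cord, f"{stem}_cord.nii")
        write_physio_trace(sub.physio, f"{stem}_cardiac.txt", f"{stem}_resp.tsv")
        pd.DataFrame(
            sub.motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
        ).to_csv(f"{stem}_motion.tsv", sep="\t", index=False)
    pd.DataFrame(
        cohort.loadings, columns=[n.name for n in cohort.networks]
    ).to_csv(out / "truth_loadings.tsv", sep="\t", index=False)
    shapes = cohort.subjects[0]
    masks = {}
    masks.update(hemicord_masks(shapes.cord.shape))
    masks.update(horn_masks(shapes.cord.shape))
    masks.update(hemisphere_masks(shapes.brain.shape))
    masks.update(nuisance_masks(shapes.brain.shape))
    masks.update(parcel_masks(shapes.brain.shape))
    manifest = []
    for name, m in masks.items():
        vox = shapes.cord.voxel_size if m.data.shape == shapes.cord.shape else shapes.brain.voxel_size
        write_mask(m, out / f"mask_{name}.nii", vox)
        manifest.append({"label": name, "side": m.side, "n_voxels": m.n_voxels})
    pd.DataFrame(manifest).to_csv(out / "truth_masks.tsv", sep="\t", index=False)
    np.savetxt(out / "slice_offsets_brain.txt", cohort.brain_slice_timing.offsets, fmt="%.6f")
    np.savetxt(out / "slice_offsets_cord.txt", cohort.cord_slice_timing.offsets, fmt="%.6f")
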