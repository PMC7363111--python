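"""Joint brain + spinal cord group spatial ICA.

Each subject's two preprocessed series are flattened to ``n_T x n_B``
(brain) and ``n_T x n_S`` (cord) matrices and concatenated column-wise
into one ``n_T x (n_B + n_S)`` joint matrix, so a single decomposition
can express networks spanning both structures. Because the cord block
has far fewer voxels and lower SNR than the brain block, each block is
variance-normalised before concatenation (unit mean voxel variance per
block by default) so neither structure dominates the decomposition.

Per subject, temporal PCA reduces the joint matrix to ``k`` rows; the
reduced matrices are stacked row-wise (time concatenation) into a
``(k * n_sub) x (n_B + n_S)`` matrix, and FastICA extracts spatially
independent component maps, z-scored over voxels. Subject-specific
component time courses come from stage-1 dual regression (each subject's
full joint matrix regressed on the group maps). Components are kept when
their subject-averaged Welch spectrum has at least ``ratio_min`` (4x)
greater mean power inside the 0.01-0.1 Hz resting-state band than
outside it; a kept component whose corrected cord activation volume
falls below 0.15 cm^3 is flagged as having no meaningful cord
involvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .clusters import SmoothnessEstimate, estimate_smoothness, grf_cluster_correct
from .io_core import MaskVolume, VolumeSeries


@dataclass
class JointMatrix:
    """One subject's concatenated brain+cord data, with split bookkeeping.

    ``values`` is ``n_T x (n_B + n_S)`` with brain columns first.
    ``col_mean`` and block scales are stored so the two source blocks can
    be reconstructed exactly.
    """

    values: np.ndarray
    split_index: int
    brain_coords: tuple[np.ndarray, ...]
    cord_coords: tuple[np.ndarray, ...]
    brain_shape: tuple[int, int, int]
    cord_shape: tuple[int, int, int]
    brain_voxel_size: tuple[float, float, float]
    cord_voxel_size: tuple[float, float, float]
    tr: float
    col_mean: np.ndarray
    brain_scale: float
    cord_scale: float

    @property
    def n_t(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class ReducedSubject:
    """Temporal-PCA-reduced subject data: ``k x (n_B + n_S)``."""

    values: np.ndarray
    basis: np.ndarray  # (n_T, k) left singular vectors
    variance_retained: float

    @property
    def k(self) -> int:
        return self.values.shape[0]


@dataclass
class GroupDecomposition:
    """Joint ICA output: z-scored maps, mixing, time courses, selection."""

    maps: np.ndarray  # (n_components, n_B + n_S), z-scored over voxels
    mixing: np.ndarray  # (stacked rows, n_components)
    split_index: int
    brain_coords: tuple[np.ndarray, ...]
    cord_coords: tuple[np.ndarray, ...]
    brain_shape: tuple[int, int, int]
    cord_shape: tuple[int, int, int]
    cord_voxel_size: tuple[float, float, float]
    brain_voxel_size: tuple[float, float, float]
    timecourses: np.ndarray | None = None  # (n_sub, n_T, n_components)
    band_power_ratios: np.ndarray | None = None
    selected: np.ndarray | None = None
    cord_volumes_cm3: np.ndarray | None = None
    small_cord_flags: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def brain_part(self, component: int) -> np.ndarray:
        vol = np.zeros(self.brain_shape)
        vol[self.brain_coords] = self.maps[component, : self.split_index]
        return vol

    def cord_part(self, component: int) -> np.ndarray:
        vol = np.zeros(self.cord_shape)
        vol[self.cord_coords] = self.maps[component, self.split_index:]
        return vol


def build_joint_matrix(
    brain: VolumeSeries,
    cord: VolumeSeries,
    brain_mask: MaskVolume | np.ndarray,
    cord_mask: MaskVolume | np.ndarray,
    normalize: str = "per-block",
) -> JointMatrix:
    """Column-wise concatenation of masked brain and cord voxels.

    Voxels are flattened in C index order within each mask; columns are
    mean-centred over time, and with ``normalize="per-block"`` each block
    is divided by the root of its mean voxel variance. The stored means
    and scales make :func:`split_joint_matrix` an exact inverse.
    """
    bm = brain_mask.data if isinstance(brain_mask, MaskVolume) else np.asarray(brain_mask, bool)
    cm = cord_mask.data if isinstance(cord_mask, MaskVolume) else np.asarray(cord_mask, bool)
    if bm.shape != brain.shape or cm.shape != cord.shape:
        raise ValueError("mask shapes do not match their series")
    if not bm.any() or not cm.any():
        raise ValueError("masks must be nonempty")
    if brain.nt != cord.nt:
        raise ValueError(f"time length mismatch: brain {brain.nt} vs cord {cord.nt}")
    if normalize not in ("per-block", "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")

    brain_coords = np.nonzero(bm)
    cord_coords = np.nonzero(cm)
    B = brain.data[brain_coords].T  # (n_T, n_B)
    S = cord.data[cord_coords].T  # (n_T, n_S)
    X = np.concatenate([B, S], axis=1)
    col_mean = X.mean(axis=0)
    X = X - col_mean

    n_b = B.shape[1]
    if normalize == "per-block":
        brain_scale = float(np.sqrt(np.mean(X[:, :n_b].var(axis=0))))
        cord_scale = float(np.sqrt(np.mean(X[:, n_b:].var(axis=0))))
        brain_scale = brain_scale if brain_scale > 0 else 1.0
        cord_scale = cord_scale if cord_scale > 0 else 1.0
        X[:, :n_b] /= brain_scale
        X[:, n_b:] /= cord_scale
    else:
        brain_scale = cord_scale = 1.0

    return JointMatrix(
        values=X,
        split_index=n_b,
        brain_coords=brain_coords,
        cord_coords=cord_coords,
        brain_shape=brain.shape,
        cord_shape=cord.shape,
        brain_voxel_size=brain.voxel_size,
        cord_voxel_size=cord.voxel_size,
        tr=brain.tr,
        col_mean=col_mean,
        brain_scale=brain_scale,
        cord_scale=cord_scale,
    )


def split_joint_matrix(joint: JointMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Undo normalisation and centring; return the two ``(n_T, n)`` blocks."""
    X = joint.values.copy()
    n_b = joint.split_index
    X[:, :n_b] *= joint.brain_scale
    X[:, n_b:] *= joint.cord_scale
    X += joint.col_mean
    return X[:, :n_b], X[:, n_b:]


def reduce_subject(joint: JointMatrix, k: int) -> ReducedSubject:
    """Temporal PCA reduction of one subject to ``k`` components.

    Keeps the top-``k`` right singular directions scaled by their
    singular values (``diag(s_k) @ V_k^T``), i.e. the best rank-``k``
    temporal compression of the joint matrix. ``k`` above the matrix
    rank is clipped with a warning; a retained-variance fraction below
    the 90% target also warns.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > joint.n_t:
        raise ValueError(f"k={k} exceeds the number of time points {joint.n_t}")
    X = joint.values - joint.values.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("all-zero subject data cannot be reduced")
    rank = int(np.sum(s > s[0] * 1e-10))
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(f"requested k={k} exceeds data rank {rank}; clipped", RuntimeWarning)
    variance_retained = float(np.sum(s[:k_eff] ** 2) / total)
    return ReducedSubject(
        values=s[:k_eff, None] * Vt[:k_eff],
        basis=U[:, :k_eff],
        variance_retained=variance_retained,
    )


def _negentropy_proxy(sources: np.ndarray) -> float:
    """Sum of squared logcosh-negentropy contrasts over unit-variance sources."""
    gauss = 0.3745672075384283  # E[log cosh g], g ~ N(0,1)
    s = sources / sources.std(axis=0, keepdims=True)
    return float(np.sum((np.mean(np.log(np.cosh(s)), axis=0) - gauss) ** 2))


def group_decompose(
    reduced: list[ReducedSubject],
    template: JointMatrix,
    n_components: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    pca_var_target: float = 0.90,
) -> GroupDecomposition:
    """Time-concatenated group spatial ICA.

    Subjects' reduced matrices are stacked row-wise into
    ``(sum k_i) x (n_B + n_S)`` and FastICA (logcosh contrast, symmetric
    decorrelation) is run on its transpose so the extracted sources are
    spatial maps. The best of ``n_restarts`` runs by the negentropy
    objective is kept; maps are z-scored over voxels. Deterministic for a
    given seed.
    """
    for r in reduced:
        if r.variance_retained < pca_var_target:
            warnings.warn(
                f"subject retains only {r.variance_retained:.2f} of variance "
                f"(target {pca_var_target})",
                RuntimeWarning,
            )
    X = np.vstack([r.values for r in reduced])  # (sum k, v)
    if n_components > X.shape[0]:
        raise ValueError(
            f"n_components={n_components} exceeds stacked row count {X.shape[0]}"
        )
    best = None
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    last_err: Exception | None = None
    for rs in restart_seeds:
        ica = FastICA(
            n_components=n_components,
            fun="logcosh",
            algorithm="parallel",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=int(rs),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(X.T)  # (v, n_components)
            except ConvergenceWarning as err:  # pragma: no cover - data dependent
                last_err = err
                continue
        score = _negentropy_proxy(sources)
        if best is None or score > best[0]:
            best = (score, sources, ica.mixing_)
    if best is None:
        raise RuntimeError(
            f"FastICA failed to converge in {n_restarts} restarts "
            f"(max_iter={max_iter}, tol={tol}): {last_err}"
        )
    _, sources, mixing = best
    maps = sources.T  # (n_components, v)
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    # ICA polarity is arbitrary: orient each map so its voxel distribution
    # is positively skewed (activations, not deactivations, carry the tail)
    skew = np.mean(maps**3, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps *= flip[:, None]
    mixing = mixing * flip[None, :]
    return GroupDecomposition(
        maps=maps,
        mixing=mixing,
        split_index=template.split_index,
        brain_coords=template.brain_coords,
        cord_coords=template.cord_coords,
        brain_shape=template.brain_shape,
        cord_shape=template.cord_shape,
        cord_voxel_size=template.cord_voxel_size,
        brain_voxel_size=template.brain_voxel_size,
    )


def subject_timecourses(
    decomposition: GroupDecomposition, joints: list[JointMatrix]
) -> np.ndarray:
    """Stage-1 dual regression: per-subject component time courses.

    Each subject's full joint matrix is regressed on the group spatial
    maps; returns ``(n_sub, n_T, n_components)``.
    """
    S = decomposition.maps  # (c, v)
    gram = S @ S.T
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError("group spatial maps are rank deficient")
    solve = np.linalg.solve(gram, S)  # (c, v) -> pseudo-inverse rows
    out = []
    for joint in joints:
        if joint.n_voxels != S.shape[1]:
            raise ValueError("subject voxel space does not match decomposition")
        Y = joint.values - joint.values.mean(axis=0)
        out.append(Y @ solve.T)
    return np.asarray(out)


def band_power_ratio(
    timecourses: np.ndarray,
    tr: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """In-band vs out-of-band mean Welch power, averaged over subjects.

    Welch estimate with a Hann window, 50% overlap and segment length
    ``min(64, n_T // 2)``; DC is excluded, band edges are inclusive.
    Returns one ratio per component.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim == 2:
        tc = tc[None]
    n_sub, n_t, n_comp = tc.shape
    nperseg = int(min(64, n_t // 2))
    if nperseg < 8:
        raise ValueError("time courses too short for Welch estimation")
    fs = 1.0 / tr
    freqs, psd = signal.welch(
        tc, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=1
    )
    psd_mean = psd.mean(axis=0)  # (n_freq, n_comp)
    nonzero = freqs > 0
    in_band = nonzero & (freqs >= band[0]) & (freqs <= band[1])
    out_band = nonzero & ~in_band
    if not in_band.any() or not out_band.any():
        raise ValueError(f"band {band} leaves no in/out frequencies at fs={fs}")
    p_in = psd_mean[in_band].mean(axis=0)
    p_out = psd_mean[out_band].mean(axis=0)
    degenerate = (p_in + p_out) <= 0
    if degenerate.any():
        raise ValueError("degenerate all-zero component time course")
    return p_in / np.maximum(p_out, 1e-300)


def select_components(
    timecourses: np.ndarray,
    tr: float,
    band: tuple[float, float] = (0.01, 0.1),
    ratio_min: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag components whose band-power ratio reaches ``ratio_min``."""
    ratios = band_power_ratio(timecourses, tr, band)
    return ratios >= ratio_min, ratios


def cord_component_volume(
    decomposition: GroupDecomposition,
    component: int,
    z_thresh: float = 3.1,
    p_thresh: float = 0.05,
    small_volume_cm3: float = 0.15,
    smoothness: SmoothnessEstimate | None = None,
) -> tuple[float, bool]:
    """GRF-corrected cord activation volume of one component map.

    The component's cord part is thresholded at ``z_thresh`` and
    cluster-corrected over the cord mask; the surviving volume in cm^3 is
    returned together with a flag marking it as below the
    ``small_volume_cm3`` bound (a component with no meaningful cord
    involvement). If no smoothness estimate is supplied, one is taken
    from the stack of all component cord maps.
    """
    cord_mask = np.zeros(decomposition.cord_shape, dtype=bool)
    cord_mask[decomposition.cord_coords] = True
    if smoothness is None:
        if decomposition.n_components >= 10:
            stack = np.stack(
                [decomposition.cord_part(c) for c in range(decomposition.n_components)],
                axis=-1,
            )
            smoothness = estimate_smoothness(stack, cord_mask)
        else:
            # too few maps to estimate smoothness: assume an unsmoothed
            # field (one-voxel FWHM), the conservative choice
            smoothness = SmoothnessEstimate(np.ones(3), float(cord_mask.sum()))
    table, _ = grf_cluster_correct(
        decomposition.cord_part(component),
        cord_mask,
        z_thresh,
        smoothness,
        p_thresh,
        voxel_size=decomposition.cord_voxel_size,
    )
    volume = float(table["volume_cm3"].sum()) if len(table) else 0.0
    return volume, volume < small_volume_cm3


def match_components(maps: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy match of decomposition maps to reference maps.

    Returns (component index, signed correlation, sign) per reference
    row, matching by maximal absolute Pearson correlation without
    replacement.
    """
    M = np.asarray(maps, dtype=float)
    Rf = np.asarray(reference, dtype=float)
    Mz = (M - M.mean(axis=1, keepdims=True))
    Mz /= np.maximum(np.linalg.norm(Mz, axis=1, keepdims=True), 1e-300)
    Rz = (Rf - Rf.mean(axis=1, keepdims=True))
    Rz /= np.maximum(np.linalg.norm(Rz, axis=1, keepdims=True), 1e-300)
    corr = Rz @ Mz.T  # (n_ref, n_comp)
    n_ref = Rf.shape[0]
    assigned = np.full(n_ref, -1)
    corrs = np.zeros(n_ref)
    signs = np.ones(n_ref)
    cm = np.abs(corr).copy()
    for _ in range(min(n_ref, M.shape[0])):
        i, j = np.unravel_index(int(np.argmax(cm)), cm.shape)
        assigned[i] = j
        corrs[i] = corr[i, j]
        signs[i] = np.sign(corr[i, j]) or 1.0
        cm[i, :] = -1
        cm[:, j] = -1
    return assigned, corrs, signs
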