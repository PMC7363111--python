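"""End-to-end orchestration of the analysis stages.

These helpers run the full study workflow on an in-memory cohort:
pre-equilibrium volume removal, 0.01 Hz high-pass, slice-wise
physiological regressor construction, per-subject seed GLMs, group
inference with GRF cluster correction, laterality accounting, and the
joint ICA with spectral selection. The CLI and the test-suite both drive
the pipeline through these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm, jica, laterality, physio, synthetic
from .clusters import SmoothnessEstimate, estimate_smoothness, grf_cluster_correct
from .io_core import AnalysisConfig, MaskVolume, VolumeSeries, drop_initial_volumes
from .synthetic import CohortDataset, SubjectData


@dataclass
class PreparedSubject:
    """One subject after volume removal and temporal filtering."""

    brain: VolumeSeries
    cord: VolumeSeries
    pnm_brain: physio.PnmRegressors
    motion: np.ndarray
    wm_ts: np.ndarray
    csf_ts: np.ndarray
    volume_times: np.ndarray


@dataclass
class SeedAnalysisResult:
    """Per-subject and group output of one seed's connectivity analysis."""

    seed_label: str
    subject_z: np.ndarray  # (n_sub, nx, ny, nz)
    subject_beta: np.ndarray  # (n_sub, nx, ny, nz)
    group_z: np.ndarray  # (nx, ny, nz)
    smoothness: SmoothnessEstimate
    cluster_table: pd.DataFrame
    thresholded_group_z: np.ndarray


def prepare_subject(
    subject: SubjectData,
    cfg: AnalysisConfig,
    brain_slice_timing: physio.SliceTiming,
    nuisance: dict[str, MaskVolume] | None = None,
) -> PreparedSubject:
    """Drop initial volumes, high-pass filter, and build PNM regressors.

    Volume times are kept on the acquisition clock (the removed initial
    volumes still advance time), so physiological phases stay aligned
    with the recorded trace.
    """
    brain = drop_initial_volumes(subject.brain, cfg.drop_volumes)
    cord = drop_initial_volumes(subject.cord, cfg.drop_volumes)
    brain = glm.highpass_filter(brain, cfg.highpass_hz)
    cord = glm.highpass_filter(cord, cfg.highpass_hz)
    motion = subject.motion[cfg.drop_volumes:]
    volume_times = (np.arange(brain.nt) + cfg.drop_volumes) * brain.tr
    pnm_brain = physio.build_pnm_regressors(
        subject.physio,
        brain_slice_timing,
        volume_times,
        cfg.n_cardiac,
        cfg.n_resp,
        cfg.n_interact,
    )
    if nuisance is None:
        nuisance = synthetic.nuisance_masks(brain.shape)
    wm_ts = glm.extract_roi_timeseries(brain, nuisance["white_matter"])
    csf_ts = glm.extract_roi_timeseries(brain, nuisance["csf"])
    return PreparedSubject(
        brain=brain,
        cord=cord,
        pnm_brain=pnm_brain,
        motion=motion,
        wm_ts=wm_ts,
        csf_ts=csf_ts,
        volume_times=volume_times,
    )


def fit_subject_seed(
    prepared: PreparedSubject,
    seed_mask: MaskVolume,
    exclusive_with: MaskVolume | None = None,
    ar1: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice-wise seed GLM over the brain for one subject.

    Returns (z volume, beta volume, residual 4D) for the first seed's
    map. The design is assembled per slice because the physiological
    regressors are slice-specific.
    """
    brain = prepared.brain
    seed_ts = glm.extract_roi_timeseries(prepared.cord, seed_mask)
    seeds = [seed_ts]
    if exclusive_with is not None:
        other = glm.extract_roi_timeseries(prepared.cord, exclusive_with)
        a = seed_ts - seed_ts.mean()
        b = other - other.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom == 0 or abs(float(a @ b) / denom) > 0.999:
            raise ValueError("seed time series are collinear; exclusive model undefined")
        seeds.append(other)

    nx, ny, nz, nt = brain.data.shape
    zvol = np.zeros((nx, ny, nz))
    bvol = np.zeros((nx, ny, nz))
    resid = np.zeros((nx, ny, nz, nt))
    for s in range(nz):
        design = glm.build_design(
            seeds,
            prepared.pnm_brain.slice_matrix(s),
            prepared.motion,
            prepared.wm_ts,
            prepared.csf_ts,
            tr=brain.tr,
        )
        Y = brain.data[:, :, s, :].reshape(-1, nt).T
        fit = glm.fit_glm(Y, design, ar1=ar1)
        zvol[:, :, s] = fit.zmap[:, 0].reshape(nx, ny)
        bvol[:, :, s] = fit.beta[:, 0].reshape(nx, ny)
        resid[:, :, s, :] = fit.residuals.T.reshape(nx, ny, nt)
    return zvol, bvol, resid


def run_seed_analysis(
    cohort: CohortDataset,
    seed_mask: MaskVolume,
    cfg: AnalysisConfig,
    exclusive_with: MaskVolume | None = None,
    brain_mask: np.ndarray | None = None,
    ar1: bool = True,
) -> SeedAnalysisResult:
    """Subject GLMs, group one-sample test and GRF cluster correction."""
    subject_z, subject_beta = [], []
    resid_last = None
    nuisance = synthetic.nuisance_masks(cohort.subjects[0].brain.shape)
    for subject in cohort.subjects:
        prepared = prepare_subject(subject, cfg, cohort.brain_slice_timing, nuisance)
        zvol, bvol, resid_last = fit_subject_seed(prepared, seed_mask, exclusive_with, ar1)
        subject_z.append(zvol)
        subject_beta.append(bvol)
    subject_z = np.asarray(subject_z)
    subject_beta = np.asarray(subject_beta)

    shape = subject_beta.shape[1:]
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    group = glm.group_onesample(subject_beta.reshape(cohort.n_sub, -1))
    group_z = group.zmap.reshape(shape)
    smoothness = estimate_smoothness(resid_last, brain_mask)
    table, thresh = grf_cluster_correct(
        group_z,
        brain_mask,
        cfg.cluster_z_seed,
        smoothness,
        cfg.cluster_p,
        voxel_size=cohort.subjects[0].brain.voxel_size,
    )
    return SeedAnalysisResult(
        seed_label=seed_mask.label,
        subject_z=subject_z,
        subject_beta=subject_beta,
        group_z=group_z,
        smoothness=smoothness,
        cluster_table=table,
        thresholded_group_z=thresh,
    )


def run_laterality(
    cohort: CohortDataset,
    cfg: AnalysisConfig,
    ar1: bool = True,
    left_result: SeedAnalysisResult | None = None,
    right_result: SeedAnalysisResult | None = None,
) -> tuple[list[laterality.LateralityRecord], dict[str, laterality.PairedTestResult]]:
    """Hemicord-seed laterality analysis over a cohort.

    Runs both hemicord seeds (unless precomputed results are passed),
    counts per-subject hemisphere activation volumes at the subject
    threshold, and returns the records with the group tests: one-sample
    tests of each seed's laterality index, paired left-vs-right volume
    tests, and the cord-side x brain-side interaction.
    """
    cord_shape = cohort.subjects[0].cord.shape
    brain_shape = cohort.subjects[0].brain.shape
    hemicords = synthetic.hemicord_masks(cord_shape)
    hemis = synthetic.hemisphere_masks(brain_shape)
    voxel_size = cohort.subjects[0].brain.voxel_size

    if left_result is None:
        left_result = run_seed_analysis(cohort, hemicords["left_hemicord"], cfg, ar1=ar1)
    if right_result is None:
        right_result = run_seed_analysis(cohort, hemicords["right_hemicord"], cfg, ar1=ar1)

    records: list[laterality.LateralityRecord] = []
    for i in range(cohort.n_sub):
        for side, result in (("left", left_result), ("right", right_result)):
            lv = laterality.activation_volume(
                result.subject_z[i], hemis["left_hemisphere"], cfg.subject_p, voxel_size
            )
            rv = laterality.activation_volume(
                result.subject_z[i], hemis["right_hemisphere"], cfg.subject_p, voxel_size
            )
            if lv + rv == 0:
                continue  # index undefined; record dropped
            records.append(
                laterality.LateralityRecord(
                    subject=f"sub-{i + 1:02d}",
                    seed=side,
                    left_volume_cm3=lv,
                    right_volume_cm3=rv,
                    index=laterality.laterality_index(lv, rv),
                )
            )
    tests: dict[str, laterality.PairedTestResult] = {}
    for side in ("left", "right"):
        idx = [r.index for r in records if r.seed == side]
        lvols = [r.left_volume_cm3 for r in records if r.seed == side]
        rvols = [r.right_volume_cm3 for r in records if r.seed == side]
        if len(idx) >= 3:
            tests[f"{side}_seed_index_vs_zero"] = laterality.one_sample_test(np.asarray(idx))
            tests[f"{side}_seed_left_vs_right_volume"] = laterality.paired_ttest(
                np.asarray(lvols), np.asarray(rvols)
            )
    try:
        tests["side_by_hemisphere_interaction"] = laterality.side_by_hemisphere_interaction(records)
    except ValueError:
        pass  # some subject lacks a defined index for one seed
    return records, tests


@dataclass
class JointIcaRun:
    decomposition: jica.GroupDecomposition
    joints: list[jica.JointMatrix]
    reduced: list[jica.ReducedSubject]


def run_joint_ica(
    cohort: CohortDataset,
    cfg: AnalysisConfig,
    brain_mask: np.ndarray | None = None,
    cord_mask: np.ndarray | None = None,
) -> JointIcaRun:
    """Joint brain+cord group ICA with selection and cord-volume flags."""
    first = cohort.subjects[0]
    if brain_mask is None:
        brain_mask = np.ones(first.brain.shape, dtype=bool)
    if cord_mask is None:
        cord_mask = np.ones(first.cord.shape, dtype=bool)

    joints, reduced = [], []
    for subject in cohort.subjects:
        brain = glm.highpass_filter(
            drop_initial_volumes(subject.brain, cfg.drop_volumes), cfg.highpass_hz
        )
        cord = glm.highpass_filter(
            drop_initial_volumes(subject.cord, cfg.drop_volumes), cfg.highpass_hz
        )
        joint = jica.build_joint_matrix(brain, cord, brain_mask, cord_mask)
        joints.append(joint)
        reduced.append(jica.reduce_subject(joint, cfg.n_pca))

    decomp = jica.group_decompose(
        reduced,
        joints[0],
        n_components=cfg.n_ica,
        seed=cfg.rng_seed,
        pca_var_target=cfg.pca_var_target,
    )
    decomp.timecourses = jica.subject_timecourses(decomp, joints)
    decomp.selected, decomp.band_power_ratios = jica.select_components(
        decomp.timecourses, cohort.tr, (cfg.band_lo, cfg.band_hi), cfg.power_ratio_min
    )
    volumes, flags = [], []
    for c in range(decomp.n_components):
        v, small = jica.cord_component_volume(
            decomp,
            c,
            z_thresh=cfg.cluster_z_ica,
            p_thresh=cfg.cluster_p,
            small_volume_cm3=cfg.small_cord_volume_cm3,
        )
        volumes.append(v)
        flags.append(small)
    decomp.cord_volumes_cm3 = np.asarray(volumes)
    decomp.small_cord_flags = np.asarray(flags)
    return JointIcaRun(decomposition=decomp, joints=joints, reduced=reduced)


def component_summary(decomp: jica.GroupDecomposition) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component": np.arange(decomp.n_components),
            "band_power_ratio": decomp.band_power_ratios,
            "selected": decomp.selected,
            "cord_volume_cm3": decomp.cord_volumes_cm3,
            "small_cord_cluster": decomp.small_cord_flags,
        }
    )
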