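"""Joint matrix construction, PCA reduction, group ICA, and selection."""

import warnings

import numpy as np
import pytest
from scipy import signal

from neuraxis import jica, synthetic
from neuraxis.io_core import VolumeSeries

TR = 3.05


def _pair(nt=60, brain_shape=(5, 4, 3), cord_shape=(3, 3, 4), seed=0):
    rng = np.random.default_rng(seed)
    brain = VolumeSeries(rng.standard_normal(brain_shape + (nt,)), (2, 2, 2), TR, "brain")
    cord = VolumeSeries(rng.standard_normal(cord_shape + (nt,)), (1.2, 1.2, 5), TR, "cord")
    return brain, cord


class TestJointMatrix:
    def test_shape_law_and_split_index(self):
        brain, cord = _pair()
        bm = np.zeros(brain.shape, bool)
        bm.ravel()[:50] = True
        cm = np.zeros(cord.shape, bool)
        cm.ravel()[:20] = True
        joint = jica.build_joint_matrix(brain, cord, bm, cm)
        assert joint.values.shape == (60, 70)
        assert joint.split_index == 50

    def test_round_trip_is_lossless(self):
        brain, cord = _pair()
        bm = np.ones(brain.shape, bool)
        cm = np.ones(cord.shape, bool)
        joint = jica.build_joint_matrix(brain, cord, bm, cm)
        B, S = jica.split_joint_matrix(joint)
        assert np.allclose(B, brain.timeseries(), atol=1e-10)
        assert np.allclose(S, cord.timeseries(), atol=1e-10)

    def test_brain_columns_never_read_cord_data(self):
        brain, cord = _pair()
        bm, cm = np.ones(brain.shape, bool), np.ones(cord.shape, bool)
        joint1 = jica.build_joint_matrix(brain, cord, bm, cm)
        other_cord = VolumeSeries(cord.data * 5 + 1, cord.voxel_size, TR, "cord")
        joint2 = jica.build_joint_matrix(brain, other_cord, bm, cm)
        n_b = joint1.split_index
        assert np.array_equal(joint1.values[:, :n_b], joint2.values[:, :n_b])

    def test_per_block_normalisation(self):
        brain, cord = _pair()
        joint = jica.build_joint_matrix(
            brain, cord, np.ones(brain.shape, bool), np.ones(cord.shape, bool)
        )
        n_b = joint.split_index
        assert np.mean(joint.values[:, :n_b].var(axis=0)) == pytest.approx(1.0)
        assert np.mean(joint.values[:, n_b:].var(axis=0)) == pytest.approx(1.0)

    def test_time_mismatch_rejected(self):
        brain, _ = _pair(nt=60)
        _, cord = _pair(nt=50, seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            jica.build_joint_matrix(
                brain, cord, np.ones(brain.shape, bool), np.ones(cord.shape, bool)
            )


class TestReduceSubject:
    def _joint(self, values):
        nt, nv = values.shape
        return jica.JointMatrix(
            values=values, split_index=nv - 2,
            brain_coords=(np.zeros(nv - 2, int),) * 3, cord_coords=(np.zeros(2, int),) * 3,
            brain_shape=(1, 1, 1), cord_shape=(1, 1, 1),
            brain_voxel_size=(2, 2, 2), cord_voxel_size=(1.2, 1.2, 5),
            tr=TR, col_mean=np.zeros(nv), brain_scale=1.0, cord_scale=1.0,
        )

    def test_low_rank_input_clips_k_with_full_variance(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((50, 3)) @ rng.standard_normal((3, 40))
        with pytest.warns(RuntimeWarning, match="rank"):
            red = jica.reduce_subject(self._joint(vals), 40)
        assert red.k == 3
        assert red.variance_retained == pytest.approx(1.0)

    def test_full_k_retains_everything(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((20, 30))
        red = jica.reduce_subject(self._joint(vals), 20)
        assert red.variance_retained == pytest.approx(1.0)

    def test_variance_matches_eigenvalue_bookkeeping(self):
        """Retained fraction equals the cumulative-eigenvalue oracle to 1e-10."""
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((40, 60)) * np.linspace(3, 0.1, 60)
        joint = self._joint(vals)
        k = 10
        red = jica.reduce_subject(joint, k)
        X = vals - vals.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(X @ X.T))[::-1]
        oracle = eig[:k].sum() / eig.sum()
        assert red.variance_retained == pytest.approx(oracle, abs=1e-10)

    def test_k_beyond_time_points_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            jica.reduce_subject(self._joint(rng.standard_normal((10, 20))), 11)


def _planted_cohort(n_sub=6, nt=80, nv=400, split=350, noise=0.02, seed=0, scale=1.0):
    """Exact-model subjects: two well-separated spatial sources."""
    rng = np.random.default_rng(seed)
    maps = np.zeros((2, nv))
    maps[0, 40:90] = rng.uniform(0.5, 1.0, 50)
    maps[1, 200:260] = rng.uniform(0.5, 1.0, 60)
    joints, truth = [], maps
    for _ in range(n_sub):
        tcs = np.stack([synthetic.band_limited_timecourse(rng, nt, TR, (0.01, 0.1))
                        for _ in range(2)], axis=1)
        vals = (tcs @ maps + noise * rng.standard_normal((nt, nv))) * scale
        joints.append(
            jica.JointMatrix(
                values=vals - vals.mean(axis=0), split_index=split,
                brain_coords=tuple(np.arange(split) for _ in range(1)) * 3,
                cord_coords=tuple(np.arange(nv - split) for _ in range(1)) * 3,
                brain_shape=(split, 1, 1), cord_shape=(nv - split, 1, 1),
                brain_voxel_size=(2, 2, 2), cord_voxel_size=(1.2, 1.2, 5),
                tr=TR, col_mean=np.zeros(nv), brain_scale=1.0, cord_scale=1.0,
            )
        )
    return joints, truth


class TestGroupDecompose:
    def _decompose(self, joints, n_components=4, seed=9):
        reduced = [jica.reduce_subject(j, 10) for j in joints]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return jica.group_decompose(reduced, joints[0], n_components, seed=seed)

    def test_planted_sources_recovered_above_95(self):
        joints, truth = _planted_cohort()
        decomp = self._decompose(joints)
        _, corrs, _ = jica.match_components(decomp.maps, truth)
        assert np.all(np.abs(corrs) > 0.95)

    def test_same_seed_identical_decomposition(self):
        joints, _ = _planted_cohort()
        d1 = self._decompose(joints, seed=9)
        d2 = self._decompose(joints, seed=9)
        assert np.array_equal(d1.maps, d2.maps)

    def test_global_scaling_invariance(self):
        joints1, truth = _planted_cohort(scale=1.0)
        joints10, _ = _planted_cohort(scale=10.0)
        d1 = self._decompose(joints1)
        d10 = self._decompose(joints10)
        a1, c1, _ = jica.match_components(d1.maps, truth)
        a10, c10, _ = jica.match_components(d10.maps, truth)
        # same sources recovered, up to order and sign
        assert np.all(np.abs(c1) > 0.95) and np.all(np.abs(c10) > 0.95)

    def test_stacked_shape_law(self):
        joints, _ = _planted_cohort(n_sub=4)
        reduced = [jica.reduce_subject(j, 10) for j in joints]
        assert sum(r.k for r in reduced) == 10 * 4

    def test_too_many_components_rejected(self):
        joints, _ = _planted_cohort(n_sub=2)
        reduced = [jica.reduce_subject(j, 5) for j in joints]
        with pytest.raises(ValueError, match="exceeds"):
            jica.group_decompose(reduced, joints[0], 11)

    def test_maps_are_z_scored(self):
        joints, _ = _planted_cohort()
        decomp = self._decompose(joints)
        assert np.allclose(decomp.maps.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(decomp.maps.std(axis=1), 1, atol=1e-9)


class TestSubjectTimecourses:
    def test_exact_model_recovery(self):
        """One active component: recovered time course matches the planted one."""
        rng = np.random.default_rng(0)
        nv, nt = 300, 80
        maps = np.zeros((3, nv))
        maps[0, :60] = 1.0
        maps[1, 100:160] = 1.0
        maps[2, 200:260] = 1.0
        maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        tc = rng.standard_normal(nt)
        joints, _ = _planted_cohort(n_sub=1, nv=nv, nt=nt)
        joint = joints[0]
        joint.values = np.outer(tc, maps[0])
        decomp = jica.GroupDecomposition(
            maps=maps, mixing=np.eye(3), split_index=250,
            brain_coords=joint.brain_coords, cord_coords=joint.cord_coords,
            brain_shape=joint.brain_shape, cord_shape=joint.cord_shape,
            cord_voxel_size=joint.cord_voxel_size, brain_voxel_size=joint.brain_voxel_size,
        )
        tcs = jica.subject_timecourses(decomp, [joint])
        got = tcs[0][:, 0]
        corr = np.corrcoef(got, tc)[0, 1]
        assert corr > 0.999
        assert np.allclose(tcs[0][:, 1:], 0, atol=1e-8)

    def test_all_zero_subject_gives_zero_timecourses(self):
        joints, _ = _planted_cohort(n_sub=1)
        joint = joints[0]
        joint.values = np.zeros_like(joint.values)
        maps = np.random.default_rng(1).standard_normal((3, joint.n_voxels))
        decomp = jica.GroupDecomposition(
            maps=maps, mixing=np.eye(3), split_index=joint.split_index,
            brain_coords=joint.brain_coords, cord_coords=joint.cord_coords,
            brain_shape=joint.brain_shape, cord_shape=joint.cord_shape,
            cord_voxel_size=joint.cord_voxel_size, brain_voxel_size=joint.brain_voxel_size,
        )
        assert np.allclose(jica.subject_timecourses(decomp, [joint]), 0)


class TestSelection:
    """The 4x band-power rule on time courses with a resolvable spectrum."""

    TR_FAST = 1.0  # 0.5 Hz Nyquist: a 0.3 Hz source is resolvable

    def _ratio(self, tc):
        return jica.band_power_ratio(tc[None, :, None], self.TR_FAST)[0]

    def test_neural_band_sinusoid_selected(self):
        rng = np.random.default_rng(0)
        t = np.arange(300) * self.TR_FAST
        tc = np.sin(2 * np.pi * 0.05 * t) + 0.1 * rng.standard_normal(t.size)
        sel, ratios = jica.select_components(tc[None, :, None], self.TR_FAST)
        assert sel[0] and ratios[0] > 4.0

    def test_high_frequency_sinusoid_rejected(self):
        rng = np.random.default_rng(1)
        t = np.arange(300) * self.TR_FAST
        tc = np.sin(2 * np.pi * 0.3 * t) + 0.1 * rng.standard_normal(t.size)
        sel, ratios = jica.select_components(tc[None, :, None], self.TR_FAST)
        assert not sel[0]
        assert ratios[0] < 1.0

    def test_white_noise_ratio_near_one_and_rejected(self):
        rng = np.random.default_rng(2)
        ratios = [self._ratio(rng.standard_normal(300)) for _ in range(40)]
        # flat spectrum: equal mean density in and out of band
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)
        sel, _ = jica.select_components(
            rng.standard_normal((5, 300, 1)), self.TR_FAST
        )
        assert not sel[0]

    def test_welch_parameters_match_scipy_oracle(self):
        rng = np.random.default_rng(3)
        tc = rng.standard_normal((2, 153, 1))
        ratios = jica.band_power_ratio(tc, TR)
        nperseg = min(64, 153 // 2)
        freqs, psd = signal.welch(tc, fs=1 / TR, window="hann", nperseg=nperseg,
                                  noverlap=nperseg // 2, axis=1)
        pm = psd.mean(axis=0)[:, 0]
        in_b = (freqs > 0) & (freqs >= 0.01) & (freqs <= 0.1)
        out_b = (freqs > 0) & ~in_b
        assert ratios[0] == pytest.approx(pm[in_b].mean() / pm[out_b].mean())

    def test_degenerate_zero_timecourse_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            jica.band_power_ratio(np.zeros((1, 300, 1)), self.TR_FAST)


class TestCordVolume:
    def _decomp_with_cord(self, cord_values, n_components=12):
        """Stack of noise maps with one structured cord map."""
        rng = np.random.default_rng(0)
        cord_shape = (6, 6, 10)
        n_cord = np.prod(cord_shape)
        maps = rng.standard_normal((n_components, 100 + n_cord))
        maps[0, 100:] = cord_values.ravel()
        coords = np.nonzero(np.ones(cord_shape, bool))
        return jica.GroupDecomposition(
            maps=maps, mixing=np.eye(n_components), split_index=100,
            brain_coords=np.nonzero(np.ones((10, 10, 1), bool)),
            cord_coords=coords, brain_shape=(10, 10, 1), cord_shape=cord_shape,
            cord_voxel_size=(1.2, 1.2, 5.0), brain_voxel_size=(2, 2, 2),
        )

    def test_empty_map_flagged_small(self):
        decomp = self._decomp_with_cord(np.zeros((6, 6, 10)))
        vol, small = jica.cord_component_volume(decomp, 0)
        assert vol == 0.0 and small

    def test_small_cluster_arithmetic(self):
        """20 cord voxels at 1.2 x 1.2 x 5 mm = 0.144 cm^3: below the 0.15 bound."""
        sm = jica.SmoothnessEstimate(np.array([1.5, 1.5, 1.0]), 100.0)
        cord = np.zeros((6, 6, 10))
        cord[1:5, 1:6, 2] = 5.0  # a single 20-voxel slab
        decomp = self._decomp_with_cord(cord)
        vol, small = jica.cord_component_volume(decomp, 0, smoothness=sm)
        assert vol == pytest.approx(20 * 7.2 / 1000) == pytest.approx(0.144)
        assert small

    def test_large_cluster_not_flagged(self):
        sm = jica.SmoothnessEstimate(np.array([1.5, 1.5, 1.0]), 100.0)
        cord = np.zeros((6, 6, 10))
        cord[1:6, 1:6, 2:6] = 5.0  # 100 voxels
        decomp = self._decomp_with_cord(cord)
        vol, small = jica.cord_component_volume(decomp, 0, smoothness=sm)
        assert vol == pytest.approx(100 * 7.2 / 1000) == pytest.approx(0.72)
        assert not small


class TestEndToEndCohort:
    """The planted-network dichotomy on the default synthetic cohort."""

    def test_cross_structure_networks_have_large_cord_volume(self, jica_run, cohort, truth_maps):
        d = jica_run.decomposition
        assigned, corrs, _ = jica.match_components(d.maps, truth_maps)
        cross = [i for i, n in enumerate(cohort.networks)
                 if n.cord_map.max() > 0 and n.band[0] < 0.1]
        for i in cross:
            c = assigned[i]
            assert abs(corrs[i]) > 0.85
            assert d.selected[c]
            assert d.cord_volumes_cm3[c] >= 0.15
            assert not d.small_cord_flags[c]

    def test_brain_only_network_flagged_small(self, jica_run, cohort, truth_maps):
        d = jica_run.decomposition
        assigned, corrs, signs = jica.match_components(d.maps, truth_maps)
        i = [k for k, n in enumerate(cohort.networks) if n.name == "brain_only"][0]
        c = assigned[i]
        assert abs(corrs[i]) > 0.9
        assert d.selected[c]
        assert d.cord_volumes_cm3[c] < 0.15
        assert d.small_cord_flags[c]
        # no cord voxel of the oriented map reaches the ICA threshold
        assert (signs[i] * d.cord_part(c)).max() < 3.1

    def test_artifact_component_has_no_cord_cluster(self, jica_run, cohort, truth_maps):
        d = jica_run.decomposition
        assigned, _, _ = jica.match_components(d.maps, truth_maps)
        i = [k for k, n in enumerate(cohort.networks) if n.name == "hf_artifact"][0]
        assert d.small_cord_flags[assigned[i]]

    def test_pca_to_ica_stacked_rows(self, jica_run, cfg, cohort):
        assert sum(r.k for r in jica_run.reduced) == cfg.n_pca * cohort.n_sub
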