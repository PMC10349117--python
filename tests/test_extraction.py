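"""Spatial concatenation, model order, ICA, clustering, group maps."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

import whiterest as wr
from whiterest.extraction import _minka_log_evidence, _t_to_z


def make_composite(data, tr=0.72, shape=None):
    n_vox = data.shape[0]
    if shape is None:
        side = int(np.ceil(n_vox ** (1 / 3))) + 1
        shape = (side, side, side)
    grid = wr.VoxelGrid.isotropic(shape)
    idx = np.arange(n_vox)
    comp = np.zeros(n_vox, dtype=np.int8)
    comp[n_vox // 2:] = 1
    return wr.CompositeSeries(grid, np.asarray(data, float), idx, comp, tr)


@pytest.fixture(scope="module")
def subject_series(anatomy, priors):
    spec = wr.PhantomSpec(seed=100)
    series, truth = wr.simulate_rest(anatomy, spec)
    wm_series = wr.project_functionnectome(series, anatomy.gm_mask, priors)
    return series, wm_series, truth


class TestConcatSplit:
    def test_voxel_counts_add(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
        n_gm = int(anatomy.gm_mask.values.sum())
        n_wm = int(anatomy.wm_mask.values.sum())
        assert comp.n_voxels == n_gm + n_wm

    def test_split_inverts_concat(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
        gm_back, wm_back = wr.split_composite(comp)
        gm = anatomy.gm_mask.values
        wm = anatomy.wm_mask.values
        np.testing.assert_array_equal(gm_back.values[gm], series.values[gm])
        np.testing.assert_array_equal(wm_back.values[wm], wm_series.values[wm])
        assert np.all(gm_back.values[~gm] == 0)

    def test_tr_mismatch_rejected(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        other = wr.FunctionalSeries(series.grid, wm_series.values, tr=2.0)
        with pytest.raises(ValueError, match="tr"):
            wr.concat_spatial(series, other, anatomy.gm_mask, anatomy.wm_mask)

    def test_overlapping_masks_rejected(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        with pytest.raises(ValueError, match="disjoint"):
            wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.gm_mask)

    def test_split_component_round_trip(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
        rng = np.random.default_rng(0)
        m = rng.normal(size=comp.n_voxels)
        gm_vol, wm_vol = wr.split_component(m, comp)
        recon = gm_vol.values.ravel()[comp.voxel_idx[comp.compartment == 0]]
        np.testing.assert_array_equal(recon, m[comp.compartment == 0])
        recon_wm = wm_vol.values.ravel()[comp.voxel_idx[comp.compartment == 1]]
        np.testing.assert_array_equal(recon_wm, m[comp.compartment == 1])


class TestOrderEstimation:
    def test_exact_rank_three_data(self):
        rng = np.random.default_rng(0)
        maps = scipy.linalg.orth(rng.normal(size=(120, 3)))
        times = rng.normal(size=(3, 60))
        comp = make_composite(maps @ times)
        assert wr.estimate_order(comp, 20) == 3

    def test_pure_noise_gives_small_order(self):
        small = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            comp = make_composite(rng.normal(size=(500, 200)))
            small += wr.estimate_order(comp, 50) <= 5
        assert small >= 18  # >= 90% of seeds

    def test_k_max_one(self):
        rng = np.random.default_rng(1)
        comp = make_composite(rng.normal(size=(100, 50)))
        assert wr.estimate_order(comp, 1) == 1

    def test_constant_data_rejected(self):
        comp = make_composite(np.ones((50, 30)))
        with pytest.raises(ValueError, match="degenerate"):
            wr.estimate_order(comp, 5)

    def test_evidence_prefers_true_order_with_noise(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(800, 4)) * 3.0
        times = rng.normal(size=(4, 100))
        data = maps @ times + rng.normal(size=(800, 100))
        comp = make_composite(data)
        assert wr.estimate_order(comp, 20) == 4


class TestSpatialICA:
    def test_recovers_planted_networks(self):
        rng = np.random.default_rng(3)
        n_vox, n_t = 600, 150
        m1 = np.zeros(n_vox)
        m1[:40] = 1.0
        m2 = np.zeros(n_vox)
        m2[300:350] = 1.0
        t1, t2 = rng.normal(size=(2, n_t))
        data = np.outer(m1, t1) + np.outer(m2, t2) + 0.1 * rng.normal(size=(n_vox, n_t))
        comp = make_composite(data)
        ics = wr.spatial_ica(comp, 2, seed=0)
        maps = np.stack([
            np.concatenate([
                ic.gm_zmap.values.ravel()[comp.voxel_idx[comp.compartment == 0]],
                ic.wm_zmap.values.ravel()[comp.voxel_idx[comp.compartment == 1]],
            ])
            for ic in ics
        ])
        corr = np.abs(np.corrcoef(np.vstack([maps, m1, m2]))[:2, 2:])
        best = corr.max(axis=1)
        assert np.all(best >= 0.95)

    def test_maps_zero_mean_unit_variance(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
        live = comp.data.std(axis=1) > 0
        for ic in wr.spatial_ica(comp, 3, seed=1):
            m = np.concatenate([
                ic.gm_zmap.values.ravel()[comp.voxel_idx[comp.compartment == 0]],
                ic.wm_zmap.values.ravel()[comp.voxel_idx[comp.compartment == 1]],
            ])[live]
            assert abs(m.mean()) < 1e-8
            assert m.std() == pytest.approx(1.0, abs=1e-8)
            assert scipy.stats.skew(m) >= 0  # sign convention

    def test_deterministic_given_seed(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
        a = wr.spatial_ica(comp, 3, seed=42)
        b = wr.spatial_ica(comp, 3, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.gm_zmap.values, y.gm_zmap.values)

    def test_k_bounds_enforced(self, anatomy, subject_series):
        series, wm_series, _ = subject_series
        comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
        with pytest.raises(ValueError):
            wr.spatial_ica(comp, 0, seed=0)
        with pytest.raises(ValueError):
            wr.spatial_ica(comp, comp.n_t + 1, seed=0)


def _identical_subjects(anatomy, priors, n_subjects=3):
    spec = wr.PhantomSpec(seed=100)
    series, _ = wr.simulate_rest(anatomy, spec)
    wm_series = wr.project_functionnectome(series, anatomy.gm_mask, priors)
    comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
    ics = wr.spatial_ica(comp, 3, seed=0, subject="s0")
    out = []
    for s in range(n_subjects):
        out.append([
            wr.ICPair(f"s{s}", ic.component, ic.gm_zmap, ic.wm_zmap, ic.timecourse)
            for ic in ics
        ])
    return out


class TestClustering:
    def test_identical_ics_one_group_per_component(self, anatomy, priors):
        subjects = _identical_subjects(anatomy, priors)
        groups = wr.cluster_components(subjects, r_min=0.4, coverage_min=0.5)
        assert len(groups) == 3
        for g in groups:
            assert len(g.members) == 3
            assert g.coverage == 1.0
            # centroid equals the member map (all identical)
            ref = g.members[0].gm_zmap.values
            for m in g.members[1:]:
                np.testing.assert_array_equal(m.gm_zmap.values, ref)

    def test_impossible_threshold_gives_zero_groups(self, anatomy, priors):
        subjects = _identical_subjects(anatomy, priors)
        assert wr.cluster_components(subjects, r_min=1.01) == []

    def test_single_subject_rejected(self, anatomy, priors):
        subjects = _identical_subjects(anatomy, priors, n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            wr.cluster_components(subjects)

    def test_at_most_one_member_per_subject(self, pipeline_run):
        _, groups, _, _, _ = pipeline_run
        for g in groups:
            subs = [m.subject for m in g.members]
            assert len(set(subs)) == len(subs)

    def test_subject_order_invariance(self, pipeline_run, anatomy):
        subjects, groups, _, _, _ = pipeline_run
        shuffled = [subjects[i] for i in [5, 2, 7, 0, 3, 6, 1, 4]]
        groups2 = wr.cluster_components(
            shuffled, r_min=0.4, coverage_min=0.5, gm_mask=anatomy.gm_mask
        )
        assert len(groups2) == len(groups)
        # same groups as sets of (subject, component) labels
        def key(g):
            return frozenset((m.subject, m.component) for m in g.members)
        assert {key(g) for g in groups} == {key(g) for g in groups2}


class TestGroupZmap:
    def _group_from_values(self, values, grid_side=4):
        """Members whose maps are constant = v at one voxel, 0 elsewhere."""
        grid = wr.VoxelGrid.isotropic((grid_side,) * 3)
        members = []
        for s, v in enumerate(values):
            arr = np.zeros(grid.shape)
            arr[0, 0, 0] = v
            vol = wr.Volume(grid, arr)
            members.append(wr.ICPair(f"s{s}", 0, vol, wr.Volume(grid, arr.copy()), np.zeros(3)))
        return wr.RSNGroup(members=members, n_subjects=len(values))

    def test_t_statistic_matches_brute_force(self):
        vals = [1.0, 1.2, 0.8]
        group = self._group_from_values(vals)
        pair = wr.group_zmap(group, method="t")
        # independent oracle: t = mean / (sd / sqrt(n)) computed from scratch
        n = len(vals)
        mean = sum(vals) / n
        sd = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5
        t_oracle = mean / (sd / n**0.5)
        assert t_oracle == pytest.approx(8.660254, abs=1e-6)
        z_oracle = scipy.stats.norm.isf(scipy.stats.t.sf(t_oracle, n - 1))
        assert pair.gm_zmap.values[0, 0, 0] == pytest.approx(z_oracle, abs=1e-9)

    def test_identical_positive_members_hit_cap(self):
        group = self._group_from_values([2.0, 2.0, 2.0])
        pair = wr.group_zmap(group, method="t")
        assert pair.gm_zmap.values[0, 0, 0] == 38.0

    def test_zero_everywhere_stays_zero(self):
        group = self._group_from_values([0.0, 0.0, 0.0])
        for method in ("t", "stouffer"):
            pair = wr.group_zmap(group, method=method)
            assert np.all(pair.gm_zmap.values == 0)

    def test_stouffer_combination_value(self):
        vals = [1.0, 2.0, 3.0]
        group = self._group_from_values(vals)
        pair = wr.group_zmap(group, method="stouffer")
        assert pair.gm_zmap.values[0, 0, 0] == pytest.approx(6.0 / np.sqrt(3.0))

    def test_needs_two_members(self):
        group = self._group_from_values([1.0])
        with pytest.raises(ValueError, match="2 members"):
            wr.group_zmap(group)

    def test_t_to_z_symmetric(self):
        t = np.array([-5.0, 0.0, 5.0])
        z = _t_to_z(t, 7)
        assert z[1] == 0
        assert z[0] == pytest.approx(-z[2])


class TestMatchToTruth:
    def test_truth_matches_itself_perfectly(self, truth_atlas, truth):
        report = wr.match_to_truth(truth_atlas, truth)
        for row in report:
            assert row["gm_corr"] == pytest.approx(1.0)
            assert row["wm_corr"] == pytest.approx(1.0)

    def test_permutation_invariance(self, truth_atlas, truth):
        report = wr.match_to_truth(truth_atlas[::-1], truth)
        total = sum(r["gm_corr"] for r in report)
        assert total == pytest.approx(len(truth_atlas))

    def test_extra_group_flagged_unmatched(self, truth_atlas, truth, anatomy):
        rng = np.random.default_rng(0)
        extra = wr.RSNMapPair(
            99,
            wr.Volume(anatomy.grid, rng.normal(size=anatomy.grid.shape)),
            wr.Volume(anatomy.grid, rng.normal(size=anatomy.grid.shape)),
        )
        report = wr.match_to_truth(truth_atlas + [extra], truth)
        unmatched = [r for r in report if r["truth_index"] is None]
        assert len(unmatched) == 1
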