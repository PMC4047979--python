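import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

import endolight as el
from endolight._svm import LinearSVM
from endolight.searchlight import cube_members, fold_partition, region_fold_seed
from endolight.volume_io import Mask


def full_mask(shape):
    return Mask(data=np.ones(shape, dtype=bool))


class TestLinearSVMWrapper:
    def test_matches_svc_predictions(self, rng):
        """The fast libsvm path must be indistinguishable from SVC(kernel='linear')."""
        for _ in range(60):
            n = int(rng.integers(8, 40))
            d = int(rng.integers(2, 30))
            X = rng.normal(0, 1, (n, d))
            y = np.where(rng.random(n) < 0.5, -1, 1)
            if len(np.unique(y)) < 2:
                continue
            if rng.random() < 0.3:
                X[y == 1] += rng.uniform(0, 4)
            Xte = rng.normal(0, 1, (9, d))
            ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(Xte)
            got = LinearSVM(C=1.0).fit(X, y).predict(Xte)
            np.testing.assert_array_equal(got, ref)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            LinearSVM().fit(np.zeros((4, 2)), np.ones(4))


class TestEnumerateRegions:
    def test_interior_side5_has_125_members(self):
        mask = full_mask((9, 9, 9))
        params = el.SearchlightParams(side=5)
        regions = {r.center: r for r in el.enumerate_regions(mask, params)}
        assert len(regions[(4, 4, 4)].members) == 125

    def test_side1_is_center_only(self):
        mask = full_mask((4, 4, 4))
        for r in el.enumerate_regions(mask, el.SearchlightParams(side=1)):
            np.testing.assert_array_equal(r.members, [list(r.center)])

    def test_clipped_counts_match_bruteforce(self):
        """6³ full grid, side 5: member counts equal explicit cube clipping."""
        shape = (6, 6, 6)
        mask = full_mask(shape)
        regions = {r.center: r for r in el.enumerate_regions(mask, el.SearchlightParams(side=5))}
        assert len(regions) == 216
        for center, region in regions.items():
            expected = [
                (i, j, k)
                for i in range(max(center[0] - 2, 0), min(center[0] + 2, 5) + 1)
                for j in range(max(center[1] - 2, 0), min(center[1] + 2, 5) + 1)
                for k in range(max(center[2] - 2, 0), min(center[2] + 2, 5) + 1)
            ]
            assert [tuple(m) for m in region.members] == expected
        assert len(regions[(0, 0, 0)].members) == 27  # corner voxel: 3x3x3
        assert len(regions[(1, 1, 1)].members) == 64  # one step in: 4x4x4

    def test_membership_symmetry_on_random_mask(self, rng):
        shape = (8, 8, 8)
        mask = Mask(data=rng.random(shape) < 0.5)
        if mask.n_voxels == 0:
            pytest.skip("empty random mask")
        params = el.SearchlightParams(side=3)
        members = {r.center: {tuple(m) for m in r.members} for r in el.enumerate_regions(mask, params)}
        for c, mem in members.items():
            for v in mem:
                if v in members:
                    assert c in members[v]

    def test_min_in_mask_drops_sparse_regions(self, caplog):
        mask = Mask(data=np.zeros((7, 7, 7), dtype=bool))
        mask.data[3, 3, 3] = True
        mask.data[0, 0, 0] = True
        params = el.SearchlightParams(side=3, min_in_mask=2)
        with caplog.at_level("INFO", logger="endolight.searchlight"):
            regions = el.enumerate_regions(mask, params)
        assert regions == []
        assert "dropped 2" in caplog.text

    def test_even_side_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            el.SearchlightParams(side=4)


class TestExtractFeatures:
    def test_direct_indexing_oracle(self, tiny_cohort, tiny_mask):
        ds, _ = tiny_cohort
        region = el.enumerate_regions(tiny_mask, el.SearchlightParams(side=3))[5]
        X, y = el.extract_features(ds, region, "control", "case")
        rows = [i for i, g in enumerate(ds.labels) if g in ("control", "case")]
        assert X.shape == (len(rows), len(region.members))
        for r_out, r_in in enumerate(rows):
            for c, (i, j, k) in enumerate(region.members):
                assert X[r_out, c] == ds.volumes[r_in].data[i, j, k]
        np.testing.assert_array_equal(
            y, [-1 if ds.labels[i] == "control" else 1 for i in rows]
        )

    def test_absent_group_rejected(self, tiny_mask):
        cfg = el.PhantomConfig(shape=(12, 12, 12), n_control=3, n_case=3, n_sibling=0, seed=0)
        ds, _ = el.generate_phantom_cohort(cfg)
        region = el.enumerate_regions(tiny_mask, el.SearchlightParams(side=3))[0]
        with pytest.raises(ValueError, match="sibling"):
            el.extract_features(ds, region, "control", "sibling")


class TestCvAccuracy:
    def test_separable_data_scores_one(self, rng):
        X = rng.normal(0, 1, (20, 6))
        y = np.array([-1] * 10 + [1] * 10)
        X[y == 1] += 10.0
        params = el.SearchlightParams(folds=5, seed=0)
        assert el.cv_accuracy(X, y, params, el.ClassifierSpec()) == 1.0

    def test_shift_invariance(self, rng):
        X = rng.normal(0, 1, (16, 5))
        y = np.array([-1, 1] * 8)
        params = el.SearchlightParams(folds=4, seed=3)
        spec = el.ClassifierSpec()
        a1 = el.cv_accuracy(X, y, params, spec)
        a2 = el.cv_accuracy(X + 7.5, y, params, spec)
        assert a1 == a2

    def test_label_swap_symmetry(self, rng):
        X = rng.normal(0, 1, (16, 5))
        y = np.array([-1, 1] * 8)
        params = el.SearchlightParams(folds=4, seed=3)
        spec = el.ClassifierSpec()
        assert el.cv_accuracy(X, y, params, spec) == el.cv_accuracy(X, -y, params, spec)

    def test_constant_features_fall_back_to_majority(self, caplog):
        X = np.full((12, 4), 0.3)
        y = np.array([-1] * 8 + [1] * 4)
        params = el.SearchlightParams(folds=4, seed=0)
        with caplog.at_level("INFO", logger="endolight.searchlight"):
            acc = el.cv_accuracy(X, y, params, el.ClassifierSpec())
        assert acc == 8 / 12
        assert "majority" in caplog.text

    def test_matches_independent_cv_loop(self, rng):
        """Fixed 12-sample dataset: pooled accuracy equals a hand-coded
        stratified-CV loop over the same folds using the reference SVC."""
        X = rng.normal(0, 1, (12, 4))
        y = np.array([-1] * 6 + [1] * 6)
        X[y == 1, 0] += 1.0
        params = el.SearchlightParams(folds=3, seed=17)
        got = el.cv_accuracy(X, y, params, el.ClassifierSpec())

        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=17)
        correct = 0
        for tr, te in skf.split(np.zeros(12), y):
            pred = SVC(kernel="linear", C=1.0).fit(X[tr], y[tr]).predict(X[te])
            correct += int((pred == y[te]).sum())
        assert got == correct / 12

    def test_too_many_folds_rejected(self, rng):
        X = rng.normal(0, 1, (8, 3))
        y = np.array([-1] * 6 + [1] * 2)
        with pytest.raises(ValueError, match="folds"):
            el.cv_accuracy(X, y, el.SearchlightParams(folds=4), el.ClassifierSpec())


class TestRunSearchlight:
    def test_deterministic_and_order_independent(self, tiny_cohort, tiny_mask):
        ds, _ = tiny_cohort
        params = el.SearchlightParams(side=3, folds=3, seed=9)
        spec = el.ClassifierSpec()
        regions = el.enumerate_regions(tiny_mask, params)
        a = el.run_searchlight(ds, tiny_mask, "control", "case", params, spec, regions=regions)
        b = el.run_searchlight(ds, tiny_mask, "control", "case", params, spec,
                               regions=list(reversed(regions)))
        accs_a = {s.center: s.accuracy for s in a}
        accs_b = {s.center: s.accuracy for s in b}
        assert accs_a == accs_b

    def test_planted_effect_raises_local_accuracy(self):
        region = el.cube_region((6, 6, 6), 3)
        eff = el.EffectSpec(region=region, affected_groups=("case",),
                            mode="mean_shift", magnitude=2.0)
        cfg = el.PhantomConfig(shape=(12, 12, 12), n_control=16, n_case=16, n_sibling=0,
                               effects=(eff,), seed=13)
        ds, truth = el.generate_phantom_cohort(cfg)
        mask = el.build_mask(ds)
        params = el.SearchlightParams(side=3, folds=4, seed=0)
        stats = el.run_searchlight(ds, mask, "control", "case", params, el.ClassifierSpec())
        inside = [s.accuracy for s in stats if truth.effect_mask_case[s.center]]
        far = [
            s.accuracy for s in stats
            if np.linalg.norm(np.array(s.center) - 6) > 5
        ]
        assert np.mean(inside) > np.mean(far) + 0.2


class TestProjectToVoxels:
    def test_single_region_paints_members(self, tiny_mask):
        params = el.SearchlightParams(side=3)
        center = (6, 6, 6)
        stats = [el.RegionAccuracy(center=center, accuracy=0.8, n_samples=12)]
        vmap = el.project_to_voxels(stats, [center], tiny_mask, params)
        members = cube_members(center, 3, tiny_mask)
        assert (vmap[members[:, 0], members[:, 1], members[:, 2]] == 0.8).all()
        assert vmap.sum() == 0.8 * len(members)

    def test_overlap_takes_max(self, tiny_mask):
        params = el.SearchlightParams(side=3)
        stats = [
            el.RegionAccuracy(center=(6, 6, 6), accuracy=0.7, n_samples=12),
            el.RegionAccuracy(center=(6, 6, 7), accuracy=0.9, n_samples=12),
        ]
        vmap = el.project_to_voxels(stats, [s.center for s in stats], tiny_mask, params)
        assert vmap[6, 6, 6] == 0.9  # voxel in both regions takes the larger value

    def test_matches_bruteforce_projection(self, rng):
        shape = (7, 7, 7)
        mask = Mask(data=rng.random(shape) < 0.7)
        params = el.SearchlightParams(side=3)
        regions = el.enumerate_regions(mask, params)
        stats = [
            el.RegionAccuracy(center=r.center, accuracy=float(rng.random()), n_samples=8)
            for r in regions
        ]
        selected = [s.center for s in stats if rng.random() < 0.5]
        vmap = el.project_to_voxels(stats, selected, mask, params)
        sel = set(selected)
        acc = {s.center: s.accuracy for s in stats}
        for v in np.ndindex(shape):
            expected = 0.0
            if mask.data[v]:
                for r in regions:
                    if r.center in sel and any((m == v).all() for m in r.members):
                        expected = max(expected, acc[r.center])
            assert vmap[v] == expected

    def test_monotone_under_added_region(self, tiny_mask):
        params = el.SearchlightParams(side=3)
        stats = [
            el.RegionAccuracy(center=(5, 5, 5), accuracy=0.6, n_samples=12),
            el.RegionAccuracy(center=(7, 7, 7), accuracy=0.75, n_samples=12),
        ]
        small = el.project_to_voxels(stats, [(5, 5, 5)], tiny_mask, params)
        large = el.project_to_voxels(stats, [(5, 5, 5), (7, 7, 7)], tiny_mask, params)
        assert (large >= small).all()


def test_region_fold_seed_depends_on_center_and_seed():
    s1 = region_fold_seed(1, (2, 3, 4))
    assert s1 == region_fold_seed(1, (2, 3, 4))
    assert s1 != region_fold_seed(2, (2, 3, 4))
    assert s1 != region_fold_seed(1, (4, 3, 2))
    assert 0 <= s1 < 2**31


def test_fold_partition_is_stratified():
    y = np.array([-1] * 9 + [1] * 6)
    for tr, te in fold_partition(y, 3, seed=5):
        assert (y[te] == -1).sum() == 3
        assert (y[te] == 1).sum() == 2
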