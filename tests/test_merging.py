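"""Selection, outlier rejection, weighted merging, CC1/2, unique sets."""

import math

import gemmi
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stillpost import merging, refinement, simulate
from stillpost.geometry import UnitCell


def brute_force_unique(cell: UnitCell, space_group: str, d_max: float, d_min: float) -> int:
    """Independent oracle: box enumeration + explicit symmetry reduction."""
    sg = gemmi.find_spacegroup_by_name(space_group)
    ops = sg.operations()
    gcell = cell.to_gemmi()
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    seen = set()
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if h == k == l == 0:
                    continue
                d = gcell.calculate_d((h, k, l))
                if d < d_min or d > d_max:
                    continue
                if ops.is_systematically_absent((h, k, l)):
                    continue
                eqs = []
                for op in ops:
                    m = op.apply_to_hkl((h, k, l))
                    eqs.append(tuple(m))
                    eqs.append((-m[0], -m[1], -m[2]))
                seen.add(min(eqs))
    return len(seen)


class TestWeightedMerge:
    def test_worked_example(self):
        # (I=10, sigma=1) and (I=20, sigma=2): <I> = (10 + 20/4)/(1 + 1/4)
        mi, ms = merging.weighted_mean([10.0, 20.0], [1.0, 2.0])
        assert mi == pytest.approx(12.0)

    def test_equal_sigmas_give_arithmetic_mean(self):
        mi, _ = merging.weighted_mean([3.0, 5.0, 10.0], [2.0, 2.0, 2.0])
        assert mi == pytest.approx(6.0)

    def test_merged_sigma_never_exceeds_best_observation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s = rng.uniform(0.5, 5.0, rng.integers(2, 9))
            i = rng.normal(100, 10, len(s))
            _, ms = merging.weighted_mean(i, s)
            assert ms <= s.min() + 1e-12

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(2, 12)
            i = rng.normal(50, 20, n)
            s = rng.uniform(0.1, 4.0, n)
            w = 1 / s**2
            mi, ms = merging.weighted_mean(i, s)
            assert mi == pytest.approx((w * i).sum() / w.sum(), rel=1e-12)
            assert ms == pytest.approx(math.sqrt(1 / w.sum()), rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_scale_equivariance(self, k):
        i = np.array([10.0, 30.0, 25.0])
        s = np.array([1.0, 2.0, 0.5])
        mi, ms = merging.weighted_mean(i, s)
        mik, msk = merging.weighted_mean(k * i, k * s)
        assert mik == pytest.approx(k * mi, rel=1e-9)
        assert msk == pytest.approx(k * ms, rel=1e-9)

    def test_permutation_invariance(self):
        i = np.array([10.0, 30.0, 25.0, 5.0])
        s = np.array([1.0, 2.0, 0.5, 3.0])
        perm = [2, 0, 3, 1]
        assert merging.weighted_mean(i, s) == merging.weighted_mean(i[perm], s[perm])


class TestOutlierRejection:
    def test_identical_values_all_kept(self):
        assert merging.reject_outliers(np.full(10, 7.0)).all()

    def test_single_outlier_rejected_matches_brute_force(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(100, 1, 20), [200.0]])

        def brute(vals, cutoff=3.0):
            keep = np.ones(len(vals), bool)
            for _ in range(10):
                sub = vals[keep]
                new = keep & (np.abs(vals - sub.mean()) <= cutoff * sub.std())
                if (new == keep).all():
                    break
                keep = new
            return keep

        got = merging.reject_outliers(values)
        assert np.array_equal(got, brute(values))
        assert not got[-1] and got[:-1].all()

    def test_degenerate_pairs_never_rejected(self):
        assert merging.reject_outliers(np.array([1.0, 1e6])).all()


class TestSelection:
    def _toy(self):
        miller = np.array([[1, 0, 0]] * 10)
        i = np.array([10.0, 1.0, 5.0, 0.5, 8.0, 1.2, 9.0, 7.0, 6.0, 4.0])
        s = np.ones(10)
        from stillpost.partiality import PredictedReflection

        pred = PredictedReflection(
            miller=miller, r_h=np.zeros(10), r_s=np.full(10, 3e-3),
            eoc=np.full(10, 0.8), vc=np.full(10, 4e-3),
            theta=np.full(10, 0.2), alpha=np.zeros(10), phi=np.zeros(10),
            pol=np.ones(10), xy_calc=np.zeros((10, 2)), d=np.full(10, 3.0),
        )

        class Obs:
            intensity = i
            sigma = s

        return pred, Obs()

    def test_all_pass_thresholds_are_identity(self):
        pred, obs = self._toy()
        crit = merging.SelectionCriteria(min_i_over_sigma=-math.inf, min_eoc=0.0)
        assert merging.select_reflections(pred, obs, crit).all()

    def test_i_over_sigma_cut(self):
        pred, obs = self._toy()
        crit = merging.SelectionCriteria(min_i_over_sigma=1.5, min_eoc=0.0)
        assert merging.select_reflections(pred, obs, crit).sum() == 7

    def test_eoc_floor(self):
        pred, obs = self._toy()
        pred.eoc = np.where(np.arange(10) < 4, 0.05, 0.8)
        crit = merging.SelectionCriteria(min_eoc=0.10)
        assert merging.select_reflections(pred, obs, crit).sum() == 6

    def test_resolution_window(self):
        pred, obs = self._toy()
        pred.d = np.linspace(1.0, 10.0, 10)
        crit = merging.SelectionCriteria(d_max=8.0, d_min=2.0, min_eoc=0.0)
        got = merging.select_reflections(pred, obs, crit)
        assert np.array_equal(got, (pred.d >= 2.0) & (pred.d <= 8.0))

    def test_cell_deviation_excludes_frame(self):
        target = UnitCell(100, 100, 50, 90, 90, 90)
        off = UnitCell(106, 106, 53, 90, 90, 90)  # 6% off
        assert not merging.cell_within_tolerance(off, target, 0.05)
        assert merging.cell_within_tolerance(off, target, 0.07)


class TestReduceMiller:
    def test_friedel_mates_merge_by_default(self):
        r1 = merging.reduce_miller("P6", [[3, -2, 5]])
        r2 = merging.reduce_miller("P6", [[-3, 2, -5]])
        assert np.array_equal(r1, r2)

    def test_anomalous_keeps_mates_separate(self):
        r1 = merging.reduce_miller("P1", [[1, 2, 3]], anomalous=True)
        r2 = merging.reduce_miller("P1", [[-1, -2, -3]], anomalous=True)
        assert np.array_equal(r1, -r2)
        assert not np.array_equal(r1, r2)

    def test_symmetry_equivalents_share_one_index(self):
        # P6: rotation about c maps (h, k, l) family onto itself
        fam = [[2, 1, 3], [-1, 3, 3], [-3, 2, 3], [-2, -1, 3], [1, -3, 3], [3, -2, 3]]
        red = merging.reduce_miller("P6", fam)
        assert len(np.unique(red, axis=0)) == 1


class TestCcHalf:
    def test_identical_halves_give_unity(self):
        rng = np.random.default_rng(7)
        reduced, vals = [], []
        for j in range(30):
            v = rng.exponential(100)
            for _ in range(4):  # four identical copies: any split has equal halves
                reduced.append([j, 0, 0])
                vals.append(v)
        cc = merging.cc_half(np.array(reduced), np.array(vals), np.ones(len(vals)), seed=1)
        assert cc == pytest.approx(1.0)

    def test_reflections_with_three_observations_excluded(self):
        reduced = np.repeat(np.arange(10)[:, None], 3, axis=0)
        reduced = np.column_stack([reduced, np.zeros((30, 2), int)])
        cc = merging.cc_half(reduced, np.random.default_rng(0).normal(100, 5, 30),
                             np.ones(30), seed=0)
        assert math.isnan(cc)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        reduced = np.column_stack([rng.integers(0, 50, 400), np.zeros((400, 2), int)])
        i = rng.normal(100, 20, 400)
        s = np.ones(400)
        a = merging.cc_half(reduced, i, s, seed=5)
        b = merging.cc_half(reduced, i, s, seed=5)
        c = merging.cc_half(reduced, i, s, seed=6)
        assert a == b
        assert a != c

    def test_matches_analytic_signal_to_noise_ratio(self):
        # I_j ~ signal with variance sig_t^2; each of 2k obs adds N(0, s^2);
        # half-mean noise variance sig_n^2 = s^2/k, so E[CC1/2] ~
        # sig_t^2/(sig_t^2 + sig_n^2)
        sig_t, s, k = 50.0, 40.0, 4
        expected = sig_t**2 / (sig_t**2 + s**2 / k)
        ccs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            true = rng.normal(200, sig_t, 400)
            reduced = np.repeat(np.arange(400)[:, None], 2 * k, axis=0)
            reduced = np.column_stack([reduced, np.zeros((len(reduced), 2), int)])
            obs = np.repeat(true, 2 * k) + rng.normal(0, s, len(reduced))
            ccs.append(merging.cc_half(reduced, obs, np.ones(len(obs)), seed=seed))
        assert np.mean(ccs) == pytest.approx(expected, abs=3 * np.std(ccs) / math.sqrt(20))


class TestUniqueReflectionSet:
    @pytest.mark.parametrize(
        "cell,sg",
        [
            (UnitCell(10, 11, 12, 85, 95, 100), "P1"),
            (UnitCell(10, 11, 12, 90, 100, 90), "P21"),
            (UnitCell(10, 11, 12, 90, 90, 90), "P21 21 21"),
            (UnitCell(10, 10, 12, 90, 90, 90), "P4"),
            (UnitCell(10, 10, 12, 90, 90, 120), "P3"),
            (UnitCell(10, 10, 12, 90, 90, 120), "P6"),
            (UnitCell(10, 10, 10, 90, 90, 90), "P23"),
        ],
    )
    def test_matches_brute_force_oracle_all_systems(self, cell, sg):
        _, count = merging.unique_reflection_set(cell, sg, 50.0, 3.0)
        assert count == brute_force_unique(cell, sg, 50.0, 3.0)

    def test_anomalous_counts_acentrics_twice(self):
        cell = UnitCell(10, 11, 12, 85, 95, 100)
        arr, n = merging.unique_reflection_set(cell, "P1", 50.0, 4.0)
        arr_a, n_a = merging.unique_reflection_set(cell, "P1", 50.0, 4.0, anomalous=True)
        assert n_a == 2 * n  # P1 has no centric reflections

    def test_systematic_absences_excluded(self):
        cell = UnitCell(10, 10, 12, 90, 90, 90)
        arr, _ = merging.unique_reflection_set(cell, "P41", 50.0, 2.0)
        l_axis = arr[(arr[:, 0] == 0) & (arr[:, 1] == 0)]
        assert np.all(l_axis[:, 2] % 4 == 0)


class TestMergeAndStats:
    def test_merge_counts_and_rejections(self):
        rng = np.random.default_rng(9)
        group1 = np.concatenate([rng.normal(10.0, 0.5, 15), [30.0]])
        i = np.concatenate([group1, [5.0, 50.0]])
        reduced = np.array([[1, 0, 0]] * 16 + [[2, 0, 0]] * 2)
        s = np.ones(18)
        ds = merging.merge(reduced, i, s, "P1", UnitCell(10, 10, 10, 90, 90, 90))
        row1 = ds.table[ds.table.h == 1].iloc[0]
        assert row1.n_rej == 1 and row1.n_obs == 15  # the 30 is clipped
        row2 = ds.table[ds.table.h == 2].iloc[0]
        assert row2.n_rej == 0 and row2.n_obs == 2  # pairs never clipped

    def test_complete_single_observation_dataset(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        miller, _ = merging.unique_reflection_set(cell, "P1", 20.0, 4.0)
        table = pd.DataFrame({
            "h": miller[:, 0], "k": miller[:, 1], "l": miller[:, 2],
            "I": 1.0, "sigma": 0.1, "n_obs": 1, "n_rej": 0,
        })
        ds = merging.MergedDataset(table, "P1", cell, d_max=20.0, d_min=4.0)
        stats = merging.merging_stats(ds, n_shells=4)
        overall = stats.iloc[-1]
        assert overall.completeness == pytest.approx(1.0)
        assert overall.multiplicity == pytest.approx(1.0)
        assert (stats.completeness[:-1] == 1.0).all()

    def test_empty_shell_reports_zero(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        table = pd.DataFrame({"h": [1], "k": [0], "l": [0],
                              "I": [5.0], "sigma": [0.5], "n_obs": [2], "n_rej": [0]})
        ds = merging.MergedDataset(table, "P1", cell, d_max=20.0, d_min=2.0)
        stats = merging.merging_stats(ds, n_shells=5)
        empty = stats.iloc[:-1][stats.iloc[:-1].n_measured == 0]
        assert len(empty) > 0
        assert (empty.completeness == 0.0).all()
        assert (empty.multiplicity == 0.0).all()


class TestInitialReference:
    def _frame_pair(self):
        miller, i_true = simulate.simulate_reference(
            cell=UnitCell(20, 20, 15, 90, 90, 120), space_group="P6",
            d_min=3.0, seed=13)
        frames, gt = simulate.simulate_frames(
            miller, i_true, n_frames=1, cell=UnitCell(20, 20, 15, 90, 90, 120),
            space_group="P6", d_min=3.0,
            noise=simulate.NoiseModel(enabled=False), seed=13, fx=1.0, min_obs=5)
        return frames[0], gt

    def test_doubled_frame_scaled_back(self):
        # two frames with identical reflection lists, B twice as bright:
        # scales are (1, 1/2) up to normalization, so the merge equals
        # frame A's corrected values
        frame, gt = self._frame_pair()
        import copy

        cfg = refinement.RefinementConfig()
        model = refinement.initial_frame_model(frame, cfg)
        refinement._apply_polarization_to_frames([frame], [model], cfg)
        frame_b = copy.deepcopy(frame)
        frame_b.frame_id = "b"
        frame_b.obs.intensity = 2.0 * frame.obs.intensity
        frame_b.obs.sigma = 2.0 * frame.obs.sigma
        frame_b.reduced = None
        crit = merging.SelectionCriteria(min_eoc=0.0)
        ref_pair = merging.initial_reference([frame, frame_b], [model, model], crit)
        ref_single = merging.initial_reference([frame], [model], crit)
        # pair reference = single reference up to the global mean normalization
        ratio = ref_pair.i_ref / ref_single.i_ref
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_single_frame_reference_is_its_corrected_observations(self):
        from stillpost.partiality import predict_reflections

        frame, gt = self._frame_pair()
        cfg = refinement.RefinementConfig()
        model = refinement.initial_frame_model(frame, cfg)
        refinement._apply_polarization_to_frames([frame], [model], cfg)
        crit = merging.SelectionCriteria(min_eoc=0.0)
        ref = merging.initial_reference([frame], [model], crit)
        pred = predict_reflections(frame, model)
        corrected = pred.vc * frame.obs.intensity / pred.eoc
        # every reference intensity appears among the corrected observations
        # (indices with one observation) or between min and max (merged)
        red = merging.reduce_miller(frame.space_group, frame.obs.miller)
        for hkl, iv in zip(ref.miller, ref.i_ref):
            mask = (red == hkl).all(axis=1)
            assert mask.any()
            assert corrected[mask].min() - 1e-9 <= iv <= corrected[mask].max() + 1e-9

    def test_no_passing_frame_aborts(self):
        frame, _ = self._frame_pair()
        cfg = refinement.RefinementConfig()
        model = refinement.initial_frame_model(frame, cfg)
        crit = merging.SelectionCriteria(min_i_over_sigma=1e9)
        with pytest.raises(ValueError):
            merging.initial_reference([frame], [model], crit)
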