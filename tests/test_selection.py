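import numpy as np
import pytest

from maxenm.maxent import ALLOWED_COMBOS, FeatureConfig
from maxenm.selection import (
    CalibrationGrid,
    CandidateResult,
    aicc,
    apply_selection,
    best_candidate,
    bootstrap_ensemble,
    enumerate_rm_values,
    jackknife_sets_for_grid,
    jackknife_variable_sets,
    omission_rate,
    partial_roc,
    run_calibration,
)


class TestRmGrid:
    def test_endpoints(self):
        vals = enumerate_rm_values()
        assert vals[:2] == [0.1, 0.2]
        assert vals[-2:] == [15.0, 20.0]

    def test_overlapping_range_values_appear_once(self):
        vals = enumerate_rm_values()
        assert vals.count(1.0) == 1 and vals.count(10.0) == 1

    def test_cardinality_matches_brute_force_enumeration(self):
        brute = set()
        for lo, hi, step in [(0.1, 1.0, 0.1), (1.0, 6.0, 1.0), (8.0, 10.0, 2.0), (10.0, 20.0, 5.0)]:
            x = lo
            while x <= hi + 1e-9:
                brute.add(round(x, 10))
                x += step
        assert len(enumerate_rm_values()) == len(brute) == 19


class TestPartialRoc:
    def _landscape(self):
        return np.random.default_rng(0).uniform(0, 1, 4000)

    def test_perfect_model_always_beats_random(self):
        land = self._landscape()
        ev = np.full(30, land.max())
        ratio, p = partial_roc(ev, land, seed=1)
        assert p == 0.0 and ratio > 1.0

    def test_null_model_ratio_near_one_p_large(self):
        land = self._landscape()
        rng = np.random.default_rng(2)
        ev = rng.choice(land, 200, replace=True)
        ratio, p = partial_roc(ev, land, seed=3)
        assert abs(ratio - 1.0) < 0.05
        assert p > 0.1

    def test_constant_landscape_undefined(self):
        with pytest.raises(ValueError):
            partial_roc(np.linspace(0, 1, 10), np.full(100, 0.4))

    def test_too_few_evaluation_points_rejected(self):
        with pytest.raises(ValueError):
            partial_roc(np.array([0.5, 0.6]), self._landscape())

    def test_seeded_reproducibility(self):
        land = self._landscape()
        ev = np.random.default_rng(4).choice(land, 40)
        assert partial_roc(ev, land, seed=5) == partial_roc(ev, land, seed=5)


class TestOmission:
    def test_constructed_threshold_count(self):
        ev = np.arange(0.1, 1.01, 0.1)
        cal = np.array([0.35, 0.35])  # quantile at any e is 0.35
        assert omission_rate(cal, ev, 0.5) == pytest.approx(0.3)

    def test_self_omission_near_e(self):
        rng = np.random.default_rng(6)
        cal = rng.uniform(0, 1, 200)
        rate = omission_rate(cal, cal, 0.05)
        assert abs(rate - 0.05) <= 1.0 / 200 + 1e-12


class TestAicc:
    def test_hand_computed_formula(self):
        raw = np.array([0.02, 0.05, 0.1, 0.2, 0.01, 0.03, 0.04, 0.15, 0.25, 0.15])
        k, n = 3, 10
        lnl = np.sum(np.log(raw))
        expected = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(raw, k, n) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_denominator_unrankable(self):
        assert np.isnan(aicc(np.array([0.1] * 5), k=4, n=5))

    def test_nonpositive_raw_rejected(self):
        with pytest.raises(ValueError):
            aicc(np.array([0.1, 0.0]), 1, 10)


def _cand(i, p, om, a, k=3):
    return CandidateResult(
        candidate_id=f"c{i}", features="lq", rm=1.0, variable_set="s",
        proc_p=p, mean_auc_ratio=1.5, omission_rate=om, aicc=a,
        delta_aicc=float("nan"), k=k,
    )


class TestSelectionFilters:
    def test_hand_filtered_ten_candidate_table(self):
        table = [
            _cand(0, 0.00, 0.05, 100.0),   # selected (min aicc among survivors)
            _cand(1, 0.00, 0.05, 101.5),   # selected (within 2)
            _cand(2, 0.00, 0.05, 103.0),   # survivor, aicc too high
            _cand(3, 0.20, 0.05, 90.0),    # non-significant
            _cand(4, 0.00, 0.30, 80.0),    # high omission
            _cand(5, 0.05, 0.08, 150.0),   # survivor, high aicc
            _cand(6, 0.15, 0.30, 70.0),    # fails both
            _cand(7, 0.10, 0.10, 102.0),   # boundary p and omission: survivor, selected
            _cand(8, 0.00, 0.05, float("nan"), k=3),  # unrankable
            _cand(9, 0.00, 0.11, 99.0),    # omission just over
        ]
        table[8].unrankable = True
        apply_selection(table)
        assert [r.candidate_id for r in table if r.selected] == ["c0", "c1", "c7"]
        # delta against the global minimum is nonnegative everywhere
        assert all(r.delta_aicc >= 0 for r in table if np.isfinite(r.delta_aicc))

    def test_selection_order_invariant(self):
        rng = np.random.default_rng(7)
        table = [_cand(i, rng.uniform(0, 0.2), rng.uniform(0, 0.2), rng.uniform(90, 110)) for i in range(20)]
        apply_selection(table)
        chosen = {r.candidate_id for r in table if r.selected}
        shuffled = list(table)
        rng.shuffle(shuffled)
        apply_selection(shuffled)
        assert {r.candidate_id for r in shuffled if r.selected} == chosen

    def test_zero_survivors_empty_selection(self):
        table = [_cand(i, 0.9, 0.5, 100.0) for i in range(4)]
        apply_selection(table)
        assert not any(r.selected for r in table)
        assert best_candidate(table) is None

    def test_parsimony_tie_break(self):
        a = _cand(0, 0.0, 0.0, 100.0, k=8)
        b = _cand(1, 0.0, 0.0, 100.5, k=2)
        apply_selection([a, b])
        assert a.selected and b.selected
        assert best_candidate([a, b]).candidate_id == "c1"


class TestJackknife:
    def test_single_variable_returned_unchanged(self, calibration_data):
        d = calibration_data
        rep = jackknife_variable_sets(
            d["cal"], d["stack"], d["area"], exclude=[n for n in d["names"] if n != "BIO_1"]
        )
        assert len(rep.steps) == 1
        assert rep.steps[0].variables == ["BIO_1"]

    def test_sets_strictly_nested_and_shrinking(self, calibration_data):
        d = calibration_data
        rep = jackknife_variable_sets(d["cal"], d["stack"], d["area"], max_steps=4, seed=1)
        for a, b in zip(rep.steps, rep.steps[1:]):
            assert set(b.variables) < set(a.variables)
        sets = jackknife_sets_for_grid(rep)
        assert len(sets) == 3

    def test_informative_variable_survives(self, calibration_data):
        d = calibration_data
        rep = jackknife_variable_sets(d["cal"], d["stack"], d["area"], max_steps=4, seed=2)
        final = rep.steps[-1].surviving
        assert "BIO_1" in final  # the strong linear driver of the virtual species

    def test_apriori_exclusion_count(self):
        # 19-layer stack minus the four mixed layers -> 15 enter step 1
        from maxenm.occurrences import build_M, spatial_thin
        from maxenm.synthetic import ClimateSimConfig, VirtualSpeciesConfig, generate_climate_stack, sample_occurrences, true_suitability

        stack = generate_climate_stack(ClimateSimConfig(grid_rows=30, grid_cols=30, n_layers=19, seed=3))
        vs = VirtualSpeciesConfig(true_coefficients={"BIO_1": (2.0, 0.0)}, n_presences=60, sampling_seed=4)
        occ = sample_occurrences(true_suitability(stack, vs), stack.grid, vs)
        occ = spatial_thin(occ, 10.0, seed=5)
        area = build_M(occ, stack, 3.0)
        rep = jackknife_variable_sets(
            occ, stack, area, max_steps=1, exclude=["BIO_8", "BIO_9", "BIO_18", "BIO_19"]
        )
        assert len(rep.steps[0].variables) == 15


class TestCalibrationRun:
    def test_candidate_count_and_selection(self, calibration_data):
        d = calibration_data
        grid = CalibrationGrid(
            variable_sets={"s1": d["names"][:3], "s2": d["names"][:2]},
            rm_values=[0.5, 1.0],
            feature_combos=(("L",), ("L", "Q")),
        )
        res = run_calibration(
            grid, d["cal"], d["ev"], d["stack"], seed=8, area=d["area"],
            max_background=800, proc_iterations=100,
        )
        assert len(res) == grid.n_candidates == 8
        assert any(r.selected for r in res)
        # every finite AICc agrees with the direct formula on its inputs
        for r in res:
            assert 0.0 <= r.omission_rate <= 1.0

    def test_single_cell_grid_selects_good_candidate(self, calibration_data):
        d = calibration_data
        grid = CalibrationGrid(
            variable_sets={"s1": d["names"][:2]}, rm_values=[1.0], feature_combos=(("L", "Q"),)
        )
        res = run_calibration(
            grid, d["cal"], d["ev"], d["stack"], seed=9, area=d["area"],
            max_background=800, proc_iterations=100,
        )
        assert len(res) == 1
        r = res[0]
        if r.passed_significance and r.passed_omission:
            assert r.selected

    def test_rerun_is_deterministic(self, calibration_data):
        d = calibration_data
        grid = CalibrationGrid(
            variable_sets={"s1": d["names"][:2]}, rm_values=[0.5], feature_combos=(("L",),)
        )
        kw = dict(seed=10, area=d["area"], max_background=500, proc_iterations=100)
        r1 = run_calibration(grid, d["cal"], d["ev"], d["stack"], **kw)[0]
        r2 = run_calibration(grid, d["cal"], d["ev"], d["stack"], **kw)[0]
        assert (r1.proc_p, r1.mean_auc_ratio, r1.omission_rate, r1.aicc) == (
            r2.proc_p, r2.mean_auc_ratio, r2.omission_rate, r2.aicc
        )


class TestBootstrap:
    def test_single_replicate_range_zero(self, calibration_data):
        d = calibration_data
        ens = bootstrap_ensemble(
            d["names"][:2], FeatureConfig(classes=("L",)), 1.0,
            d["cal"], d["stack"], d["area"], n_replicates=1, max_background=500, seed=11,
        )
        assert np.nanmax(ens.range_) == 0.0

    def test_median_within_min_max(self, calibration_data):
        d = calibration_data
        ens = bootstrap_ensemble(
            d["names"][:2], FeatureConfig(classes=("L", "Q")), 1.0,
            d["cal"], d["stack"], d["area"], n_replicates=4, max_background=500, seed=12,
        )
        cube = np.stack([m.predict_logistic(d["stack"].subset(d["names"][:2])) for m in ens.models])
        lo, hi = np.nanmin(cube, 0), np.nanmax(cube, 0)
        ok = np.isfinite(ens.median)
        assert np.all(ens.median[ok] >= lo[ok] - 1e-12)
        assert np.all(ens.median[ok] <= hi[ok] + 1e-12)

    def test_fixed_seed_bit_identical(self, calibration_data):
        d = calibration_data
        kw = dict(n_replicates=2, max_background=500, seed=13)
        e1 = bootstrap_ensemble(d["names"][:2], FeatureConfig(classes=("L",)), 1.0, d["cal"], d["stack"], d["area"], **kw)
        e2 = bootstrap_ensemble(d["names"][:2], FeatureConfig(classes=("L",)), 1.0, d["cal"], d["stack"], d["area"], **kw)
        assert np.array_equal(e1.median, e2.median, equal_nan=True)


def test_proc_null_rejection_rate_controlled():
    """Type-I behaviour: drawing evaluation points from the landscape itself
    should rarely produce a significant partial-ROC result."""
    rng = np.random.default_rng(14)
    land = rng.uniform(0, 1, 2000)
    rejections = 0
    n_sets = 60  # trimmed null ensemble for the unit suite
    for i in range(n_sets):
        ev = rng.choice(land, 100, replace=True)
        _, p = partial_roc(ev, land, n_iterations=200, seed=1000 + i)
        rejections += p <= 0.1
    assert rejections / n_sets <= 0.15
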