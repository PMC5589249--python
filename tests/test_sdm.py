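import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from threatscape import sdm, synthetic
from threatscape.grid import GridLayer, GridSpec


def stack_from(arrays, spec):
    return {name: GridLayer(spec, vals) for name, vals in arrays.items()}


class TestAuc:
    def test_separated_scores_give_one(self):
        assert sdm.auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_identical_constants_give_half(self):
        assert sdm.auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_enumerated_pairs(self):
        # pairs (1,2): loss, (3,2): win -> 0.5
        assert sdm.auc([1, 3], [2]) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sdm.auc([], [1.0])

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=1, max_size=30),
        st.lists(st.floats(0, 1, width=32), min_size=1, max_size=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_complement_symmetry(self, pos, neg):
        assert sdm.auc(pos, neg) + sdm.auc(neg, pos) == pytest.approx(1.0)

    def test_matches_sklearn_roc_auc(self, rng):
        pos = rng.normal(1.0, 1.0, 40)
        neg = rng.normal(0.0, 1.0, 60)
        y = np.concatenate([np.ones(40), np.zeros(60)])
        s = np.concatenate([pos, neg])
        assert sdm.auc(pos, neg) == pytest.approx(roc_auc_score(y, s))


class TestVifStepwise:
    spec = GridSpec(n_rows=40, n_cols=40, cell_size=0.1, origin_lat=10.0)

    def test_independent_variables_all_retained(self, rng):
        env = stack_from(
            {f"x{i}": rng.standard_normal(self.spec.shape) for i in range(5)}, self.spec
        )
        assert sdm.vif_stepwise(env) == [f"x{i}" for i in range(5)]

    def test_duplicated_pair_drops_exactly_one(self, rng):
        a = rng.standard_normal(self.spec.shape)
        env = stack_from(
            {"a": a, "a_copy": a.copy(), "b": rng.standard_normal(self.spec.shape)},
            self.spec,
        )
        kept = sdm.vif_stepwise(env)
        assert "b" in kept
        assert sum(name in kept for name in ("a", "a_copy")) == 1

    def test_near_linear_combination_pruned_below_ceiling(self, rng):
        x1 = rng.standard_normal(self.spec.shape)
        x2 = rng.standard_normal(self.spec.shape)
        x3 = x1 + x2 + 1e-3 * rng.standard_normal(self.spec.shape)
        env = stack_from({"x1": x1, "x2": x2, "x3": x3}, self.spec)
        kept = sdm.vif_stepwise(env, threshold=20.0)
        # brute-force recomputation of retained VIFs
        X = np.column_stack([env[k].values.ravel() for k in kept])
        assert sdm._vif_values(X).max() <= 20.0

    def test_single_variable_rejected(self, rng):
        env = stack_from({"only": rng.standard_normal(self.spec.shape)}, self.spec)
        with pytest.raises(ValueError):
            sdm.vif_stepwise(env)


class TestThresholds:
    def test_minimum_is_min_presence_score(self):
        assert sdm.threshold_min_scores([0.3, 0.5]) == 0.3
        assert sdm.threshold_min_scores([0.4, 0.4, 0.4]) == 0.4

    def test_tpr90_order_statistic(self):
        scores = np.arange(1, 11) / 10.0  # 0.1 .. 1.0
        t = sdm.threshold_tpr90_scores(scores)
        assert t == pytest.approx(0.2)
        assert (scores >= t).mean() == pytest.approx(0.9)

    def test_tpr90_single_score(self):
        assert sdm.threshold_tpr90_scores([0.42]) == 0.42

    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_tpr90_dominates_minimum_and_guarantees_coverage(self, scores):
        arr = np.asarray(scores)
        t90 = sdm.threshold_tpr90_scores(arr)
        tmin = sdm.threshold_min_scores(arr)
        assert t90 >= tmin
        assert (arr >= t90).mean() >= 0.90
        assert (arr >= tmin).mean() == 1.0


class TestDetectNovel:
    spec = GridSpec(n_rows=5, n_cols=5, cell_size=0.2, origin_lat=5.0)

    def make_stacks(self, rng):
        cur = stack_from(
            {"BIO1": rng.uniform(20, 30, self.spec.shape),
             "BIO12": rng.uniform(500, 1000, self.spec.shape)},
            self.spec,
        )
        fut = {k: GridLayer(self.spec, v.values.copy()) for k, v in cur.items()}
        return cur, fut

    def test_identical_future_has_no_novel_cells(self, rng):
        cur, fut = self.make_stacks(rng)
        out = sdm.detect_novel(cur, fut, ["BIO1", "BIO12"])
        assert out.values.sum() == 0

    def test_single_raised_cell_is_the_only_novel_one(self, rng):
        cur, fut = self.make_stacks(rng)
        fut["BIO1"].values[2, 3] = cur["BIO1"].values.max() + 1.0
        out = sdm.detect_novel(cur, fut, ["BIO1", "BIO12"])
        assert out.values[2, 3] == 1.0
        assert out.values.sum() == 1.0

    def test_value_at_current_max_is_not_novel(self, rng):
        cur, fut = self.make_stacks(rng)
        fut["BIO1"].values[:] = cur["BIO1"].values.max()  # closed interval
        out = sdm.detect_novel(cur, fut, ["BIO1", "BIO12"])
        assert out.values.sum() == 0


class TestCalibratedEnsemble:
    """Checks on the shared default-configuration calibration."""

    def test_rejects_too_few_unique_presences(self, climate):
        spec = climate["current"]["BIO1"].spec
        rng = np.random.default_rng(0)
        rows = rng.choice(spec.n_rows, 29, replace=False)
        cols = rng.choice(spec.n_cols, 29, replace=False)
        occ = pd.DataFrame({
            "lon": spec.cell_center_lons()[cols],
            "lat": spec.cell_center_lats()[rows],
        })
        with pytest.raises(sdm.SpeciesRejected, match="30 unique"):
            sdm.calibrate_ensemble(occ, climate["current"], seed=0)

    def test_exactly_ten_weights_summing_to_one(self, calibrated_model):
        w = calibrated_model.weights
        assert len(w) == 10
        assert all(v > 0 for v in w.values())
        assert sum(w.values()) == pytest.approx(1.0)

    def test_kept_candidates_discriminate(self, calibrated_model):
        for cand in calibrated_model.weights:
            assert calibrated_model.candidate_aucs[cand] > 0.5

    def test_suitability_recovery(self, calibrated_model, niche, climate):
        truth = niche.suitability(climate["current"])
        rho = spearmanr(
            truth.masked_values(), calibrated_model.suitability.masked_values()
        ).statistic
        assert rho >= 0.8

    def test_threshold_coverage_guarantees(self, calibrated_model):
        m = calibrated_model
        pres_min = sdm.predict_presence(m, which_threshold="minimum")
        pres_90 = sdm.predict_presence(m, which_threshold="tpr90")
        cov_min = pres_min.values[m.presence_rows, m.presence_cols].mean()
        cov_90 = pres_90.values[m.presence_rows, m.presence_cols].mean()
        assert cov_min == 1.0
        assert cov_90 >= 0.90
        assert m.threshold_tpr90 >= m.threshold_min

    def test_projection_missing_variable_named(self, calibrated_model, climate):
        partial = {
            k: v for k, v in climate["rcp45"].items()
            if k != calibrated_model.retained_variables[0]
        }
        with pytest.raises(KeyError, match=calibrated_model.retained_variables[0]):
            sdm.project_suitability(calibrated_model, partial)

    def test_projection_on_calibration_stack_reproduces_surface(
        self, calibrated_model, climate
    ):
        reproj = sdm.project_suitability(calibrated_model, climate["current"])
        np.testing.assert_allclose(
            reproj.values, calibrated_model.suitability.values, atol=1e-10
        )

    def test_report_lists_all_candidates(self, calibrated_model):
        report = calibrated_model.report()
        assert len(report) == 12
        assert report["weight"].sum() == pytest.approx(1.0)


class TestShuffledLabels:
    def test_shuffled_niche_auc_near_half(self, climate):
        """Occurrences placed uniformly at random carry no signal: the mean
        candidate test AUC should sit at the permutation-null value 0.5."""
        spec = climate["current"]["BIO1"].spec
        rng = np.random.default_rng(9)
        idx = rng.choice(spec.n_rows * spec.n_cols, 120, replace=False)
        rows, cols = np.unravel_index(idx, spec.shape)
        occ = pd.DataFrame({
            "lon": spec.cell_center_lons()[cols],
            "lat": spec.cell_center_lats()[rows],
        })
        model = sdm.calibrate_ensemble(
            occ, climate["current"], n_repeats=2, seed=10
        )
        aucs = np.array(list(model.candidate_aucs.values()))
        assert abs(aucs.mean() - 0.5) < 0.08
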