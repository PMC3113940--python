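"""Dataset filtering, parameter fitting, cross-validation and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabscan.predictor import ModelParameters, N_COEFFICIENTS
from stabscan.synthetic import simulate_mutant_dataset
from stabscan.training import (CVResult, DesignMatrix, MutantRecord,
                               baselines, binned_rmse, build_design,
                               cross_validate, evaluate, filter_dataset,
                               fit_parameters, model_predictions,
                               read_mutant_table, reduce_parameters,
                               retrain_without_training_outliers,
                               shuffle_baseline_distribution,
                               stabilizing_specificity, write_mutant_table)


def _rec(**kw):
    base = dict(structure_id="s", chain="A", seq_number="1", s_w="L",
                s_m="V", ddg_M=1.0, flags=())
    base.update(kw)
    return MutantRecord(**base)


class TestFilter:
    @pytest.mark.parametrize("record,kept,rule", [
        (_rec(ddg_M=5.1), False, "ddg_above_cutoff"),
        (_rec(ddg_M=5.0), True, None),
        (_rec(s_w="A", s_m="P"), False, "proline"),
        (_rec(s_w="P", s_m="A"), False, "proline"),
        (_rec(ddg_M=-1.0), True, None),
        (_rec(flags=("heme_protein",)), False, "flagged"),
        (_rec(flags=("pseudo_wild_type",)), False, "flagged"),
    ])
    def test_rules(self, record, kept, rule):
        retained, report = filter_dataset([record])
        assert (len(retained) == 1) == kept
        if rule:
            assert report[rule] == 1

    def test_table_round_trip(self, tmp_path):
        records = [_rec(), _rec(seq_number="2", s_m="I", ddg_M=-0.75,
                                flags=("heme_protein",))]
        path = tmp_path / "muts.tsv"
        write_mutant_table(records, path)
        assert read_mutant_table(path) == records


class TestEvaluate:
    def test_identical_vectors(self):
        out = evaluate(np.arange(5.0), np.arange(5.0))
        assert out["R"] == pytest.approx(1.0) and out["sigma"] == 0.0

    def test_perfect_linearity(self):
        assert evaluate([0, 1, 2], [0, 2, 4])["R"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        out = evaluate([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert out["R"] is None and out["zero_variance"]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 1000))
    def test_trimming_never_increases_sigma(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.normal(0, 2, 40)
        meas = pred + rng.normal(0, 1, 40)
        full = evaluate(pred, meas)["sigma"]
        trimmed = evaluate(pred, meas, trim_fraction=0.10)["sigma"]
        assert trimmed <= full + 1e-12

    def test_trim_count(self):
        out = evaluate(np.zeros(10) + np.arange(10), np.zeros(10),
                       trim_fraction=0.10)
        assert out["n_used"] == 9


class TestBinnedRmse:
    def test_single_bin_equals_global(self):
        pred = np.array([0.01, 0.1, 0.2, 0.24])
        meas = pred + np.array([0.5, -0.5, 0.3, -0.1])
        df = binned_rmse(pred, meas, min_count=1)
        assert len(df) == 1
        assert df.iloc[0]["sigma"] == pytest.approx(
            evaluate(pred, meas)["sigma"])

    def test_small_bin_dismissed(self):
        pred = np.concatenate([np.full(9, 0.1), np.full(12, 1.1)])
        meas = pred + 0.2
        df = binned_rmse(pred, meas, min_count=10)
        assert df[df["bin_left"] == 0.0].iloc[0]["retained"] == False  # noqa: E712
        assert df[df["bin_left"] == 1.0].iloc[0]["retained"] == True   # noqa: E712

    def test_bins_partition_all_pairs(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(0, 2, 200)
        meas = rng.normal(0, 2, 200)
        df = binned_rmse(pred, meas, axis="measured")
        assert df["n"].sum() == 200


class TestSpecificity:
    def test_constructed_seven_of_ten(self):
        pred = np.array([-1.0] * 10 + [0.5] * 5)
        meas = np.array([-0.5] * 7 + [0.5] * 3 + [1.0] * 5)
        out = stabilizing_specificity(pred, meas, pred_threshold=-0.5)
        assert out["fraction"] == pytest.approx(0.7)
        assert out["n_selected"] == 10

    def test_all_correct_sign(self):
        out = stabilizing_specificity([-1.0, -2.0, 1.0], [-0.1, -0.2, 0.3],
                                      pred_threshold=-0.5)
        assert out["fraction"] == 1.0

    def test_undefined_below_range(self):
        out = stabilizing_specificity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                      pred_threshold=-10.0)
        assert out["undefined"] and out["fraction"] is None


class TestBaselines:
    def test_constant_mean_sigma_is_population_std(self):
        rng = np.random.default_rng(2)
        y = rng.normal(1.0, 1.5, 300)
        out = baselines(y, seed=0)
        assert out["constant_mean"]["sigma"] == np.std(y)

    def test_shuffle_reproducible(self):
        y = np.random.default_rng(3).normal(0, 1, 50)
        assert baselines(y, seed=7) == baselines(y, seed=7)

    def test_shuffle_null_centred(self):
        y = np.random.default_rng(4).normal(1.0, 1.2, 500)
        rs = shuffle_baseline_distribution(y, n_seeds=200, seed=0)
        assert abs(rs.mean()) < 0.05


@pytest.fixture(scope="module")
def fit600(noisy_design):
    return fit_parameters(noisy_design, init_seed=5, restarts=3)


class TestFit:
    def test_single_record_fit_exact(self, noisy_design):
        one = noisy_design.subset(np.array([0]))
        fit = fit_parameters(one, init_seed=0, restarts=2)
        assert fit.sigma_train < 1e-6

    def test_sigma_matches_recomputation(self, noisy_design, fit600):
        from stabscan.training import sigma_of
        assert fit600.sigma_train == pytest.approx(
            sigma_of(fit600.params, noisy_design), abs=1e-9)

    def test_history_nonincreasing(self, fit600):
        assert all(b <= a + 1e-15 for a, b in
                   zip(fit600.history, fit600.history[1:]))

    def test_noise_floor(self, fit600):
        # generator noise sd is 0.3; with 600 records and 64 parameters the
        # training RMSE sits just below it
        assert 0.20 <= fit600.sigma_train <= 0.35

    def test_deterministic_given_seed(self, noisy_design):
        sub = noisy_design.subset(np.arange(150))
        f1 = fit_parameters(sub, init_seed=9, restarts=2)
        f2 = fit_parameters(sub, init_seed=9, restarts=2)
        assert np.array_equal(f1.params.theta, f2.params.theta)

    def test_model_archive_round_trip(self, fit600, tmp_path):
        path = tmp_path / "model.json"
        fit600.params.save(path)
        back = ModelParameters.load(path)
        assert np.array_equal(back.theta, fit600.params.theta)
        assert np.array_equal(back.active, fit600.params.active)


class TestReduce:
    def test_infinite_threshold_is_identity(self, noisy_design, fit600):
        red = reduce_parameters(noisy_design, fit600, cv_threshold=np.inf)
        assert np.array_equal(red.params.active, fit600.params.active)

    def test_recovers_constant_coefficients(self):
        """Coefficients truly constant in A get their slope/scale frozen."""
        rng = np.random.default_rng(0)
        n = 400
        theta = np.zeros((N_COEFFICIENTS, 4))
        active = np.zeros((N_COEFFICIENTS, 4), bool)
        truth_rows = {
            0: (20, 0.25, 2.0, 0.5), 1: (40, 0.2, -1.5, 1.0),
            2: (60, 0.15, 1.0, -0.5), 3: (30, 0.3, 1.8, 0.2),
            4: (50, 0.2, -2.0, 0.8), 5: (35, 0.25, 1.2, 0.4),
            6: (30, 0.1, 0.0, 0.8),    # constant in A
            7: (30, 0.1, 0.0, -0.6),   # constant in A
        }
        for i, row in truth_rows.items():
            theta[i] = row
            active[i] = True
        truth = ModelParameters(theta, active)
        X = np.zeros((n, N_COEFFICIENTS))
        X[:, :8] = rng.normal(0, 1, (n, 8))
        A = rng.uniform(0, 100, n)
        y = (truth.coefficients(A) * X).sum(1) + rng.normal(0, 0.3, n)
        design = DesignMatrix(X, A, y)
        fit = fit_parameters(design, init_seed=1, restarts=4, init=truth,
                             active=active)
        red = reduce_parameters(design, fit, n_resamples=8, cv_threshold=1.0,
                                seed=0)
        assert red.params.n_active < fit.params.n_active
        frozen = active & ~red.params.active
        # only slots of the constant coefficients are frozen, and for both of
        # them the unidentifiable slope and scale go
        assert frozen[:6].sum() == 0
        for i in (6, 7):
            assert frozen[i, 1] and frozen[i, 2]   # r and f


@pytest.fixture(scope="module")
def cv300(noisy_design):
    return cross_validate(noisy_design.subset(np.arange(300)), k=3, seed=4,
                          restarts=2)


class TestCrossValidate:
    def test_exact_partition(self, cv300):
        counts = np.bincount(cv300.fold_of, minlength=cv300.k)
        assert counts.sum() == 300
        assert counts.min() >= 2

    def test_requires_k_at_least_2(self, noisy_design):
        with pytest.raises(ValueError):
            cross_validate(noisy_design, k=1)

    def test_tiny_folds_rejected(self, noisy_design):
        with pytest.raises(ValueError):
            cross_validate(noisy_design.subset(np.arange(5)), k=5)

    def test_zero_noise_recovery(self, truth):
        data = simulate_mutant_dataset(truth, n_mutants=300, seed=31,
                                       noise_sd=0.0)
        design = build_design(data.records, truth.structures, truth.potentials)
        cv = cross_validate(design, k=5, seed=0, restarts=2)
        assert cv.averages["R_c"] >= 0.999

    def test_train_error_below_validation_on_average(self, noisy_design):
        gaps = []
        for seed in range(5):
            cv = cross_validate(noisy_design.subset(np.arange(250)), k=3,
                                seed=seed, restarts=1)
            gaps.append(cv.averages["sigma_c"] - cv.averages["sigma_d"])
        assert np.mean(gaps) >= 0.0

    def test_validation_error_monotone_in_noise(self, truth):
        sigmas = []
        for noise in (1.0, 0.5, 0.1):
            data = simulate_mutant_dataset(truth, n_mutants=250, seed=41,
                                           noise_sd=noise)
            design = build_design(data.records, truth.structures,
                                  truth.potentials)
            cv = cross_validate(design, k=3, seed=1, restarts=1)
            sigmas.append(cv.averages["sigma_c"])
        assert sigmas[0] > sigmas[1] > sigmas[2]


class TestRetrain:
    def test_infinite_cutoff_identity(self, cv300):
        out = retrain_without_training_outliers(cv300, cutoff=np.inf)
        assert out["n_outliers"] == 0
        for key in ("R_c", "sigma_c"):
            assert out["averages"][key] == pytest.approx(
                cv300.averages[key], abs=1e-12)

    def test_outliers_are_intersection_over_runs(self, cv300):
        cutoff = 0.4   # low cutoff so the set is non-trivial
        out = retrain_without_training_outliers(cv300, cutoff=cutoff)
        err = np.abs(cv300.run_predictions - cv300.design.y[None, :])
        expected = set(np.flatnonzero((err > cutoff).all(axis=0)).tolist())
        assert set(out["outlier_indices"].tolist()) == expected

    def test_validation_sizes_unchanged(self, cv300):
        out = retrain_without_training_outliers(cv300, cutoff=0.4)
        for f_new, f_old in zip(out["folds"], cv300.folds):
            assert f_new["n_val"] == f_old["n_val"]
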