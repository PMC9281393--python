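import numpy as np
import pytest

from ghbfit import (
    N_TYPES,
    Observable,
    POPULATION,
    ParamVector,
    RegSpec,
    SplitError,
    SystemEnsemble,
    chi2_system,
    cross_validate,
    cv_split,
    fit,
    manual_override,
    select_model,
    total_cost,
)
from ghbfit.fitting import CVCurve, best_alpha_index


def _pop_system(rng, n_frames=300, name="pop"):
    features = np.zeros((n_frames, N_TYPES))
    features[:, 0] = rng.binomial(3, 0.5, n_frames)
    ind = (rng.random(n_frames) < 0.4).astype(float)
    obs = [Observable("p", POPULATION, ind, 0.4, 0.05, "population")]
    return SystemEnsemble(name=name, features=features, prior=np.full(n_frames, 1 / n_frames),
                          observables=obs)


class TestFit:
    def test_huge_l2_pins_to_reference(self, small_suite):
        systems, truth = small_suite
        res = fit(systems, RegSpec("L2", 1e6), truth["params0"], seed=0, n_restarts=2)
        assert np.abs(res.lam_hat - truth["params0"].lam0).max() < 1e-3

    def test_infeasible_target_clips_to_box_face(self, rng):
        # two frames, one active type; matching the target needs lambda = ln 99,
        # far outside the box, so the fit must end on a face
        features = np.zeros((2, N_TYPES))
        features[0, 3] = 1.0
        sys = SystemEnsemble(
            name="face", features=features, prior=np.array([0.5, 0.5]),
            observables=[Observable("p", POPULATION, np.array([1.0, 0.0]), 0.99, 0.01, "population")],
        )
        pv = ParamVector(np.zeros(N_TYPES), lam_max=1.0)
        res = fit([sys], None, pv, seed=0, n_restarts=2)
        assert res.lam_hat[3] == pytest.approx(1.0, abs=1e-6)  # active constraint

    def test_never_loses_to_reference_point(self, small_suite):
        systems, truth = small_suite
        pv = truth["params0"]
        spec = RegSpec("REL_ENTROPY", 2.0)
        res = fit(systems, spec, pv, seed=3, n_restarts=3)
        from ghbfit import regularized_cost

        assert res.cost_train <= regularized_cost(systems, pv, spec) + 1e-12

    def test_deterministic_given_seed(self, small_suite):
        systems, truth = small_suite
        a = fit(systems, RegSpec("L2", 0.1), truth["params0"], seed=42, n_restarts=3)
        b = fit(systems, RegSpec("L2", 0.1), truth["params0"], seed=42, n_restarts=3)
        assert np.array_equal(a.lam_hat, b.lam_hat)
        assert a.cost_train == b.cost_train


class TestCvSplit:
    def test_segments_counts(self, rng):
        sys = _pop_system(rng, n_frames=10)
        folds = cv_split([sys], "SEGMENTS", n_segments=5)
        assert len(folds) == 5
        for train, val in folds:
            assert val[0].n_frames == 2
            assert train[0].n_frames == 8
        # folds exhaust the data
        total = sum(v[0].n_frames for _, v in folds)
        assert total == 10

    def test_observables_counts(self, small_suite):
        systems, _ = small_suite
        folds = cv_split(systems, "OBSERVABLES")
        assert len(folds) == 7  # 5 tetramer NMR groups + 2 tetraloop populations

    def test_systems_counts(self, small_suite):
        systems, _ = small_suite
        folds = cv_split(systems, "SYSTEMS")
        assert len(folds) == 3
        for train, val in folds:
            assert len(train) == 2 and len(val) == 1

    def test_too_few_inputs(self, rng):
        sys = _pop_system(rng, n_frames=3)
        with pytest.raises(SplitError):
            cv_split([sys], "SEGMENTS", n_segments=5)
        with pytest.raises(SplitError):
            cv_split([sys], "SYSTEMS")
        with pytest.raises(SplitError):
            cv_split([sys], "OBSERVABLES")


class TestCrossValidate:
    def test_single_alpha_grid(self, rng):
        sys = _pop_system(rng)
        curve = cross_validate([sys], "L2", [0.5], "SEGMENTS", ParamVector(np.zeros(N_TYPES)), seed=0)
        assert curve.best_alpha == 0.5
        assert curve.fold_val_errors.shape == (1, 5)

    def test_reproducible_bit_for_bit(self, rng):
        sys = _pop_system(rng)
        pv = ParamVector(np.zeros(N_TYPES))
        a = cross_validate([sys], "L2", [0.01, 1.0], "SEGMENTS", pv, seed=9)
        b = cross_validate([sys], "L2", [0.01, 1.0], "SEGMENTS", pv, seed=9)
        assert np.array_equal(a.val_error, b.val_error)
        assert np.array_equal(a.fold_val_errors, b.fold_val_errors)

    def test_tie_break_toward_larger_alpha(self):
        assert best_alpha_index([3.0, 1.0, 1.0, 2.0]) == 2
        assert best_alpha_index([1.0, 1.0]) == 1
        assert best_alpha_index([2.0, 1.0]) == 1

    def test_segments_no_significant_overfitting(self):
        """With ample frames the segment-CV validation curve is nearly flat at
        small alpha: the gap to its minimum is tiny on the scale of the
        reference-parameter error (median over seeds)."""
        from ghbfit import make_training_suite

        gaps = []
        for seed in (0, 1, 2):
            systems, truth = make_training_suite(seed=seed, n_frames=8000, noise_scale=1.0)
            pv = truth["params0"]
            curve = cross_validate(
                systems, "L2", np.logspace(-4, 2, 7), "SEGMENTS", pv, seed=0
            )
            reference = total_cost(systems, pv)
            gaps.append(
                (curve.val_error[0] - curve.val_error.min())
                / (reference - curve.val_error.min())
            )
        assert np.median(gaps) < 0.1

    def test_observables_cv_shows_interior_minimum(self):
        """Sparse noisy observables overfit without regularization, so the
        observable-CV error has an interior minimum in alpha."""
        from ghbfit import make_training_suite

        systems, truth = make_training_suite(seed=13, n_frames=2000, noise_scale=1.5)
        curve = cross_validate(
            systems, "REL_KISH", np.logspace(-4, 4, 9), "OBSERVABLES", truth["params0"], seed=0
        )
        assert curve.best_val_error < curve.val_error[0]


class TestSelectModel:
    def test_single_curve_refit(self, rng):
        sys = _pop_system(rng)
        pv = ParamVector(np.zeros(N_TYPES))
        curve = cross_validate([sys], "L2", [0.1, 10.0], "SEGMENTS", pv, seed=0)
        spec, result = select_model([curve], [sys], pv, seed=0, n_restarts=2)
        assert spec.kind == "L2" and spec.alpha == curve.best_alpha
        from ghbfit import regularized_cost

        assert result.cost_train <= regularized_cost([sys], pv, spec) + 1e-12

    def test_dominating_curve_selected(self):
        a = CVCurve("L2", np.array([1.0]), np.array([1.0]), np.array([5.0]),
                    np.array([[5.0]]), np.array([[1.0]]), 1.0)
        b = CVCurve("REL_KISH", np.array([1.0]), np.array([1.0]), np.array([2.0]),
                    np.array([[2.0]]), np.array([[1.0]]), 1.0)
        assert min([a, b], key=lambda c: c.best_val_error).reg_kind == "REL_KISH"


class TestManualOverride:
    def test_empty_set_is_identity(self, small_suite):
        systems, truth = small_suite
        res = fit(systems, RegSpec("L2", 0.5), truth["params0"], seed=0, n_restarts=1)
        same = manual_override(res, systems, RegSpec("L2", 0.5), set())
        assert np.array_equal(same.lam_hat, res.lam_hat)
        assert same.cost_train == pytest.approx(res.cost_train, rel=1e-12)

    def test_zero_inactive_type_leaves_costs_unchanged(self, rng):
        sys = _pop_system(rng)  # only type 0 is active
        pv = ParamVector(np.zeros(N_TYPES))
        res = fit([sys], None, pv, seed=0, n_restarts=1)
        out = manual_override(res, [sys], None, {11})
        assert out.per_system_chi2 == pytest.approx(res.per_system_chi2)

    def test_zero_active_type_changes_and_matches_recompute(self, small_suite):
        systems, truth = small_suite
        res = fit(systems, None, truth["params0"], seed=0, n_restarts=1)
        out = manual_override(res, systems, None, {11})
        assert out.lam_hat[11] == 0.0
        expected = {s.name: chi2_system(s, out.params) for s in systems}
        for name in expected:
            assert out.per_system_chi2[name] == pytest.approx(expected[name], rel=1e-12)
        assert out.per_system_chi2["UUCG_tetraloop"] != pytest.approx(
            res.per_system_chi2["UUCG_tetraloop"]
        )
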