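import numpy as np
import pytest

from ghbfit import (
    ContractError,
    N_TYPES,
    Observable,
    POPULATION,
    ParamVector,
    RegSpec,
    SystemEnsemble,
    chi2_system,
    cost_and_grad,
    cost_gradient,
    regularization_value,
    regularized_cost,
    total_cost,
)
from ghbfit.observables import J_COUPLING, NOE, UNOE


def _toy_system(rng, name="toy", n_frames=30, omega=1.0, uniform_prior=False):
    features = rng.poisson(1.2, size=(n_frames, N_TYPES)).astype(float)
    prior = (
        np.full(n_frames, 1.0 / n_frames)
        if uniform_prior
        else rng.uniform(0.2, 1.0, n_frames)
    )
    obs = [
        Observable("r1", NOE, rng.uniform(2.0, 5.0, n_frames), 3.1, 0.2, "NOE"),
        Observable("u1", UNOE, rng.uniform(2.5, 5.0, n_frames), 2.2, 0.2, "uNOE"),
        Observable(
            "j1", J_COUPLING, rng.uniform(0, np.pi, n_frames), 4.0, 0.5, "backbone1",
            karplus=(9.7, -1.8, 0.0),
        ),
        Observable(
            "p1", POPULATION, (rng.random(n_frames) < 0.4).astype(float), 0.4, 0.05,
            "population",
        ),
    ]
    return SystemEnsemble(name=name, features=features, prior=prior, observables=obs, omega=omega)


@pytest.fixture
def toy(rng):
    return _toy_system(rng)


@pytest.fixture
def params():
    return ParamVector(np.zeros(N_TYPES))


class TestChi2:
    def test_exact_targets_give_zero(self, toy, params):
        from ghbfit.observables import back_calculate

        w = toy.posterior(params.lam)
        for obs in toy.observables:
            obs.exp_value = back_calculate(obs, w)
        assert chi2_system(toy, params) == pytest.approx(0.0, abs=1e-24)

    def test_single_observable_discrepancy_two_gives_four(self, toy, params):
        from ghbfit.observables import back_calculate

        obs = toy.observables[0]
        w = toy.posterior(params.lam)
        obs.exp_value = back_calculate(obs, w) - 2.0 * obs.sigma
        assert chi2_system(toy, params, mask=[0]) == pytest.approx(4.0)

    def test_empty_mask_rejected(self, toy, params):
        with pytest.raises(ContractError):
            chi2_system(toy, params, mask=[])


class TestTotalCost:
    def test_single_system_equals_chi2(self, toy, params):
        assert total_cost([toy], params) == pytest.approx(chi2_system(toy, params))

    def test_duplication_doubles(self, toy, params):
        assert total_cost([toy, toy], params) == pytest.approx(2 * chi2_system(toy, params))

    def test_zero_omega_ignores_system(self, rng, params):
        a = _toy_system(rng, "a")
        b = _toy_system(rng, "b")
        b.omega = 0.0
        assert total_cost([a, b], params) == pytest.approx(chi2_system(a, params))


class TestRegularization:
    def test_l1_l2_zero_at_reference(self, toy, params):
        assert regularization_value(RegSpec("L2", 1.0), params, [toy]) == 0.0
        assert regularization_value(RegSpec("L1", 1.0), params, [toy]) == 0.0

    def test_rel_kish_lse_at_reference_is_one_plus_ln3(self, rng, params):
        systems = [_toy_system(rng, f"s{i}") for i in range(3)]
        val = regularization_value(RegSpec("REL_KISH", 1.0), params, systems)
        assert val == pytest.approx(1 + np.log(3), abs=1e-12)

    def test_unit_perturbation_l1_equals_l2(self, toy):
        lam = np.zeros(N_TYPES)
        lam[5] = 1.0
        p = ParamVector(lam)
        assert regularization_value(RegSpec("L1", 1.0), p, [toy]) == pytest.approx(1.0)
        assert regularization_value(RegSpec("L2", 1.0), p, [toy]) == pytest.approx(1.0)

    def test_regularized_cost_additivity(self, toy, params):
        spec = RegSpec("REL_ENTROPY", 0.37)
        lam = params.with_lam(np.full(N_TYPES, 0.1))
        total = regularized_cost([toy], lam, spec)
        parts = total_cost([toy], lam) + spec.alpha * regularization_value(spec, lam, [toy])
        assert total == pytest.approx(parts, rel=1e-12)
        assert regularized_cost([toy], lam, RegSpec("L2", 0.0)) == pytest.approx(
            total_cost([toy], lam)
        )

    def test_anchored_kinds_minimized_at_reference(self, rng, params):
        """L1/L2/REL_KISH/REL_ENTROPY attain their global minimum at lambda0;
        for KISH with a nonuniform prior the minimizer differs."""
        sys = _toy_system(rng, uniform_prior=False)
        at_ref = {
            k: regularization_value(RegSpec(k, 1.0), params, [sys])
            for k in ("L1", "L2", "REL_KISH", "REL_ENTROPY", "KISH")
        }
        for _ in range(20):
            lam = params.with_lam(rng.normal(0, 0.4, N_TYPES))
            for kind in ("L1", "L2", "REL_KISH", "REL_ENTROPY"):
                assert (
                    regularization_value(RegSpec(kind, 1.0), lam, [sys])
                    >= at_ref[kind] - 1e-10
                )
        # KISH: with a nonuniform prior its gradient at lambda0 is nonzero, so
        # a small step against it lowers the penalty below the lambda0 value
        from ghbfit.objective import _regularization_and_grad

        _, grad = _regularization_and_grad(RegSpec("KISH", 1.0), params, [sys])
        assert np.linalg.norm(grad) > 1e-8
        step = params.with_lam(params.lam0 - 1e-3 * grad / np.linalg.norm(grad))
        assert regularization_value(RegSpec("KISH", 1.0), step, [sys]) < at_ref["KISH"]


class TestFrameDuplication:
    @pytest.mark.parametrize("kind", ["L1", "L2", "REL_KISH", "REL_ENTROPY"])
    def test_invariant_for_prior_relative_kinds(self, rng, kind):
        sys = _toy_system(rng)
        doubled = SystemEnsemble(
            name=sys.name,
            features=np.vstack([sys.features, sys.features]),
            prior=np.concatenate([sys.prior, sys.prior]) / 2,
            observables=[
                Observable(
                    o.name, o.kind, np.concatenate([o.per_frame_values] * 2),
                    o.exp_value, o.sigma, o.group, o.karplus,
                )
                for o in sys.observables
            ],
        )
        p = ParamVector(np.full(N_TYPES, 0.15))
        spec = RegSpec(kind, 0.8)
        assert regularized_cost([sys], p, spec) == pytest.approx(
            regularized_cost([doubled], p, spec), rel=1e-10
        )

    def test_kish_inverse_halves_under_duplication(self, rng):
        # the Kish size counts frames, so duplication doubles it by definition
        sys = _toy_system(rng)
        p = ParamVector(np.full(N_TYPES, 0.15))
        doubled = SystemEnsemble(
            name=sys.name,
            features=np.vstack([sys.features, sys.features]),
            prior=np.concatenate([sys.prior, sys.prior]) / 2,
            observables=[
                Observable(
                    o.name, o.kind, np.concatenate([o.per_frame_values] * 2),
                    o.exp_value, o.sigma, o.group, o.karplus,
                )
                for o in sys.observables
            ],
        )
        v1 = regularization_value(RegSpec("KISH", 1.0), p, [sys])
        v2 = regularization_value(RegSpec("KISH", 1.0), p, [doubled])
        # LSE of a single system is ln(exp(v)) = v; v halves
        assert v2 == pytest.approx(v1 / 2, rel=1e-10)


class TestGradient:
    def test_symbolic_oracle_single_type_population(self):
        """Three frames, one active type, one population observable: the cost
        is differentiated symbolically and compared with the analytic gradient."""
        import sympy as sp

        n = [0.0, 1.0, 2.0]
        w0 = [0.5, 0.3, 0.2]
        ind = [0.0, 1.0, 1.0]
        exp_value, sigma = 0.6, 0.1
        lam = sp.Symbol("lam")
        weights = [sp.Rational(str(v)) * sp.exp(lam * c) for v, c in zip(w0, n)]
        z = sum(weights)
        pop = sum(wi * i for wi, i in zip(weights, ind)) / z
        chi2 = ((pop - exp_value) / sigma) ** 2
        lam_val = 0.31
        expected = float(sp.diff(chi2, lam).subs(lam, lam_val))

        features = np.zeros((3, N_TYPES))
        features[:, 7] = n
        sys = SystemEnsemble(
            name="sym",
            features=features,
            prior=np.array(w0),
            observables=[Observable("p", POPULATION, np.array(ind), exp_value, sigma, "population")],
        )
        lam_vec = np.zeros(N_TYPES)
        lam_vec[7] = lam_val
        grad = cost_gradient([sys], ParamVector(lam_vec), None)
        assert grad[7] == pytest.approx(expected, rel=1e-10)
        assert np.all(grad[np.arange(N_TYPES) != 7] == 0.0)

    def test_l2_regularization_gradient_zero_at_reference(self, toy, params):
        g_data = cost_gradient([toy], params, None)
        g_reg = cost_gradient([toy], params, RegSpec("L2", 5.0))
        np.testing.assert_allclose(g_data, g_reg, atol=1e-12)

    @pytest.mark.parametrize("kind", ["L1", "L2", "KISH", "REL_KISH", "REL_ENTROPY"])
    def test_finite_difference_agreement(self, rng, kind, params):
        systems = [_toy_system(rng, f"s{i}") for i in range(2)]
        lam = rng.uniform(0.05, 0.5, N_TYPES) * rng.choice([-1, 1], N_TYPES)  # off-kink
        spec = RegSpec(kind, 0.7)
        p = params.with_lam(lam)
        _, grad = cost_and_grad(systems, p, spec)
        h = 1e-5
        fd = np.zeros(N_TYPES)
        for j in range(N_TYPES):
            up, dn = lam.copy(), lam.copy()
            up[j] += h
            dn[j] -= h
            fd[j] = (
                regularized_cost(systems, params.with_lam(up), spec)
                - regularized_cost(systems, params.with_lam(dn), spec)
            ) / (2 * h)
        assert np.linalg.norm(fd - grad) / np.linalg.norm(fd) < 1e-6
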