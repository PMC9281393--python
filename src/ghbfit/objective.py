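"""Regularized multi-system cost function and its analytic gradient.

The per-system error is the average squared standardized discrepancy over
its observables (chi^2); the total data cost is the omega-weighted linear
combination over systems.  Five regularization strategies are supported:

* ``L2`` -- sum (lambda - lambda0)^2, a Gaussian prior on the parameters;
* ``L1`` -- sum |lambda - lambda0|, a Laplace prior promoting sparsity;
* ``KISH`` -- inverse Kish size of each reweighted trajectory;
* ``REL_KISH`` -- inverse relative Kish size w.r.t. the prior ensemble;
* ``REL_ENTROPY`` -- exp of the KL divergence from the prior ensemble.

The last three are ensemble-dependent; their per-system values are combined
with a LogSumExp, which effectively picks the largest penalty across systems
so that every system retains sufficient statistical weight.  Hard box
constraints |lambda - lambda0| <= lambda_max act as an L-infinity term on
top (default 1 kcal/mol expressed in k_B*T units); they are enforced by the
optimizer, not by this module.

Gradients use the covariance identity d<O>/d lambda_j = cov_w(O, n_j),
which follows from dw(x)/d lambda_j = w(x) (n_j(x) - <n_j>).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp, softmax

from .errors import ConfigurationError, ContractError, DimensionError, InputError
from .hbonds import N_TYPES
from .observables import J_COUPLING, NOE, POPULATION, UNOE, Observable
from .reweight import compute_weights
from .units import DEFAULT_LAM_MAX

REG_KINDS = ("L1", "L2", "KISH", "REL_KISH", "REL_ENTROPY")
#: Regularizers whose global minimum is at lambda = lambda0 (not true for KISH
#: under nonuniform priors, which favors uniform weights instead).
REG_KINDS_ANCHORED = ("L1", "L2", "REL_KISH", "REL_ENTROPY")


@dataclass
class ParamVector:
    """Correction strengths lambda with their reference and box half-width.

    All entries are unitless; multiply by k_B*T for kcal/mol.
    """

    lam: np.ndarray
    lam0: np.ndarray | None = None
    lam_max: float = DEFAULT_LAM_MAX

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.shape != (N_TYPES,):
            raise DimensionError(f"lam must have shape ({N_TYPES},), got {self.lam.shape}")
        self.lam0 = (
            np.zeros(N_TYPES) if self.lam0 is None else np.asarray(self.lam0, dtype=float)
        )
        if self.lam0.shape != (N_TYPES,):
            raise DimensionError(f"lam0 must have shape ({N_TYPES},), got {self.lam0.shape}")
        if self.lam_max <= 0:
            raise InputError(f"lam_max must be positive, got {self.lam_max}")

    def bounds(self) -> list[tuple[float, float]]:
        return [(l0 - self.lam_max, l0 + self.lam_max) for l0 in self.lam0]

    def is_feasible(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.lam - self.lam0) <= self.lam_max + tol))

    def with_lam(self, lam) -> "ParamVector":
        return replace(self, lam=np.asarray(lam, dtype=float))

    def in_kcal(self, temperature: float | None = None) -> np.ndarray:
        from .units import DEFAULT_TEMPERATURE, kbt

        return kbt(temperature if temperature is not None else DEFAULT_TEMPERATURE) * self.lam


@dataclass
class RegSpec:
    """Regularization kind and strength alpha >= 0."""

    kind: str
    alpha: float

    def __post_init__(self):
        if self.kind not in REG_KINDS:
            raise ConfigurationError(f"unknown regularization kind {self.kind!r}")
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")


@dataclass
class SystemEnsemble:
    """One training system: features, prior weights, observables, weight omega."""

    name: str
    features: np.ndarray
    prior: np.ndarray
    observables: list[Observable]
    omega: float = 1.0

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != N_TYPES:
            raise DimensionError(
                f"system {self.name!r}: features must be (frames, {N_TYPES}), "
                f"got {self.features.shape}"
            )
        n = self.features.shape[0]
        if self.prior.shape != (n,):
            raise DimensionError(
                f"system {self.name!r}: {n} feature rows vs {self.prior.shape} prior weights"
            )
        if self.prior.sum() <= 0 or np.any(self.prior < 0):
            raise InputError(f"system {self.name!r}: prior weights must be non-negative, not all zero")
        self.prior = self.prior / self.prior.sum()
        if not self.observables:
            raise InputError(f"system {self.name!r}: at least one observable required")
        for obs in self.observables:
            if obs.per_frame_values.shape != (n,):
                raise DimensionError(
                    f"system {self.name!r}, observable {obs.name!r}: "
                    f"{obs.per_frame_values.shape[0]} values vs {n} frames"
                )
        if self.omega < 0:
            raise InputError(f"system {self.name!r}: omega must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    def posterior(self, lam) -> np.ndarray:
        """Normalized posterior weights at the given correction strengths."""
        return compute_weights(self.features, lam, self.prior)


def _resolve_mask(sys: SystemEnsemble, mask) -> np.ndarray:
    if mask is None:
        idx = np.arange(len(sys.observables))
    else:
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ContractError(f"system {sys.name!r}: observable mask is empty")
    return idx


def _residual_and_grad(obs: Observable, w, features, nbar, with_grad):
    """Residual and d(residual)/d lambda for one observable.

    The gradient flows through the weights only: for a per-frame transform t,
    d<t>/d lambda_j = cov_w(t, n_j) = sum_x w t n_j - <t> <n_j>.
    """
    v = obs.per_frame_values
    if obs.kind in (NOE, UNOE):
        q = v**-6
        mean_q = float(w @ q)
        calc = mean_q ** (-1.0 / 6.0)
        if obs.kind == UNOE:
            res = max(0.0, obs.exp_value - calc) / obs.sigma
        else:
            res = (calc - obs.exp_value) / obs.sigma
        if not with_grad:
            return res, None
        if obs.kind == UNOE and res == 0.0:
            return res, np.zeros(features.shape[1])
        dmean = (w * q) @ features - mean_q * nbar
        dcalc = -(1.0 / 6.0) * mean_q ** (-7.0 / 6.0) * dmean
        sign = -1.0 if obs.kind == UNOE else 1.0
        return res, sign * dcalc / obs.sigma
    if obs.kind == J_COUPLING:
        a, b, c = obs.karplus
        cos = np.cos(v)
        t = a * cos**2 + b * cos + c
    elif obs.kind == POPULATION:
        t = v
    else:  # pragma: no cover - guarded by Observable validation
        raise InputError(f"unknown observable kind {obs.kind!r}")
    calc = float(w @ t)
    res = (calc - obs.exp_value) / obs.sigma
    if not with_grad:
        return res, None
    dcalc = (w * t) @ features - calc * nbar
    return res, dcalc / obs.sigma


def system_residuals(sys: SystemEnsemble, params: ParamVector, mask=None, with_grad=False):
    """Standardized residuals (and optionally their Jacobian) for one system."""
    idx = _resolve_mask(sys, mask)
    w = sys.posterior(params.lam)
    nbar = w @ sys.features
    residuals = np.empty(idx.size)
    jac = np.empty((idx.size, N_TYPES)) if with_grad else None
    for k, i in enumerate(idx):
        res, grad = _residual_and_grad(sys.observables[i], w, sys.features, nbar, with_grad)
        residuals[k] = res
        if with_grad:
            jac[k] = grad
    return residuals, jac


def chi2_system(sys: SystemEnsemble, params: ParamVector, mask=None) -> float:
    """Mean squared standardized discrepancy over the (masked) observables."""
    residuals, _ = system_residuals(sys, params, mask)
    return float(np.mean(residuals**2))


def total_cost(systems, params: ParamVector) -> float:
    """Omega-weighted linear combination of per-system chi^2 (not normalized by sum omega)."""
    if not systems:
        raise InputError("at least one system required")
    return float(sum(s.omega * chi2_system(s, params) for s in systems))


def _diag_and_grad(kind, w, w0, features, nbar, with_grad):
    """Per-system value (and gradient) of an ensemble-dependent regularizer."""
    if kind == "KISH":
        v = float(w @ w)
        if not with_grad:
            return v, None
        return v, 2.0 * ((w * w) @ features - v * nbar)
    active = w > 0
    if np.any(w0[active] <= 0):
        from .errors import SupportError

        raise SupportError("posterior weight positive where prior weight is zero")
    if kind == "REL_KISH":
        r = np.zeros_like(w)
        r[active] = w[active] ** 2 / w0[active]
        v = float(r.sum())
        if not with_grad:
            return v, None
        return v, 2.0 * (r @ features - v * nbar)
    if kind == "REL_ENTROPY":
        wl = np.zeros_like(w)
        wl[active] = w[active] * np.log(w[active] / w0[active])
        div = float(wl.sum())
        v = float(np.exp(div))
        if not with_grad:
            return v, None
        ddiv = wl @ features - div * nbar
        return v, v * ddiv
    raise ConfigurationError(f"unknown regularization kind {kind!r}")


def regularization_value(spec: RegSpec, params: ParamVector, systems=None) -> float:
    """Value of the regularization function R(lambda) for the given spec.

    Parameter-space kinds (L1/L2) need no systems; ensemble-dependent kinds
    (KISH/REL_KISH/REL_ENTROPY) evaluate one value per system and combine
    them with LogSumExp, ln sum_i exp(v_i).
    """
    value, _ = _regularization_and_grad(spec, params, systems, with_grad=False)
    return value


def _regularization_and_grad(spec: RegSpec, params: ParamVector, systems, with_grad=True):
    d = params.lam - params.lam0
    if spec.kind == "L2":
        return float(d @ d), (2.0 * d if with_grad else None)
    if spec.kind == "L1":
        # subgradient 0 at the kink, so lambda = lambda0 is a fixed point
        return float(np.abs(d).sum()), (np.sign(d) if with_grad else None)
    if not systems:
        raise InputError(f"regularization kind {spec.kind!r} requires systems")
    vals, grads = [], []
    for sys in systems:
        w = sys.posterior(params.lam)
        nbar = w @ sys.features
        v, g = _diag_and_grad(spec.kind, w, sys.prior, sys.features, nbar, with_grad)
        vals.append(v)
        grads.append(g)
    vals = np.asarray(vals)
    value = float(logsumexp(vals))
    if not with_grad:
        return value, None
    weights = softmax(vals)
    return value, np.einsum("i,ij->j", weights, np.asarray(grads))


def regularized_cost(systems, params: ParamVector, spec: RegSpec) -> float:
    """total_cost + alpha * regularization_value."""
    return total_cost(systems, params) + spec.alpha * regularization_value(spec, params, systems)


def cost_and_grad(systems, params: ParamVector, spec: RegSpec | None = None):
    """Regularized cost and its analytic 12-vector gradient in one pass.

    With ``spec=None`` (or alpha = 0) only the data term is evaluated.
    """
    if not systems:
        raise InputError("at least one system required")
    lam = params.lam
    value = 0.0
    grad = np.zeros(N_TYPES)
    reg_vals, reg_grads = [], []
    ensemble_reg = spec is not None and spec.kind in ("KISH", "REL_KISH", "REL_ENTROPY")
    for sys in systems:
        w = sys.posterior(lam)
        nbar = w @ sys.features
        m = len(sys.observables)
        c2 = 0.0
        g = np.zeros(N_TYPES)
        for obs in sys.observables:
            res, dres = _residual_and_grad(obs, w, sys.features, nbar, True)
            c2 += res * res
            g += 2.0 * res * dres
        value += sys.omega * c2 / m
        grad += sys.omega * g / m
        if ensemble_reg:
            v, dv = _diag_and_grad(spec.kind, w, sys.prior, sys.features, nbar, True)
            reg_vals.append(v)
            reg_grads.append(dv)
    if spec is not None and spec.alpha != 0.0:
        if ensemble_reg:
            vals = np.asarray(reg_vals)
            value += spec.alpha * float(logsumexp(vals))
            grad += spec.alpha * np.einsum("i,ij->j", softmax(vals), np.asarray(reg_grads))
        else:
            rv, rg = _regularization_and_grad(spec, params, systems)
            value += spec.alpha * rv
            grad += spec.alpha * rg
    return value, grad


def cost_gradient(systems, params: ParamVector, spec: RegSpec | None = None) -> np.ndarray:
    """Analytic gradient of the regularized cost with respect to lambda."""
    _, grad = cost_and_grad(systems, params, spec)
    return grad


def evaluation_report(systems, params: ParamVector, spec: RegSpec | None = None) -> dict:
    """Machine-readable breakdown: total, per-system chi^2, residuals, diagnostics."""
    from .reweight import kish_inverse, relative_kish_inverse

    report: dict = {"lam": params.lam.tolist(), "systems": {}}
    total = 0.0
    for sys in systems:
        w = sys.posterior(params.lam)
        residuals, _ = system_residuals(sys, params)
        c2 = float(np.mean(residuals**2))
        total += sys.omega * c2
        report["systems"][sys.name] = {
            "chi2": c2,
            "omega": sys.omega,
            "residuals": {o.name: float(r) for o, r in zip(sys.observables, residuals)},
            "kish_inverse": kish_inverse(w),
            "relative_kish_inverse": relative_kish_inverse(w, sys.prior),
        }
    report["total_cost"] = total
    if spec is not None:
        report["regularization"] = {
            "kind": spec.kind,
            "alpha": spec.alpha,
            "value": regularization_value(spec, params, systems),
        }
    return report
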