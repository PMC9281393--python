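"""Box-constrained fitting, hyperparameter scans and cross-validation.

Fitting minimizes the regularized cost over the 12 correction strengths
with L-BFGS-B inside the hard box |lambda - lambda0| <= lambda_max, using
the analytic gradient, starting from lambda0 plus optional random feasible
restarts.  Three cross-validation protocols choose the regularization
hyperparameter alpha:

``SEGMENTS``
    Split every trajectory into contiguous equal blocks (default 5), leave
    one block out jointly across systems per fold.  Checks transferability
    to a new trajectory of the same systems.
``OBSERVABLES``
    Leave one (system, observable-group) unit out per fold.  Checks
    transferability to new kinds of data.
``SYSTEMS``
    Leave one whole system out per fold.  Checks transferability to new
    molecules.

Validation error is the *unregularized* data cost on the left-out view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .errors import FitError, InputError, SplitError
from .objective import (
    ParamVector,
    RegSpec,
    SystemEnsemble,
    chi2_system,
    cost_and_grad,
    regularization_value,
    total_cost,
)
from .reweight import kish_inverse

STRATEGIES = ("SEGMENTS", "OBSERVABLES", "SYSTEMS")


@dataclass
class FitResult:
    """Optimized parameters with per-system diagnostics."""

    params: ParamVector
    cost_train: float  # regularized cost at the optimum
    data_cost: float  # unregularized omega-weighted chi^2 sum
    per_system_chi2: dict[str, float]
    reg_value: float
    kish_per_system: dict[str, float]
    converged: bool
    n_restarts_used: int
    seed: int

    @property
    def lam_hat(self) -> np.ndarray:
        return self.params.lam


@dataclass
class CVCurve:
    """Train/validation error as a function of the regularization strength."""

    reg_kind: str
    alphas: np.ndarray
    train_error: np.ndarray  # mean over folds of the unregularized train cost
    val_error: np.ndarray  # mean over folds of the unregularized validation cost
    fold_val_errors: np.ndarray  # (n_alphas, n_folds)
    fold_train_errors: np.ndarray  # (n_alphas, n_folds)
    best_alpha: float

    @property
    def best_val_error(self) -> float:
        return float(self.val_error[int(np.nonzero(self.alphas == self.best_alpha)[0][0])])


def _diagnose(systems, params, spec) -> tuple[float, dict, float, dict]:
    per_chi2 = {s.name: chi2_system(s, params) for s in systems}
    data_cost = float(sum(s.omega * per_chi2[s.name] for s in systems))
    reg_value = regularization_value(spec, params, systems) if spec is not None else 0.0
    kish = {s.name: kish_inverse(s.posterior(params.lam)) for s in systems}
    return data_cost, per_chi2, reg_value, kish


def fit(
    systems,
    spec: RegSpec | None,
    params0: ParamVector,
    seed: int = 0,
    n_restarts: int = 5,
    gtol: float = 1e-8,
    maxiter: int = 1000,
) -> FitResult:
    """Minimize the regularized cost inside the box; deterministic given seed.

    Starts from lambda0 and ``n_restarts - 1`` seeded uniform draws inside
    the box; returns the best optimum found.  The result never loses to the
    reference point lambda0.
    """
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    bounds = params0.bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(lam):
        return cost_and_grad(systems, params0.with_lam(lam), spec)

    rng = np.random.default_rng(seed)
    starts = [params0.lam0.copy()]
    for _ in range(n_restarts - 1):
        starts.append(rng.uniform(lo, hi))

    best_x, best_fun, any_success = None, np.inf, False
    failures = []
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
        )
        if not np.isfinite(res.fun):
            failures.append(str(res.message))
            continue
        any_success = any_success or bool(res.success)
        if res.fun < best_fun:
            best_fun, best_x = float(res.fun), np.clip(res.x, lo, hi)
    if best_x is None:
        raise FitError(f"all {n_restarts} optimizer starts failed: {failures}")

    # a minimizer never loses to its own starting point
    f0, _ = objective(params0.lam0)
    if f0 < best_fun:
        best_fun, best_x = float(f0), params0.lam0.copy()

    params = params0.with_lam(best_x)
    data_cost, per_chi2, reg_value, kish = _diagnose(systems, params, spec)
    return FitResult(
        params=params,
        cost_train=best_fun,
        data_cost=data_cost,
        per_system_chi2=per_chi2,
        reg_value=reg_value,
        kish_per_system=kish,
        converged=any_success,
        n_restarts_used=n_restarts,
        seed=seed,
    )


# --- cross-validation views -------------------------------------------------


def _frame_view(sys: SystemEnsemble, index: np.ndarray) -> SystemEnsemble:
    prior = sys.prior[index]
    return SystemEnsemble(
        name=sys.name,
        features=sys.features[index],
        prior=prior / prior.sum(),
        observables=[o.with_frames(index) for o in sys.observables],
        omega=sys.omega,
    )


def _observable_view(sys: SystemEnsemble, obs_subset: list) -> SystemEnsemble:
    return replace(sys, observables=obs_subset)


def _group_units(systems) -> list[tuple[int, str]]:
    units = []
    for si, sys in enumerate(systems):
        seen = []
        for obs in sys.observables:
            if obs.group not in seen:
                seen.append(obs.group)
        units.extend((si, g) for g in seen)
    return units


def cv_split(systems, strategy: str, n_segments: int = 5):
    """Folds of (train_systems, validation_systems) views exhausting the data."""
    if strategy not in STRATEGIES:
        raise InputError(f"unknown CV strategy {strategy!r}")
    if strategy == "SEGMENTS":
        if n_segments < 2:
            raise SplitError("SEGMENTS needs n_segments >= 2")
        for sys in systems:
            if sys.n_frames < n_segments:
                raise SplitError(
                    f"system {sys.name!r} has {sys.n_frames} frames < {n_segments} segments"
                )
        folds = []
        blocks = {
            sys.name: np.array_split(np.arange(sys.n_frames), n_segments) for sys in systems
        }
        for k in range(n_segments):
            train, val = [], []
            for sys in systems:
                val_idx = blocks[sys.name][k]
                train_idx = np.concatenate(
                    [b for j, b in enumerate(blocks[sys.name]) if j != k]
                )
                train.append(_frame_view(sys, train_idx))
                val.append(_frame_view(sys, val_idx))
            folds.append((train, val))
        return folds
    if strategy == "OBSERVABLES":
        units = _group_units(systems)
        if len(units) < 2:
            raise SplitError("OBSERVABLES needs at least 2 (system, group) units")
        folds = []
        for si, group in units:
            train = []
            for sj, sys in enumerate(systems):
                if sj == si:
                    keep = [o for o in sys.observables if o.group != group]
                    if keep:
                        train.append(_observable_view(sys, keep))
                else:
                    train.append(sys)
            held = [o for o in systems[si].observables if o.group == group]
            val = [_observable_view(systems[si], held)]
            if not train:
                raise SplitError("OBSERVABLES fold would leave no training observables")
            folds.append((train, val))
        return folds
    # SYSTEMS
    if len(systems) < 2:
        raise SplitError("SYSTEMS needs at least 2 systems")
    return [
        ([s for j, s in enumerate(systems) if j != i], [systems[i]])
        for i in range(len(systems))
    ]


def cross_validate(
    systems,
    reg_kind: str,
    alpha_grid,
    strategy: str,
    params0: ParamVector,
    seed: int = 0,
    n_segments: int = 5,
    n_restarts: int = 1,
    gtol: float = 1e-8,
) -> CVCurve:
    """Scan alpha over the grid; per alpha and fold, fit on the training view
    and score the unregularized cost on the validation view.

    ``best_alpha`` minimizes the mean validation error; exact ties break
    toward the larger (more regularized) alpha.
    """
    alphas = np.asarray(alpha_grid, dtype=float)
    if alphas.size == 0:
        raise InputError("alpha grid must be nonempty")
    if np.any(np.diff(alphas) <= 0):
        raise InputError("alpha grid must be strictly increasing")
    folds = cv_split(systems, strategy, n_segments)
    n_folds = len(folds)
    fold_val = np.empty((alphas.size, n_folds))
    fold_train = np.empty((alphas.size, n_folds))
    for ai, alpha in enumerate(alphas):
        spec = RegSpec(reg_kind, float(alpha))
        for fi, (train, val) in enumerate(folds):
            result = fit(
                train, spec, params0,
                seed=seed + 1000 * ai + fi, n_restarts=n_restarts, gtol=gtol,
            )
            fold_train[ai, fi] = total_cost(train, result.params)
            fold_val[ai, fi] = total_cost(val, result.params)
    val_error = fold_val.mean(axis=1)
    train_error = fold_train.mean(axis=1)
    best_idx = best_alpha_index(val_error)
    return CVCurve(
        reg_kind=reg_kind,
        alphas=alphas,
        train_error=train_error,
        val_error=val_error,
        fold_val_errors=fold_val,
        fold_train_errors=fold_train,
        best_alpha=float(alphas[best_idx]),
    )


def best_alpha_index(val_error) -> int:
    """Index of the minimal validation error; exact ties break toward the
    larger (more regularized) alpha."""
    val_error = np.asarray(val_error, dtype=float)
    return val_error.size - 1 - int(np.argmin(val_error[::-1]))


def default_alpha_grid(n: int = 25, low: float = 1e-4, high: float = 1e4) -> np.ndarray:
    """Logarithmic grid spanning 8 orders of magnitude (configurable)."""
    return np.logspace(np.log10(low), np.log10(high), n)


def select_model(curves, systems, params0: ParamVector, seed: int = 0, n_restarts: int = 5):
    """Pick the (kind, alpha) with the lowest cross-validation error and refit
    on all data; the regularization kind acts as a categorical hyperparameter."""
    if not curves:
        raise InputError("at least one CV curve required")
    best_curve = min(curves, key=lambda c: c.best_val_error)
    spec = RegSpec(best_curve.reg_kind, best_curve.best_alpha)
    result = fit(systems, spec, params0, seed=seed, n_restarts=n_restarts)
    return spec, result


def manual_override(
    result: FitResult,
    systems,
    spec: RegSpec | None,
    type_indices_to_zero,
    to_zero: bool = True,
) -> FitResult:
    """Copy of a fit with selected correction strengths reset, costs re-evaluated.

    Mirrors post-hoc edits made when a fitted term has side effects on motifs
    absent from the training set (e.g. zeroing a sugar-sugar correction).
    ``to_zero=True`` sets the entries to 0.0; otherwise to their lambda0.
    """
    indices = sorted(set(int(i) for i in type_indices_to_zero))
    lam = result.params.lam.copy()
    for i in indices:
        if not 0 <= i < lam.size:
            raise InputError(f"type index {i} out of range 0..{lam.size - 1}")
        lam[i] = 0.0 if to_zero else result.params.lam0[i]
    params = result.params.with_lam(lam)
    data_cost, per_chi2, reg_value, kish = _diagnose(systems, params, spec)
    cost = data_cost + (spec.alpha * reg_value if spec is not None else 0.0)
    return replace(
        result,
        params=params,
        cost_train=cost,
        data_cost=data_cost,
        per_system_chi2=per_chi2,
        reg_value=reg_value,
        kish_per_system=kish,
    )
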