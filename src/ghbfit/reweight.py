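"""Posterior frame weights, ensemble diagnostics and binless WHAM.

Reweighting re-estimates ensemble averages under modified correction
strengths by weighting existing frames instead of running new simulations:
with correction exponent f(x, lambda) = -sum_j lambda_j n_j(x), the
posterior distribution is P(x, lambda) proportional to P0(x) exp(-f), so the
frame weight is w(x) proportional to w0(x) exp(sum_j lambda_j n_j(x)).

Diagnostics quantify how far the reweighted ensemble has strayed from the
prior: the inverse Kish size sum w^2 (reciprocal of the effective number of
frames), the inverse *relative* Kish size sum w^2/w0 and the exponential of
the Kullback-Leibler divergence exp(KL(w||w0)).  The relative forms equal
exactly 1 when w = w0 and grow as the two distributions depart.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .errors import (
    ContractError,
    ConvergenceError,
    DimensionError,
    InputError,
    NumericalError,
    SupportError,
)

_NORM_TOL = 1e-8


def normalize(w) -> np.ndarray:
    """Normalize non-negative weights to sum 1."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise InputError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise InputError("all-zero weight vector cannot be normalized")
    return w / total


def _check_normalized(w: np.ndarray, name: str = "w") -> None:
    if abs(w.sum() - 1.0) > _NORM_TOL:
        raise ContractError(f"{name} must be normalized (sum={w.sum()!r})")


def compute_weights(features, lam, prior) -> np.ndarray:
    """Normalized posterior frame weights under correction strengths lambda.

    Computed in log space with a max-shift, so exponents of magnitude up to
    ~700 per frame do not overflow.

    Parameters
    ----------
    features : (frames, n_types) smooth bond counts.
    lam : (n_types,) unitless correction strengths.
    prior : (frames,) prior weights (need not be normalized; zeros allowed).
    """
    features = np.asarray(features, dtype=float)
    lam = np.asarray(lam, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if features.ndim != 2 or lam.ndim != 1 or features.shape[1] != lam.shape[0]:
        raise DimensionError(
            f"features {features.shape} incompatible with lambda {lam.shape}"
        )
    if features.shape[0] != prior.shape[0]:
        raise DimensionError(
            f"{features.shape[0]} feature rows vs {prior.shape[0]} prior weights"
        )
    if np.any(prior < 0):
        raise InputError("prior weights must be non-negative")
    if prior.sum() <= 0:
        raise InputError("all-zero prior")

    with np.errstate(divide="ignore"):
        logw = np.log(prior) + features @ lam
    shift = np.max(logw)
    if not np.isfinite(shift):
        bad = int(np.argmax(~np.isfinite(features @ lam)))
        raise NumericalError(f"non-finite log-weight at frame {bad}")
    w = np.exp(logw - shift)
    return w / w.sum()


def expectation(w, values) -> float:
    """Reweighted ensemble average sum_x w(x) O(x) (w normalized)."""
    w = np.asarray(w, dtype=float)
    values = np.asarray(values, dtype=float)
    if w.shape != values.shape:
        raise DimensionError(f"weights {w.shape} vs values {values.shape}")
    return float(w @ values)


def kish_inverse(w) -> float:
    """Inverse Kish sample size sum_x w(x)^2, in (0, 1].

    The Kish effective sample size is its reciprocal: the number of
    equally-weighted frames statistically equivalent to the weighted sample.
    """
    w = np.asarray(w, dtype=float)
    _check_normalized(w)
    return float(w @ w)


def relative_kish_inverse(w, w0) -> float:
    """Inverse relative Kish size sum_x w(x)^2 / w0(x); equals 1 iff w == w0."""
    w = np.asarray(w, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if w.shape != w0.shape:
        raise DimensionError(f"weights {w.shape} vs prior {w0.shape}")
    _check_normalized(w)
    _check_normalized(w0, "w0")
    active = w > 0
    if np.any(w0[active] <= 0):
        raise SupportError("posterior weight positive where prior weight is zero")
    return float(np.sum(w[active] ** 2 / w0[active]))


def relative_entropy_reg(w, w0) -> float:
    """exp(KL(w || w0)) with 0*log(0) := 0; equals 1 iff w == w0, else > 1."""
    w = np.asarray(w, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if w.shape != w0.shape:
        raise DimensionError(f"weights {w.shape} vs prior {w0.shape}")
    _check_normalized(w)
    _check_normalized(w0, "w0")
    active = w > 0
    if np.any(w0[active] <= 0):
        raise SupportError("posterior weight positive where prior weight is zero")
    div = float(np.sum(w[active] * np.log(w[active] / w0[active])))
    return float(np.exp(div))


def kish_size(w) -> float:
    """Kish effective sample size 1 / sum w^2."""
    return 1.0 / kish_inverse(w)


def binless_wham(
    reduced_energies,
    frames_per_run,
    target=None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    damping: float = 1.0,
) -> np.ndarray:
    """Merge runs generated under different parameter sets into one ensemble.

    Solves the binless WHAM / multistate-reweighting self-consistency
    equations by damped fixed-point iteration on the per-run log free
    energies.  Frame weights for the target potential are::

        w(x) propto exp(-u_t(x)) / sum_k N_k exp(f_k - u_k(x))

    with f_k = -log sum_x w_mix(x) exp(-u_k(x)) determined self-consistently.

    Parameters
    ----------
    reduced_energies : (frames, K) dimensionless energies of every frame
        under each of the K parameter sets, frames ordered run by run.
    frames_per_run : (K,) frame counts; must sum to the number of rows.
    target : (frames,) reduced energies of the target potential.  Default is
        column 0, i.e. the ensemble of the first parameter set.  Passing
        zeros reweights a biased run back to the unbiased potential
        (inverse-Boltzmann reweighting when K = 1).
    tol : convergence threshold on the max change of the normalized
        log-weights between iterations.

    Returns
    -------
    (frames,) normalized weights.  Invariant to adding a constant to any
    column of ``reduced_energies``.
    """
    u = np.asarray(reduced_energies, dtype=float)
    counts = np.asarray(frames_per_run, dtype=float)
    if u.ndim != 2:
        raise DimensionError("reduced_energies must be a frames x K matrix")
    n_frames, n_runs = u.shape
    if counts.shape != (n_runs,) or counts.sum() != n_frames:
        raise DimensionError(
            f"frames_per_run {counts} inconsistent with {n_frames} frames, {n_runs} runs"
        )
    if not np.all(np.isfinite(u)):
        raise InputError("every frame needs a finite reduced energy under every parameter set")
    if target is None:
        target = u[:, 0]
    target = np.asarray(target, dtype=float)
    if target.shape != (n_frames,):
        raise DimensionError(f"target has shape {target.shape}, expected ({n_frames},)")

    log_counts = np.log(counts)
    f = np.zeros(n_runs)
    prev_logw = None
    residual = np.inf
    for _ in range(max_iter):
        # log mixture denominator per frame
        denom = logsumexp(log_counts + f - u, axis=1)
        new_f = -logsumexp(-u - denom[:, None], axis=0)
        new_f -= new_f[0]  # gauge: free energy of run 0 is 0
        f = f + damping * (new_f - f)

        logw = -target - logsumexp(log_counts + f - u, axis=1)
        logw -= logsumexp(logw)
        if prev_logw is not None:
            residual = float(np.max(np.abs(logw - prev_logw)))
            if residual < tol:
                return np.exp(logw - logsumexp(logw))
        prev_logw = logw
    raise ConvergenceError(
        f"binless WHAM did not converge in {max_iter} iterations "
        f"(max log-weight change {residual:.3e})",
        residual=residual,
    )
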