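"""Synthetic ensembles with known ground-truth correction strengths.

The generator emulates the statistical structure of a realistic training
set -- a flexible tetramer carrying many NMR observables (NOE, unobserved
NOE, scalar couplings in three torsion groups) and two tetraloops carrying
a single native-population observable each -- without attempting to mimic
real RNA conformational ensembles.  Each frame carries a latent binary
native/non-native state; per-type bond counts are binomial with
logit-linear dependence on that state, so the exponential-family
reweighting is well conditioned and all 12 coordinates are recoverable.

"Experimental" values are exact reweighted averages of the generated
ensemble at the ground-truth parameters ``lam_true`` plus Gaussian noise of
``noise_scale`` times the stated sigma, so at ``lam_true`` the expected
chi^2 is ~``noise_scale**2`` (a bit lower when one-sided uNOE bounds are
present) and exactly 0 at zero noise.

The three-system suite engineers a deliberate asymmetry: the UUCG-like
tetraloop's native state depends only on a bond type (index 11) that is
inactive in the other two systems, so leaving it out of training leaves
that coordinate unconstrained -- whereas the GAGA-like loop's native type
(index 10) is also active in the tetramer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GhbfitError, InputError
from .hbonds import N_TYPES
from .objective import ParamVector, SystemEnsemble
from .observables import J_COUPLING, NOE, POPULATION, UNOE, Observable
from .reweight import compute_weights
from .units import DEFAULT_LAM_MAX


class GenerationError(GhbfitError):
    """Degenerate synthetic configuration (e.g. zero-variance features)."""


#: Ground-truth correction strengths, interior to the default +/-1 kcal/mol box.
DEFAULT_LAM_TRUE = np.array(
    [0.5, -0.3, 0.4, -0.5, 0.3, -0.4, 0.6, -0.2, 0.45, -0.35, 0.55, 0.8]
)

TETRAMER = "TETRAMER"
TETRALOOP = "TETRALOOP"

# observable design of the tetramer: which feature column each data point
# probes, per NMR group
_NOE_TYPES = (0, 1, 2, 3, 4, 5, 6, 7)
_UNOE_TYPES = (0, 1, 2, 3)
_J_GROUPS = (
    ("backbone1", (8, 9, 10), (9.7, -1.8, 0.0)),
    ("backbone2", (8, 9, 10), (6.9, -3.4, 0.7)),
    ("sugar", (4, 6, 10), (10.2, -0.8, 0.1)),
)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic training set."""

    n_frames: int = 50_000
    lam_true: np.ndarray = field(default_factory=lambda: DEFAULT_LAM_TRUE.copy())
    noise_scale: float = 1.0
    seed: int = 0
    lam_max: float = DEFAULT_LAM_MAX
    pairs_per_type: int = 4  # pair count m_j of each active tetramer type
    sigma_noe: float = 0.1  # Angstrom
    sigma_j: float = 0.5  # Hz
    sigma_pop: float = 0.05  # fraction
    prior_bias_strength: float = 0.15  # known bias on the tetramer prior
    n_noe: int = 8
    n_unoe: int = 4
    n_j_per_group: int = 3

    def __post_init__(self):
        self.lam_true = np.asarray(self.lam_true, dtype=float)
        if self.n_frames < 100:
            raise InputError(f"n_frames must be >= 100, got {self.n_frames}")
        if self.lam_true.shape != (N_TYPES,):
            raise InputError(f"lam_true must have {N_TYPES} entries")
        if np.any(np.abs(self.lam_true) > self.lam_max):
            raise InputError("lam_true must lie within the default box |lam| <= lam_max")
        if self.noise_scale < 0:
            raise InputError("noise_scale must be >= 0")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _experimental_value(obs: Observable, features, lam_true, prior, noise, rng):
    from .observables import back_calculate

    w_true = compute_weights(features, lam_true, prior)
    exact = back_calculate(obs, w_true)
    return exact + noise * obs.sigma * rng.standard_normal()


def generate_system(
    cfg: SynthConfig,
    profile: str,
    rng: np.random.Generator | None = None,
    name: str | None = None,
    native_type: int = 10,
    native_prior: float = 0.2,
    native_pairs: int = 6,
    native_logit: tuple[float, float] = (-1.0, 2.2),
):
    """Generate one system; returns (SystemEnsemble, ground-truth record).

    ``TETRAMER`` carries 8 NOE + 4 uNOE + 9 J observables in 5 groups, a
    nonuniform prior built from a known bias column, and active feature
    types 0..10.  ``TETRALOOP`` carries a single POPULATION observable whose
    indicator depends only on ``native_type`` counts; its other active
    types (0..3) are independent of the latent state.
    """
    if profile not in (TETRAMER, TETRALOOP):
        raise InputError(f"unknown profile {profile!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    m = cfg.pairs_per_type
    features = np.zeros((n, N_TYPES))

    if profile == TETRAMER:
        state = (rng.random(n) < 0.3).astype(float)
        for j in range(11):  # types 0..10 active in the tetramer
            base = -0.6 + 0.1 * (j % 5)
            p = _sigmoid(base + 1.0 * state)
            features[:, j] = rng.binomial(m, p)
        # known bias on the prior: exercises nonuniform w0
        bias = cfg.prior_bias_strength * (features[:, 0] - features[:, 0].mean())
        prior = np.exp(bias - bias.max())
        prior /= prior.sum()

        observables = []
        jitter = 0.15
        for i in range(cfg.n_noe):
            t = _NOE_TYPES[i % len(_NOE_TYPES)]
            r = 4.0 - 1.5 * features[:, t] / m + jitter * rng.standard_normal(n)
            observables.append(
                Observable(
                    name=f"NOE_{i}", kind=NOE, per_frame_values=np.clip(r, 1.8, None),
                    exp_value=0.0, sigma=cfg.sigma_noe, group="NOE",
                )
            )
        for i in range(cfg.n_unoe):
            t = _UNOE_TYPES[i % len(_UNOE_TYPES)]
            r = 3.6 - 1.2 * features[:, t] / m + jitter * rng.standard_normal(n)
            observables.append(
                Observable(
                    name=f"uNOE_{i}", kind=UNOE, per_frame_values=np.clip(r, 1.8, None),
                    exp_value=0.0, sigma=cfg.sigma_noe, group="uNOE",
                )
            )
        for group, types, karplus in _J_GROUPS:
            for i in range(cfg.n_j_per_group):
                t = types[i % len(types)]
                sign = 1.0 if group != "sugar" else -1.0
                theta = (
                    (1.0 if group == "backbone1" else 0.5 if group == "backbone2" else 2.0)
                    + sign * 1.3 * features[:, t] / m
                    + 0.2 * rng.standard_normal(n)
                )
                observables.append(
                    Observable(
                        name=f"J_{group}_{i}", kind=J_COUPLING, per_frame_values=theta,
                        exp_value=0.0, sigma=cfg.sigma_j, group=group, karplus=karplus,
                    )
                )
    else:
        state = (rng.random(n) < native_prior).astype(float)
        a, b = native_logit
        features[:, native_type] = rng.binomial(native_pairs, _sigmoid(a + b * state))
        for j in range(4):  # shared stem-like types, independent of the state
            features[:, j] = rng.binomial(m, 0.5, size=n)
        prior = np.full(n, 1.0 / n)
        observables = [
            Observable(
                name="native_population", kind=POPULATION, per_frame_values=state,
                exp_value=0.0, sigma=cfg.sigma_pop, group="population",
            )
        ]

    active = np.flatnonzero(features.std(axis=0) > 0)
    if active.size == 0:
        raise GenerationError("generated features have zero variance in every type")

    # experimental targets: exact reweighted averages at lam_true + noise
    for obs in observables:
        obs.exp_value = _experimental_value(
            obs, features, cfg.lam_true, prior, cfg.noise_scale, rng
        )

    system = SystemEnsemble(
        name=name or profile.lower(),
        features=features,
        prior=prior,
        observables=observables,
        omega=1.0,
    )
    truth = {
        "lam_true": cfg.lam_true.copy(),
        "latent_state": state,
        "profile": profile,
        "active_types": active,
        "name": system.name,
    }
    return system, truth


def make_training_suite(
    seed: int = 0,
    n_frames: int | None = None,
    noise_scale: float | None = None,
    cfg: SynthConfig | None = None,
):
    """Three-system training suite sharing one ground truth.

    Returns (systems, truth): a tetramer plus two tetraloops whose seven
    observable groups reproduce the leave-one-out structures used in
    cross-validation.  ``truth`` carries ``lam_true``, the reference
    parameters ``params0`` (lambda0 = 0 inside the default box) and the
    per-system records.
    """
    import dataclasses

    if cfg is None:
        cfg = SynthConfig(seed=seed)
    if n_frames is not None:
        cfg = dataclasses.replace(cfg, n_frames=n_frames)
    if noise_scale is not None:
        cfg = dataclasses.replace(cfg, noise_scale=noise_scale)
    rng = np.random.default_rng(cfg.seed)
    tetramer, t1 = generate_system(cfg, TETRAMER, rng=rng, name="GACC_tetramer")
    gaga, t2 = generate_system(
        cfg, TETRALOOP, rng=rng, name="GAGA_tetraloop",
        native_type=10, native_prior=0.2, native_pairs=6, native_logit=(-1.0, 2.2),
    )
    uucg, t3 = generate_system(
        cfg, TETRALOOP, rng=rng, name="UUCG_tetraloop",
        native_type=11, native_prior=0.15, native_pairs=8, native_logit=(-1.5, 2.5),
    )
    params0 = ParamVector(lam=np.zeros(N_TYPES), lam0=np.zeros(N_TYPES), lam_max=cfg.lam_max)
    truth = {
        "lam_true": cfg.lam_true.copy(),
        "params0": params0,
        "systems": {s["name"]: s for s in (t1, t2, t3)},
        "config": cfg,
    }
    return [tetramer, gaga, uucg], truth
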