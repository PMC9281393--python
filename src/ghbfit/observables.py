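"""Forward models mapping weighted ensembles to experiment-comparable values.

Supported observable kinds:

``NOE``
    Effective distance <r^-6>^(-1/6) under the frame weights, compared
    two-sided against the experimental distance.
``uNOE``
    Unobserved NOE cross-peak, implying the effective distance must *not*
    fall below the experimental bound; contributes a one-sided penalty.
``J_COUPLING``
    Scalar coupling via the Karplus equation J = A cos^2(theta) +
    B cos(theta) + C, averaged over frames (fast-exchange convention:
    the coupling is averaged, not the torsion).
``POPULATION``
    Reweighted average of a binary native-state indicator (the indicator
    is consumed precomputed, e.g. from eRMSD plus signature bonds).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DimensionError, InputError
from .reweight import expectation

NOE = "NOE"
UNOE = "uNOE"
J_COUPLING = "J_COUPLING"
POPULATION = "POPULATION"
KINDS = (NOE, UNOE, J_COUPLING, POPULATION)


@dataclass
class Observable:
    """One experimental data point and its per-frame forward-model input.

    ``per_frame_values`` holds distances in Angstrom for NOE/uNOE, torsions
    in radians for J_COUPLING and a 0/1 indicator for POPULATION.
    ``exp_value`` is the experimental value on the back-calculated scale
    (distance or bound in Angstrom, coupling in Hz, fraction in [0, 1]).
    """

    name: str
    kind: str
    per_frame_values: np.ndarray
    exp_value: float
    sigma: float
    group: str
    karplus: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.per_frame_values = np.asarray(self.per_frame_values, dtype=float)
        if self.kind not in KINDS:
            raise InputError(f"unknown observable kind {self.kind!r}")
        if self.sigma <= 0:
            raise InputError(f"observable {self.name!r}: sigma must be > 0, got {self.sigma}")
        if not self.group:
            raise InputError(f"observable {self.name!r}: group label must be nonempty")
        if self.kind in (NOE, UNOE) and np.any(self.per_frame_values <= 0):
            raise InputError(f"observable {self.name!r}: distances must be positive")
        if self.kind == POPULATION and not np.isin(self.per_frame_values, (0.0, 1.0)).all():
            raise InputError(f"observable {self.name!r}: indicator must be binary")
        if self.kind == J_COUPLING and self.karplus is None:
            raise InputError(f"observable {self.name!r}: J_COUPLING needs Karplus coefficients")

    def with_frames(self, index) -> "Observable":
        """Copy restricted to the given frame indices (for CV views)."""
        return replace(self, per_frame_values=self.per_frame_values[index])


def noe_effective_distance(w, distances) -> float:
    """<r^-6>^(-1/6) in Angstrom; dominated by the shortest distances."""
    distances = np.asarray(distances, dtype=float)
    if np.any(distances <= 0):
        raise InputError("distances must be positive")
    return float(expectation(w, distances**-6) ** (-1.0 / 6.0))


def karplus_coupling(w, torsions, a, b, c) -> float:
    """Ensemble-averaged scalar coupling <A cos^2 + B cos + C> in Hz."""
    cos = np.cos(np.asarray(torsions, dtype=float))
    return float(expectation(w, a * cos**2 + b * cos + c))


def native_population(w, indicator) -> float:
    """Reweighted native-state fraction <indicator> in [0, 1]."""
    indicator = np.asarray(indicator, dtype=float)
    if not np.isin(indicator, (0.0, 1.0)).all():
        raise InputError("indicator must be binary")
    return float(expectation(w, indicator))


def back_calculate(obs: Observable, w) -> float:
    """Back-calculated value of one observable under the frame weights."""
    if obs.kind in (NOE, UNOE):
        return noe_effective_distance(w, obs.per_frame_values)
    if obs.kind == J_COUPLING:
        return karplus_coupling(w, obs.per_frame_values, *obs.karplus)
    if obs.kind == POPULATION:
        return native_population(w, obs.per_frame_values)
    raise InputError(f"unknown observable kind {obs.kind!r}")


def observable_discrepancy(obs: Observable, w) -> float:
    """Signed standardized residual entering the chi^2.

    Two-sided (calc - exp)/sigma for NOE, J and population observables;
    one-sided max(0, exp - calc)/sigma for uNOE, zero whenever the effective
    distance respects the unobserved-NOE lower bound.
    """
    calc = back_calculate(obs, w)
    if obs.kind == UNOE:
        return float(max(0.0, obs.exp_value - calc) / obs.sigma)
    return float((calc - obs.exp_value) / obs.sigma)
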