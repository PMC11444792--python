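"""Physical model of burst-swimming fatigue.

A fish swimming against a steady flow experiences a drag force that, over
the burst range of velocities, scales as a power of the fish-to-water
relative velocity ``U_r``::

    F_D = Gamma * U_r**beta

``Gamma`` lumps water properties and fish geometry (for dominant pressure
drag, ``Gamma = rho * L * S``), and the drag exponent ``beta`` is
theoretically constrained to a narrow band, ``[1.73, 2.0]`` by default.
Swimming power is then ``P = F_D * U_r = Gamma * U_r**(beta + 1)``, and a
fish whose anaerobic energy reserve is ``E`` fatigues after

    T_f = E / (Gamma * U_r**(beta + 1)).

Averaging this budget over a population of fish of the same species and
size gives the scaling laws linking moments of the time-to-fatigue to
velocity: the mean falls as ``U_r**-(beta + 1)`` and the k-th central
moment as ``U_r**(-k (beta + 1))``.  In log-log coordinates those are
straight lines, so a fitted slope converts directly to an estimate of
``beta``; this module holds that algebra.

All proportionality constants are fixed to one: only the scaling with
velocity is ever used downstream, never an absolute drag or energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BETA_MIN",
    "BETA_MAX",
    "DragParams",
    "ScalingLaw",
    "gamma_pressure_drag",
    "drag_force",
    "energy_spent",
    "slope_from_beta",
    "beta_from_slope",
]

#: Theoretical band for the drag-velocity exponent.  The lower bound arises
#: from skin-friction/undulation arguments, the upper from pure pressure
#: drag; both are taken as given constants here.
BETA_MIN: float = 1.73
BETA_MAX: float = 2.0


class AdmissibilityWarning(UserWarning):
    """A drag exponent lies outside the configured admissible band."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class DragParams:
    """Parameters of the drag law ``F_D = gamma * U_r**beta``.

    Parameters
    ----------
    rho : float
        Water density, g/cm^3.
    L : float
        Total fish length, cm.
    S : float
        Body depth, cm.
    beta : float
        Drag-velocity exponent (dimensionless).
    gamma : float
        Lumped drag scale; its units absorb water properties and fish
        geometry so that ``gamma * U_r**beta`` has the dimension of force.
    A : float or None
        Tail-beat amplitude, cm.  Carried as metadata only.
    beta_bounds : (float, float)
        Admissible band for ``beta``; exceeding it is flagged, not fatal.
    """

    rho: float
    L: float
    S: float
    beta: float
    gamma: float
    A: float | None = None
    beta_bounds: tuple[float, float] = (BETA_MIN, BETA_MAX)

    def __post_init__(self) -> None:
        _require_positive(rho=self.rho, L=self.L, S=self.S, gamma=self.gamma)
        lo, hi = self.beta_bounds
        if not lo <= self.beta <= hi:
            warnings.warn(
                f"beta={self.beta} outside admissible range [{lo}, {hi}]",
                AdmissibilityWarning,
                stacklevel=2,
            )

    @classmethod
    def pressure_drag(
        cls, rho: float, L: float, S: float, beta: float = BETA_MAX, **kw
    ) -> "DragParams":
        """Build parameters with the pressure-drag lumping ``gamma = rho*L*S``."""
        return cls(rho=rho, L=L, S=S, beta=beta,
                   gamma=gamma_pressure_drag(rho, L, S), **kw)


@dataclass(frozen=True)
class ScalingLaw:
    """Power laws for time-to-fatigue moments, ``moment_k = alpha_k * U**slope_k``.

    ``alpha`` maps moment order k to the scaling coefficient alpha_k
    (k = 1 is the mean); coefficients depend on species, size and water
    temperature and must be positive.  The slopes are pinned to ``beta``:
    ``-(beta + 1)`` for the mean, ``-k (beta + 1)`` for central moments.
    """

    beta: float
    alpha: dict[int, float]

    def __post_init__(self) -> None:
        for k, a in self.alpha.items():
            if k < 1 or int(k) != k:
                raise ValueError(f"moment order must be a positive integer, got {k!r}")
            if not a > 0:
                raise ValueError(f"alpha_{k} must be > 0, got {a!r}")

    def slope(self, k: int = 1) -> float:
        return slope_from_beta(self.beta, k)

    def moment(self, U: float | np.ndarray, k: int = 1) -> float | np.ndarray:
        """Evaluate the k-th moment law at velocity ``U`` (cm/s)."""
        return self.alpha[k] * np.asarray(U, dtype=float) ** self.slope(k)


def gamma_pressure_drag(rho: float, L: float, S: float) -> float:
    """Lumped drag scale for dominant pressure drag: ``rho * L * S``.

    Parameters are water density (g/cm^3), total length (cm) and body
    depth (cm); all must be positive.
    """
    _require_positive(rho=rho, L=L, S=S)
    return rho * L * S


def drag_force(
    gamma: float,
    U_r: float | np.ndarray,
    beta: float,
    beta_bounds: tuple[float, float] | None = (BETA_MIN, BETA_MAX),
    strict: bool = False,
) -> float | np.ndarray:
    """Drag force scale ``gamma * U_r**beta``.

    ``U_r`` is the fish-to-water relative velocity (cm/s, >= 0).  A beta
    outside ``beta_bounds`` raises a warning, or ``ValueError`` when
    ``strict``; pass ``beta_bounds=None`` to skip the check.
    """
    _require_positive(gamma=gamma)
    U_r = np.asarray(U_r, dtype=float) if np.ndim(U_r) else float(U_r)
    if np.any(np.asarray(U_r) < 0):
        raise ValueError("U_r must be >= 0")
    if beta_bounds is not None:
        lo, hi = beta_bounds
        if not lo <= beta <= hi:
            msg = f"beta={beta} outside admissible range [{lo}, {hi}]"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, AdmissibilityWarning, stacklevel=2)
    return gamma * U_r**beta


def energy_spent(gamma: float, U_r: float, beta: float, T_f: float) -> float:
    """Energy burned swimming at ``U_r`` for ``T_f`` seconds.

    Power is drag times velocity, ``gamma * U_r**(beta+1)``; integrated over
    a trial of duration ``T_f`` this gives ``gamma * U_r**(beta+1) * T_f``
    (proportionality constant one).  ``T_f`` must be non-negative.
    """
    _require_positive(gamma=gamma)
    if U_r < 0:
        raise ValueError("U_r must be >= 0")
    if T_f < 0:
        raise ValueError(f"T_f must be >= 0, got {T_f!r}")
    return gamma * U_r ** (beta + 1.0) * T_f


def _check_order(k: int) -> int:
    if isinstance(k, bool) or int(k) != k or k < 1:
        raise ValueError(f"moment order k must be an integer >= 1, got {k!r}")
    return int(k)


def slope_from_beta(beta: float, k: int = 1) -> float:
    """Predicted log-log slope of the k-th time-to-fatigue moment vs velocity.

    The mean (k = 1) falls as ``U**-(beta+1)`` and the k-th central moment
    (k >= 2) as ``U**(-k (beta+1))``, so the slope is ``-k * (beta + 1)``.

    >>> slope_from_beta(2.0, 1)
    -3.0
    >>> slope_from_beta(1.73, 2)
    -5.46
    """
    k = _check_order(k)
    return -k * (beta + 1.0)


def beta_from_slope(slope: float, k: int = 1) -> tuple[float, bool]:
    """Invert :func:`slope_from_beta`: ``beta = -slope / k - 1``.

    Returns ``(beta_hat, physical)``.  ``physical`` is False for a
    non-negative slope, whose inverted exponent is <= -1 and carries no
    hydrodynamic meaning; such fits are screened out later rather than
    raising here.
    """
    k = _check_order(k)
    beta_hat = -slope / k - 1.0
    return beta_hat, slope < 0


def predicted_slopes(beta: float, orders: Sequence[int] = (1, 2)) -> dict[int, float]:
    """Convenience: slopes for several moment orders at one beta."""
    return {k: slope_from_beta(beta, k) for k in orders}
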