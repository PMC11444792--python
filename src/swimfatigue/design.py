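"""Fish-passage design algebra built on the mean fatigue curve.

With the mean fatigue curve ``T_f_bar = alpha1 * U_r**-(beta+1)``, a fish
swimming at relative velocity ``U_r`` against an opposing flow ``U_f``
makes headway at ground speed ``U_g = U_r - U_f`` and covers

    D_s(U_r) = (U_r - U_f) * alpha1 * U_r**-(beta + 1)

before fatiguing.  ``D_s`` is unimodal on ``U_r > U_f``: swim barely
faster than the flow and you fatigue slowly but crawl; sprint and you
cover ground fast but fatigue almost immediately.  The maximum sits at

    U_r_opt = U_f * (1 + 1/beta),    U_g_opt = U_f / beta,

so with a drag exponent near 2 the optimal ground speed is about half the
opposing flow.  The corresponding distance,

    D_s_max = (alpha1 / beta) * U_f**-beta * (1 + 1/beta)**-(beta + 1),

is the longest velocity barrier the average fish can pass — the design
length limit for a fishway operating at flow ``U_f``.  All quantities stay
in the unit system of the inputs (cm, cm/s, s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DesignResult", "swim_distance", "optimal_speeds",
           "max_swim_distance", "design_from_fit"]


@dataclass(frozen=True)
class DesignResult:
    """Optimal swimming strategy against one opposing flow velocity."""

    U_f: float            # opposing flow, cm/s
    alpha1: float         # mean fatigue-curve coefficient
    beta: float           # drag exponent
    U_r_opt: float        # optimal relative (swimming) velocity, cm/s
    U_g_opt: float        # optimal ground speed, cm/s
    D_s_max: float        # maximum passable distance, cm


def swim_distance(U_r: float | np.ndarray, U_f: float,
                  alpha1: float, beta: float) -> float | np.ndarray:
    """Distance covered before fatigue at relative velocity ``U_r``.

    Zero when the fish makes no headway (``U_r <= U_f``) and in the
    sprint limit ``U_r -> inf``.
    """
    if not alpha1 > 0:
        raise ValueError("alpha1 must be > 0")
    if U_f < 0:
        raise ValueError("U_f must be >= 0")
    U_r_arr = np.asarray(U_r, dtype=float)
    if np.any(U_r_arr < 0):
        raise ValueError("U_r must be >= 0")
    d = (U_r_arr - U_f) * alpha1 * np.power(U_r_arr, -(beta + 1.0),
                                            where=U_r_arr > 0,
                                            out=np.zeros_like(U_r_arr))
    d = np.where(U_r_arr >= U_f, d, 0.0)   # no headway -> no distance
    return float(d) if np.ndim(U_r) == 0 else d


def optimal_speeds(U_f: float, beta: float) -> tuple[float, float]:
    """Optimal relative velocity and ground speed against flow ``U_f``.

    Returns ``(U_r_opt, U_g_opt) = (U_f (1 + 1/beta), U_f / beta)``.
    """
    if not U_f > 0:
        raise ValueError("U_f must be > 0")
    if not beta > 0:
        raise ValueError("beta must be > 0")
    U_r_opt = U_f * (1.0 + 1.0 / beta)
    return U_r_opt, U_r_opt - U_f


def max_swim_distance(U_f: float, alpha1: float, beta: float) -> float:
    """Maximum passable distance ``D_s(U_r_opt)``, in closed form.

    Equals ``(alpha1/beta) * U_f**-beta * (1 + 1/beta)**-(beta+1)`` — the
    swim-distance function evaluated at the optimal relative velocity.
    """
    if not U_f > 0:
        raise ValueError("U_f must be > 0")
    if not alpha1 > 0:
        raise ValueError("alpha1 must be > 0")
    if not beta > 0:
        raise ValueError("beta must be > 0")
    return (alpha1 / beta) * U_f**-beta * (1.0 + 1.0 / beta) ** -(beta + 1.0)


def design(U_f: float, alpha1: float, beta: float) -> DesignResult:
    """Bundle the optimal speeds and maximum distance for one flow."""
    U_r_opt, U_g_opt = optimal_speeds(U_f, beta)
    return DesignResult(U_f=U_f, alpha1=alpha1, beta=beta,
                        U_r_opt=U_r_opt, U_g_opt=U_g_opt,
                        D_s_max=max_swim_distance(U_f, alpha1, beta))


def design_from_fit(fit, U_f: float) -> DesignResult:
    """Design numbers from a fitted mean fatigue curve.

    ``fit`` is a k=1 :class:`~swimfatigue.analysis.FitResult`; the curve
    coefficient is recovered from the log-log intercept,
    ``alpha1 = exp(intercept)``.
    """
    if fit.k != 1:
        raise ValueError("design requires a k=1 (mean-curve) fit")
    if not fit.physical:
        raise ValueError("fit has a non-physical (non-negative) slope")
    return design(U_f=U_f, alpha1=fit.alpha_coefficient, beta=fit.beta_hat)
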