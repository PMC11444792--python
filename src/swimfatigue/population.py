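"""Synthetic fixed-velocity fatigue experiments.

Generates trials tables with the statistical structure the moment-scaling
analysis assumes.  Each synthetic fish carries an individual anaerobic
energy reserve ``E_i`` (lognormal by default: strictly positive and
right-skewed, matching the wide spread seen in real time-to-fatigue data)
and a body geometry drawn from a truncated normal length distribution with
depth proportional to length.  A trial at flow velocity ``U_f`` then
resolves deterministically through the energy budget::

    T_f = E_i / (Gamma(L_i) * U_f**(beta_true + 1)),   Gamma = rho * L * S

with the relative velocity equated to the bulk flow velocity, as in flume
tests.  Two contamination channels emulate real experiments: trials fail
outright with probability ``failure_prob`` (no time recorded), and trials
are occasionally partly aerobic, inflating ``T_f`` by a multiplicative
factor.  Aerobic episodes are made more likely at the lower test
velocities — the slower the flow, the more plausible it is that red-muscle
metabolism contributes — which is what biases fitted scaling exponents
high when left unscreened.

Each fish is used in exactly one trial (no repeated measures).  All
randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .theory import BETA_MIN, BETA_MAX, gamma_pressure_drag

__all__ = [
    "PopulationConfig",
    "SpeciesPreset",
    "SPECIES_PRESETS",
    "sample_fish",
    "simulate_trial",
    "simulate_experiment",
]

#: Columns of a trials table, in serialization order.
TRIAL_COLUMNS = [
    "species", "fish_id", "fork_length", "body_depth", "mass",
    "U_f", "temperature", "T_f", "success", "is_outlier",
]

_ENERGY_FAMILIES = ("lognormal", "gamma", "point")


@dataclass(frozen=True)
class PopulationConfig:
    """Generative parameters of a synthetic fish population.

    Lengths are in cm, velocities in cm/s, temperature in deg C.  The
    energy reserve is parameterized on the log scale (``energy_logmean``,
    ``energy_logsd``); for the gamma family the same two numbers are
    converted to a matching mean and coefficient of variation, and the
    point family ignores ``energy_logsd``.  Energy units are arbitrary:
    only ratios of ``T_f`` across velocities matter downstream, so the
    efficiency factor converting anaerobic reserves to mechanical work is
    absorbed into them.
    """

    species: str = "synthetic"
    length_mean: float = 4.87
    length_sd: float = 0.46
    length_min: float = 4.0
    length_max: float = 6.6
    depth_allometry: float = 0.22       # body depth S = c * fork length
    mass_condition: float = 0.0135      # mass = K * L**3, metadata only
    rho: float = 1.0                    # water density, g/cm^3
    energy_dist: str = "lognormal"
    energy_logmean: float = math.log(6.5e6)
    energy_logsd: float = 0.5
    beta_true: float = 2.0
    temperature: float = 13.4
    outlier_prob: float = 0.0
    outlier_factor_range: tuple[float, float] = (5.0, 20.0)
    outlier_velocity_exponent: float = 6.0
    failure_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.energy_dist not in _ENERGY_FAMILIES:
            raise ValueError(
                f"energy_dist must be one of {_ENERGY_FAMILIES}, got {self.energy_dist!r}")
        if not 0 <= self.outlier_prob < 1:
            raise ValueError("outlier_prob must be in [0, 1)")
        if not 0 <= self.failure_prob < 1:
            raise ValueError("failure_prob must be in [0, 1)")
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")
        if not self.length_min <= self.length_max:
            raise ValueError("infeasible truncation bounds: length_min > length_max")
        if self.length_sd == 0 and not (
                self.length_min <= self.length_mean <= self.length_max):
            raise ValueError(
                "infeasible truncation bounds: degenerate length_mean outside bounds")
        if self.energy_logsd < 0:
            raise ValueError("energy_logsd must be >= 0")
        lo, hi = self.outlier_factor_range
        if not 1.0 <= lo <= hi:
            raise ValueError("outlier_factor_range must satisfy 1 <= low <= high")
        if self.outlier_velocity_exponent < 0:
            raise ValueError("outlier_velocity_exponent must be >= 0")
        for name in ("length_mean", "depth_allometry", "rho", "beta_true"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def with_(self, **kw) -> "PopulationConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outlier_factor_range"] = list(self.outlier_factor_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        if "outlier_factor_range" in d:
            d["outlier_factor_range"] = tuple(d["outlier_factor_range"])
        return cls(**d)


@dataclass(frozen=True)
class SpeciesPreset:
    """Published summary of one species' fixed-velocity test campaign."""

    species: str
    total_fish: int
    successful_trials: int
    velocities: tuple[float, ...]
    length_min: float
    length_max: float
    length_mean: float
    length_sd: float
    temperature: float
    mass_mean: float

    @property
    def failure_prob(self) -> float:
        return 1.0 - self.successful_trials / self.total_fish

    def config(self, **overrides) -> PopulationConfig:
        """Population config emulating this species' campaign."""
        kw = dict(
            species=self.species,
            length_mean=self.length_mean,
            length_sd=self.length_sd,
            length_min=self.length_min,
            length_max=self.length_max,
            temperature=self.temperature,
            mass_condition=self.mass_mean / self.length_mean**3,
            failure_prob=round(self.failure_prob, 6),
        )
        kw.update(overrides)
        return PopulationConfig(**kw)


#: Five small riverine Cypriniformes, as tested in the flume campaign the
#: generator emulates: sample sizes, test velocities (cm/s), fork-length
#: statistics (cm), mean water temperature (deg C) and mean mass (g).
SPECIES_PRESETS: dict[str, SpeciesPreset] = {
    p.species: p
    for p in [
        SpeciesPreset("Telestes muticellus", 202, 180, (40, 45, 50, 55),
                      4.0, 6.6, 4.87, 0.46, 13.4, 1.56),
        SpeciesPreset("Phoxinus phoxinus", 225, 162, (50, 55, 60),
                      3.7, 6.8, 4.90, 0.70, 16.2, 2.05),
        SpeciesPreset("Rhodeus amarus", 148, 90, (45, 50, 55),
                      5.4, 6.7, 6.04, 0.34, 11.7, 3.13),
        SpeciesPreset("Leucos aula", 160, 112, (45, 50, 55),
                      4.6, 6.0, 5.24, 0.36, 12.7, 1.85),
        SpeciesPreset("Alburnus alborella", 115, 82, (45, 50, 55),
                      4.5, 6.0, 5.04, 0.38, 11.4, 1.16),
    ]
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_lengths(config: PopulationConfig, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    if config.length_sd == 0:
        return np.full(n, config.length_mean)
    a = (config.length_min - config.length_mean) / config.length_sd
    b = (config.length_max - config.length_mean) / config.length_sd
    if a >= b:
        raise ValueError("infeasible truncation bounds for length distribution")
    return stats.truncnorm.rvs(a, b, loc=config.length_mean,
                               scale=config.length_sd, size=n, random_state=rng)


def _sample_energies(config: PopulationConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    mu, sig = config.energy_logmean, config.energy_logsd
    if config.energy_dist == "point" or sig == 0:
        return np.full(n, math.exp(mu))
    if config.energy_dist == "lognormal":
        return rng.lognormal(mean=mu, sigma=sig, size=n)
    # gamma family matched to the lognormal's mean and CV
    mean = math.exp(mu + sig**2 / 2)
    cv2 = math.exp(sig**2) - 1.0
    shape = 1.0 / cv2
    return rng.gamma(shape=shape, scale=mean / shape, size=n)


def sample_fish(config: PopulationConfig, n: int,
                seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``n`` synthetic fish.

    Fork lengths come from a normal distribution truncated to
    ``[length_min, length_max]``; body depth is ``depth_allometry * L`` and
    mass ``mass_condition * L**3`` (Fulton-type condition, metadata only).
    Energy reserves are i.i.d. from the configured family.  Reproducible
    given a seed; defaults to ``config.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(config.seed if seed is None else seed)
    L = _sample_lengths(config, n, rng)
    E = _sample_energies(config, n, rng)
    return pd.DataFrame({
        "fish_id": np.arange(n),
        "fork_length": L,
        "body_depth": config.depth_allometry * L,
        "mass": config.mass_condition * L**3,
        "energy": E,
    })


def _time_to_fatigue(fish: pd.Series | dict, U_f: float,
                     config: PopulationConfig) -> float:
    gamma = gamma_pressure_drag(config.rho, fish["fork_length"], fish["body_depth"])
    return fish["energy"] / (gamma * U_f ** (config.beta_true + 1.0))


def simulate_trial(fish, U_f: float, config: PopulationConfig,
                   rng: np.random.Generator | int | None = None,
                   outlier_prob: float | None = None) -> dict:
    """Run one fish once at a fixed flow velocity; return a trial record.

    With probability ``failure_prob`` the trial is unsuccessful and no time
    is recorded.  Otherwise the energy budget fixes ``T_f``, after which an
    aerobic episode (probability ``outlier_prob``, overridable per call so
    experiments can weight it by velocity) inflates it by a factor drawn
    uniformly from ``outlier_factor_range``.
    """
    if not U_f > 0:
        raise ValueError("U_f must be > 0")
    rng = _as_rng(rng)
    p_out = config.outlier_prob if outlier_prob is None else outlier_prob
    rec = {
        "species": config.species,
        "fish_id": fish["fish_id"],
        "fork_length": fish["fork_length"],
        "body_depth": fish["body_depth"],
        "mass": fish.get("mass", np.nan) if hasattr(fish, "get") else fish["mass"],
        "U_f": float(U_f),
        "temperature": config.temperature,
        "T_f": np.nan,
        "success": False,
        "is_outlier": False,
    }
    if rng.random() < config.failure_prob:
        return rec
    T_f = _time_to_fatigue(fish, U_f, config)
    if p_out > 0 and rng.random() < p_out:
        T_f *= rng.uniform(*config.outlier_factor_range)
        rec["is_outlier"] = True
    rec["T_f"] = T_f
    rec["success"] = True
    return rec


def outlier_prob_by_velocity(config: PopulationConfig,
                             velocities: Sequence[float]) -> np.ndarray:
    """Per-velocity aerobic-episode probability.

    ``outlier_prob`` applies at the lowest test velocity and decays as
    ``(U_min / U) ** outlier_velocity_exponent``: slow flows leave room for
    aerobic metabolism, fast ones do not.  An exponent of 0 makes
    contamination uniform across velocities.
    """
    U = np.asarray(velocities, dtype=float)
    if np.any(U <= 0):
        raise ValueError("velocities must be > 0")
    scale = (U.min() / U) ** config.outlier_velocity_exponent
    return np.clip(config.outlier_prob * scale, 0.0, 1.0)


def simulate_experiment(config: PopulationConfig,
                        velocities: Sequence[float],
                        n_per_velocity: int,
                        seed: int | np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Simulate a full fixed-velocity campaign; return the trials table.

    ``n_per_velocity`` fresh fish are tested at each velocity (one trial
    per fish, never reused), unsuccessful trials included in the output
    with an empty ``T_f``.  Vectorized; reproducible given the seed.
    """
    velocities = list(velocities)
    if not velocities:
        raise ValueError("velocities must be non-empty")
    if n_per_velocity < 1:
        raise ValueError("n_per_velocity must be >= 1")
    rng = _as_rng(config.seed if seed is None else seed)

    n_total = len(velocities) * n_per_velocity
    fish = sample_fish(config, n_total, seed=rng)
    U = np.repeat(np.asarray(velocities, dtype=float), n_per_velocity)
    p_out = np.repeat(outlier_prob_by_velocity(config, velocities), n_per_velocity)

    gamma = config.rho * fish["fork_length"].to_numpy() * fish["body_depth"].to_numpy()
    T_f = fish["energy"].to_numpy() / (gamma * U ** (config.beta_true + 1.0))

    failed = rng.random(n_total) < config.failure_prob
    is_outlier = (rng.random(n_total) < p_out) & ~failed
    factors = rng.uniform(*config.outlier_factor_range, size=n_total)
    T_f = np.where(is_outlier, T_f * factors, T_f)
    T_f = np.where(failed, np.nan, T_f)

    out = pd.DataFrame({
        "species": config.species,
        "fish_id": fish["fish_id"],
        "fork_length": fish["fork_length"],
        "body_depth": fish["body_depth"],
        "mass": fish["mass"],
        "U_f": U,
        "temperature": config.temperature,
        "T_f": T_f,
        "success": ~failed,
        "is_outlier": is_outlier,
    })
    return out[TRIAL_COLUMNS]
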