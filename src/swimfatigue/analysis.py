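"""Moment-scaling estimation of the drag exponent from trials tables.

The pipeline mirrors how fixed-velocity campaigns are analysed:

1. successful trials are reorganized into subsamples within which fork
   length varies by at most +/-10%, so each group approximates a
   population of fish "of the same size";
2. per group and per test velocity, the mean and the k-th central moment
   of time-to-fatigue are computed (plain divide-by-n averaging);
3. each moment series is regressed on velocity in log-log coordinates —
   one point per velocity level, unweighted — and the slope converted to
   an estimate of the drag exponent, ``beta_hat = -slope/k - 1``;
4. fits failing the overall F-test of zero slope at the 5% level are
   screened out, and each fit is scored with the reliability index
   ``ReI = p * ln(U_max / U_min)`` where ``p`` counts the individual
   trials behind the regression — more trials over a wider velocity
   range, more trustworthy exponent.

Kernel density estimates of the per-velocity time-to-fatigue distribution
and case-resampling bootstrap intervals support the descriptive side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .theory import beta_from_slope

__all__ = [
    "SubsampleGroup",
    "MomentSeries",
    "FitResult",
    "DensityEstimate",
    "PipelineResult",
    "PooledEstimate",
    "subsample_by_length",
    "compute_moments",
    "fit_loglog",
    "reliability_index",
    "kde_density",
    "bootstrap_ci",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_TOLERANCE = 0.10
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SubsampleGroup:
    """Trials whose fork lengths all lie within +/-tolerance of a center."""

    group_id: str
    trials: pd.DataFrame
    length_center: float
    max_relative_deviation: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def check(self) -> bool:
        """Direct check of the length-window invariant."""
        L = self.trials["fork_length"].to_numpy(dtype=float)
        tol = self.max_relative_deviation
        return bool(np.all(np.abs(L - self.length_center)
                           <= tol * self.length_center + 1e-12))


@dataclass(frozen=True)
class MomentSeries:
    """Per-velocity sample size and k-th moment of T_f within one group.

    ``k = 1`` is the mean; ``k >= 2`` the k-th central moment
    (population convention unless built with ``ddof=1``).
    """

    group_id: str
    k: int
    table: pd.DataFrame  # columns U_f, n, value; one row per velocity

    @property
    def n_trials(self) -> int:
        return int(self.table["n"].sum())


@dataclass(frozen=True)
class FitResult:
    """Log-log regression of one moment series, with the derived exponent."""

    group_id: str
    k: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    beta_hat: float
    physical: bool          # slope was negative, so beta_hat is meaningful
    accepted: bool          # p_value below the screening level
    rei: float
    n_points: int           # velocity levels entering the regression
    p_trials: int           # individual trials behind those levels
    U_min: float
    U_max: float
    species: str | None = None

    @property
    def alpha_coefficient(self) -> float:
        """Scaling coefficient alpha_k = exp(intercept) of the power law."""
        return float(np.exp(self.intercept))


@dataclass(frozen=True)
class DensityEstimate:
    """Gaussian-kernel density of T_f at one velocity."""

    U_f: float
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def interquartile_width(self) -> float:
        """Width between the 25th and 75th percentiles of the estimate."""
        cdf = np.cumsum(self.density)
        cdf = cdf / cdf[-1]
        lo = self.grid[np.searchsorted(cdf, 0.25)]
        hi = self.grid[np.searchsorted(cdf, 0.75)]
        return float(hi - lo)


class FitRefusedError(ValueError):
    """A regression could not be run (too few usable velocity levels)."""


def subsample_by_length(trials: pd.DataFrame,
                        tolerance: float = DEFAULT_LENGTH_TOLERANCE,
                        group_prefix: str = "g") -> list[SubsampleGroup]:
    """Partition successful trials into fork-length windows.

    Greedy sweep over length-sorted trials: open a group at the smallest
    unassigned length and absorb fish while ``max/min <= (1+tol)/(1-tol)``
    — the widest spread compatible with every member sitting within
    +/-tolerance of a common center.  Groups are disjoint, cover all
    successful trials, and are deterministic (ties broken by row order).
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    ok = trials[trials["success"].astype(bool)]
    if ok.empty:
        return []
    order = ok.sort_values(["fork_length"], kind="stable")
    L = order["fork_length"].to_numpy(dtype=float)
    ratio_bound = (1 + tolerance) / (1 - tolerance) if tolerance < 1 else np.inf

    groups: list[SubsampleGroup] = []
    start = 0
    while start < len(L):
        stop = start
        while stop < len(L) and L[stop] <= L[start] * ratio_bound:
            stop += 1
        members = order.iloc[start:stop]
        lo, hi = L[start], L[stop - 1]
        # any center with hi <= (1+tol) c and lo >= (1-tol) c works; take the midpoint
        center = 0.5 * (lo / (1 - min(tolerance, 0.999999)) + hi / (1 + tolerance))
        center = float(np.clip(center, hi / (1 + tolerance),
                               lo / (1 - min(tolerance, 0.999999))))
        groups.append(SubsampleGroup(
            group_id=f"{group_prefix}{len(groups)}",
            trials=members,
            length_center=center,
            max_relative_deviation=tolerance,
        ))
        start = stop
    return groups


def compute_moments(group: SubsampleGroup | pd.DataFrame,
                    k_max: int = 2,
                    ddof: int = 0) -> list[MomentSeries]:
    """Per-velocity moments of T_f for orders 1..k_max.

    Order 1 is the arithmetic mean; order k >= 2 the k-th central moment,
    by default with the population (divide-by-n) convention that matches
    the plain averaging operator of the scaling derivation (``ddof=1``
    switches order 2 to the sample convention).  Velocities with fewer
    than two trials are omitted from central-moment series.
    """
    if k_max < 1 or int(k_max) != k_max:
        raise ValueError("k_max must be an integer >= 1")
    if isinstance(group, SubsampleGroup):
        trials, gid = group.trials, group.group_id
    else:
        trials, gid = group, "all"
    ok = trials[trials["success"].astype(bool)]
    if ok.empty:
        raise ValueError("group contains no successful trials")

    out: list[MomentSeries] = []
    grouped = ok.groupby("U_f")["T_f"]
    for k in range(1, int(k_max) + 1):
        rows = []
        for U, vals in grouped:
            x = vals.to_numpy(dtype=float)
            n = len(x)
            if k == 1:
                rows.append((U, n, x.mean()))
            elif n >= 2:
                dev = x - x.mean()
                denom = n - ddof if k == 2 else n
                rows.append((U, n, float((dev**k).sum() / denom)))
        table = pd.DataFrame(rows, columns=["U_f", "n", "value"]).sort_values("U_f")
        out.append(MomentSeries(group_id=gid, k=k, table=table.reset_index(drop=True)))
    return out


def reliability_index(p_trials: int, U_max: float, U_min: float) -> float:
    """``ReI = p * ln(U_max / U_min)``: trial count times log velocity span."""
    if p_trials < 0:
        raise ValueError("p_trials must be >= 0")
    if not 0 < U_min <= U_max:
        raise ValueError("need U_max >= U_min > 0")
    return p_trials * float(np.log(U_max / U_min))


def fit_loglog(series: MomentSeries,
               alpha: float = DEFAULT_ALPHA,
               species: str | None = None) -> FitResult:
    """OLS of ln(moment) on ln(U_f), one point per velocity level.

    Velocities with non-positive moment values cannot be log-transformed
    and are dropped with a warning; fewer than three usable levels refuses
    the fit.  Significance is the regression overall F-test of zero slope
    (with a single predictor, the squared slope t-test); ``accepted`` is
    ``p_value < alpha``.  The exponent estimate and the reliability index
    are attached.
    """
    t = series.table
    usable = t[t["value"] > 0]
    dropped = t[~(t["value"] > 0)]
    if not dropped.empty:
        logger.warning("group %s k=%d: dropped %d velocity level(s) with "
                       "non-positive moment: %s", series.group_id, series.k,
                       len(dropped), dropped["U_f"].tolist())
    if len(usable) < 3:
        raise FitRefusedError(
            f"group {series.group_id} k={series.k}: {len(usable)} usable velocity "
            "level(s); at least 3 required for a log-log fit")

    x = np.log(usable["U_f"].to_numpy(dtype=float))
    y = np.log(usable["value"].to_numpy(dtype=float))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0])
    # numerically perfect fits make the F statistic degenerate: a noiseless
    # power law is unambiguous evidence of slope, a constant series of none
    scale = 1e-24 * max(1.0, float(np.abs(y).max()) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_value = float(model.f_pvalue)
        r_squared = float(model.rsquared)
        if not np.isfinite(p_value) or model.ssr <= scale:
            p_value = 1.0 if float(model.ess) <= scale else 0.0
        if not np.isfinite(r_squared):
            r_squared = 0.0
    beta_hat, physical = beta_from_slope(slope, series.k)

    p_trials = int(usable["n"].sum())
    U_min = float(usable["U_f"].min())
    U_max = float(usable["U_f"].max())
    return FitResult(
        group_id=series.group_id,
        k=series.k,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        p_value=p_value,
        beta_hat=beta_hat,
        physical=physical,
        accepted=bool(p_value < alpha),
        rei=reliability_index(p_trials, U_max, U_min),
        n_points=len(usable),
        p_trials=p_trials,
        U_min=U_min,
        U_max=U_max,
        species=species,
    )


def kde_density(values: Sequence[float],
                U_f: float = float("nan"),
                bandwidth_rule: str = "silverman",
                grid_size: int = 512) -> DensityEstimate:
    """Gaussian-kernel density estimate of a T_f sample.

    The grid covers ``[0, max + 3*bandwidth]`` — time-to-fatigue is
    non-negative, so mass the kernels place below zero is excluded and the
    reported integral may fall slightly short of one (no renormalization).
    A degenerate (zero-variance) sample gets a single narrow peak.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if np.ptp(x) == 0:
        h = max(1e-3 * abs(x[0]), 1e-6)
        grid = np.linspace(max(0.0, x[0] - 4 * h), x[0] + 4 * h, grid_size)
        dens = stats.norm.pdf(grid, loc=x[0], scale=h)
        return DensityEstimate(U_f=U_f, grid=grid, density=dens,
                               bandwidth=h, n=len(x))
    kde = stats.gaussian_kde(x, bw_method=bandwidth_rule)
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(0.0, x.max() + 3 * h, grid_size)
    return DensityEstimate(U_f=U_f, grid=grid, density=kde(grid),
                           bandwidth=h, n=len(x))


def bootstrap_ci(values: Sequence[float],
                 statistic: Callable[[np.ndarray], float] = np.mean,
                 reps: int = 2000,
                 level: float = 0.95,
                 seed: int | np.random.Generator | None = None
                 ) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of one sample.

    Case resampling with replacement; degenerate input yields a zero-width
    interval.  Reproducible given a seed.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    boots = np.apply_along_axis(statistic, 1, x[idx])
    lo, hi = np.quantile(boots, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


@dataclass
class PipelineResult:
    """Everything the estimation pipeline produces for one trials table."""

    fits: list[FitResult]
    refused: list[dict]                  # groups/orders where no fit was possible
    groups: list[SubsampleGroup]
    densities: list[DensityEstimate] = field(default_factory=list)
    success_summary: pd.DataFrame | None = None

    def fits_frame(self) -> pd.DataFrame:
        cols = ["species", "group_id", "k", "slope", "intercept", "r_squared",
                "p_value", "beta_hat", "physical", "accepted", "rei",
                "n_points", "p_trials", "U_min", "U_max"]
        if not self.fits:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([{c: getattr(f, c) for c in cols} for f in self.fits])

    def best_fit(self, k: int = 1, accepted_only: bool = True) -> FitResult | None:
        """Highest-reliability fit of a given moment order."""
        pool = [f for f in self.fits
                if f.k == k and (f.accepted or not accepted_only)]
        return max(pool, key=lambda f: f.rei, default=None)

    def pooled(self, k: int = 1, accepted_only: bool = False
               ) -> "PooledEstimate | None":
        """Reliability-weighted summary over subsample groups.

        Each physical fit of order ``k`` contributes its slope and exponent
        estimate with weight ``ReI`` — the index that scores how much a
        group's regression can be trusted.  Returns None when no physical
        fit exists.
        """
        pool = [f for f in self.fits
                if f.k == k and f.physical and (f.accepted or not accepted_only)]
        if not pool:
            return None
        w = np.array([f.rei for f in pool], dtype=float)
        if w.sum() == 0:
            w = np.ones_like(w)
        slopes = np.array([f.slope for f in pool])
        betas = np.array([f.beta_hat for f in pool])
        return PooledEstimate(
            k=k,
            slope=float(np.average(slopes, weights=w)),
            beta_hat=float(np.average(betas, weights=w)),
            total_rei=float(w.sum()),
            n_fits=len(pool),
            p_trials=int(sum(f.p_trials for f in pool)),
        )


@dataclass(frozen=True)
class PooledEstimate:
    """ReI-weighted average of slopes/exponents across subsample groups."""

    k: int
    slope: float
    beta_hat: float
    total_rei: float
    n_fits: int
    p_trials: int


def success_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-species trial counts and success rates, plus a pooled total.

    Percentages are rounded half-up to the nearest integer.
    """
    def _pct(succ: int, total: int) -> int:
        return int(100.0 * succ / total + 0.5) if total else 0

    def _one(df: pd.DataFrame) -> pd.Series:
        total = len(df)
        succ = int(df["success"].astype(bool).sum())
        return pd.Series({"total_fish": total, "successful_trials": succ,
                          "success_rate_pct": _pct(succ, total)})
    per = trials.groupby("species").apply(_one, include_groups=False)
    per = per.astype({"total_fish": int, "successful_trials": int,
                      "success_rate_pct": int})
    total = len(trials)
    succ = int(trials["success"].astype(bool).sum())
    per.loc["TOTAL"] = [total, succ, _pct(succ, total)]
    return per


def run_pipeline(trials: pd.DataFrame,
                 k_max: int = 2,
                 tolerance: float = DEFAULT_LENGTH_TOLERANCE,
                 alpha: float = DEFAULT_ALPHA,
                 ddof: int = 0,
                 with_densities: bool = False) -> PipelineResult:
    """Full estimation pass over a trials table.

    Per species: length-window subsampling, per-velocity moments for
    orders 1..k_max, log-log fits, significance screening, exponent
    conversion and reliability scoring.  Unsuccessful trials are excluded
    from the statistics but counted in the success summary.  Groups where
    no regression is possible are reported in ``refused`` rather than
    raising.  No multiplicity correction is applied across groups; the
    p-values are per-fit.
    """
    fits: list[FitResult] = []
    refused: list[dict] = []
    all_groups: list[SubsampleGroup] = []
    densities: list[DensityEstimate] = []

    for species, sub in trials.groupby("species", sort=True):
        groups = subsample_by_length(sub, tolerance=tolerance,
                                     group_prefix=f"{species}/g")
        all_groups.extend(groups)
        for g in groups:
            try:
                series_list = compute_moments(g, k_max=k_max, ddof=ddof)
            except ValueError as e:
                refused.append({"species": species, "group_id": g.group_id,
                                "k": None, "reason": str(e)})
                continue
            for series in series_list:
                try:
                    fits.append(fit_loglog(series, alpha=alpha, species=species))
                except FitRefusedError as e:
                    refused.append({"species": species, "group_id": g.group_id,
                                    "k": series.k, "reason": str(e)})
        if with_densities:
            ok = sub[sub["success"].astype(bool)]
            for U, vals in ok.groupby("U_f")["T_f"]:
                if len(vals) >= 2:
                    densities.append(kde_density(vals, U_f=float(U)))

    return PipelineResult(fits=fits, refused=refused, groups=all_groups,
                          densities=densities,
                          success_summary=success_summary(trials))
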