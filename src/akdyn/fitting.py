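"""Global chi-square fitting of the kinetic model to turnover data.

Activity datasets (v0 versus substrate concentration, with standard errors)
measured at several urea concentrations are fitted jointly: the catalytic
and rearrangement rate constants (k_cat, k_r_T, k_r_M) are shared across
urea levels -- the shielded active site makes them urea-insensitive -- while
the AMP affinity and the conformational rates are per-urea inputs measured
independently (MST, smFRET).  Confidence intervals come from profile
likelihood: each parameter is stepped over a grid, the others re-optimized,
and the interval is the region where the reduced chi-square stays within a
threshold of its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import steady_state_turnover, velocity_curve
from .params import Conditions, ModelParameters

#: Parameters that may be fitted (all optimized in log-space).
FITTABLE = ("k_cat", "k_r_T", "k_r_M", "Kd_ATP", "Kd_AMP")


@dataclass(frozen=True)
class ActivityDataset:
    """One turnover-vs-substrate curve at fixed co-substrate and urea.

    ``axis`` names the scanned substrate; ``fixed_conc`` is the co-substrate
    concentration (M).  Rows carry concentration (M), v0 (s^-1 per enzyme)
    and its standard error.
    """

    axis: str                      # "ATP" or "AMP"
    fixed_conc: float              # co-substrate concentration, M
    urea: float                    # M, dataset label
    conc: np.ndarray
    v0: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conc, float)
        v = np.asarray(self.v0, float)
        s = np.asarray(self.sem, float)
        object.__setattr__(self, "conc", c)
        object.__setattr__(self, "v0", v)
        object.__setattr__(self, "sem", s)
        if self.axis not in ("ATP", "AMP"):
            raise ValueError("axis must be 'ATP' or 'AMP'")
        if not (c.size == v.size == s.size):
            raise ValueError("conc, v0 and sem must have equal length")
        if c.size < 4:
            raise ValueError("dataset needs at least 4 rows")
        if np.any(s <= 0):
            raise ValueError("standard errors must be positive")

    def conditions(self) -> List[Conditions]:
        if self.axis == "AMP":
            return [Conditions(atp=self.fixed_conc, amp=c, urea=self.urea) for c in self.conc]
        return [Conditions(atp=c, amp=self.fixed_conc, urea=self.urea) for c in self.conc]


@dataclass(frozen=True)
class SharedParameterSpec:
    """Role assignment for every fittable parameter.

    ``global_free`` parameters take one value shared by all datasets;
    ``fixed`` parameters are read from the per-urea base parameter sets
    (typically Kd_AMP from MST and the conformational rates from smFRET).
    Any fittable parameter not listed as free is fixed.
    """

    global_free: Tuple[str, ...] = ("k_cat", "k_r_T", "k_r_M")

    def __post_init__(self) -> None:
        unknown = set(self.global_free) - set(FITTABLE)
        if unknown:
            raise ValueError(f"unknown fittable parameters: {sorted(unknown)}")


@dataclass
class FitResult:
    """Best-fit parameter values, reduced chi-square and confidence intervals."""

    values: Dict[str, float]
    fixed: Dict[float, ModelParameters]       # per-urea base parameter sets
    chi2_red: float
    n_points: int
    n_free: int
    converged: bool
    conf_intervals: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def parameters_for(self, urea: float) -> ModelParameters:
        """Base parameters of a urea level with the fitted values swapped in."""
        return self.fixed[urea].with_updates(**self.values)


def _chi2(datasets: Sequence[ActivityDataset], params_by_urea: Mapping[float, ModelParameters]) -> float:
    return float(np.sum(_residuals(datasets, params_by_urea) ** 2))


def _residuals(datasets: Sequence[ActivityDataset], params_by_urea: Mapping[float, ModelParameters]) -> np.ndarray:
    res = []
    for ds in datasets:
        params = params_by_urea[ds.urea]
        for cond, v_obs, sem in zip(ds.conditions(), ds.v0, ds.sem):
            v_model, _ = steady_state_turnover(params, cond)
            res.append((v_model - v_obs) / sem)
    return np.asarray(res)


def global_fit(
    datasets: Sequence[ActivityDataset],
    spec: SharedParameterSpec,
    inputs: Mapping[float, ModelParameters],
    n_starts: int = 16,
    seed: int = 1234,
    start_guess: Optional[Mapping[str, float]] = None,
) -> FitResult:
    """Globally fit the shared rate constants across urea levels.

    ``inputs`` maps each dataset's urea label to a complete base
    ModelParameters carrying the per-urea fixed inputs.  The free parameters
    of ``spec`` are optimized in log-space by trust-region least squares,
    restarted from ``n_starts`` points log-uniform within +/-2 decades of the
    seed guess (deterministic RNG); the best final chi-square wins.
    Non-convergence of every start is reported via ``converged=False`` rather
    than an exception.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    missing = {ds.urea for ds in datasets} - set(inputs)
    if missing:
        raise ValueError(f"no base parameters supplied for urea levels {sorted(missing)}")
    free = list(spec.global_free)
    if not free:
        raise ValueError("no free parameters to fit")

    base_guess = np.array([
        (start_guess or {}).get(name, getattr(inputs[datasets[0].urea], name))
        for name in free
    ])
    if np.any(base_guess <= 0):
        raise ValueError("start guesses must be positive")
    log_guess = np.log10(base_guess)

    def params_by_urea(theta_log: np.ndarray) -> Dict[float, ModelParameters]:
        updates = {name: 10.0 ** v for name, v in zip(free, theta_log)}
        return {urea: p.with_updates(**updates) for urea, p in inputs.items()}

    def residuals(theta_log: np.ndarray) -> np.ndarray:
        return _residuals(datasets, params_by_urea(theta_log))

    rng = np.random.default_rng(seed)
    starts = [log_guess]
    starts += [log_guess + rng.uniform(-2.0, 2.0, len(free)) for _ in range(n_starts - 1)]

    best = None
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, method="trf",
                                bounds=(log_guess - 4, log_guess + 4),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        any_success = any_success or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    # unbounded Levenberg-Marquardt polish: pins the optimum so tightly that
    # dataset ordering (float summation order) cannot move it
    try:
        polished = least_squares(residuals, best.x, method="lm", xtol=1e-15, ftol=1e-15)
        if polished.cost <= best.cost:
            best = polished
    except Exception:
        pass

    n_points = sum(ds.conc.size for ds in datasets)
    dof = max(n_points - len(free), 1)
    chi2_red = float(2 * best.cost / dof)
    values = {name: float(10.0 ** v) for name, v in zip(free, best.x)}
    return FitResult(
        values=values,
        fixed=dict(inputs),
        chi2_red=chi2_red,
        n_points=n_points,
        n_free=len(free),
        converged=bool(any_success),
    )


def profile_ci(
    fit: FitResult,
    datasets: Sequence[ActivityDataset],
    spec: SharedParameterSpec,
    param: str,
    grid: Sequence[float],
    threshold: Optional[float] = None,
) -> Tuple[float, float, bool, bool]:
    """Profile-likelihood confidence interval for one fitted parameter.

    The parameter is clamped at each grid value while the remaining free
    parameters are re-optimized; the interval is the grid region where the
    reduced chi-square stays below chi2_red_min + threshold.  The default
    threshold corresponds to Delta-chi2 = 1 on the profiled parameter (a 1
    sigma interval): threshold = 1 / dof.

    Returns ``(lower, upper, lower_open, upper_open)`` -- an open flag marks
    a bound that never crossed the threshold inside the grid (for example a
    rate so fast it is no longer limiting, where only a lower bound exists).
    """
    if param not in fit.values:
        raise ValueError(f"{param} was not a free parameter of the fit")
    if not fit.converged:
        raise ValueError("profile_ci requires a converged fit")
    grid = np.sort(np.asarray(list(grid), float))
    dof = max(fit.n_points - fit.n_free, 1)
    if threshold is None:
        threshold = 1.0 / dof
    others = tuple(name for name in spec.global_free if name != param)

    profile = []
    for value in grid:
        inputs_clamped = {
            urea: p.with_updates(**{param: float(value)}) for urea, p in fit.fixed.items()
        }
        if others:
            sub = global_fit(
                datasets, SharedParameterSpec(global_free=others), inputs_clamped,
                n_starts=1, start_guess={k: fit.values[k] for k in others},
            )
            profile.append(sub.chi2_red)
        else:
            pb = {urea: p for urea, p in inputs_clamped.items()}
            chi2 = _chi2(datasets, pb)
            profile.append(chi2 / dof)
    profile = np.asarray(profile)
    limit = profile.min() + threshold
    inside = profile <= limit
    if not inside.any():
        raise RuntimeError("profile never reaches its own minimum; grid too coarse")
    idx = np.flatnonzero(inside)
    lower_open = bool(idx[0] == 0)
    upper_open = bool(idx[-1] == grid.size - 1)
    # linear interpolation of the threshold crossings between grid points
    if lower_open:
        lower = float(grid[0])
    else:
        i = idx[0]
        frac = (limit - profile[i - 1]) / (profile[i] - profile[i - 1])
        lower = float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))
    if upper_open:
        upper = float(grid[-1])
    else:
        j = idx[-1]
        frac = (limit - profile[j + 1]) / (profile[j] - profile[j + 1])
        upper = float(grid[j + 1] - frac * (grid[j + 1] - grid[j]))
    return lower, upper, lower_open, upper_open
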