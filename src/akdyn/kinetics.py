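"""Steady-state turnover, velocity curves and in-silico perturbations.

The central quantity is the steady-state turnover per enzyme,
v0/[E]_total = k_cat * p_ss(ETM closed), obtained from the stationary
distribution of the 12-state generator.  Two independent routes are
implemented -- a null-space solve and long-time stiff ODE integration --
and can be cross-checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ATP_BOUND, Conditions, ModelParameters
from .states import N_STATES, build_generator, state_index

_IDX_ETM_CLOSED = state_index("ETM", "closed")
_IDX_ETMI_OPEN = state_index("ETMi", "open")
_IDX_EMTI_OPEN = state_index("EMTi", "open")

#: Steady state declared when the occupancy derivative falls below this (s^-1).
STEADY_STATE_TOL = 1e-10


@dataclass(frozen=True)
class FluxDecomposition:
    """Catalytic flux split by the pathway that assembled the ternary complex."""

    total: float          # turnover, s^-1 per enzyme
    via_atp_first: float  # flux entering ETM through ETMi (s^-1)
    via_amp_first: float  # flux entering ETM through EMTi (s^-1)


def stationary_distribution(G: np.ndarray) -> np.ndarray:
    """Stationary distribution of a conservative column-generator.

    Solves G p = 0 with sum(p) = 1 via a bordered linear system; raises if the
    system is numerically singular beyond the one conservation law.
    """
    n = G.shape[0]
    A = np.vstack([G, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < n:
        raise np.linalg.LinAlgError(
            f"generator has a {n - rank + 1}-dimensional null space; stationary state not unique"
        )
    # tolerate tiny negative round-off only
    if p.min() < -1e-9:
        raise np.linalg.LinAlgError(f"stationary solve produced negative occupancy {p.min():.3e}")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _ode_steady_state(G: np.ndarray, t_max: float = 10.0) -> np.ndarray:
    """Integrate dp/dt = G p from a uniform start until the derivative vanishes."""
    p0 = np.full(N_STATES, 1.0 / N_STATES)

    def rhs(_t, p):
        return G @ p

    t_end = t_max
    p = p0
    for _ in range(6):
        sol = solve_ivp(rhs, (0.0, t_end), p, method="BDF", jac=lambda _t, _p: G,
                        rtol=1e-8, atol=1e-12)
        p = sol.y[:, -1]
        if np.max(np.abs(G @ p)) < STEADY_STATE_TOL:
            return p / p.sum()
        t_end *= 10.0
    raise RuntimeError("ODE integration did not reach steady state; system may be ill-conditioned")


def steady_state_turnover(
    params: ModelParameters,
    cond: Conditions,
    method: Literal["nullspace", "ode"] = "nullspace",
    cross_check: bool = False,
) -> tuple[float, FluxDecomposition]:
    """Steady-state turnover (s^-1 per enzyme) and its pathway decomposition.

    Parameters
    ----------
    method
        "nullspace" (default) solves the stationary linear system;
        "ode" integrates the master equation to long times.
    cross_check
        If True, compute both and require relative agreement to 1e-6.
    """
    G = build_generator(params, cond)
    p = stationary_distribution(G) if method == "nullspace" else _ode_steady_state(G)
    if cross_check:
        p_alt = _ode_steady_state(G) if method == "nullspace" else stationary_distribution(G)
        v_a = params.k_cat * p[_IDX_ETM_CLOSED]
        v_b = params.k_cat * p_alt[_IDX_ETM_CLOSED]
        scale = max(abs(v_a), abs(v_b), 1e-30)
        if abs(v_a - v_b) / scale > 1e-6:
            raise RuntimeError(f"steady-state solvers disagree: {v_a:.9e} vs {v_b:.9e}")
    turnover = params.k_cat * p[_IDX_ETM_CLOSED]
    flux = FluxDecomposition(
        total=turnover,
        via_atp_first=params.k_r_T * p[_IDX_ETMI_OPEN],
        via_amp_first=params.k_r_M * p[_IDX_EMTI_OPEN],
    )
    return turnover, flux


def velocity_curve(
    params: ModelParameters,
    base_cond: Conditions,
    scan: Sequence[float],
    axis: Literal["ATP", "AMP"] = "AMP",
) -> pd.DataFrame:
    """Turnover as a function of one substrate concentration.

    Returns a DataFrame with columns ``conc_M`` and ``velocity_per_s``.
    """
    scan = np.asarray(list(scan), dtype=float)
    if scan.size == 0:
        raise ValueError("scan must be non-empty")
    if np.any(scan < 0):
        raise ValueError("scan concentrations must be non-negative")
    rows = []
    for conc in scan:
        if axis == "AMP":
            cond = Conditions(atp=base_cond.atp, amp=conc,
                              enzyme_total=base_cond.enzyme_total, urea=base_cond.urea)
        elif axis == "ATP":
            cond = Conditions(atp=conc, amp=base_cond.amp,
                              enzyme_total=base_cond.enzyme_total, urea=base_cond.urea)
        else:
            raise ValueError("axis must be 'ATP' or 'AMP'")
        v, _ = steady_state_turnover(params, cond)
        rows.append((conc, v))
    return pd.DataFrame(rows, columns=["conc_M", "velocity_per_s"])


def isolate_effect(
    params_0M: ModelParameters,
    params_0p8M: ModelParameters,
    which: Literal["affinity_only", "dynamics_only"],
    base_cond: Conditions,
    scan: Sequence[float],
    axis: Literal["ATP", "AMP"] = "AMP",
) -> pd.DataFrame:
    """Velocity curve with only one urea effect switched in.

    ``affinity_only`` takes Kd_AMP from the urea parameter set and everything
    else from the no-urea set; ``dynamics_only`` swaps only the conformational
    rates.  This isolates how much of the urea activation is carried by the
    weakened AMP binding versus the shifted open/closed balance.
    """
    if which == "affinity_only":
        hybrid = params_0M.with_updates(Kd_AMP=params_0p8M.Kd_AMP)
    elif which == "dynamics_only":
        hybrid = params_0M.with_updates(conformational_rates=params_0p8M.conformational_rates)
    else:
        raise ValueError("which must be 'affinity_only' or 'dynamics_only'")
    return velocity_curve(hybrid, base_cond, scan, axis=axis)


def kc_scan(
    params: ModelParameters,
    cond: Conditions,
    factors: Iterable[float],
    mode: Literal["opening", "closing", "both"] = "both",
) -> pd.DataFrame:
    """Turnover while scaling conformational rates of the ATP-bound species.

    ``mode='opening'`` multiplies opening rates by each factor (lowering K_C
    for factors > 1), ``'closing'`` the closing rates, ``'both'`` multiplies
    opening and closing rates by the same factor, preserving K_C while moving
    the dynamics towards or away from the catalytic time scale.

    Returns a DataFrame with columns ``factor`` and ``velocity_per_s``.
    """
    rows = []
    for factor in factors:
        if factor <= 0:
            raise ValueError("scale factors must be strictly positive")
        if mode == "opening":
            scaled = params.conformational_rates.scaled(factor, 1.0, states=ATP_BOUND)
        elif mode == "closing":
            scaled = params.conformational_rates.scaled(1.0, factor, states=ATP_BOUND)
        elif mode == "both":
            scaled = params.conformational_rates.scaled(factor, factor, states=ATP_BOUND)
        else:
            raise ValueError("mode must be 'opening', 'closing' or 'both'")
        v, _ = steady_state_turnover(params.with_updates(conformational_rates=scaled), cond)
        rows.append((factor, v))
    return pd.DataFrame(rows, columns=["factor", "velocity_per_s"])
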