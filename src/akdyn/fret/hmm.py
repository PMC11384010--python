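"""Photon-by-photon two-state maximum-likelihood HMM for smFRET bursts.

The hidden state is the enzyme conformation (open/closed), switching as a
continuous-time two-state Markov process with rates k_open (closed -> open)
and k_close (open -> closed).  Observations are individual donor-excitation
photons: an acceptor photon is emitted with probability E_state.  Between
consecutive photons the state distribution is propagated with the analytic
2x2 transition matrix

    P(j | i, dt) = pi_j + (delta_ij - pi_j) * exp(-(k_open + k_close) dt),

so the likelihood is exact for arbitrary inter-photon intervals -- no time
binning.  Fitting maximizes the summed log-likelihood over bursts; the two
state efficiencies can be shared ("global E") across measurement conditions
while the rates remain per-condition, or fixed to previously determined
values.  The conformational equilibrium coefficient follows as
K_C = P_closed / P_open = k_close / k_open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .bursts import PhotonBurst

OPEN, CLOSED = 0, 1

_LOG_RATE_LO, _LOG_RATE_HI = np.log(1e1), np.log(1e7)
_LOGIT_LO, _LOGIT_HI = -6.0, 6.0


@dataclass(frozen=True)
class HMMModel:
    """Two-state photon HMM: state efficiencies, switching rates, start probs.

    By labeling convention the closed state is the high-FRET state
    (E_closed > E_open).  ``p0_open`` is the open-state probability at the
    first photon of a burst; the stationary value k_open/(k_open+k_close) is
    used by default.
    """

    E_open: float
    E_closed: float
    k_open: float       # closed -> open rate, s^-1
    k_close: float      # open -> closed rate, s^-1
    p0_open: Optional[float] = None
    loglik: Optional[float] = None
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.E_open <= 1.0 and 0.0 <= self.E_closed <= 1.0):
            raise ValueError("state efficiencies must lie in [0, 1]")
        if self.E_closed <= self.E_open:
            raise ValueError("labeling convention requires E_closed > E_open")
        if not (self.k_open > 0 and self.k_close > 0):
            raise ValueError("switching rates must be positive")

    @property
    def stationary_p_open(self) -> float:
        return self.k_open / (self.k_open + self.k_close)

    @property
    def start_p_open(self) -> float:
        return self.stationary_p_open if self.p0_open is None else self.p0_open


def kc_from_model(model: HMMModel) -> float:
    """Equilibrium coefficient K_C = P_closed / P_open = k_close / k_open."""
    return model.k_close / model.k_open


@dataclass(frozen=True)
class DwellRecord:
    """Viterbi state path of one burst and the dwell durations it implies."""

    states: np.ndarray          # per-photon state, 0 open / 1 closed
    dwell_states: np.ndarray    # state of each dwell
    dwell_durations_us: np.ndarray


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_loglik_batch(times_s, colors, starts, stops, Eo, Ec, k_open, k_close, p0_open):
    """Summed log-likelihood of all bursts under the two-state photon HMM."""
    lam = k_open + k_close
    pi_o = k_open / lam
    pi_c = k_close / lam
    total = 0.0
    for b in range(starts.size):
        i0, i1 = starts[b], stops[b]
        c = colors[i0]
        eo = Eo if c == 1 else 1.0 - Eo
        ec = Ec if c == 1 else 1.0 - Ec
        a_o = p0_open * eo
        a_c = (1.0 - p0_open) * ec
        s = a_o + a_c
        if s <= 0.0:
            return -np.inf
        total += np.log(s)
        a_o /= s
        a_c /= s
        for i in range(i0 + 1, i1):
            dt = times_s[i] - times_s[i - 1]
            e = np.exp(-lam * dt)
            # propagate: P(o|o)=pi_o+pi_c*e, P(o|c)=pi_o*(1-e), etc.
            b_o = a_o * (pi_o + pi_c * e) + a_c * (pi_o - pi_o * e)
            b_c = a_o * (pi_c - pi_c * e) + a_c * (pi_c + pi_o * e)
            ci = colors[i]
            eo = Eo if ci == 1 else 1.0 - Eo
            ec = Ec if ci == 1 else 1.0 - Ec
            a_o = b_o * eo
            a_c = b_c * ec
            s = a_o + a_c
            if s <= 0.0:
                return -np.inf
            total += np.log(s)
            a_o /= s
            a_c /= s
    return total


@njit(cache=True)
def _viterbi_path(times_s, colors, Eo, Ec, k_open, k_close, p0_open):
    """Most probable state path of one burst (log-space max-product)."""
    n = times_s.size
    lam = k_open + k_close
    pi_o = k_open / lam
    pi_c = k_close / lam
    back = np.zeros((n, 2), dtype=np.int8)
    c0 = colors[0]
    d_o = np.log(max(p0_open, 1e-300)) + np.log(max(Eo if c0 == 1 else 1.0 - Eo, 1e-300))
    d_c = np.log(max(1.0 - p0_open, 1e-300)) + np.log(max(Ec if c0 == 1 else 1.0 - Ec, 1e-300))
    for i in range(1, n):
        dt = times_s[i] - times_s[i - 1]
        e = np.exp(-lam * dt)
        loo = np.log(max(pi_o + pi_c * e, 1e-300))   # open -> open
        loc = np.log(max(pi_c - pi_c * e, 1e-300))   # open -> closed
        lco = np.log(max(pi_o - pi_o * e, 1e-300))   # closed -> open
        lcc = np.log(max(pi_c + pi_o * e, 1e-300))   # closed -> closed
        cand_o_from_o = d_o + loo
        cand_o_from_c = d_c + lco
        cand_c_from_o = d_o + loc
        cand_c_from_c = d_c + lcc
        if cand_o_from_o >= cand_o_from_c:
            new_o = cand_o_from_o
            back[i, 0] = 0
        else:
            new_o = cand_o_from_c
            back[i, 0] = 1
        if cand_c_from_c >= cand_c_from_o:
            new_c = cand_c_from_c
            back[i, 1] = 1
        else:
            new_c = cand_c_from_o
            back[i, 1] = 0
        ci = colors[i]
        d_o = new_o + np.log(max(Eo if ci == 1 else 1.0 - Eo, 1e-300))
        d_c = new_c + np.log(max(Ec if ci == 1 else 1.0 - Ec, 1e-300))
    states = np.zeros(n, dtype=np.int8)
    states[n - 1] = 0 if d_o >= d_c else 1
    for i in range(n - 1, 0, -1):
        states[i - 1] = back[i, states[i]]
    return states


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _burst_arrays(bursts: Sequence[PhotonBurst]):
    """Concatenate donor-excitation photons of many bursts for the kernels."""
    times, colors, starts, stops = [], [], [], []
    offset = 0
    for burst in bursts:
        t, c = burst.donor_excitation_photons()
        if t.size == 0:
            continue
        times.append(t.astype(np.float64) * 1e-9)
        colors.append(c)
        starts.append(offset)
        offset += t.size
        stops.append(offset)
    if not times:
        raise ValueError("no donor-excitation photons in the burst set")
    return (
        np.concatenate(times),
        np.concatenate(colors),
        np.asarray(starts, np.int64),
        np.asarray(stops, np.int64),
    )


def hmm_likelihood(model: HMMModel, burst: PhotonBurst) -> float:
    """Exact forward log-likelihood of one burst's donor-excitation photons."""
    t, c = burst.donor_excitation_photons()
    if t.size == 0:
        raise ValueError("burst has no donor-excitation photons")
    times = t.astype(np.float64) * 1e-9
    if not np.all(np.isfinite(times)):
        raise ValueError("non-finite photon times")
    ll = _forward_loglik_batch(
        times, c, np.array([0], np.int64), np.array([t.size], np.int64),
        model.E_open, model.E_closed, model.k_open, model.k_close, model.start_p_open,
    )
    return float(ll)


@dataclass
class HMMFitResult:
    """Outcome of a (possibly multi-set) photon HMM fit."""

    models: List[HMMModel]
    E_open: float
    E_closed: float
    loglik: float
    converged: bool
    n_photons: int

    @property
    def model(self) -> HMMModel:
        """Convenience accessor for single-set fits."""
        if len(self.models) != 1:
            raise ValueError("fit has multiple condition sets; index .models instead")
        return self.models[0]


BurstSets = Union[Sequence[PhotonBurst], Sequence[Sequence[PhotonBurst]]]


def _as_sets(bursts: BurstSets) -> List[Sequence[PhotonBurst]]:
    if len(bursts) and isinstance(bursts[0], PhotonBurst):
        return [bursts]  # type: ignore[list-item]
    return list(bursts)  # type: ignore[arg-type]


def hmm_fit(
    bursts: BurstSets,
    global_E: bool = True,
    fix_E: Optional[Tuple[float, float]] = None,
    n_restarts: int = 4,
    seed: int = 0,
) -> HMMFitResult:
    """Maximum-likelihood fit of the two-state photon HMM.

    Parameters
    ----------
    bursts
        Either one burst set, or a list of sets measured under different
        conditions.  Rates (k_open, k_close) are fitted per set.
    global_E
        Share E_open/E_closed across all sets (the default); with a single
        set this is simply a free-E fit.
    fix_E
        Fix the state efficiencies to ``(E_open, E_closed)`` instead of
        fitting them -- used for perturbation series where the state
        structures are known to be unchanged.
    n_restarts
        Number of optimizer starts from dispersed initial rates (fixed RNG
        seed for reproducibility); the best final likelihood wins.

    Notes
    -----
    Optimization is direct L-BFGS-B on transformed parameters (log rates,
    logit efficiencies) over the exact forward-algorithm likelihood.  A fit
    is flagged degenerate when the two-state model fails to improve on a
    single-state (binomial) description, in which case the rates are
    unidentifiable.
    """
    if fix_E is not None and fix_E[1] <= fix_E[0]:
        raise ValueError("fix_E must satisfy E_closed > E_open")
    sets = _as_sets(bursts)
    arrays = [_burst_arrays(s) for s in sets]
    n_sets = len(arrays)
    n_photons = int(sum(a[0].size for a in arrays))
    free_E = fix_E is None
    if not global_E and free_E and n_sets > 1:
        # fit each set independently and collect
        results = [hmm_fit([list(s)], global_E=True, n_restarts=n_restarts, seed=seed + i)
                   for i, s in enumerate(sets)]
        models = [r.models[0] for r in results]
        return HMMFitResult(
            models=models,
            E_open=float(np.mean([m.E_open for m in models])),
            E_closed=float(np.mean([m.E_closed for m in models])),
            loglik=float(sum(r.loglik for r in results)),
            converged=all(r.converged for r in results),
            n_photons=n_photons,
        )

    def unpack(theta):
        if free_E:
            Eo = 1.0 / (1.0 + np.exp(-theta[0]))
            Ec = 1.0 / (1.0 + np.exp(-theta[1]))
            rates = theta[2:]
        else:
            Eo, Ec = fix_E
            rates = theta
        return Eo, Ec, np.exp(rates)

    def negloglik(theta):
        Eo, Ec, rates = unpack(theta)
        total = 0.0
        for i, (times, colors, starts, stops) in enumerate(arrays):
            ko, kc = rates[2 * i], rates[2 * i + 1]
            p0 = ko / (ko + kc)
            ll = _forward_loglik_batch(times, colors, starts, stops, Eo, Ec, ko, kc, p0)
            if not np.isfinite(ll):
                return 1e300
            total += ll
        return -total

    rng = np.random.default_rng(seed)
    # initial guesses: E from the spread of per-burst efficiencies, rates from
    # the photon time scale
    all_E = np.concatenate([
        np.array([b.raw_E for b in s if np.isfinite(b.raw_E)]) for s in sets
    ])
    e_lo = float(np.clip(np.quantile(all_E, 0.2), 0.02, 0.95))
    e_hi = float(np.clip(np.quantile(all_E, 0.8), e_lo + 0.02, 0.98))

    best = None
    for restart in range(max(1, n_restarts)):
        theta0 = []
        bounds = []
        if free_E:
            jitter = 0.0 if restart == 0 else rng.normal(0, 0.5, 2)
            theta0 += [np.log(e_lo / (1 - e_lo)) + (jitter[0] if restart else 0.0),
                       np.log(e_hi / (1 - e_hi)) + (jitter[1] if restart else 0.0)]
            bounds += [(_LOGIT_LO, _LOGIT_HI)] * 2
        for _ in range(n_sets):
            if restart == 0:
                k0 = np.log(1e3), np.log(1e3)
            else:
                k0 = rng.uniform(np.log(1e2), np.log(1e5), 2)
            theta0 += list(k0)
            bounds += [(_LOG_RATE_LO, _LOG_RATE_HI)] * 2
        res = minimize(negloglik, np.asarray(theta0), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    Eo, Ec, rates = unpack(best.x)
    # enforce labeling convention: closed = high-FRET state
    flipped = Ec < Eo
    if flipped:
        Eo, Ec = Ec, Eo
    loglik = -float(best.fun)

    # degeneracy check: compare against a single-state binomial model
    single_ll = 0.0
    for times, colors, starts, stops in arrays:
        p = max(min(colors.mean(), 1 - 1e-12), 1e-12)
        single_ll += colors.sum() * np.log(p) + (colors.size - colors.sum()) * np.log(1 - p)
    degenerate = (loglik - single_ll) < 5.0 or (Ec - Eo) < 0.02

    models = []
    for i in range(n_sets):
        ko, kc = rates[2 * i], rates[2 * i + 1]
        if flipped:
            ko, kc = kc, ko
        models.append(HMMModel(
            E_open=Eo, E_closed=max(Ec, Eo + 1e-9), k_open=float(ko), k_close=float(kc),
            loglik=None, converged=bool(best.success), degenerate=bool(degenerate),
        ))
    return HMMFitResult(
        models=models, E_open=float(Eo), E_closed=float(Ec),
        loglik=loglik, converged=bool(best.success), n_photons=n_photons,
    )


def viterbi(model: HMMModel, burst: PhotonBurst) -> DwellRecord:
    """Most probable state path and the dwells it implies.

    Dwell boundaries are placed at the state-change photons: a dwell runs
    from the first photon assigned to a state to the first photon of the next
    state (the last dwell ends at the final photon), so the dwells tile the
    burst's photon span.
    """
    t, c = burst.donor_excitation_photons()
    if t.size == 0:
        raise ValueError("burst has no donor-excitation photons")
    times = t.astype(np.float64) * 1e-9
    states = _viterbi_path(times, c, model.E_open, model.E_closed,
                           model.k_open, model.k_close, model.start_p_open)
    changes = np.flatnonzero(np.diff(states)) + 1
    boundaries = np.concatenate(([0], changes, [t.size - 1]))
    dwell_states = states[boundaries[:-1]]
    durations_us = (times[boundaries[1:]] - times[boundaries[:-1]]) * 1e6
    keep = durations_us > 0
    return DwellRecord(
        states=states,
        dwell_states=dwell_states[keep],
        dwell_durations_us=durations_us[keep],
    )
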