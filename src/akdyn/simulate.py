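"""Synthetic-data generators: the statistical twins of every measured input.

These generators emulate the experiments the analysis chain consumes --
diffusion-burst photon streams with two-state conformational switching,
steady-state activity curves, product-inhibited reverse-assay time courses
and binding titrations -- with known ground truth, so every stage of the
pipeline can be validated by round-trip recovery.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assays import ProductTimeCourse
from .kinetics import steady_state_turnover, velocity_curve
from .params import Conditions, ModelParameters
from .fret.bursts import ACCEPTOR, AEXC, DEXC, DONOR, PhotonBurst, PhotonStream


# ---------------------------------------------------------------------------
# photon-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretSimConfig:
    """Settings of the generative smFRET twin.

    A hidden two-state trajectory (open/closed, rates ``k_open``/``k_close``)
    runs inside each diffusion burst; photons arrive as a Poisson process at
    ``photon_rate`` and are colored acceptor with probability E of the state
    at emission.  Optional distortions mirror the real instrument: donor
    photons leak into the acceptor channel (``leakage``, expressed as the
    correction-factor ratio l), the acceptor dye is directly excited by the
    donor laser (``direct_excitation`` d, relative to the acceptor-excitation
    rate), and uncorrelated background arrives in both channels.  Donor-only
    and acceptor-only species emulate incompletely labeled molecules.
    """

    E_open: float = 0.37
    E_closed: float = 0.72
    k_open: float = 2500.0            # closed -> open, s^-1
    k_close: float = 2500.0           # open -> closed, s^-1
    photon_rate: float = 2.0e5        # donor-excitation photons per second in a burst
    acceptor_exc_rate: float = 2.0e5  # acceptor-excitation photons per second (labeled acceptor)
    mean_burst_duration: float = 1e-3     # s, exponential
    mean_interburst_gap: float = 10e-3    # s, exponential
    n_bursts: int = 1000
    leakage: float = 0.0
    direct_excitation: float = 0.0
    background_rate_donor: float = 0.0    # Hz, per channel, uniform in time
    background_rate_acceptor: float = 0.0
    donor_only_fraction: float = 0.0
    acceptor_only_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("E_open", "E_closed", "leakage", "direct_excitation",
                     "donor_only_fraction", "acceptor_only_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.donor_only_fraction + self.acceptor_only_fraction > 1.0:
            raise ValueError("single-label fractions must sum to at most 1")
        for name in ("k_open", "k_close", "photon_rate", "mean_burst_duration", "n_bursts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StatePath:
    """Ground-truth hidden trajectory of one burst: switch times and states."""

    times: np.ndarray    # segment start times (s), first = burst start
    states: np.ndarray   # 0 open / 1 closed per segment
    duration: float

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def time_in_state(self, state: int) -> float:
        edges = np.append(self.times, self.duration)
        return float(np.sum(np.diff(edges)[self.states == state]))


def _gillespie_path(rng: np.random.Generator, duration: float,
                    k_open: float, k_close: float, p0_closed: float) -> StatePath:
    """Sample a two-state trajectory over [0, duration] by Gillespie stepping."""
    state = 1 if rng.random() < p0_closed else 0
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = k_open if state == 1 else k_close
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        state = 1 - state
        times.append(t)
        states.append(state)
    return StatePath(times=np.array(times), states=np.array(states, np.int8), duration=duration)


def simulate_bursts(
    cfg: FretSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[PhotonBurst], List[StatePath]]:
    """Simulate double-labeled bursts (donor-excitation photons only).

    Returns the bursts together with their ground-truth state paths.  This is
    the distortion-free core used for HMM recovery studies; leakage is
    applied (if configured) but background, species mixtures and
    acceptor-excitation photons are left to :func:`simulate_photon_stream`.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p_closed = cfg.k_close / (cfg.k_open + cfg.k_close)
    beta = cfg.leakage / (1.0 + cfg.leakage)  # fraction of donor photons detected as acceptor
    bursts, paths = [], []
    t_origin = 0.0
    for _ in range(cfg.n_bursts):
        duration = rng.exponential(cfg.mean_burst_duration)
        n = rng.poisson(cfg.photon_rate * duration)
        if n == 0:
            t_origin += duration + rng.exponential(cfg.mean_interburst_gap)
            continue
        path = _gillespie_path(rng, duration, cfg.k_open, cfg.k_close, p_closed)
        t_rel = np.sort(rng.uniform(0.0, duration, n))
        states = path.state_at(t_rel)
        E = np.where(states == 1, cfg.E_closed, cfg.E_open)
        acceptor = rng.random(n) < E
        # leakage: donor-emitted photons misdirected into the acceptor channel
        if beta > 0:
            donor_mask = ~acceptor
            acceptor = acceptor | (donor_mask & (rng.random(n) < beta))
        ts = np.round((t_origin + t_rel) * 1e9).astype(np.int64)
        ts = np.maximum.accumulate(ts)
        bursts.append(PhotonBurst(
            timestamps_ns=ts,
            channel=acceptor.astype(np.uint8),
            excitation=np.zeros(n, np.uint8),
        ))
        paths.append(path)
        t_origin += duration + rng.exponential(cfg.mean_interburst_gap)
    return bursts, paths


def simulate_photon_stream(cfg: FretSimConfig) -> Tuple[PhotonStream, dict]:
    """Simulate a full PIE photon stream: bursts, species mixture, background.

    Each burst is assigned a species (double-labeled, donor-only or
    acceptor-only by the configured fractions).  Donor-excitation photons
    follow the hidden conformational path (double-labeled) or are all-donor
    (donor-only); direct excitation and leakage distort the colors;
    acceptor-excitation photons arrive at ``acceptor_exc_rate`` for
    acceptor-carrying species.  Poisson background fills the whole record.

    Returns the stream and a ground-truth dict with burst windows, species
    labels and state paths.
    """
    rng = np.random.default_rng(cfg.seed)
    p_closed = cfg.k_close / (cfg.k_open + cfg.k_close)
    beta = cfg.leakage / (1.0 + cfg.leakage)
    times, channels, excitations = [], [], []
    truth = {"burst_windows": [], "species": [], "paths": []}
    t0 = rng.exponential(cfg.mean_interburst_gap)
    for _ in range(cfg.n_bursts):
        duration = rng.exponential(cfg.mean_burst_duration)
        u = rng.random()
        if u < cfg.donor_only_fraction:
            species = "DO"
        elif u < cfg.donor_only_fraction + cfg.acceptor_only_fraction:
            species = "AO"
        else:
            species = "DA"
        seg_t, seg_ch, seg_ex = [], [], []
        path = None
        if species in ("DA", "DO"):
            n = rng.poisson(cfg.photon_rate * duration)
            t_rel = np.sort(rng.uniform(0.0, duration, n))
            if species == "DA":
                path = _gillespie_path(rng, duration, cfg.k_open, cfg.k_close, p_closed)
                E = np.where(path.state_at(t_rel) == 1, cfg.E_closed, cfg.E_open)
                acceptor = rng.random(n) < E
            else:
                acceptor = np.zeros(n, bool)
            if beta > 0:
                acceptor = acceptor | (~acceptor & (rng.random(n) < beta))
            seg_t.append(t_rel)
            seg_ch.append(acceptor.astype(np.uint8))
            seg_ex.append(np.zeros(n, np.uint8))
        if species in ("DA", "AO"):
            # acceptor-excitation photons (acceptor present)
            n_aa = rng.poisson(cfg.acceptor_exc_rate * duration)
            t_aa = np.sort(rng.uniform(0.0, duration, n_aa))
            seg_t.append(t_aa)
            seg_ch.append(np.full(n_aa, ACCEPTOR, np.uint8))
            seg_ex.append(np.full(n_aa, AEXC, np.uint8))
            # direct excitation: acceptor photons in the donor-excitation slot
            n_dir = rng.poisson(cfg.direct_excitation * cfg.acceptor_exc_rate * duration)
            t_dir = np.sort(rng.uniform(0.0, duration, n_dir))
            seg_t.append(t_dir)
            seg_ch.append(np.full(n_dir, ACCEPTOR, np.uint8))
            seg_ex.append(np.full(n_dir, DEXC, np.uint8))
        if seg_t:
            t_all = np.concatenate(seg_t)
            order = np.argsort(t_all, kind="stable")
            times.append(t0 + t_all[order])
            channels.append(np.concatenate(seg_ch)[order])
            excitations.append(np.concatenate(seg_ex)[order])
        truth["burst_windows"].append((t0, t0 + duration))
        truth["species"].append(species)
        truth["paths"].append(path)
        t0 += duration + rng.exponential(cfg.mean_interburst_gap)

    total_time = t0
    for ch, rate in ((DONOR, cfg.background_rate_donor), (ACCEPTOR, cfg.background_rate_acceptor)):
        if rate > 0:
            n_bg = rng.poisson(rate * total_time)
            t_bg = rng.uniform(0.0, total_time, n_bg)
            times.append(t_bg)
            channels.append(np.full(n_bg, ch, np.uint8))
            # background is uncorrelated with excitation; 3:1 donor:acceptor slots
            excitations.append((rng.random(n_bg) < 0.25).astype(np.uint8))

    if times:
        t_all = np.concatenate(times)
        order = np.argsort(t_all, kind="stable")
        stream = PhotonStream(
            timestamps_ns=np.maximum.accumulate(np.round(t_all[order] * 1e9).astype(np.int64)),
            channel=np.concatenate(channels)[order],
            excitation=np.concatenate(excitations)[order],
        )
    else:
        stream = PhotonStream(np.empty(0, np.int64), np.empty(0, np.uint8), np.empty(0, np.uint8))
    return stream, truth


# ---------------------------------------------------------------------------
# assay-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySimConfig:
    """Activity-curve simulation: model + conditions grid + relative noise."""

    params: ModelParameters
    base_cond: Conditions
    scan: Sequence[float]
    axis: str = "AMP"
    sigma_rel: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("relative noise must be non-negative")


def simulate_activity_curves(cfg: AssaySimConfig) -> pd.DataFrame:
    """Steady-state velocities on a concentration grid with relative noise.

    Each point is v * (1 + sigma_rel * N(0,1)); the reported SEM is
    sigma_rel * v, mirroring how replicate scatter is summarized in bulk
    assays.  Columns: ``conc_M``, ``v0_per_s``, ``sem``.
    """
    rng = np.random.default_rng(cfg.seed)
    curve = velocity_curve(cfg.params, cfg.base_cond, cfg.scan, axis=cfg.axis)
    v = curve["velocity_per_s"].to_numpy()
    noisy = v * (1.0 + cfg.sigma_rel * rng.standard_normal(v.size))
    sem = np.maximum(cfg.sigma_rel * v, 1e-12)
    return pd.DataFrame({"conc_M": curve["conc_M"], "v0_per_s": noisy, "sem": sem})


def simulate_reverse_timecourse(
    v0: float,
    eta: float,
    time_grid: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
) -> ProductTimeCourse:
    """Product-inhibited reverse-assay time course [P](t) = (v0/eta)(1-e^(-eta t)).

    ``noise`` is an absolute Gaussian standard deviation on [P] (M); eta = 0
    gives a straight line of slope v0.
    """
    if v0 < 0 or eta < 0:
        raise ValueError("v0 and eta must be non-negative")
    t = np.asarray(time_grid, float)
    rng = np.random.default_rng(seed)
    if eta == 0:
        p = v0 * t
    else:
        p = -v0 / eta * np.expm1(-eta * t)
    if noise > 0:
        p = p + rng.normal(0.0, noise, t.size)
    return ProductTimeCourse(times=t, product=p, direction="reverse")


def simulate_titration(
    Kd: float,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    ligand_grid: Optional[Sequence[float]] = None,
    noise: float = 0.0,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """1:1 binding titration f(L) = baseline + amplitude * L / (L + Kd) + noise.

    ``noise`` adds absolute Gaussian scatter; ``noise_rel`` adds relative
    Gaussian scatter f * (1 + noise_rel * N(0,1)), the convention used for
    the activity curves.  Default grid: 12 log-spaced concentrations from
    1 uM to 10 mM, matching a typical MST dilution series.  Columns:
    ``conc_M``, ``fraction_bound``.
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    L = (np.logspace(-6, -2, 12) if ligand_grid is None
         else np.asarray(ligand_grid, float))
    rng = np.random.default_rng(seed)
    f = baseline + amplitude * L / (L + Kd)
    if noise_rel > 0:
        f = f * (1.0 + noise_rel * rng.standard_normal(L.size))
    if noise > 0:
        f = f + rng.normal(0.0, noise, L.size)
    return pd.DataFrame({"conc_M": L, "fraction_bound": f})
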