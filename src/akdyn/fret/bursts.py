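"""Burst search, spectroscopic corrections and burst-level statistics.

Freely diffusing molecules cross the confocal volume in ~1 ms, producing
bursts of photons over a sparse background.  Bursts are located by smoothing
the inter-photon intervals with a running average and keeping stretches where
the smoothed interval falls below a cut-off.  Per burst, the raw FRET
efficiency E (acceptor fraction after donor excitation) and raw stoichiometry
S (donor-excitation fraction of all photons) are computed; donor-only and
acceptor-only subpopulations calibrate the leakage and direct-excitation
corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

DONOR, ACCEPTOR = 0, 1          # detection channel codes
DEXC, AEXC = 0, 1               # excitation slot codes


@dataclass(frozen=True)
class PhotonStream:
    """A time-ordered photon record from a PIE smFRET measurement.

    ``timestamps_ns`` are integer arrival times; ``channel`` is the detection
    channel (0 donor, 1 acceptor); ``excitation`` the excitation slot the
    photon followed (0 donor excitation, 1 acceptor excitation).
    """

    timestamps_ns: np.ndarray
    channel: np.ndarray
    excitation: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps_ns, dtype=np.int64)
        ch = np.asarray(self.channel, dtype=np.uint8)
        ex = np.asarray(self.excitation, dtype=np.uint8)
        if not (t.size == ch.size == ex.size):
            raise ValueError("timestamps, channel and excitation must have equal length")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if ch.size and ch.max() > 1:
            raise ValueError("channel codes must be 0 (donor) or 1 (acceptor)")
        if ex.size and ex.max() > 1:
            raise ValueError("excitation codes must be 0 (donor exc) or 1 (acceptor exc)")
        object.__setattr__(self, "timestamps_ns", t)
        object.__setattr__(self, "channel", ch)
        object.__setattr__(self, "excitation", ex)

    def __len__(self) -> int:
        return self.timestamps_ns.size

    @classmethod
    def concatenate(cls, chunks: Sequence["PhotonStream"]) -> "PhotonStream":
        """Join stream chunks; burst search on the result is chunking-independent."""
        if not chunks:
            return cls(np.empty(0, np.int64), np.empty(0, np.uint8), np.empty(0, np.uint8))
        return cls(
            np.concatenate([c.timestamps_ns for c in chunks]),
            np.concatenate([c.channel for c in chunks]),
            np.concatenate([c.excitation for c in chunks]),
        )


@dataclass(frozen=True)
class BurstSearchConfig:
    """Burst-search settings: interval smoothing window, cut-off, minimum size."""

    smoothing_window: int = 15     # photons in the running average
    cutoff_us: float = 5.0         # smoothed inter-photon interval threshold
    min_size: int = 50             # minimum photons per burst

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1 photon")
        if self.cutoff_us <= 0:
            raise ValueError("cut-off must be positive")
        if self.min_size < self.smoothing_window:
            raise ValueError("minimum burst size must be >= smoothing window")


@dataclass
class PhotonBurst:
    """One single-molecule transit: photon slice plus derived burst statistics."""

    timestamps_ns: np.ndarray
    channel: np.ndarray
    excitation: np.ndarray
    corrected_E: Optional[float] = None
    corrected_S: Optional[float] = None

    def __len__(self) -> int:
        return self.timestamps_ns.size

    # --- per-slot counts -------------------------------------------------
    @property
    def n_donor_dexc(self) -> int:
        return int(np.sum((self.channel == DONOR) & (self.excitation == DEXC)))

    @property
    def n_acceptor_dexc(self) -> int:
        return int(np.sum((self.channel == ACCEPTOR) & (self.excitation == DEXC)))

    @property
    def n_acceptor_aexc(self) -> int:
        return int(np.sum((self.channel == ACCEPTOR) & (self.excitation == AEXC)))

    @property
    def raw_E(self) -> float:
        """Acceptor fraction of donor-excitation photons, clipped to [0, 1]."""
        total = self.n_donor_dexc + self.n_acceptor_dexc
        return float(np.clip(self.n_acceptor_dexc / total, 0.0, 1.0)) if total else np.nan

    @property
    def raw_S(self) -> float:
        """Donor-excitation fraction of all photons, clipped to [0, 1]."""
        dexc = self.n_donor_dexc + self.n_acceptor_dexc
        total = dexc + self.n_acceptor_aexc
        return float(np.clip(dexc / total, 0.0, 1.0)) if total else np.nan

    def donor_excitation_photons(self) -> tuple[np.ndarray, np.ndarray]:
        """(timestamps_ns, colors) of donor-excitation photons; color 1 = acceptor."""
        mask = self.excitation == DEXC
        return self.timestamps_ns[mask], (self.channel[mask] == ACCEPTOR).astype(np.uint8)


@dataclass(frozen=True)
class CorrectionFactors:
    """Leakage (donor photons into the acceptor channel) and direct excitation."""

    leakage: float = 0.0
    direct_excitation: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.leakage < 1 and 0 <= self.direct_excitation < 1):
            raise ValueError("correction factors must lie in [0, 1)")

    def corrected_ES(self, burst: PhotonBurst) -> tuple[float, float]:
        """Corrected FRET efficiency and stoichiometry of one burst.

        The acceptor signal is stripped of leakage and direct excitation,
        F_A = A_Dexc - l*D_Dexc - d*A_Aexc; the donor signal is rescaled by
        (1 + l) to restore the donor photons lost to the acceptor channel
        (the spectral complement of the leakage fraction).
        """
        D = burst.n_donor_dexc
        A = burst.n_acceptor_dexc
        AA = burst.n_acceptor_aexc
        FA = A - self.leakage * D - self.direct_excitation * AA
        FD = (1.0 + self.leakage) * D
        E = FA / (FA + FD) if (FA + FD) > 0 else np.nan
        S = (FA + FD) / (FA + FD + AA) if (FA + FD + AA) > 0 else np.nan
        return float(np.clip(E, 0.0, 1.0)), float(np.clip(S, 0.0, 1.0))


def burst_search(stream: PhotonStream, cfg: BurstSearchConfig = BurstSearchConfig()) -> List[PhotonBurst]:
    """Locate photon bursts by running-average smoothing of inter-photon intervals.

    Each photon after the first carries the interval to its predecessor; the
    intervals are smoothed with a centered running average of
    ``cfg.smoothing_window`` photons, and maximal runs of photons whose
    smoothed interval is below ``cfg.cutoff_us`` form candidate bursts.  Runs
    shorter than ``cfg.min_size`` photons are discarded.
    """
    n = len(stream)
    if n < cfg.min_size:
        return []
    t = stream.timestamps_ns
    intervals = np.diff(t).astype(np.float64)  # ns, length n-1
    w = cfg.smoothing_window
    kernel = np.full(w, 1.0 / w)
    # centered running average with edge truncation
    padded = np.convolve(intervals, kernel, mode="same")
    if w > 1:
        counts = np.convolve(np.ones_like(intervals), kernel, mode="same")
        padded = padded / counts
    below = padded < cfg.cutoff_us * 1e3
    # photon i (1..n-1) is "in burst" if its preceding interval is below cut-off;
    # photon 0 joins if the first interval is below.
    in_burst = np.empty(n, dtype=bool)
    in_burst[1:] = below
    in_burst[0] = below[0] if below.size else False

    bursts: List[PhotonBurst] = []
    edges = np.flatnonzero(np.diff(in_burst.astype(np.int8)))
    starts = [0] if in_burst[0] else []
    starts += [e + 1 for e in edges if not in_burst[e]]
    stops = [e + 1 for e in edges if in_burst[e]]
    if in_burst[-1]:
        stops.append(n)
    for a, b in zip(starts, stops):
        if b - a >= cfg.min_size:
            bursts.append(PhotonBurst(
                timestamps_ns=t[a:b].copy(),
                channel=stream.channel[a:b].copy(),
                excitation=stream.excitation[a:b].copy(),
            ))
    return bursts


def estimate_corrections(
    bursts: Sequence[PhotonBurst],
    donor_only_s_min: float = 0.85,
    acceptor_only_s_max: float = 0.15,
) -> CorrectionFactors:
    """Estimate leakage and direct excitation from single-label subpopulations.

    Donor-only bursts (raw S above ``donor_only_s_min``) should show zero
    FRET; their mean raw E reflects pure leakage, l = E_DO / (1 - E_DO).
    Acceptor-only bursts (raw S below ``acceptor_only_s_max``) should show
    zero donor-excitation signal; their mean raw S reflects direct
    excitation, d = S_AO / (1 - S_AO).  Missing populations leave the
    corresponding factor at zero.
    """
    import warnings

    raw_S = np.array([b.raw_S for b in bursts])
    raw_E = np.array([b.raw_E for b in bursts])
    leakage = 0.0
    direct = 0.0
    donor_only = raw_S > donor_only_s_min
    if donor_only.any():
        e_do = float(np.nanmean(raw_E[donor_only]))
        leakage = e_do / (1.0 - e_do) if e_do < 1.0 else 0.0
    else:
        warnings.warn("no donor-only population found; leakage set to 0", stacklevel=2)
    acceptor_only = raw_S < acceptor_only_s_max
    if acceptor_only.any():
        s_ao = float(np.nanmean(raw_S[acceptor_only]))
        direct = s_ao / (1.0 - s_ao) if s_ao < 1.0 else 0.0
    else:
        warnings.warn("no acceptor-only population found; direct excitation set to 0", stacklevel=2)
    return CorrectionFactors(leakage=leakage, direct_excitation=direct)


def apply_corrections(bursts: Sequence[PhotonBurst], factors: CorrectionFactors) -> None:
    """Attach corrected E and S to each burst in place."""
    for burst in bursts:
        burst.corrected_E, burst.corrected_S = factors.corrected_ES(burst)


def select_double_labeled(
    bursts: Sequence[PhotonBurst],
    s_window: tuple[float, float] = (0.3, 0.7),
) -> List[PhotonBurst]:
    """Keep bursts whose corrected stoichiometry falls inside ``s_window``.

    Intermediate stoichiometry marks molecules carrying both dyes; donor-only
    (S near 1) and acceptor-only (S near 0) molecules are rejected.  Requires
    corrections to have been applied.
    """
    lo, hi = s_window
    out = []
    for b in bursts:
        if b.corrected_S is None:
            raise ValueError("apply corrections before stoichiometry selection")
        if lo <= b.corrected_S <= hi:
            out.append(b)
    return out


def fret_histogram(bursts: Sequence[PhotonBurst], bins: int | np.ndarray = 40) -> pd.DataFrame:
    """Unit-area histogram of per-burst corrected FRET efficiencies.

    Returns a DataFrame with columns ``E_left``, ``E_right`` and ``density``
    (normalized so the densities integrate to 1 over [0, 1]).
    """
    E = np.array([b.corrected_E if b.corrected_E is not None else b.raw_E for b in bursts])
    E = E[np.isfinite(E)]
    edges = np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) else np.asarray(bins, float)
    density, edges = np.histogram(E, bins=edges, density=True)
    if E.size == 0:
        density = np.zeros(len(edges) - 1)
    return pd.DataFrame({"E_left": edges[:-1], "E_right": edges[1:], "density": density})


def burst_variance_analysis(
    bursts: Sequence[PhotonBurst],
    window: int = 5,
) -> tuple[pd.DataFrame, int]:
    """Per-burst FRET variance over photon windows versus shot-noise expectation.

    Donor-excitation photons of each burst are cut into consecutive windows of
    ``window`` photons; the standard deviation of the window FRET efficiencies
    is compared to the binomial shot-noise level sqrt(E(1-E)/window).  Bursts
    with conformational exchange on the window time scale exceed shot noise.

    Returns a table with columns ``mean_E``, ``observed_sd``, ``shot_noise_sd``
    and the number of bursts skipped for being shorter than two windows.
    """
    if window < 2:
        raise ValueError("window must be at least 2 photons")
    rows = []
    skipped = 0
    for burst in bursts:
        _, colors = burst.donor_excitation_photons()
        n_windows = colors.size // window
        if n_windows < 2:
            skipped += 1
            continue
        trimmed = colors[: n_windows * window].reshape(n_windows, window)
        window_E = trimmed.mean(axis=1)
        mean_E = float(window_E.mean())
        rows.append((
            mean_E,
            float(window_E.std(ddof=1)),
            float(np.sqrt(mean_E * (1.0 - mean_E) / window)),
        ))
    return pd.DataFrame(rows, columns=["mean_E", "observed_sd", "shot_noise_sd"]), skipped
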