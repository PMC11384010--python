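"""State enumeration and rate-matrix construction for the AK reaction network.

The network has 12 states: six ligation states {E, ET, EM, ETMi, EMTi, ETM},
each as an open and a closed conformer.  Edges:

* ligand binding/unbinding connects OPEN conformers only (the closed active
  site is shielded from solvent), with pseudo-first-order on-rates
  k_on * [ligand] and off-rates k_on * Kd;
* conformational exchange k_open / k_close within every ligation state;
* irreversible substrate rearrangement ETMi(open) -> ETM(open) at k_r_T and
  EMTi(open) -> ETM(open) at k_r_M;
* catalytic turnover ETM(closed) -> E(open) at k_cat, recycling the enzyme.

The generator is a column-convention rate matrix: dp/dt = G p, with each
column summing to zero (the catalytic edge recycles probability to E(open),
so the full matrix is conservative; setting k_cat = 0 removes that edge).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .params import LIGATION_STATES, Conditions, ModelParameters

OPEN, CLOSED = 0, 1
N_STATES = 12

#: Fixed state ordering: index = 2 * ligation_index + conformation,
#: ligation order (E, ET, EM, ETMi, EMTi, ETM), open before closed.
STATE_LABELS = tuple(
    f"{lig}_{conf}" for lig in LIGATION_STATES for conf in ("open", "closed")
)


def state_index(ligation: str, conformation: str) -> int:
    """Index of a conformer state in the fixed enumeration."""
    lig = LIGATION_STATES.index(ligation)
    conf = {"open": OPEN, "closed": CLOSED}[conformation]
    return 2 * lig + conf


def build_generator(params: ModelParameters, cond: Conditions) -> np.ndarray:
    """Assemble the 12x12 rate matrix G (s^-1) with dp/dt = G p.

    Off-diagonal entry G[j, i] is the rate of the transition i -> j; each
    diagonal entry is minus its column's off-diagonal sum, so columns sum to
    zero and probability is conserved (catalysis recycles to E(open)).
    """
    G = np.zeros((N_STATES, N_STATES))

    def add(src: int, dst: int, rate: float) -> None:
        if rate < 0:
            raise ValueError("transition rates must be non-negative")
        G[dst, src] += rate

    k_on = params.k_on
    on_atp = k_on * cond.atp
    on_amp = k_on * cond.amp
    off_atp = k_on * params.Kd_ATP
    off_amp = k_on * params.Kd_AMP

    idx = {lig: (state_index(lig, "open"), state_index(lig, "closed")) for lig in LIGATION_STATES}

    # conformational exchange within every ligation state
    rates = params.conformational_rates
    for lig in LIGATION_STATES:
        o, c = idx[lig]
        add(o, c, rates.k_close[lig])
        add(c, o, rates.k_open[lig])

    # binding / unbinding between open conformers only
    add(idx["E"][OPEN], idx["ET"][OPEN], on_atp)
    add(idx["ET"][OPEN], idx["E"][OPEN], off_atp)
    add(idx["E"][OPEN], idx["EM"][OPEN], on_amp)
    add(idx["EM"][OPEN], idx["E"][OPEN], off_amp)
    add(idx["ET"][OPEN], idx["ETMi"][OPEN], on_amp)
    add(idx["ETMi"][OPEN], idx["ET"][OPEN], off_amp)
    add(idx["EM"][OPEN], idx["EMTi"][OPEN], on_atp)
    add(idx["EMTi"][OPEN], idx["EM"][OPEN], off_atp)

    # irreversible rearrangement into the catalytically competent complex
    add(idx["ETMi"][OPEN], idx["ETM"][OPEN], params.k_r_T)
    add(idx["EMTi"][OPEN], idx["ETM"][OPEN], params.k_r_M)

    # catalytic drain with enzyme recycling
    add(idx["ETM"][CLOSED], idx["E"][OPEN], params.k_cat)

    # diagonal = minus the column's off-diagonal sum (conservation up to
    # one rounding ulp of the largest rate)
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=0))
    return G
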