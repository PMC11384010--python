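"""Parameter containers for the conformational-kinetic model of adenylate kinase.

Adenylate kinase (AK) catalyzes ATP + AMP -> 2 ADP.  The ternary complex can be
assembled in two orders ("ATP first" / "AMP first"), each producing an initially
misaligned complex that must rearrange -- in the open conformation only -- before
phosphotransfer.  Every ligation state exists as an open and a closed conformer,
interconverting on the microsecond time scale.  The containers here collect the
rate constants and experimental conditions that parameterize that network.

Units are SI throughout: rates in s^-1, concentrations and dissociation
constants in M, association rates in M^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

LIGATION_STATES = ("E", "ET", "EM", "ETMi", "EMTi", "ETM")

#: Ligation states carrying bound ATP; their conformational dynamics track the
#: ATP-bound smFRET measurements rather than the apo ones.
ATP_BOUND = ("ET", "ETMi", "EMTi", "ETM")

#: Default total conformational relaxation rate k_open + k_close (s^-1).
#: Domain opening/closing completes within tens of microseconds, about two
#: orders of magnitude faster than the maximal turnover of ~370 s^-1.
DEFAULT_RELAXATION_RATE = 4.0e4

#: Diffusion-limited bimolecular association rate (M^-1 s^-1) used for both
#: nucleotides; dissociation rates follow from k_off = k_on * Kd.
DEFAULT_K_ON = 1.0e8


@dataclass(frozen=True)
class ConformationalRates:
    """Opening and closing rates (s^-1) per ligation state.

    ``k_open[lig]`` and ``k_close[lig]`` define the open<->closed exchange of
    ligation state ``lig``; their ratio k_close/k_open is the conformational
    equilibrium coefficient K_C (population of closed over open).
    """

    k_open: Mapping[str, float]
    k_close: Mapping[str, float]

    def __post_init__(self) -> None:
        for table, name in ((self.k_open, "k_open"), (self.k_close, "k_close")):
            missing = set(LIGATION_STATES) - set(table)
            if missing:
                raise ValueError(f"{name} missing ligation states: {sorted(missing)}")
            for lig in LIGATION_STATES:
                rate = table[lig]
                if not (rate > 0.0 and rate < float("inf")):
                    raise ValueError(f"{name}[{lig}] must be positive and finite, got {rate}")

    def kc(self, lig: str) -> float:
        """Conformational equilibrium coefficient K_C = k_close / k_open."""
        return self.k_close[lig] / self.k_open[lig]

    @classmethod
    def from_kc(
        cls,
        kc_apo: float,
        kc_atp_bound: float,
        relaxation_rate: float = DEFAULT_RELAXATION_RATE,
        kc_ternary: float | None = None,
    ) -> "ConformationalRates":
        """Build rates from equilibrium coefficients and a shared relaxation rate.

        The apo enzyme and the AMP-only complex share ``kc_apo`` (AMP binding
        alone leaves the conformational balance unchanged); the binary ATP
        complex ET takes ``kc_atp_bound``; the ternary species ETMi/EMTi/ETM
        take ``kc_ternary`` (defaulting to ``kc_atp_bound``), matching the
        smFRET condition at which each species dominates.  The total
        relaxation rate k_open + k_close is held at ``relaxation_rate`` for
        every state, so K_C alone distinguishes the species.
        """
        if kc_ternary is None:
            kc_ternary = kc_atp_bound
        if min(kc_apo, kc_atp_bound, kc_ternary, relaxation_rate) <= 0:
            raise ValueError("K_C values and relaxation rate must be positive")
        k_open: Dict[str, float] = {}
        k_close: Dict[str, float] = {}
        for lig in LIGATION_STATES:
            if lig in ("E", "EM"):
                kc = kc_apo
            elif lig == "ET":
                kc = kc_atp_bound
            else:
                kc = kc_ternary
            k_open[lig] = relaxation_rate / (1.0 + kc)
            k_close[lig] = relaxation_rate * kc / (1.0 + kc)
        return cls(k_open=k_open, k_close=k_close)

    def scaled(self, factor_open: float, factor_close: float, states=ATP_BOUND) -> "ConformationalRates":
        """Return a copy with opening/closing rates of ``states`` multiplied."""
        if factor_open <= 0 or factor_close <= 0:
            raise ValueError("scale factors must be positive")
        k_open = dict(self.k_open)
        k_close = dict(self.k_close)
        for lig in states:
            k_open[lig] *= factor_open
            k_close[lig] *= factor_close
        return ConformationalRates(k_open=k_open, k_close=k_close)


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the two-pathway conformational model.

    Attributes
    ----------
    k_cat : float
        Phosphotransfer rate from the closed, catalytically competent ternary
        complex ETM (s^-1).
    k_r_T : float
        Substrate rearrangement rate ETMi -> ETM in the "ATP first" pathway
        (s^-1); possible only in the open conformation.
    k_r_M : float
        Rearrangement rate EMTi -> ETM in the "AMP first" pathway (s^-1).
        k_r_M << k_cat produces substrate inhibition at high AMP.
    Kd_ATP, Kd_AMP : float
        Nucleotide dissociation constants (M).
    k_on : float
        Bimolecular association rate (M^-1 s^-1), shared by both nucleotides;
        k_off = k_on * Kd.
    conformational_rates : ConformationalRates
        Opening/closing rates per ligation state.
    """

    k_cat: float
    k_r_T: float
    k_r_M: float
    Kd_ATP: float
    Kd_AMP: float
    conformational_rates: ConformationalRates
    k_on: float = DEFAULT_K_ON

    def __post_init__(self) -> None:
        for name in ("k_cat", "k_r_T", "k_r_M", "Kd_ATP", "Kd_AMP", "k_on"):
            value = getattr(self, name)
            if not (value >= 0.0 and value < float("inf")):
                raise ValueError(f"{name} must be non-negative and finite, got {value}")
        for name in ("Kd_ATP", "Kd_AMP", "k_on"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    def with_updates(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Conditions:
    """Experimental conditions for a steady-state turnover calculation.

    Substrate pools are treated as undepleted reservoirs, so concentrations
    enter only through pseudo-first-order binding rates.  ``urea`` is a label
    carried for bookkeeping; urea affects the model solely through the
    parameter values supplied.
    """

    atp: float
    amp: float
    enzyme_total: float = 4e-9
    urea: float = 0.0

    def __post_init__(self) -> None:
        if self.atp < 0 or self.amp < 0:
            raise ValueError("substrate concentrations must be non-negative")
        if self.enzyme_total <= 0:
            raise ValueError("total enzyme concentration must be positive")


# ---------------------------------------------------------------------------
# Measured constants for E. coli adenylate kinase (wild type, A73C-V142C FRET
# construct).  These are the global-fit kinetic constants and the smFRET /
# MST observables the model takes as inputs.
# ---------------------------------------------------------------------------

#: Kinetic constants (urea-independent) of the wild-type enzyme.
WT_RATE_CONSTANTS = {"k_cat": 3.1e3, "k_r_T": 4.2e3, "k_r_M": 370.0}

#: AMP dissociation constants (M) measured by microscale thermophoresis.
WT_KD_AMP = {0.0: 332e-6, 0.4: 522e-6, 0.8: 758e-6}

#: ATP dissociation constant (M); not significantly affected by urea.
WT_KD_ATP = 50e-6

#: Conformational equilibrium coefficients K_C = P_closed / P_open from the
#: photon-by-photon smFRET analysis.  Keys: (condition, urea M).
KC_MEASURED = {
    ("apo", 0.0): 0.16,
    ("AMP", 0.0): 0.16,
    ("ATP", 0.0): 1.28,
    ("ATP+AMP", 0.0): 1.65,
    ("ATP", 0.8): 0.85,
    ("ATP+AMP", 0.8): 1.10,
}

#: Globally fitted state FRET efficiencies of the LID-CORE dye pair.
E_OPEN = 0.37
E_CLOSED = 0.72


def wild_type_parameters(urea: float = 0.0, relaxation_rate: float = DEFAULT_RELAXATION_RATE) -> ModelParameters:
    """Wild-type model parameters at a given urea concentration (0, 0.4, 0.8 M).

    Urea enters through two measured inputs: the AMP dissociation constant and
    the conformational equilibrium of the ATP-bound species.  The apo/AMP-only
    equilibrium (K_C = 0.16) is urea-insensitive.  ET takes the K_C measured
    with 1 mM ATP alone; the ternary species take the value measured with
    1 mM ATP + 5 mM AMP, the condition where those complexes dominate.  At
    0.4 M urea no ATP-bound K_C was measured; the 0 M values are used.
    """
    if urea not in WT_KD_AMP:
        raise ValueError(f"no measured AMP affinity at {urea} M urea; choose from {sorted(WT_KD_AMP)}")
    kc_apo = KC_MEASURED[("apo", 0.0)]
    kc_urea = 0.8 if urea == 0.8 else 0.0
    kc_atp = KC_MEASURED[("ATP", kc_urea)]
    kc_ternary = KC_MEASURED[("ATP+AMP", kc_urea)]
    return ModelParameters(
        k_cat=WT_RATE_CONSTANTS["k_cat"],
        k_r_T=WT_RATE_CONSTANTS["k_r_T"],
        k_r_M=WT_RATE_CONSTANTS["k_r_M"],
        Kd_ATP=WT_KD_ATP,
        Kd_AMP=WT_KD_AMP[urea],
        conformational_rates=ConformationalRates.from_kc(
            kc_apo, kc_atp, relaxation_rate, kc_ternary=kc_ternary
        ),
    )
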