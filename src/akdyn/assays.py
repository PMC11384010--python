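"""Fits for bulk assay and titration data.

Covers the four fitting tasks of the activity/affinity side of the study:

* initial velocity from a linear window of a coupled-assay time course
  (NADH/NADPH absorbance at 340 nm or product concentration directly);
* the product-inhibited reverse-reaction time course
  [P](t) = (v0/eta) * (1 - exp(-eta*t)), whose initial slope is v0 and whose
  non-linearity factor eta quantifies product (AMP) inhibition;
* Michaelis-Menten fits of v0 versus substrate;
* 1:1 binding isotherms (fraction bound versus ligand) for MST titrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

#: Molar extinction coefficient of NADH/NADPH at 340 nm (M^-1 cm^-1),
#: standard literature value; 1 cm path length assumed.
NADH_EXTINCTION_340 = 6220.0

#: Default initial-velocity window: first 10 % of the time course or the
#: first 60 s, whichever is shorter (minimizes product-inhibition bias).
MAX_LINEAR_WINDOW_S = 60.0


@dataclass(frozen=True)
class ProductTimeCourse:
    """A product-formation time course from a coupled enzymatic assay."""

    times: np.ndarray              # s, strictly increasing
    product: np.ndarray            # M (or absorbance, see from_absorbance)
    direction: str = "forward"     # forward | reverse

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        p = np.asarray(self.product, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "product", p)
        if t.size != p.size:
            raise ValueError("times and product must have equal length")
        if t.size < 10:
            raise ValueError("time course needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")

    @classmethod
    def from_absorbance(
        cls,
        times: Sequence[float],
        absorbance: Sequence[float],
        direction: str = "forward",
        extinction: float = NADH_EXTINCTION_340,
        path_cm: float = 1.0,
    ) -> "ProductTimeCourse":
        """Convert a 340 nm absorbance trace to product concentration.

        In the forward assay NADH is consumed (absorbance falls) in 1:1
        proportion to product formed, so the negated absorbance change is
        used; in the reverse assay NADPH is produced and the raw change is
        used directly.
        """
        a = np.asarray(absorbance, float)
        delta = a - a[0]
        if direction == "forward":
            delta = -delta
        return cls(times=np.asarray(times, float), product=delta / (extinction * path_cm),
                   direction=direction)


@dataclass(frozen=True)
class InhibitionFit:
    """Result of an Eq.-type product-inhibition fit [P] = (v0/eta)(1-e^(-eta t))."""

    v0: float                      # initial velocity, M s^-1
    eta: float                     # non-linearity factor, s^-1 (0 = linear)
    covariance: Optional[np.ndarray]
    residual_norm: float
    linear_fallback: bool = False  # eta indistinguishable from zero


@dataclass(frozen=True)
class MMFit:
    v_max: float
    K_M: float
    covariance: np.ndarray
    saturated: bool = True         # False when data do not reach saturation


@dataclass(frozen=True)
class IsothermFit:
    Kd: float
    amplitude: float
    baseline: float
    covariance: np.ndarray
    monotone: bool = True


def fit_initial_velocity_linear(
    tc: ProductTimeCourse,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Initial velocity (M s^-1) as the least-squares slope over a time window.

    Without an explicit window, uses the first 10 % of the time course or the
    first 60 s, whichever is shorter.  Product formation is positive by
    convention.
    """
    t, p = tc.times, tc.product
    if window is None:
        t_end = t[0] + min(0.1 * (t[-1] - t[0]), MAX_LINEAR_WINDOW_S)
        window = (t[0], t_end)
    lo, hi = window
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ValueError("window must lie within the time range")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points in the fitting window")
    return float(linregress(t[mask], p[mask]).slope)


def _eq1(t: np.ndarray, v0: float, eta: float) -> np.ndarray:
    # numerically stable for eta*t -> 0 via expm1
    return -v0 / eta * np.expm1(-eta * t)


def fit_product_inhibition(tc: ProductTimeCourse, eta_floor: float = 1e-12) -> InhibitionFit:
    """Fit the product-inhibited time course [P](t) = (v0/eta)(1 - e^(-eta t)).

    Initial guesses come from the early slope (v0) and the curvature implied
    by the late-time plateau.  If the fitted eta is indistinguishable from
    zero (or the optimizer pushes it to the floor), a plain linear fit is
    returned with ``eta=0`` and ``linear_fallback=True``.
    """
    t, p = tc.times, tc.product
    # early-slope guess from the first few points (robust to coarse grids)
    n_head = max(3, t.size // 10)
    v0_guess = max(float(linregress(t[:n_head], p[:n_head]).slope), 1e-30)
    # plateau-based eta guess; fall back to mild curvature if no plateau
    p_late = p[-1]
    eta_guess = v0_guess / p_late if p_late > 0 else 1.0 / (t[-1] - t[0])
    eta_guess = max(eta_guess * 0.5, 1e-6 / (t[-1] - t[0] + 1e-300))
    try:
        popt, pcov = curve_fit(
            _eq1, t, p, p0=[v0_guess, eta_guess],
            bounds=([0.0, eta_floor], [np.inf, np.inf]), maxfev=20000,
            x_scale=[max(v0_guess, 1e-30), max(eta_guess, 1e-30)],
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        v0, eta = popt
        resid = p - _eq1(t, v0, eta)
        # compare against a straight line through the origin
        slope = float(np.dot(t, p) / np.dot(t, t))
        resid_lin = p - slope * t
        if eta <= 10 * eta_floor or np.linalg.norm(resid_lin) <= np.linalg.norm(resid) * (1 + 1e-9):
            return InhibitionFit(v0=slope, eta=0.0, covariance=None,
                                 residual_norm=float(np.linalg.norm(resid_lin)),
                                 linear_fallback=True)
        return InhibitionFit(v0=float(v0), eta=float(eta), covariance=pcov,
                             residual_norm=float(np.linalg.norm(resid)))
    except RuntimeError:
        slope = float(np.dot(t, p) / np.dot(t, t))
        resid_lin = p - slope * t
        return InhibitionFit(v0=slope, eta=0.0, covariance=None,
                             residual_norm=float(np.linalg.norm(resid_lin)),
                             linear_fallback=True)


def fit_michaelis_menten(
    conc: Sequence[float],
    v0: Sequence[float],
    sem: Optional[Sequence[float]] = None,
) -> MMFit:
    """Least-squares Michaelis-Menten fit v = v_max * S / (K_M + S).

    Weighted by the supplied standard errors when given.  ``saturated`` is
    False when the largest concentration does not exceed the fitted K_M,
    signalling a poorly constrained v_max.
    """
    S = np.asarray(conc, float)
    v = np.asarray(v0, float)
    if S.size < 4:
        raise ValueError("need at least 4 concentrations")
    sigma = np.asarray(sem, float) if sem is not None else None
    vmax_guess = v.max() * 1.2
    km_guess = S[np.argmin(np.abs(v - v.max() / 2))]
    popt, pcov = curve_fit(
        lambda s, vm, km: vm * s / (km + s), S, v,
        p0=[vmax_guess, max(km_guess, S.min())], sigma=sigma, absolute_sigma=sigma is not None,
        bounds=([0, 0], [np.inf, np.inf]), maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return MMFit(v_max=float(popt[0]), K_M=float(popt[1]), covariance=pcov,
                 saturated=bool(S.max() > popt[1]))


def fit_isotherm(
    ligand: Sequence[float],
    signal: Sequence[float],
    sem: Optional[Sequence[float]] = None,
    enzyme_conc: Optional[float] = None,
) -> IsothermFit:
    """1:1 binding isotherm fit f(L) = baseline + amplitude * L / (L + Kd).

    Ligand depletion is not corrected (titrations are run with enzyme far
    below Kd); a warning is emitted if ``enzyme_conc`` exceeds Kd/10.
    Non-monotone data beyond the noise level set ``monotone=False``.
    """
    L = np.asarray(ligand, float)
    f = np.asarray(signal, float)
    if L.size < 5:
        raise ValueError("need at least 5 ligand concentrations")
    sigma = np.asarray(sem, float) if sem is not None else None
    kd_guess = L[np.argmin(np.abs(f - (f.min() + f.max()) / 2))]
    popt, pcov = curve_fit(
        lambda l, kd, amp, base: base + amp * l / (l + kd), L, f,
        p0=[max(kd_guess, L.min()), f.max() - f.min(), f.min()],
        sigma=sigma, absolute_sigma=sigma is not None, maxfev=20000,
        bounds=([L.min() * 1e-6, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    kd, amp, base = (float(x) for x in popt)
    if kd <= 0:
        raise RuntimeError("isotherm fit produced non-positive Kd")
    if enzyme_conc is not None and enzyme_conc > kd / 10:
        warnings.warn(
            f"enzyme concentration {enzyme_conc:.3g} M exceeds Kd/10; "
            "ligand depletion may bias the fitted Kd", stacklevel=2,
        )
    order = np.argsort(L)
    diffs = np.diff(f[order]) * np.sign(amp if amp != 0 else 1.0)
    resid = f - (base + amp * L / (L + kd))
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))  # robust to outliers
    monotone = bool(np.all(diffs >= -max(3 * noise, 1e-12)))
    if not monotone:
        warnings.warn("titration is non-monotone beyond the noise level", stacklevel=2)
    return IsothermFit(Kd=kd, amplitude=amp, baseline=base, covariance=pcov, monotone=monotone)
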