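"""Assay-derived statistics for two-substrate dehydrogenase screens.

Covers the stereoselectivity value s = (SA_cis − SA_trans)/(SA_cis +
SA_trans) and its equivalent cis:trans ratio (1+s)/(1−s); first-order
thermal-deactivation fits (t_1/2 = ln 2 / k_d); Michaelis–Menten kinetics
(k_cat, K_m, k_cat/K_m); enantiomeric excess and conversion yield; and
guarded fold changes. Units are fixed: activities in U/mg, K_m in mM,
k_cat in s⁻¹, time in min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for the given inputs (e.g. 0/0)."""


@dataclass(frozen=True)
class ActivityPair:
    """Specific activities toward the two substrates (U/mg)."""

    sa_cis: float
    sa_trans: float

    def __post_init__(self) -> None:
        if self.sa_cis < 0 or self.sa_trans < 0:
            raise ValueError("specific activities must be non-negative")


def stereoselectivity_value(p: ActivityPair) -> float:
    """s = (SA_cis − SA_trans) / (SA_cis + SA_trans), in [−1, 1].

    +1 is exclusive cis preference, −1 exclusive trans preference. Undefined
    (typed error, never 0) when both activities vanish.
    """
    total = p.sa_cis + p.sa_trans
    if total == 0:
        raise UndefinedStatisticError(
            "stereoselectivity undefined: both activities are zero"
        )
    return (p.sa_cis - p.sa_trans) / total


def selectivity_ratio(s: float) -> float:
    """cis:trans ratio r = (1+s)/(1−s); s = ±1 maps to ±inf."""
    if not -1 <= s <= 1:
        raise ValueError("stereoselectivity value must lie in [-1, 1]")
    if s == 1:
        return math.inf
    if s == -1:
        return 0.0
    return (1 + s) / (1 - s)


def ratio_to_value(r: float) -> float:
    """Inverse of :func:`selectivity_ratio`: s = (r−1)/(r+1)."""
    if r < 0:
        raise ValueError("selectivity ratio must be non-negative")
    if math.isinf(r):
        return 1.0
    return (r - 1) / (r + 1)


@dataclass
class DeactivationFit:
    """First-order deactivation: kd (min⁻¹), t_half = ln2/kd (min)."""

    kd: float
    t_half: float
    r_squared: float
    n_points: int


def half_life(kd: float) -> float:
    """t_1/2 = ln(2) / k_d for a first-order deactivation rate (min⁻¹)."""
    if kd <= 0:
        raise ValueError("half-life defined only for kd > 0")
    return math.log(2) / kd


def deactivation_fit(times, residual_fractions) -> DeactivationFit:
    """Linear regression of ln(residual activity) against incubation time.

    kd is the negated slope; a negative kd (apparent activation) is reported
    with an undefined (NaN) half-life rather than rejected.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(residual_fractions, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if len(np.unique(t)) != len(t):
        raise ValueError("time points must be distinct")
    bad = np.nonzero(f <= 0)[0]
    if len(bad):
        raise ValueError(
            f"non-positive residual fraction at point(s) {bad.tolist()} — "
            "cannot take logarithm"
        )
    res = stats.linregress(t, np.log(f))
    kd = -res.slope
    return DeactivationFit(
        kd=kd,
        t_half=half_life(kd) if kd > 0 else math.nan,
        r_squared=res.rvalue ** 2,
        n_points=len(t),
    )


@dataclass
class KineticsFit:
    """Michaelis–Menten parameters with standard errors."""

    km: float              # mM
    kcat: float            # s^-1
    km_se: float
    kcat_se: float
    enzyme_conc: float     # µM (molar concentration used to scale Vmax)

    @property
    def efficiency(self) -> float:
        """k_cat / K_m in s⁻¹·mM⁻¹."""
        return self.kcat / self.km


def michaelis_menten_fit(concentrations, rates, enzyme_conc: float = 1.0) -> KineticsFit:
    """Nonlinear least-squares fit of v = Vmax·S / (Km + S).

    Initialisation: Vmax from the maximum observed rate, Km from the
    concentration nearest half-max. kcat = Vmax / enzyme_conc (pass
    enzyme_conc=1 when rates are already turnover numbers). Requires ≥5
    concentrations spanning both sides of the half-saturation estimate.
    """
    S = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(S) < 5:
        raise ValueError("need at least 5 concentration points")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates are zero — Km unidentifiable")
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2))])
    if km0 <= 0:
        km0 = float(np.median(S))
    if not (S.min() < km0 < S.max()):
        raise ValueError(
            "concentrations do not span the half-saturation estimate"
        )

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    popt, pcov = optimize.curve_fit(
        mm, S, v, p0=(vmax0, km0), maxfev=10000
    )
    vmax, km = popt
    if vmax < 0 or km <= 0:
        raise RuntimeError(
            f"fit returned non-physical parameters (Vmax={vmax:.3g}, Km={km:.3g})"
        )
    perr = np.sqrt(np.diag(pcov))
    return KineticsFit(
        km=float(km),
        kcat=float(vmax / enzyme_conc),
        km_se=float(perr[1]),
        kcat_se=float(perr[0] / enzyme_conc),
        enzyme_conc=enzyme_conc,
    )


@dataclass(frozen=True)
class EnantioResult:
    ee: float              # percent
    dominant: str          # "R" or "S" (or "none" at ee = 0)
    conversion_yield: float  # percent


def ee_and_yield(
    r_conc: float, s_conc: float, product_conc: float, initial_substrate: float
) -> EnantioResult:
    """Enantiomeric excess ee = 100·|R−S|/(R+S) and conversion yield
    = 100·product/(initial convertible substrate).

    The yield denominator is the convertible substrate pool (the
    stereoisomer(s) the enzyme accepts), not total substrate; pass the total
    to use the other convention.
    """
    if r_conc < 0 or s_conc < 0:
        raise ValueError("concentrations must be non-negative")
    total = r_conc + s_conc
    if total == 0:
        raise UndefinedStatisticError("ee undefined: no product formed")
    if initial_substrate <= 0:
        raise ValueError("initial substrate must be positive")
    ee = 100.0 * abs(r_conc - s_conc) / total
    dominant = "none" if r_conc == s_conc else ("R" if r_conc > s_conc else "S")
    return EnantioResult(
        ee=ee,
        dominant=dominant,
        conversion_yield=100.0 * product_conc / initial_substrate,
    )


GAINED_FROM_ZERO = "gained_from_zero"
"""Sentinel for activity acquired on a substrate the reference cannot
convert (reference activity exactly 0)."""


def fold_change(a: float, b: float) -> float | str:
    """a / b; a zero reference returns the :data:`GAINED_FROM_ZERO`
    sentinel instead of infinity."""
    if b < 0 or a < 0:
        raise ValueError("fold change defined for non-negative inputs")
    if b == 0:
        return GAINED_FROM_ZERO
    return a / b
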