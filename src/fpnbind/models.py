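"""Closed-form model equations for every assay readout.

This module holds the pure mathematics of the analysis chain: the
fluorescence-polarization (FP) formula, the one-site direct-binding
isotherm with a linear nonspecific component, the four-parameter Hill
(logistic) dose-response curve, the competition binding model in
fractional-saturation space, Michaelis-Menten transport kinetics, the
thermal-melt sigmoid, and the 1:1 Langmuir SPR kinetic response.

No fitting and no I/O happens here; everything is a deterministic
function of its arguments.  All binding concentrations are in nM,
transport substrate in uM, polarization in mP, SPR analyte
concentration in M, temperatures in degrees Celsius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FPIntensityPair",
    "DirectBindingParams",
    "HillParams",
    "CompetitionParams",
    "MichaelisParams",
    "MeltParams",
    "SPRParams",
    "polarization",
    "fp_from_intensities",
    "direct_binding_fp",
    "hill_fp",
    "competition_saturation",
    "implied_ic50",
    "kd_from_ic50",
    "fractional_saturation_from_fp",
    "mm_rate",
    "melt_fraction",
    "spr_response",
]

MP_FULL_SCALE = 1000.0  # mP corresponding to fully polarized emission


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FPIntensityPair:
    """Raw parallel/perpendicular fluorescence intensities of one well.

    ``g_factor`` is the dimensionless instrument correction multiplying
    the perpendicular channel; plate readers calibrated per-run report
    intensities with g already applied, hence the default of 1.
    """

    f_parallel: float
    f_perpendicular: float
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.f_parallel < 0 or self.f_perpendicular < 0:
            raise ValueError("invalid read: negative fluorescence intensity")
        if self.g_factor <= 0:
            raise ValueError("invalid read: g_factor must be positive")
        if self.f_parallel + self.g_factor * self.f_perpendicular <= 0:
            raise ValueError("degenerate well: zero total intensity")


@dataclass(frozen=True)
class DirectBindingParams:
    """One-site saturation binding with linear nonspecific component.

    b_max      maximal specific FP signal (mP)
    k_d        dissociation constant of the titrated interaction (nM)
    ns_slope   nonspecific signal slope (mP per nM titrant)
    background baseline FP of the free tracer (mP)
    """

    b_max: float
    k_d: float
    ns_slope: float = 0.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError("k_d must be strictly positive")
        if self.b_max < 0:
            raise ValueError("b_max must be nonnegative")
        if self.ns_slope < 0:
            raise ValueError("ns_slope must be nonnegative")


@dataclass(frozen=True)
class HillParams:
    """Four-parameter logistic dose-response curve on a log10 axis.

    The curve is evaluated against log10(concentration).  With the
    convention used here (exponent ``(log_ic50 - log10 x) * hill_n``) a
    *decreasing* displacement read corresponds to ``hill_n < 0``: the
    curve then runs from ``top`` at zero competitor to ``bottom`` at
    full displacement.  See :func:`hill_fp`.
    """

    bottom: float
    top: float
    log_ic50: float
    hill_n: float

    @property
    def ic50(self) -> float:
        """IC50 on the linear concentration scale (nM)."""
        return float(10.0 ** self.log_ic50)


@dataclass(frozen=True)
class CompetitionParams:
    """Competition binding model in fractional-saturation space.

    l_dis    concentration of the binding partner titrated in the direct
             assay and held fixed in the displacement assay (nM)
    k_d_dis  dissociation constant of the displaced (tracer) interaction (nM)
    k_d_x    dissociation constant of the competitor (nM); may be inf to
             model an inactive competitor
    """

    l_dis: float
    k_d_dis: float
    k_d_x: float

    def __post_init__(self) -> None:
        if self.l_dis <= 0 or self.k_d_dis <= 0 or self.k_d_x <= 0:
            raise ValueError("competition parameters must be strictly positive")


@dataclass(frozen=True)
class MichaelisParams:
    """Saturable single-substrate transport kinetics."""

    v_max: float  # maximal rate, normalized fluorescence change per s
    k_m: float    # apparent Michaelis constant, uM

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k_m <= 0:
            raise ValueError("v_max and k_m must be strictly positive")


@dataclass(frozen=True)
class MeltParams:
    """Logistic melting curve of normalized monomer-peak height.

    For a protein losing stability with temperature ``slope > 0`` and
    the curve decreases from ``top`` (low T) to ``bottom`` (high T).
    """

    t_m: float     # midpoint temperature, degC
    slope: float   # transition steepness, per degC
    top: float = 100.0     # upper plateau, % stability
    bottom: float = 0.0    # lower plateau, % stability

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise ValueError("top plateau must exceed bottom plateau")


@dataclass(frozen=True)
class SPRParams:
    """1:1 Langmuir kinetic model of an SPR sensorgram."""

    k_on: float   # association rate constant, per M per s
    k_off: float  # dissociation rate constant, per s
    r_max: float  # maximal response, RU

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0 or self.r_max <= 0:
            raise ValueError("SPR parameters must be strictly positive")

    @property
    def k_d(self) -> float:
        """Equilibrium dissociation constant k_off/k_on in M."""
        return self.k_off / self.k_on

    @property
    def k_d_nm(self) -> float:
        """Equilibrium dissociation constant in nM."""
        return self.k_d * 1e9


# ---------------------------------------------------------------------------
# fluorescence polarization
# ---------------------------------------------------------------------------


def polarization(f_parallel, f_perpendicular, g_factor: float = 1.0):
    """Vectorized FP in mP: 1000 * (F_par - g*F_perp) / (F_par + g*F_perp).

    Array-friendly core used by the plate pipeline; inputs are not
    validated here (see :func:`fp_from_intensities` for the checked
    scalar entry point).  Wells with zero total intensity yield NaN.
    """
    f_parallel = np.asarray(f_parallel, dtype=float)
    f_perpendicular = np.asarray(f_perpendicular, dtype=float)
    total = f_parallel + g_factor * f_perpendicular
    with np.errstate(divide="ignore", invalid="ignore"):
        out = MP_FULL_SCALE * (f_parallel - g_factor * f_perpendicular) / total
    out = np.clip(out, -MP_FULL_SCALE, MP_FULL_SCALE)  # guard float rounding
    return out if out.ndim else float(out)


def fp_from_intensities(pair: FPIntensityPair) -> float:
    """FP value in mP of one well; result is bounded in [-1000, 1000]."""
    return float(
        polarization(pair.f_parallel, pair.f_perpendicular, pair.g_factor)
    )


# ---------------------------------------------------------------------------
# direct binding
# ---------------------------------------------------------------------------


def direct_binding_fp(x, p: DirectBindingParams):
    """FP of a direct titration: B_max*x/(x + K_D) + NS*x + background.

    ``x`` is the variable protein concentration in nM.  Monotone
    nondecreasing for ``ns_slope >= 0``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("invalid concentration: x must be >= 0")
    out = p.b_max * x / (x + p.k_d) + p.ns_slope * x + p.background
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# displacement: Hill and competition
# ---------------------------------------------------------------------------


def hill_fp(x, p: HillParams):
    """Four-parameter Hill curve evaluated at competitor concentration x (nM).

    Y = bottom + (top - bottom) / (1 + 10**((log_ic50 - log10 x) * hill_n))

    The concentration enters on a log10 scale, so ``x`` must be strictly
    positive; zero-competitor wells are excluded from Hill fits (the
    competition model, defined at x = 0, retains them).  At
    ``x = 10**log_ic50`` the curve passes through (top + bottom)/2
    regardless of the sign of ``hill_n``; a decreasing displacement
    curve corresponds to ``hill_n < 0`` under this convention.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("point excluded from log-scale model: x must be > 0")
    expo = (p.log_ic50 - np.log10(x)) * p.hill_n
    out = p.bottom + (p.top - p.bottom) / (1.0 + 10.0 ** expo)
    return out if out.ndim else float(out)


def competition_saturation(x, p: CompetitionParams):
    """Fractional tracer saturation in the presence of competitor at x nM.

    Y = L_dis / (L_dis + K_D(dis) * (1 + x / K_D(x)))

    Free concentrations are approximated by totals (no ligand
    depletion), matching the model the displacement data are fitted to.
    Strictly decreasing in x, equal to L/(L + K_D(dis)) at x = 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("invalid concentration: x must be >= 0")
    out = p.l_dis / (p.l_dis + p.k_d_dis * (1.0 + x / p.k_d_x))
    return out if out.ndim else float(out)


def implied_ic50(p: CompetitionParams) -> float:
    """Competitor concentration (nM) at which saturation halves.

    Closed form of the root of Y(x) = Y(0)/2 under the competition
    model: IC50 = K_D(x) * (1 + L_dis / K_D(dis)).  This is the
    Cheng-Prusoff-type bridge between the mechanistic K_D and the
    empirical Hill IC50.
    """
    return p.k_d_x * (1.0 + p.l_dis / p.k_d_dis)


def kd_from_ic50(ic50: float, l_dis: float, k_d_dis: float) -> float:
    """Invert :func:`implied_ic50`: K_D(x) = IC50 / (1 + L_dis/K_D(dis))."""
    if ic50 <= 0:
        raise ValueError("ic50 must be strictly positive")
    return ic50 / (1.0 + l_dis / k_d_dis)


def fractional_saturation_from_fp(fp, direct: DirectBindingParams, l_dis: float):
    """Convert displacement FP readings to fractional tracer saturation.

    Linear inversion of the direct-binding signal model at the fixed
    protein concentration ``l_dis``:

        Y = (FP - background - ns_slope * l_dis) / b_max

    The nonspecific term is a constant offset at fixed ``l_dis``.  Raw
    values are returned unmodified; values outside [0, 1] trigger a
    warning so calibration problems surface but information is not
    destroyed.
    """
    if direct.b_max == 0:
        raise ValueError("degenerate conversion: b_max is zero")
    fp = np.asarray(fp, dtype=float)
    out = (fp - direct.background - direct.ns_slope * l_dis) / direct.b_max
    if np.any((out < -1e-9) | (out > 1 + 1e-9)):
        warnings.warn(
            "fractional saturation outside [0, 1]; raw values retained",
            stacklevel=2,
        )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# transport, melting, SPR
# ---------------------------------------------------------------------------


def mm_rate(s, p: MichaelisParams):
    """Michaelis-Menten initial rate v_max*s/(k_m + s) at substrate s (uM)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("invalid concentration: s must be >= 0")
    out = p.v_max * s / (p.k_m + s)
    return out if out.ndim else float(out)


def melt_fraction(t, p: MeltParams):
    """Percent stability at pre-incubation temperature t (degC).

    bottom + (top - bottom) / (1 + exp(slope * (t - t_m))); equals
    (top + bottom)/2 at t = t_m and approaches top as t -> -inf for
    slope > 0.
    """
    t = np.asarray(t, dtype=float)
    out = p.bottom + (p.top - p.bottom) / (1.0 + np.exp(p.slope * (t - p.t_m)))
    return out if out.ndim else float(out)


def spr_response(t, conc: float, phase: str, p: SPRParams, r0: float | None = None):
    """1:1 Langmuir SPR response at time t (s past the phase start).

    association:  R(t) = R_eq * (1 - exp(-(k_on*conc + k_off) * t)),
                  R_eq = r_max * conc / (conc + k_off/k_on)
    dissociation: R(t) = r0 * exp(-k_off * t)

    ``conc`` is the analyte concentration in M (association phase only);
    ``r0`` is the response at the start of dissociation in RU.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must not precede the phase start")
    if phase == "association":
        if conc <= 0:
            raise ValueError("invalid analyte concentration")
        k_obs = p.k_on * conc + p.k_off
        r_eq = p.r_max * conc / (conc + p.k_d)
        out = r_eq * (1.0 - np.exp(-k_obs * t))
    elif phase == "dissociation":
        if r0 is None:
            raise ValueError("dissociation phase requires r0")
        out = r0 * np.exp(-p.k_off * t)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return out if out.ndim else float(out)
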