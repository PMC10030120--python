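"""Thermal-stability, proteoliposome-transport and SPR analyses.

Melting curves (normalized monomer-peak height vs pre-incubation
temperature) are fitted to a logistic sigmoid to yield an apparent Tm.
Calcein-quench transport traces are reduced to normalized initial
rates, which feed a Michaelis-Menten fit for the apparent K_M.
Sensorgram ladders are fitted globally to the 1:1 Langmuir kinetic
model with one k_on/k_off/R_max per ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .fitting import Dataset, FitError, FitOptions, ParameterSpec, FitResult, fit

__all__ = [
    "MeltSeries",
    "TransportTrace",
    "SPRSensorgram",
    "MeltFitResult",
    "fit_melt",
    "delta_tm",
    "extract_initial_rate",
    "KmFitResult",
    "fit_km",
    "SPRFitResult",
    "fit_spr",
]


# ---------------------------------------------------------------------------
# thermal stability
# ---------------------------------------------------------------------------


@dataclass
class MeltSeries:
    """Temperature (degC) vs monomer-peak height normalized to the
    lowest-temperature reference (100% stability)."""

    temperature_c: np.ndarray
    stability_pct: np.ndarray
    condition: str = "apo"

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.stability_pct = np.asarray(self.stability_pct, dtype=float)
        if self.temperature_c.shape != self.stability_pct.shape:
            raise ValueError("temperature/stability length mismatch")


@dataclass
class MeltFitResult:
    params: models.MeltParams
    t_m_se: float | None
    stderr: dict[str, float | None]
    extrapolated: bool
    fit: FitResult


def _melt_model(t, t_m, slope, top, bottom):
    # raw logistic: intermediate optimizer steps may violate top > bottom,
    # so skip the MeltParams invariant here
    t = np.asarray(t, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.exp(slope * (t - t_m)))


def fit_melt(series: MeltSeries, options: FitOptions | None = None) -> MeltFitResult:
    """Fit the melting sigmoid; Tm outside the sampled range is flagged.

    Requires at least 5 temperatures.  A series whose stability rises
    with temperature has no thermal transition to fit and raises
    ``no transition detected``.
    """
    t = series.temperature_c
    y = series.stability_pct
    if t.size < 5:
        raise ValueError("melt series needs >= 5 temperatures")
    order = np.argsort(t)
    lo = y[order][: max(2, t.size // 4)].mean()
    hi = y[order][-max(2, t.size // 4):].mean()
    if hi >= lo:
        raise ValueError("no transition detected: stability does not decrease")

    # initial Tm: first temperature crossing the half height
    half = (lo + hi) / 2.0
    below = np.flatnonzero(y[order] <= half)
    tm0 = float(t[order][below[0]]) if below.size else float(np.median(t))
    specs = [
        ParameterSpec("t_m", tm0, -50.0, 200.0),
        ParameterSpec("slope", 0.3, 1e-4, 20.0),
        ParameterSpec("top", 100.0, 0.0, np.inf),
        ParameterSpec("bottom", max(float(np.min(y)), 0.0), 0.0, np.inf),
    ]
    result = fit(_melt_model, [Dataset(series.condition, t, y)], specs, options)
    vals, errs = result.params[0], result.stderr[0]
    params = models.MeltParams(
        t_m=vals["t_m"], slope=vals["slope"], top=vals["top"], bottom=vals["bottom"]
    )
    extrapolated = not (t.min() <= params.t_m <= t.max())
    return MeltFitResult(params, errs["t_m"], dict(errs), extrapolated, result)


def delta_tm(apo: MeltFitResult, holo: MeltFitResult) -> tuple[float, float | None]:
    """Ligand-induced Tm shift holo - apo with independence-propagated SE."""
    if apo.extrapolated or holo.extrapolated:
        raise ValueError("delta_tm: a Tm fit is flagged as extrapolated")
    d = holo.params.t_m - apo.params.t_m
    if apo.t_m_se is None or holo.t_m_se is None:
        return d, None
    return d, float(np.hypot(apo.t_m_se, holo.t_m_se))


# ---------------------------------------------------------------------------
# transport traces
# ---------------------------------------------------------------------------


@dataclass
class TransportTrace:
    """Calcein-quench fluorescence trace with its event schedule.

    Events (in s): valinomycin (sets the membrane potential; no effect
    on electroneutral transport), CoCl2 addition (starts influx at
    ``co_conc_um`` uM) and calcimycin (equilibrates Co2+, defining the
    full-quench plateau used for normalization).
    """

    time_s: np.ndarray
    fluorescence_au: np.ndarray
    t_valinomycin: float
    t_cocl2: float
    t_calcimycin: float | None
    co_conc_um: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.time_s.shape != self.fluorescence_au.shape:
            raise ValueError("time/fluorescence length mismatch")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.t_valinomycin >= self.t_cocl2:
            raise ValueError("events out of order: valinomycin must precede CoCl2")
        if self.t_calcimycin is not None and self.t_calcimycin <= self.t_cocl2:
            raise ValueError("events out of order: calcimycin must follow CoCl2")


def extract_initial_rate(
    trace: TransportTrace,
    window_s: float = 30.0,
    baseline_s: float = 60.0,
    plateau_settle_s: float = 20.0,
) -> tuple[float, bool]:
    """Normalized initial influx rate from one quench trace.

    The slope of a straight line fitted over the first ``window_s``
    seconds after CoCl2 addition is divided by the quenchable span
    (baseline mean minus post-calcimycin plateau mean) and negated, so
    influx reports as a positive rate in fraction of quenchable signal
    per second.  Normalization makes the result invariant to affine
    rescaling of the raw fluorescence.  Returns ``(rate, normalized)``;
    without a calcimycin plateau the raw (negated) slope is returned
    with ``normalized=False``.
    """
    t, f = trace.time_s, trace.fluorescence_au
    win = (t >= trace.t_cocl2) & (t <= trace.t_cocl2 + window_s)
    if win.sum() < 5:
        raise ValueError("fewer than 5 samples in the post-CoCl2 window")
    slope = float(np.polyfit(t[win], f[win], 1)[0])
    base = (t >= trace.t_cocl2 - baseline_s) & (t < trace.t_cocl2)
    if not base.any():
        raise ValueError("no baseline samples before CoCl2 addition")
    baseline = float(f[base].mean())
    if trace.t_calcimycin is None:
        import warnings

        warnings.warn("no calcimycin plateau; returning unnormalized rate",
                      stacklevel=2)
        return -slope, False
    plat = t >= trace.t_calcimycin + plateau_settle_s
    if not plat.any():
        raise ValueError("no samples on the post-calcimycin plateau")
    plateau = float(f[plat].mean())
    span = baseline - plateau
    if span <= 0:
        raise ValueError("quenchable span is not positive")
    return -slope / span, True


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


@dataclass
class KmFitResult:
    params: models.MichaelisParams
    stderr: dict[str, float | None]
    flags: list[str]
    fit: FitResult


def _mm_model(s, v_max, k_m):
    return models.mm_rate(s, models.MichaelisParams(v_max=v_max, k_m=k_m))


def fit_km(
    rates: np.ndarray,
    concentrations_um: np.ndarray,
    options: FitOptions | None = None,
) -> KmFitResult:
    """Michaelis-Menten fit of initial rates vs substrate concentration.

    A zero-substrate rate, if present, is treated as the assay blank
    and subtracted from all rates before fitting.  Requires >= 4
    concentrations; non-saturating data (fitted K_M at or above the top
    concentration) are flagged ``poorly constrained``.
    """
    rates = np.asarray(rates, dtype=float)
    conc = np.asarray(concentrations_um, dtype=float)
    if conc.size < 4:
        raise ValueError("fit_km needs >= 4 concentrations")
    blank_mask = conc == 0
    if blank_mask.any():
        blank = float(rates[blank_mask].mean())
        rates = rates - blank
    pos = conc > 0
    x, y = conc[pos], rates[pos]
    if np.allclose(y, 0.0, atol=1e-15):
        raise ValueError("no transport: all rates are zero")
    specs = [
        ParameterSpec("v_max", float(np.max(y)), 1e-12, np.inf, log_scale=True),
        ParameterSpec("k_m", float(np.median(x)), 1e-6, 1e6, log_scale=True,
                      multistart=True),
    ]
    result = fit(_mm_model, [Dataset("km", x, y)], specs, options)
    vals, errs = result.params[0], result.stderr[0]
    params = models.MichaelisParams(v_max=vals["v_max"], k_m=vals["k_m"])
    flags = []
    if params.k_m >= x.max():
        flags.append("poorly constrained: K_M at or above the top concentration")
    return KmFitResult(params, dict(errs), flags, result)


# ---------------------------------------------------------------------------
# SPR kinetics
# ---------------------------------------------------------------------------


@dataclass
class SPRSensorgram:
    """Baseline-subtracted sensorgram of one analyte concentration.

    Association runs on [0, t_assoc_end); dissociation follows.
    """

    time_s: np.ndarray
    response_ru: np.ndarray
    conc_nm: float
    t_assoc_end: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_ru = np.asarray(self.response_ru, dtype=float)
        if self.time_s.shape != self.response_ru.shape:
            raise ValueError("time/response length mismatch")
        if self.conc_nm <= 0:
            raise ValueError("invalid analyte concentration")


@dataclass
class SPRFitResult:
    params: models.SPRParams
    k_d_nm: float
    stderr: dict[str, float | None]
    k_d_nm_se: float | None
    flags: list[str]
    fit: FitResult


def _spr_curve(t, conc_m, t_assoc_end, p: models.SPRParams):
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    assoc = t < t_assoc_end
    out[assoc] = models.spr_response(t[assoc], conc_m, "association", p)
    r0 = models.spr_response(t_assoc_end, conc_m, "association", p)
    out[~assoc] = models.spr_response(
        t[~assoc] - t_assoc_end, conc_m, "dissociation", p, r0=r0
    )
    return out


def fit_spr(
    sensorgrams: list[SPRSensorgram],
    options: FitOptions | None = None,
) -> SPRFitResult:
    """Global 1:1 Langmuir fit of a sensorgram ladder.

    One k_on, k_off and R_max is shared across all analyte
    concentrations (single-site semantics).  Requires >= 3
    concentrations.  K_D = k_off/k_on is reported in nM with a
    delta-method SE (covariance between the log-rate constants
    included when available).  A dissociation window too short to
    constrain k_off (k_off * t_diss < 0.1) is flagged.
    """
    if len(sensorgrams) < 3:
        raise ValueError("fit_spr needs >= 3 analyte concentrations")

    datasets, model_list = [], []
    for sg in sensorgrams:
        conc_m = sg.conc_nm * 1e-9
        t_end = sg.t_assoc_end

        def make(conc_m=conc_m, t_end=t_end):
            def m(t, k_on, k_off, r_max):
                return _spr_curve(
                    t, conc_m, t_end,
                    models.SPRParams(k_on=k_on, k_off=k_off, r_max=r_max),
                )
            return m

        model_list.append(make())
        datasets.append(Dataset(f"{sg.conc_nm:g}nM", sg.time_s, sg.response_ru))

    r_max0 = max(float(np.max(sg.response_ru)) for sg in sensorgrams)
    specs = [
        ParameterSpec("k_on", 1e5, 1e1, 1e9, share_group="k_on", log_scale=True),
        ParameterSpec("k_off", 1e-2, 1e-7, 1e2, share_group="k_off", log_scale=True),
        ParameterSpec("r_max", max(r_max0, 1.0), 1e-3, np.inf,
                      share_group="r_max", log_scale=True),
    ]
    result = fit(model_list, datasets, specs, options)
    vals, errs = result.params[0], result.stderr[0]
    params = models.SPRParams(k_on=vals["k_on"], k_off=vals["k_off"],
                              r_max=vals["r_max"])
    k_d_nm = params.k_d_nm
    # delta method on log-scale internal parameters: Var(log kd) =
    # Var(log koff) + Var(log kon) - 2 Cov
    k_d_se = None
    if errs["k_on"] is not None and errs["k_off"] is not None:
        se_log_on = errs["k_on"] / (np.log(10) * vals["k_on"])
        se_log_off = errs["k_off"] / (np.log(10) * vals["k_off"])
        cov_term = 0.0
        if result.covar is not None:
            names = result.covar_names
            if "k_on" in names and "k_off" in names:
                cov_term = result.covar[names.index("k_on"), names.index("k_off")]
        var_log_kd = se_log_on**2 + se_log_off**2 - 2 * cov_term
        if var_log_kd > 0:
            k_d_se = float(np.log(10) * k_d_nm * np.sqrt(var_log_kd))
    flags = []
    t_diss = max(
        float(sg.time_s.max() - sg.t_assoc_end) for sg in sensorgrams
    )
    if params.k_off * t_diss < 0.1:
        flags.append("dissociation too short to constrain k_off")
    return SPRFitResult(params, k_d_nm, dict(errs), k_d_se, flags, result)
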