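"""Seeded generators emulating the statistical structure of each assay.

Every generator is a deterministic function of its design and a seed,
and emits exactly the in-memory objects (or plate tables) the analysis
stages consume, so the whole chain is testable without instrument
exports.  Defaults mirror the study conditions: protein titrated from
13 nM to 6 uM against 10 nM tracer, displacement series at 400 nM
protein (800 nM for the low-affinity Arg466Ala-like case), nonspecific
control wells with 30 uM blocker, melting series up to 75 degC
normalized to a 4 degC reference, calcein-quench traces with
valinomycin/CoCl2/calcimycin events, and multi-concentration SPR
ladders.

Noise is applied on the FP scale (mP) by default and then mapped to a
parallel/perpendicular intensity pair at fixed total intensity; an
intensity-level multiplicative mode exists because real plate noise
lives on the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .assays import MeltSeries, SPRSensorgram, TransportTrace
from .pipeline import PLATE_COLUMNS

__all__ = [
    "SHARED_SIGNAL",
    "STUDY_TRUTHS",
    "intensities_from_fp",
    "DirectTitrationDesign",
    "DisplacementDesign",
    "MeltDesign",
    "TransportDesign",
    "SPRDesign",
    "gen_direct_titration",
    "gen_displacement",
    "gen_melt",
    "gen_transport_trace",
    "gen_spr",
    "gen_study_plate",
]

# Shared signal calibration of the FP plate model.  Chosen so that a
# 400 nM displacement series with a 100 nM-tracer-K_D construct spans
# 225 mP (full displacement) to 307 mP (no competitor): background
# 220 mP, nonspecific slope 0.0125 mP/nM and maximal specific signal
# 102.5 mP give bottom = 220 + 0.0125*400 = 225 and top = 225 +
# 102.5 * 0.8 = 307.
SHARED_SIGNAL = {"b_max": 102.5, "background": 220.0, "ns_slope": 0.0125}

# Ground-truth dissociation constants (nM) per construct used by the
# end-to-end study simulation: tracer K_D from the direct titrations,
# competitor K_Ds from the competition fits, and the fixed protein
# concentration of the displacement assay.
STUDY_TRUTHS: dict[str, dict] = {
    "WT": {"k_d_tracer": 100.0, "hepcidin-25": 131.0, "vamifeport": 24.0, "l_dis": 400.0},
    "R466A": {"k_d_tracer": 501.0, "hepcidin-25": 713.0, "vamifeport": 83.0, "l_dis": 800.0},
    "L469A": {"k_d_tracer": 57.0, "hepcidin-25": 108.0, "vamifeport": 37.0, "l_dis": 400.0},
    "L469S": {"k_d_tracer": 94.0, "hepcidin-25": 180.0, "vamifeport": 60.0, "l_dis": 400.0},
    "W470S": {"k_d_tracer": 227.0, "hepcidin-25": 222.0, "vamifeport": 82.0, "l_dis": 400.0},
    "V68S": {"k_d_tracer": 1044.0, "hepcidin-25": None, "vamifeport": None, "l_dis": 400.0},
}


def intensities_from_fp(fp: float, total_intensity: float) -> models.FPIntensityPair:
    """Invert the FP formula at g = 1 for a given total intensity.

    f_parallel = total*(1 + fp/1000)/2, f_perpendicular = total*(1 - fp/1000)/2;
    round-trips exactly through :func:`fpnbind.models.fp_from_intensities`.
    """
    if abs(fp) > models.MP_FULL_SCALE:
        raise ValueError("|fp| must not exceed 1000 mP")
    if total_intensity <= 0:
        raise ValueError("total intensity must be positive")
    frac = fp / models.MP_FULL_SCALE
    return models.FPIntensityPair(
        f_parallel=total_intensity * (1.0 + frac) / 2.0,
        f_perpendicular=total_intensity * (1.0 - frac) / 2.0,
    )


def _serial_dilution(top: float, factor: float, n: int) -> np.ndarray:
    return top / factor ** np.arange(n)


def _titration_ladder(top: float, bottom: float, n: int) -> np.ndarray:
    # serial dilution whose factor is chosen to reach `bottom` in n steps
    factor = (top / bottom) ** (1.0 / (n - 1))
    return _serial_dilution(top, factor, n)


def _plate_rows(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    cols = PLATE_COLUMNS + ["blocked"]
    return df[cols]


def _emit_wells(
    rows: list[dict],
    rng: np.random.Generator,
    construct: str,
    competitor: str,
    conc_nm: float,
    competitor_conc_nm: float,
    fp_true: float,
    replicate: int,
    blocked: bool,
    fp_sd_mp: float,
    total_intensity: float,
    intensity_cv: float,
) -> None:
    fp = fp_true + (rng.normal(0.0, fp_sd_mp) if fp_sd_mp > 0 else 0.0)
    fp = float(np.clip(fp, -999.9, 999.9))
    pair = intensities_from_fp(fp, total_intensity)
    f_para, f_perp = pair.f_parallel, pair.f_perpendicular
    if intensity_cv > 0:
        f_para *= 1.0 + rng.normal(0.0, intensity_cv)
        f_perp *= 1.0 + rng.normal(0.0, intensity_cv)
    rows.append(
        {
            "sample_id": f"w{len(rows):04d}",
            "construct": construct,
            "competitor": competitor,
            "conc_nm": conc_nm,
            "competitor_conc_nm": competitor_conc_nm,
            "f_para": f_para,
            "f_perp": f_perp,
            "replicate": replicate,
            "blocked": blocked,
        }
    )


# ---------------------------------------------------------------------------
# FP plate generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectTitrationDesign:
    """Direct-binding titration: variable protein against fixed tracer."""

    truths: dict[str, models.DirectBindingParams]
    top_nm: float = 6000.0
    bottom_nm: float = 13.0
    n_points: int = 24
    replicates: int = 3
    fp_sd_mp: float = 5.0
    total_intensity: float = 2000.0
    intensity_cv: float = 0.0
    include_blocked: bool = True
    blocked_competitor: str = "vamifeport"
    blocked_conc_nm: float = 30000.0
    blocked_replicates: int = 1


def gen_direct_titration(design: DirectTitrationDesign, seed: int) -> pd.DataFrame:
    """Simulate direct titrations (and 30 uM-blocker controls) as a plate.

    Blocked control wells have the specific binding term zeroed; they
    read background + ns_slope*x only.
    """
    rng = np.random.default_rng(seed)
    ladder = _titration_ladder(design.top_nm, design.bottom_nm, design.n_points)
    rows: list[dict] = []
    for construct, p in design.truths.items():
        for rep in range(design.replicates):
            for x in ladder:
                _emit_wells(
                    rows, rng, construct, "", float(x), 0.0,
                    models.direct_binding_fp(x, p), rep, False,
                    design.fp_sd_mp, design.total_intensity, design.intensity_cv,
                )
        if design.include_blocked:
            for rep in range(design.blocked_replicates):
                for x in ladder:
                    fp_true = p.background + p.ns_slope * x
                    _emit_wells(
                        rows, rng, construct, design.blocked_competitor,
                        float(x), design.blocked_conc_nm, fp_true, rep, True,
                        design.fp_sd_mp, design.total_intensity,
                        design.intensity_cv,
                    )
    return _plate_rows(rows)


@dataclass(frozen=True)
class DisplacementDesign:
    """Displacement series at fixed protein/tracer against a competitor ladder.

    ``k_d_x`` may be inf to emulate an inactive competitor (flat series).
    """

    construct: str
    competitor: str
    direct: models.DirectBindingParams   # signal model of the construct
    l_dis_nm: float
    k_d_x_nm: float
    top_nm: float = 30000.0
    dilution_factor: float = 2.0
    n_points: int = 16
    include_zero: bool = True
    replicates: int = 3
    fp_sd_mp: float = 5.0
    total_intensity: float = 2000.0
    intensity_cv: float = 0.0


def gen_displacement(design: DisplacementDesign, seed: int) -> pd.DataFrame:
    """Simulate one displacement series as a plate table.

    FP = background + ns_slope*l_dis + b_max * Y(x) with Y the
    competition-model fractional saturation, so at zero competitor the
    wells reproduce the direct-binding FP at x_titrant = l_dis.
    """
    rng = np.random.default_rng(seed)
    ladder = _serial_dilution(design.top_nm, design.dilution_factor, design.n_points)
    xs = np.concatenate([[0.0], ladder]) if design.include_zero else ladder
    p = design.direct
    offset = p.background + p.ns_slope * design.l_dis_nm
    y0 = design.l_dis_nm / (design.l_dis_nm + p.k_d)
    rows: list[dict] = []
    for rep in range(design.replicates):
        for x in xs:
            if np.isinf(design.k_d_x_nm):
                y = y0
            else:
                y = models.competition_saturation(
                    x,
                    models.CompetitionParams(
                        l_dis=design.l_dis_nm, k_d_dis=p.k_d,
                        k_d_x=design.k_d_x_nm,
                    ),
                )
            _emit_wells(
                rows, rng, design.construct, design.competitor,
                design.l_dis_nm, float(x), offset + p.b_max * y, rep, False,
                design.fp_sd_mp, design.total_intensity, design.intensity_cv,
            )
    return _plate_rows(rows)


def _direct_params_for(construct: str) -> models.DirectBindingParams:
    return models.DirectBindingParams(
        b_max=SHARED_SIGNAL["b_max"],
        k_d=STUDY_TRUTHS[construct]["k_d_tracer"],
        ns_slope=SHARED_SIGNAL["ns_slope"],
        background=SHARED_SIGNAL["background"],
    )


def gen_study_plate(
    seed: int,
    constructs: list[str] | None = None,
    competitors: tuple[str, ...] = ("hepcidin-25", "vamifeport"),
    fp_sd_mp: float = 5.0,
    replicates: int = 3,
) -> pd.DataFrame:
    """One plate covering the whole study: all constructs' titrations
    plus displacement series for every construct/competitor with a
    defined ground-truth K_D (see ``STUDY_TRUTHS``)."""
    if constructs is None:
        constructs = list(STUDY_TRUTHS)
    rng = np.random.default_rng(seed)
    truths = {c: _direct_params_for(c) for c in constructs}
    parts = [
        gen_direct_titration(
            DirectTitrationDesign(truths=truths, fp_sd_mp=fp_sd_mp,
                                  replicates=replicates),
            int(rng.integers(2**31 - 1)),
        )
    ]
    for c in constructs:
        for comp in competitors:
            kdx = STUDY_TRUTHS[c].get(comp)
            if kdx is None:
                continue
            parts.append(
                gen_displacement(
                    DisplacementDesign(
                        construct=c, competitor=comp,
                        direct=truths[c],
                        l_dis_nm=STUDY_TRUTHS[c]["l_dis"],
                        k_d_x_nm=kdx, fp_sd_mp=fp_sd_mp,
                        replicates=replicates,
                    ),
                    int(rng.integers(2**31 - 1)),
                )
            )
    plate = pd.concat(parts, ignore_index=True)
    plate["sample_id"] = [f"w{i:04d}" for i in range(len(plate))]
    return plate


# ---------------------------------------------------------------------------
# melting, transport, SPR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeltDesign:
    truth: models.MeltParams
    temperatures_c: tuple[float, ...] = (
        4.0, 25.0, 30.0, 35.0, 40.0, 42.5, 45.0, 47.5, 50.0, 52.5, 55.0,
        60.0, 65.0, 70.0, 75.0,
    )
    noise_sd_pct: float = 2.0
    condition: str = "apo"


def gen_melt(design: MeltDesign, seed: int) -> MeltSeries:
    """Simulate a normalized melting series (logistic decay + noise)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(design.temperatures_c, dtype=float)
    y = models.melt_fraction(t, design.truth)
    if design.noise_sd_pct > 0:
        y = y + rng.normal(0.0, design.noise_sd_pct, size=t.shape)
    return MeltSeries(t, np.clip(y, 0.0, None), condition=design.condition)


@dataclass(frozen=True)
class TransportDesign:
    """Calcein-quench trace: baseline, ionophore events, exponential quench.

    The quench approaches the full-quench plateau as a single
    exponential whose initial slope equals the Michaelis-Menten rate
    scaled to the quenchable span; that makes the generated initial
    slope exactly the quantity the rate extractor targets without
    claiming a mechanistic time course.
    """

    truth: models.MichaelisParams
    co_conc_um: float
    dt_s: float = 4.0
    t_valinomycin_s: float = 60.0
    t_cocl2_s: float = 120.0
    t_calcimycin_s: float = 480.0
    t_end_s: float = 700.0
    f_baseline_au: float = 50000.0
    quenchable_fraction: float = 0.7
    calcimycin_rate_per_s: float = 0.2
    noise_sd_au: float = 100.0


def gen_transport_trace(design: TransportDesign, seed: int) -> TransportTrace:
    rng = np.random.default_rng(seed)
    if not (design.t_valinomycin_s < design.t_cocl2_s < design.t_calcimycin_s):
        raise ValueError("events out of order: valinomycin < CoCl2 < calcimycin required")
    t = np.arange(0.0, design.t_end_s, design.dt_s)
    span = design.quenchable_fraction * design.f_baseline_au
    plateau = design.f_baseline_au - span
    rate = (
        models.mm_rate(design.co_conc_um, design.truth)
        if design.co_conc_um > 0
        else 0.0
    )
    f = np.full_like(t, design.f_baseline_au)
    quench = (t >= design.t_cocl2_s) & (t < design.t_calcimycin_s)
    if rate > 0:
        f[quench] = plateau + span * np.exp(-rate * (t[quench] - design.t_cocl2_s))
    after = t >= design.t_calcimycin_s
    f_at_cal = (
        plateau + span * np.exp(-rate * (design.t_calcimycin_s - design.t_cocl2_s))
        if rate > 0
        else design.f_baseline_au
    )
    f[after] = plateau + (f_at_cal - plateau) * np.exp(
        -design.calcimycin_rate_per_s * (t[after] - design.t_calcimycin_s)
    )
    if design.noise_sd_au > 0:
        f = f + rng.normal(0.0, design.noise_sd_au, size=t.shape)
    return TransportTrace(
        time_s=t,
        fluorescence_au=f,
        t_valinomycin=design.t_valinomycin_s,
        t_cocl2=design.t_cocl2_s,
        t_calcimycin=design.t_calcimycin_s,
        co_conc_um=design.co_conc_um,
    )


@dataclass(frozen=True)
class SPRDesign:
    truth: models.SPRParams
    concs_nm: tuple[float, ...] = (3.4, 13.5, 54.5, 109.0, 217.5, 435.0, 870.0)
    t_assoc_s: float = 120.0
    t_diss_s: float = 300.0
    dt_s: float = 1.0
    noise_sd_ru: float = 1.0


def gen_spr(design: SPRDesign, seed: int) -> list[SPRSensorgram]:
    """Simulate a sensorgram ladder from the closed-form 1:1 model."""
    rng = np.random.default_rng(seed)
    out = []
    for conc in design.concs_nm:
        t = np.arange(0.0, design.t_assoc_s + design.t_diss_s, design.dt_s)
        conc_m = conc * 1e-9
        assoc = t < design.t_assoc_s
        r = np.empty_like(t)
        r[assoc] = models.spr_response(t[assoc], conc_m, "association", design.truth)
        r0 = models.spr_response(design.t_assoc_s, conc_m, "association", design.truth)
        r[~assoc] = models.spr_response(
            t[~assoc] - design.t_assoc_s, conc_m, "dissociation",
            design.truth, r0=r0,
        )
        if design.noise_sd_ru > 0:
            r = r + rng.normal(0.0, design.noise_sd_ru, size=t.shape)
        out.append(
            SPRSensorgram(
                time_s=t, response_ru=r, conc_nm=conc,
                t_assoc_end=design.t_assoc_s,
            )
        )
    return out
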