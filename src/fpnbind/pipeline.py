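"""Two-stage inference chain for FP plate data.

Stage 1 fits direct-binding titrations (variable protein, fixed tracer)
globally across constructs with the maximal signal and background
shared, yielding the tracer dissociation constant of each construct.
Stage 2 analyses displacement series (fixed protein/tracer mix,
variable competitor) twice: empirically with a four-parameter Hill
curve (IC50) and mechanistically with the competition binding model in
fractional-saturation space (competitor K_D), the latter consuming the
stage-1 parameters.  The stage order is strict: competition fits refuse
to run without stage-1 results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import models
from .fitting import Dataset, FitError, FitOptions, FitResult, ParameterSpec, fit

__all__ = [
    "PLATE_COLUMNS",
    "PipelineConfig",
    "PipelineError",
    "PipelineReport",
    "compute_plate_fp",
    "fit_direct",
    "fit_displacement_hill",
    "fit_displacement_competition",
    "run_pipeline",
]

PLATE_COLUMNS = [
    "sample_id",
    "construct",
    "competitor",
    "conc_nm",
    "competitor_conc_nm",
    "f_para",
    "f_perp",
    "replicate",
]

BLOCKED_CONC_NM = 30000.0  # 30 uM competitor defines a nonspecific control


class PipelineError(RuntimeError):
    """Raised on violations of the stage order or unusable input."""


# ---------------------------------------------------------------------------
# plate-level FP computation
# ---------------------------------------------------------------------------


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise PipelineError(f"plate is missing required columns: {missing}")
    if plate.empty:
        raise PipelineError("no data: plate is empty")
    plate = plate.copy()
    if "blocked" not in plate.columns:
        comp = plate["competitor"].fillna("")
        plate["blocked"] = (comp != "") & (
            plate["competitor_conc_nm"].fillna(0) >= BLOCKED_CONC_NM
        )
    return plate


def compute_plate_fp(plate: pd.DataFrame) -> pd.DataFrame:
    """Add per-well FP (mP) and a status column; never drop wells silently.

    Wells with negative intensities are marked ``invalid``, wells with
    zero total intensity ``degenerate``; both carry NaN FP and are
    excluded from fits but stay in the table so the report can account
    for every input well.
    """
    plate = validate_plate(plate)
    f_para = plate["f_para"].to_numpy(dtype=float)
    f_perp = plate["f_perp"].to_numpy(dtype=float)
    status = np.full(len(plate), "ok", dtype=object)
    status[(f_para < 0) | (f_perp < 0)] = "invalid"
    status[(f_para + f_perp) <= 0] = "degenerate"
    fp = np.where(
        status == "ok", models.polarization(f_para, f_perp), np.nan
    )
    plate["fp_mp"] = fp
    plate["well_status"] = status
    return plate


def _require_fp(plate: pd.DataFrame) -> pd.DataFrame:
    if "fp_mp" not in plate.columns:
        plate = compute_plate_fp(plate)
    return plate


def _ok(plate: pd.DataFrame) -> pd.DataFrame:
    return plate[plate["well_status"] == "ok"]


# ---------------------------------------------------------------------------
# stage 1: direct binding
# ---------------------------------------------------------------------------


@dataclass
class DirectFitResult:
    params: dict[str, models.DirectBindingParams]
    stderr: dict[str, dict[str, float | None]]
    shared: dict[str, float]
    flags: dict[str, list[str]]
    rejected: dict[str, str]
    fit: FitResult
    x_max: float


def _direct_model(x, b_max, k_d, ns_slope, background):
    return models.direct_binding_fp(
        x, models.DirectBindingParams(b_max, k_d, ns_slope, background)
    )


def _blocked_model(x, ns_slope, background):
    return background + ns_slope * np.asarray(x, dtype=float)


def fit_direct(
    plate: pd.DataFrame,
    constructs: list[str] | None = None,
    share: tuple[str, ...] = ("b_max", "background"),
    include_blocked: bool = True,
    options: FitOptions | None = None,
) -> DirectFitResult:
    """Global direct-binding fit with b_max/background shared by default.

    Each construct contributes one titration dataset (wells without
    competitor); 30 uM-blocker control wells, which report background
    plus the nonspecific component only, are co-fit against
    ``background + ns_slope * x`` sharing those parameters with the
    titration of the same construct.  Constructs whose titration has
    fewer points than free parameters are rejected by name.

    Constructs whose specific amplitude at the top of the titration is
    smaller than twice its standard error are flagged
    ``no specific binding`` and should be excluded from stage 2.
    """
    plate = _ok(_require_fp(plate))
    direct = plate[(plate["competitor"].fillna("") == "") & (~plate["blocked"])]
    blocked = plate[plate["blocked"]]
    if constructs is None:
        constructs = sorted(direct["construct"].unique())
    if not constructs:
        raise PipelineError("no data: no direct-binding titrations found")

    y_all = direct["fp_mp"].to_numpy(dtype=float)
    bg0 = float(np.min(y_all))
    amp0 = max(float(np.max(y_all) - np.min(y_all)), 1.0)
    x_max = float(direct["conc_nm"].max())

    datasets: list[Dataset] = []
    spec_sets: list[list[ParameterSpec]] = []
    model_list = []
    kept: list[str] = []
    rejected: dict[str, str] = {}
    for c in constructs:
        sub = direct[direct["construct"] == c]
        # shared b_max/background plus per-construct k_d and ns_slope
        if len(sub) < 5:
            rejected[c] = f"only {len(sub)} usable wells (< 5 required)"
            continue
        x = sub["conc_nm"].to_numpy(dtype=float)
        datasets.append(
            Dataset(c, x, sub["fp_mp"].to_numpy(dtype=float),
                    sub["replicate"].to_numpy(dtype=int))
        )
        kd0 = float(np.median(x[x > 0])) if np.any(x > 0) else 100.0
        spec_sets.append(
            [
                ParameterSpec("b_max", amp0, 0.0, np.inf,
                              share_group="b_max" if "b_max" in share else ""),
                ParameterSpec("background", bg0, -np.inf, np.inf,
                              share_group="background" if "background" in share else ""),
                ParameterSpec("k_d", kd0, 1e-3, 1e7,
                              share_group=f"k_d__{c}", log_scale=True,
                              multistart=True),
                ParameterSpec("ns_slope", 1e-3, 0.0, np.inf,
                              share_group=f"ns_slope__{c}"),
            ]
        )
        model_list.append(_direct_model)
        kept.append(c)
    if not kept:
        raise PipelineError("no data: all constructs rejected in stage 1")

    if include_blocked and not blocked.empty:
        for c in sorted(blocked["construct"].unique()):
            if c not in kept:
                continue
            sub = blocked[blocked["construct"] == c]
            datasets.append(
                Dataset(f"{c}__blocked", sub["conc_nm"].to_numpy(dtype=float),
                        sub["fp_mp"].to_numpy(dtype=float),
                        sub["replicate"].to_numpy(dtype=int))
            )
            spec_sets.append(
                [
                    ParameterSpec("background", bg0, -np.inf, np.inf,
                                  share_group="background" if "background" in share else f"bg__{c}"),
                    ParameterSpec("ns_slope", 1e-3, 0.0, np.inf,
                                  share_group=f"ns_slope__{c}"),
                ]
            )
            model_list.append(_blocked_model)

    result = fit(model_list, datasets, spec_sets, options)

    params: dict[str, models.DirectBindingParams] = {}
    stderr: dict[str, dict[str, float | None]] = {}
    flags: dict[str, list[str]] = {}
    for i, c in enumerate(kept):
        vals = result.params[i]
        errs = result.stderr[i]
        params[c] = models.DirectBindingParams(
            b_max=vals["b_max"], k_d=vals["k_d"],
            ns_slope=vals["ns_slope"], background=vals["background"],
        )
        stderr[c] = dict(errs)
        cflags: list[str] = []
        # specific amplitude actually reached at the top of the titration
        amp = vals["b_max"] * x_max / (x_max + vals["k_d"])
        se_b = errs["b_max"] or 0.0
        se_k = errs["k_d"] or 0.0
        d_db = x_max / (x_max + vals["k_d"])
        d_dk = -vals["b_max"] * x_max / (x_max + vals["k_d"]) ** 2
        se_amp = float(np.hypot(d_db * se_b, d_dk * se_k))
        if se_amp > 0 and amp < 2.0 * se_amp:
            cflags.append("no specific binding")
        if result.internal_names[i]["k_d"] in result.on_bounds:
            cflags.append("k_d at bound")
        flags[c] = cflags
    shared = {}
    if "b_max" in share:
        shared["b_max"] = result.params[0]["b_max"]
    if "background" in share:
        shared["background"] = result.params[0]["background"]
    return DirectFitResult(params, stderr, shared, flags, rejected, result, x_max)


# ---------------------------------------------------------------------------
# stage 2a: empirical Hill IC50
# ---------------------------------------------------------------------------


@dataclass
class HillFitResult:
    params: dict[str, models.HillParams]
    ic50: dict[str, float]
    ic50_se: dict[str, float | None]
    shared: dict[str, float]
    flags: dict[str, list[str]]
    fit: FitResult


def _hill_model(x, top, bottom, ic50, hill_n):
    return models.hill_fp(
        x, models.HillParams(bottom=bottom, top=top,
                             log_ic50=np.log10(ic50), hill_n=hill_n)
    )


def fit_displacement_hill(
    plate: pd.DataFrame,
    construct: str,
    competitors: list[str] | None = None,
    share: tuple[str, ...] = ("top", "bottom"),
    options: FitOptions | None = None,
) -> HillFitResult:
    """Four-parameter Hill fit of displacement series, one IC50 per competitor.

    Top and bottom plateaus are shared across competitors of the same
    construct by default.  Zero-competitor wells are excluded (the
    curve lives on a log10 axis); competitor series that do not
    decrease are flagged ``unexpected direction``; series that leave
    the IC50 unconstrained (flat controls such as an inactive truncated
    peptide) are flagged rather than reported as estimates.
    """
    plate = _ok(_require_fp(plate))
    disp = plate[
        (plate["construct"] == construct)
        & (plate["competitor"].fillna("") != "")
        & (~plate["blocked"])
    ]
    if competitors is None:
        competitors = sorted(disp["competitor"].unique())
    if not competitors:
        raise PipelineError(f"no displacement series for construct {construct!r}")

    datasets, spec_sets = [], []
    flags: dict[str, list[str]] = {c: [] for c in competitors}
    for comp in competitors:
        sub = disp[(disp["competitor"] == comp) & (disp["competitor_conc_nm"] > 0)]
        if len(sub) < 5:
            raise PipelineError(
                f"competitor {comp!r}: only {len(sub)} positive-dose wells"
            )
        x = sub["competitor_conc_nm"].to_numpy(dtype=float)
        y = sub["fp_mp"].to_numpy(dtype=float)
        datasets.append(Dataset(comp, x, y, sub["replicate"].to_numpy(dtype=int)))
        order = np.argsort(x)
        lo = y[order][: max(3, len(y) // 4)].mean()
        hi = y[order][-max(3, len(y) // 4):].mean()
        if hi > lo:
            flags[comp].append("unexpected direction")
        spec_sets.append(
            [
                ParameterSpec("top", float(np.max(y)), -np.inf, np.inf,
                              share_group="top" if "top" in share else ""),
                ParameterSpec("bottom", float(np.min(y)), -np.inf, np.inf,
                              share_group="bottom" if "bottom" in share else ""),
                ParameterSpec("ic50", float(np.median(x)), 1e-4, 1e8,
                              share_group=f"ic50__{comp}", log_scale=True,
                              multistart=True),
                ParameterSpec("hill_n", -1.0, -10.0, 10.0,
                              share_group=f"hill_n__{comp}"),
            ]
        )
    result = fit(_hill_model, datasets, spec_sets, options)

    params, ic50, ic50_se = {}, {}, {}
    for i, comp in enumerate(competitors):
        vals, errs = result.params[i], result.stderr[i]
        params[comp] = models.HillParams(
            bottom=vals["bottom"], top=vals["top"],
            log_ic50=float(np.log10(vals["ic50"])), hill_n=vals["hill_n"],
        )
        ic50[comp] = vals["ic50"]
        ic50_se[comp] = errs["ic50"]
        se = errs["ic50"]
        if se is None or not np.isfinite(se) or se > vals["ic50"]:
            flags[comp].append("IC50 unconstrained")
        if result.internal_names[i]["ic50"] in result.on_bounds:
            flags[comp].append("IC50 at bound")
    shared = {}
    if "top" in share:
        shared["top"] = result.params[0]["top"]
    if "bottom" in share:
        shared["bottom"] = result.params[0]["bottom"]
    return HillFitResult(params, ic50, ic50_se, shared, flags, result)


# ---------------------------------------------------------------------------
# stage 2b: mechanistic competition K_D
# ---------------------------------------------------------------------------


@dataclass
class CompetitionFitResult:
    k_d_x: float
    k_d_x_se: float | None       # combined with stage-1 K_D(dis) uncertainty
    k_d_x_se_fit: float | None   # from the competition fit alone
    l_dis: float
    k_d_dis: float
    implied_ic50: float
    flags: list[str]
    fit: FitResult


def fit_displacement_competition(
    plate: pd.DataFrame,
    construct: str,
    competitor: str,
    l_dis: float,
    direct: models.DirectBindingParams | None,
    k_d_dis_se: float = 0.0,
    options: FitOptions | None = None,
) -> CompetitionFitResult:
    """Fit the competition binding model for one competitor series.

    FP readings are first converted to fractional tracer saturation
    using the stage-1 parameters (linear inversion of the signal
    model), then Y = L/(L + K_D(dis)*(1 + x/K_D(x))) is fitted with
    ``l_dis`` and ``k_d_dis`` fixed and K_D(x) free.  Because the
    stage-1 K_D(dis) enters as a constant, its uncertainty is
    propagated into the reported SE via the closed-form sensitivity
    dK_D(x)/dK_D(dis) at fixed IC50.
    """
    if direct is None:
        raise PipelineError(
            "pipeline order violation: stage-1 direct-binding parameters required"
        )
    plate = _ok(_require_fp(plate))
    sub = plate[
        (plate["construct"] == construct)
        & (plate["competitor"] == competitor)
        & (~plate["blocked"])
    ]
    if len(sub) < 3:
        raise PipelineError(
            f"competitor {competitor!r}: insufficient displacement wells"
        )
    x = sub["competitor_conc_nm"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y = models.fractional_saturation_from_fp(
            sub["fp_mp"].to_numpy(dtype=float), direct, l_dis
        )
    k_d_dis = direct.k_d

    def model(x, k_d_x):
        return models.competition_saturation(
            x, models.CompetitionParams(l_dis=l_dis, k_d_dis=k_d_dis, k_d_x=k_d_x)
        )

    specs = [
        ParameterSpec("k_d_x", float(np.median(x[x > 0])), 1e-4, 1e8,
                      log_scale=True, multistart=True)
    ]
    result = fit(model, [Dataset(competitor, x, y,
                                 sub["replicate"].to_numpy(dtype=int))], specs,
                 options)
    k_d_x = result.params[0]["k_d_x"]
    se_fit = result.stderr[0]["k_d_x"]
    flags = []
    if result.internal_names[0]["k_d_x"] in result.on_bounds:
        flags.append("K_D at bound")
    # propagate stage-1 uncertainty: at fixed IC50, K_D(x) = IC50*Kdis/(Kdis+L)
    se_combined = se_fit
    if se_fit is not None and k_d_dis_se:
        dkx_dkdis = k_d_x * l_dis / (k_d_dis * (k_d_dis + l_dis))
        se_combined = float(np.hypot(se_fit, dkx_dkdis * k_d_dis_se))
    cp = models.CompetitionParams(l_dis=l_dis, k_d_dis=k_d_dis, k_d_x=k_d_x)
    return CompetitionFitResult(
        k_d_x=k_d_x,
        k_d_x_se=se_combined,
        k_d_x_se_fit=se_fit,
        l_dis=l_dis,
        k_d_dis=k_d_dis,
        implied_ic50=models.implied_ic50(cp),
        flags=flags,
        fit=result,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Options steering the full two-stage analysis of one plate table."""

    l_dis_nm: float = 400.0
    l_dis_overrides: dict[str, float] = field(default_factory=dict)
    share_direct: tuple[str, ...] = ("b_max", "background")
    share_hill: tuple[str, ...] = ("top", "bottom")
    include_blocked: bool = True
    fit_options: FitOptions = field(default_factory=FitOptions)
    seed: int = 0

    def l_dis_for(self, construct: str) -> float:
        return float(self.l_dis_overrides.get(construct, self.l_dis_nm))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["share_direct"] = list(self.share_direct)
        d["share_hill"] = list(self.share_hill)
        return d


@dataclass
class PipelineReport:
    """Table-2-shaped summary plus full per-fit detail and provenance."""

    rows: list[dict]
    shared: dict[str, float]
    well_accounting: dict[str, int]
    errors: dict[str, str]
    provenance: dict

    def competitors(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            for comp in row.get("competitors", {}):
                if comp not in seen:
                    seen.append(comp)
        return seen

    def to_table(self) -> pd.DataFrame:
        comps = self.competitors()
        records = []
        for row in self.rows:
            rec = {"construct": row["construct"]}
            kd, se = row.get("k_d_tracer"), row.get("k_d_tracer_se")
            rec["K_D TMR-hepcidin (nM)"] = _fmt_pm(kd, se, row.get("flags", []))
            for comp in comps:
                entry = row.get("competitors", {}).get(comp)
                if entry is None or entry.get("k_d_x") is None:
                    rec[f"K_D {comp} (nM)"] = "n.d."
                else:
                    rec[f"K_D {comp} (nM)"] = _fmt_pm(
                        entry["k_d_x"], entry.get("k_d_x_se"), entry.get("flags", [])
                    )
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_json_dict(self) -> dict:
        return {
            "rows": self.rows,
            "shared": self.shared,
            "well_accounting": self.well_accounting,
            "errors": self.errors,
            "provenance": self.provenance,
        }


def _fmt_pm(value, se, flags) -> str:
    if value is None or flags:
        return "n.d."
    if se is None or not np.isfinite(se):
        return f"{value:.0f}"
    return f"{value:.0f}±{se:.0f}"


def run_pipeline(plate: pd.DataFrame, config: PipelineConfig | None = None) -> PipelineReport:
    """Run FP computation, stage-1 and stage-2 fits over a whole plate.

    Failures are recorded per construct and the pipeline continues for
    the remaining ones.  Deterministic for identical inputs and config.
    """
    from . import __version__

    config = config or PipelineConfig()
    plate = compute_plate_fp(plate)
    accounting = {
        "total": int(len(plate)),
        "ok": int((plate["well_status"] == "ok").sum()),
        "invalid": int((plate["well_status"] == "invalid").sum()),
        "degenerate": int((plate["well_status"] == "degenerate").sum()),
    }
    errors: dict[str, str] = {}
    try:
        stage1 = fit_direct(
            plate,
            share=config.share_direct,
            include_blocked=config.include_blocked,
            options=config.fit_options,
        )
    except (FitError, PipelineError) as e:
        raise PipelineError(f"stage 1 failed: {e}") from e

    rows: list[dict] = []
    ok_plate = _ok(plate)
    for construct in sorted(
        set(stage1.params) | set(stage1.rejected)
    ):
        row: dict = {"construct": construct, "competitors": {}}
        if construct in stage1.rejected:
            row["flags"] = ["rejected: " + stage1.rejected[construct]]
            row["k_d_tracer"] = None
            rows.append(row)
            continue
        direct = stage1.params[construct]
        row["k_d_tracer"] = direct.k_d
        row["k_d_tracer_se"] = stage1.stderr[construct]["k_d"]
        row["flags"] = list(stage1.flags[construct])
        if "no specific binding" in row["flags"]:
            rows.append(row)
            continue
        comps = sorted(
            ok_plate[
                (ok_plate["construct"] == construct)
                & (ok_plate["competitor"].fillna("") != "")
                & (~ok_plate["blocked"])
            ]["competitor"].unique()
        )
        if not comps:
            rows.append(row)
            continue
        l_dis = config.l_dis_for(construct)
        try:
            hill = fit_displacement_hill(
                plate, construct, comps, share=config.share_hill,
                options=config.fit_options,
            )
        except (FitError, PipelineError) as e:
            errors[f"{construct}/hill"] = str(e)
            hill = None
        for comp in comps:
            entry: dict = {}
            if hill is not None:
                entry.update(
                    ic50=hill.ic50[comp],
                    ic50_se=hill.ic50_se[comp],
                    hill_n=hill.params[comp].hill_n,
                    flags=list(hill.flags[comp]),
                )
            else:
                entry["flags"] = ["hill fit failed"]
            if not any("unconstrained" in f or "direction" in f
                       for f in entry["flags"]):
                try:
                    compfit = fit_displacement_competition(
                        plate, construct, comp, l_dis, direct,
                        k_d_dis_se=stage1.stderr[construct]["k_d"] or 0.0,
                        options=config.fit_options,
                    )
                    entry.update(
                        k_d_x=compfit.k_d_x,
                        k_d_x_se=compfit.k_d_x_se,
                        implied_ic50=compfit.implied_ic50,
                    )
                    entry["flags"].extend(compfit.flags)
                except (FitError, PipelineError) as e:
                    errors[f"{construct}/{comp}"] = str(e)
                    entry["k_d_x"] = None
            else:
                entry["k_d_x"] = None
            row["competitors"][comp] = entry
        rows.append(row)

    return PipelineReport(
        rows=rows,
        shared=stage1.shared,
        well_accounting=accounting,
        errors=errors,
        provenance={
            "package": "fpnbind",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        },
    )
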