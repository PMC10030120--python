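"""Readers, writers and run configuration.

All tabular inputs are comma-separated UTF-8 with '.' decimals; reports
are written as tab-separated tables (spreadsheet-safe) plus a JSON
document carrying the full per-fit detail and provenance.  Readers
validate row by row and collect errors with line numbers instead of
failing on the first bad cell; a missing required column or an empty
file is fatal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import MeltSeries, SPRSensorgram, TransportTrace
from .pipeline import PLATE_COLUMNS, PipelineError, PipelineReport

__all__ = [
    "RunConfig",
    "load_config",
    "read_plate",
    "write_plate",
    "read_melt",
    "write_melt",
    "read_trace",
    "write_trace",
    "read_spr",
    "write_spr",
    "write_report",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "inputs",
    "assay",
    "l_dis_nm",
    "l_dis_overrides",
    "share_direct",
    "share_hill",
    "include_blocked",
    "n_starts",
    "bootstrap_n",
    "seed",
    "out_dir",
    "verbosity",
}


@dataclass
class RunConfig:
    """Validated run options; unknown keys in config files are rejected."""

    inputs: list[str] = field(default_factory=list)
    assay: str = "fp"
    l_dis_nm: float = 400.0
    l_dis_overrides: dict[str, float] = field(default_factory=dict)
    share_direct: tuple[str, ...] = ("b_max", "background")
    share_hill: tuple[str, ...] = ("top", "bottom")
    include_blocked: bool = True
    n_starts: int = 7
    bootstrap_n: int = 0
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 0

    def to_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "assay": self.assay,
            "l_dis_nm": self.l_dis_nm,
            "l_dis_overrides": dict(self.l_dis_overrides),
            "share_direct": list(self.share_direct),
            "share_hill": list(self.share_hill),
            "include_blocked": self.include_blocked,
            "n_starts": self.n_starts,
            "bootstrap_n": self.bootstrap_n,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "verbosity": self.verbosity,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or TOML run configuration, rejecting unknown keys."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    for k, v in data.items():
        if k in ("share_direct", "share_hill"):
            v = tuple(v)
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise PipelineError(f"no data: {path} is empty")
    df = pd.read_csv(path)
    if df.empty:
        raise PipelineError(f"no data: {path} has a header but no rows")
    return df


def read_plate(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read an FP plate table; returns (table, row-level error messages).

    Rows with non-numeric cells or negative concentrations are dropped
    from the returned table and reported with 1-based data line numbers.
    """
    df = _read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError(f"plate file missing required columns: {missing}")
    errors: list[str] = []
    numeric = ["conc_nm", "competitor_conc_nm", "f_para", "f_perp", "replicate"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_numeric = df[numeric].isna().any(axis=1)
    for i in df.index[bad_numeric]:
        errors.append(f"line {i + 1}: non-numeric value; row flagged")
    neg = (~bad_numeric) & (
        (df["conc_nm"] < 0) | (df["competitor_conc_nm"] < 0)
    )
    for i in df.index[neg]:
        errors.append(f"line {i + 1}: negative concentration; row rejected")
    keep = df[~(bad_numeric | neg)].copy()
    if keep.empty:
        raise PipelineError("no data: all rows rejected")
    keep["competitor"] = keep["competitor"].fillna("")
    if "blocked" in keep.columns:
        keep["blocked"] = keep["blocked"].astype(bool)
    return keep, errors


def write_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# melt series
# ---------------------------------------------------------------------------


def read_melt(path: str | Path, condition: str = "apo") -> MeltSeries:
    """Read (temperature_c, peak_height) and normalize to the lowest
    temperature (100% stability)."""
    df = _read_csv(path)
    for col in ("temperature_c", "peak_height"):
        if col not in df.columns:
            raise PipelineError(f"melt file missing required column: {col}")
    t = pd.to_numeric(df["temperature_c"], errors="coerce")
    h = pd.to_numeric(df["peak_height"], errors="coerce")
    ok = ~(t.isna() | h.isna())
    t, h = t[ok].to_numpy(), h[ok].to_numpy()
    if t.size == 0:
        raise PipelineError("no data: melt file has no numeric rows")
    ref = h[np.argmin(t)]
    if ref <= 0:
        raise PipelineError("melt reference peak height must be positive")
    return MeltSeries(t, 100.0 * h / ref, condition=condition)


def write_melt(series: MeltSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"temperature_c": series.temperature_c,
         "peak_height": series.stability_pct / 100.0}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transport traces
# ---------------------------------------------------------------------------


def read_trace(path: str | Path, events_path: str | Path) -> TransportTrace:
    """Read a (time_s, fluorescence_au) trace plus a JSON event schedule.

    The event file carries ``valinomycin_s``, ``cocl2_s``, optional
    ``calcimycin_s`` and the CoCl2 concentration ``co_conc_um``.
    """
    df = _read_csv(path)
    for col in ("time_s", "fluorescence_au"):
        if col not in df.columns:
            raise PipelineError(f"trace file missing required column: {col}")
    events = json.loads(Path(events_path).read_text())
    for key in ("valinomycin_s", "cocl2_s", "co_conc_um"):
        if key not in events:
            raise PipelineError(f"event file missing required key: {key}")
    return TransportTrace(
        time_s=df["time_s"].to_numpy(dtype=float),
        fluorescence_au=df["fluorescence_au"].to_numpy(dtype=float),
        t_valinomycin=float(events["valinomycin_s"]),
        t_cocl2=float(events["cocl2_s"]),
        t_calcimycin=(
            float(events["calcimycin_s"]) if events.get("calcimycin_s") is not None
            else None
        ),
        co_conc_um=float(events["co_conc_um"]),
    )


def write_trace(trace: TransportTrace, path: str | Path, events_path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "fluorescence_au": trace.fluorescence_au}
    ).to_csv(path, index=False)
    Path(events_path).write_text(
        json.dumps(
            {
                "valinomycin_s": trace.t_valinomycin,
                "cocl2_s": trace.t_cocl2,
                "calcimycin_s": trace.t_calcimycin,
                "co_conc_um": trace.co_conc_um,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# SPR sensorgrams
# ---------------------------------------------------------------------------


def read_spr(path: str | Path) -> list[SPRSensorgram]:
    """Read a long-format sensorgram table (time_s, response_ru, conc_nm,
    phase) into one sensorgram per analyte concentration."""
    df = _read_csv(path)
    for col in ("time_s", "response_ru", "conc_nm", "phase"):
        if col not in df.columns:
            raise PipelineError(f"SPR file missing required column: {col}")
    out = []
    for conc, sub in df.groupby("conc_nm"):
        sub = sub.sort_values("time_s")
        diss = sub[sub["phase"] == "dissociation"]
        if diss.empty:
            t_end = float(sub["time_s"].max()) + 1.0
        else:
            t_end = float(diss["time_s"].min())
        out.append(
            SPRSensorgram(
                time_s=sub["time_s"].to_numpy(dtype=float),
                response_ru=sub["response_ru"].to_numpy(dtype=float),
                conc_nm=float(conc),
                t_assoc_end=t_end,
            )
        )
    if len(out) < 2:
        raise PipelineError("SPR ladder needs >= 2 analyte concentrations")
    return out


def write_spr(sensorgrams: list[SPRSensorgram], path: str | Path) -> None:
    frames = []
    for sg in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.time_s,
                    "response_ru": sg.response_ru,
                    "conc_nm": sg.conc_nm,
                    "phase": np.where(
                        sg.time_s < sg.t_assoc_end, "association", "dissociation"
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(
    report: PipelineReport,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("tsv", "json"),
) -> list[Path]:
    """Write the pipeline report as report.tsv and/or report.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "tsv" in formats:
        p = out_dir / "report.tsv"
        report.to_table().to_csv(p, sep="\t", index=False)
        written.append(p)
    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report.to_json_dict(), indent=2, default=_json_default))
        written.append(p)
    return written


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
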