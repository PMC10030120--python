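"""Generic nonlinear least-squares machinery shared by all fitting stages.

Wraps :mod:`lmfit` with the conventions every assay fit in this package
uses: unweighted residuals, parameter sharing across datasets (the
"constrained to the same value" scheme of global dose-response fits),
log10-transformed positive parameters, log-spaced multi-start for
concentration-scale parameters, and asymptotic standard errors with
delta-method back-transformation to the linear scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import lmfit
import numpy as np

__all__ = [
    "Dataset",
    "ParameterSpec",
    "FitOptions",
    "FitResult",
    "FitError",
    "fit",
    "bootstrap_se",
]

LN10 = np.log(10.0)


class FitError(RuntimeError):
    """Raised when a fit cannot be set up or fails to converge."""


@dataclass
class Dataset:
    """One labelled series of observations entering a (global) fit."""

    label: str
    x: np.ndarray
    y: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError(f"dataset {self.label!r}: x/y length mismatch")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError(f"dataset {self.label!r}: non-finite values")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(self.x.shape, dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id, dtype=int)


@dataclass(frozen=True)
class ParameterSpec:
    """Declaration of one model parameter for a (multi-dataset) fit.

    share_group  nonempty string ties the parameter to one common value
                 across all datasets carrying the same group id; empty
                 means one independent copy per dataset.
    log_scale    fit log10 of the parameter internally (enforces
                 positivity); estimates and SEs are reported on the
                 linear scale via the delta method.
    multistart   include this parameter in the log-spaced multi-start
                 grid spanning the abscissa range.
    """

    name: str
    value: float
    min: float = -np.inf
    max: float = np.inf
    share_group: str = ""
    fixed: bool = False
    log_scale: bool = False
    multistart: bool = False

    def __post_init__(self) -> None:
        if not (self.min <= self.value <= self.max):
            raise ValueError(
                f"parameter {self.name!r}: initial value outside bounds"
            )
        if self.log_scale and self.value <= 0:
            raise ValueError(f"parameter {self.name!r}: log scale needs value > 0")


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 7          # log-spaced multi-start grid size
    ftol: float = 1e-10        # relative tolerance on RSS change
    xtol: float = 1e-10
    max_nfev: int = 10000
    scale_covar: bool = True   # asymptotic SEs scaled by reduced chi-square


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one least-squares fit."""

    params: list[dict[str, float]]          # per-dataset, linear scale
    stderr: list[dict[str, float | None]]   # per-dataset, linear scale
    internal_names: list[dict[str, str]]    # per-dataset spec name -> lmfit name
    covar: np.ndarray | None                # internal (possibly log) scale
    covar_names: list[str]
    rss: float
    dof: int
    converged: bool
    nfev: int
    on_bounds: set[str]                     # internal names pinned at a bound
    curves: list[np.ndarray]
    residuals: list[np.ndarray]
    n_points: int

    def value(self, name: str, dataset: int = 0) -> float:
        return self.params[dataset][name]

    def se(self, name: str, dataset: int = 0) -> float | None:
        return self.stderr[dataset][name]


def _sanitize(label: str) -> str:
    return re.sub(r"\W+", "_", str(label))


def _build_parameters(
    datasets: Sequence[Dataset],
    spec_sets: Sequence[Sequence[ParameterSpec]],
) -> tuple[lmfit.Parameters, list[dict[str, str]], list[dict[str, ParameterSpec]]]:
    params = lmfit.Parameters()
    name_maps: list[dict[str, str]] = []
    spec_maps: list[dict[str, ParameterSpec]] = []
    for i, (ds, specs) in enumerate(zip(datasets, spec_sets)):
        name_map: dict[str, str] = {}
        spec_map: dict[str, ParameterSpec] = {}
        for spec in specs:
            internal = (
                _sanitize(spec.share_group)
                if spec.share_group
                else f"{spec.name}_d{i}_{_sanitize(ds.label)}"
            )
            name_map[spec.name] = internal
            spec_map[spec.name] = spec
            if internal in params:
                continue
            if spec.log_scale:
                lo = np.log10(spec.min) if spec.min > 0 else -12.0
                hi = np.log10(spec.max) if np.isfinite(spec.max) else 12.0
                params.add(
                    internal,
                    value=np.log10(spec.value),
                    min=lo,
                    max=hi,
                    vary=not spec.fixed,
                )
            else:
                params.add(
                    internal,
                    value=spec.value,
                    min=spec.min,
                    max=spec.max,
                    vary=not spec.fixed,
                )
        name_maps.append(name_map)
        spec_maps.append(spec_map)
    return params, name_maps, spec_maps


def _resolve(
    pars: lmfit.Parameters,
    name_map: dict[str, str],
    spec_map: dict[str, ParameterSpec],
) -> dict[str, float]:
    out = {}
    for name, internal in name_map.items():
        v = pars[internal].value
        out[name] = 10.0 ** v if spec_map[name].log_scale else v
    return out


def fit(
    model: Callable | Sequence[Callable],
    datasets: Sequence[Dataset],
    specs: Sequence[ParameterSpec] | Sequence[Sequence[ParameterSpec]],
    options: FitOptions | None = None,
) -> FitResult:
    """Global unweighted least squares over one or more datasets.

    ``model`` is one callable ``model(x, **params) -> y`` applied to all
    datasets, or one callable per dataset (needed e.g. when control
    wells obey a restricted model).  ``specs`` likewise is either one
    spec list applied to every dataset or a per-dataset list of lists.
    Parameters carrying the same ``share_group`` collapse to a single
    fitted value across datasets.

    Multi-start: every spec flagged ``multistart`` is restarted on a
    log-spaced grid spanning the positive abscissa range; the fit with
    the lowest residual sum of squares wins, ties broken by fewest
    function evaluations.
    """
    options = options or FitOptions()
    if not datasets:
        raise FitError("fit failed: no datasets")
    models = list(model) if isinstance(model, (list, tuple)) else [model] * len(datasets)
    if len(models) != len(datasets):
        raise FitError("fit failed: one model per dataset required")
    if specs and isinstance(specs[0], (list, tuple)):
        spec_sets = [list(s) for s in specs]
    else:
        spec_sets = [list(specs)] * len(datasets)
    if len(spec_sets) != len(datasets):
        raise FitError("fit failed: one spec set per dataset required")

    params0, name_maps, spec_maps = _build_parameters(datasets, spec_sets)
    n_points = int(sum(ds.x.size for ds in datasets))
    n_free = sum(1 for p in params0.values() if p.vary)
    dof = n_points - n_free
    if dof < 1:
        raise FitError("underdetermined: fewer points than free parameters + 1")

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        chunks = []
        for m, ds, nm, sm in zip(models, datasets, name_maps, spec_maps):
            chunks.append(m(ds.x, **_resolve(pars, nm, sm)) - ds.y)
        return np.concatenate(chunks)

    # multi-start grid over the pooled positive abscissa range
    ms_internals = sorted(
        {
            nm[s.name]
            for nm, sm in zip(name_maps, spec_maps)
            for s in sm.values()
            if s.multistart and not s.fixed
        }
    )
    starts: list[dict[str, float]] = [{}]
    if ms_internals and options.n_starts > 1:
        xs = np.concatenate([ds.x for ds in datasets])
        xs = xs[xs > 0]
        if xs.size >= 2 and xs.min() < xs.max():
            grid = np.geomspace(xs.min(), xs.max(), options.n_starts)
            starts = [{} ] + [
                {name: v for name in ms_internals} for v in grid
            ]

    best = None
    for start in starts:
        pars = params0.copy()
        ok = True
        for internal, v in start.items():
            p = pars[internal]
            val = np.log10(v) if _is_log_internal(internal, name_maps, spec_maps) else v
            if not (p.min <= val <= p.max):
                ok = False
                break
            p.value = val
        if not ok:
            continue
        try:
            mini = lmfit.Minimizer(
                residual, pars,
                max_nfev=options.max_nfev,
                scale_covar=options.scale_covar,
            )
            res = mini.minimize(
                method="leastsq", ftol=options.ftol, xtol=options.xtol,
            )
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        key = (rss, res.nfev)
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise FitError("fit failed: no start converged")
    res = best[1]

    # assemble per-dataset linear-scale estimates and delta-method SEs
    params_out: list[dict[str, float]] = []
    stderr_out: list[dict[str, float | None]] = []
    curves: list[np.ndarray] = []
    residuals: list[np.ndarray] = []
    on_bounds: set[str] = set()
    for p in res.params.values():
        if p.vary and (
            (np.isfinite(p.min) and abs(p.value - p.min) < 1e-8 * max(1, abs(p.min)))
            or (np.isfinite(p.max) and abs(p.value - p.max) < 1e-8 * max(1, abs(p.max)))
        ):
            on_bounds.add(p.name)
    for m, ds, nm, sm in zip(models, datasets, name_maps, spec_maps):
        vals = _resolve(res.params, nm, sm)
        errs: dict[str, float | None] = {}
        for name, internal in nm.items():
            se = res.params[internal].stderr
            if se is None:
                errs[name] = None
            elif sm[name].log_scale:
                errs[name] = LN10 * vals[name] * se
            else:
                errs[name] = float(se)
        params_out.append(vals)
        stderr_out.append(errs)
        yhat = m(ds.x, **vals)
        curves.append(np.asarray(yhat, dtype=float))
        residuals.append(np.asarray(yhat - ds.y, dtype=float))

    covar = getattr(res, "covar", None)
    covar_names = [p.name for p in res.params.values() if p.vary]
    return FitResult(
        params=params_out,
        stderr=stderr_out,
        internal_names=name_maps,
        covar=covar,
        covar_names=covar_names,
        rss=float(np.sum(res.residual**2)),
        dof=dof,
        converged=bool(res.success),
        nfev=int(res.nfev),
        on_bounds=on_bounds,
        curves=curves,
        residuals=residuals,
        n_points=n_points,
    )


def _is_log_internal(internal, name_maps, spec_maps) -> bool:
    for nm, sm in zip(name_maps, spec_maps):
        for name, i in nm.items():
            if i == internal:
                return sm[name].log_scale
    return False


def bootstrap_se(
    model: Callable | Sequence[Callable],
    datasets: Sequence[Dataset],
    specs: Sequence[ParameterSpec] | Sequence[Sequence[ParameterSpec]],
    n_boot: int = 200,
    seed: int = 0,
    options: FitOptions | None = None,
) -> list[dict[str, float]]:
    """Case-resampling bootstrap standard errors, resampling replicates.

    Within each dataset whole replicate groups are drawn with
    replacement; each resample is refitted and the per-parameter spread
    (sample standard deviation over resamples) returned on the linear
    scale, one dict per dataset.  A cross-check for the asymptotic SEs,
    reproducible under ``seed``.
    """
    if n_boot < 10:
        raise ValueError("insufficient resamples: n_boot must be >= 10")
    rng = np.random.default_rng(seed)
    # single-start refits from the full-data solution keep this cheap
    base = fit(model, datasets, specs, options)
    fast = FitOptions(
        n_starts=1,
        ftol=(options or FitOptions()).ftol,
        xtol=(options or FitOptions()).xtol,
    )
    collected: list[dict[str, list[float]]] = [
        {name: [] for name in ds_params} for ds_params in base.params
    ]
    if specs and isinstance(specs[0], (list, tuple)):
        spec_sets = [list(s) for s in specs]
    else:
        spec_sets = [list(specs)] * len(datasets)
    for _ in range(n_boot):
        boot_ds = []
        for ds in datasets:
            groups = np.unique(ds.replicate_id)
            take = rng.choice(groups, size=groups.size, replace=True)
            idx = np.concatenate([np.flatnonzero(ds.replicate_id == g) for g in take])
            boot_ds.append(
                Dataset(ds.label, ds.x[idx], ds.y[idx], ds.replicate_id[idx])
            )
        try:
            r = fit(model, boot_ds, spec_sets, fast)
        except FitError:
            continue
        for coll, vals in zip(collected, r.params):
            for name, v in vals.items():
                coll[name].append(v)
    out = []
    for coll in collected:
        out.append(
            {
                name: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
                for name, v in coll.items()
            }
        )
    return out
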