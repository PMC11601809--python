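"""Parameter sweeps, baseline normalization, re-quantification and OLS
trend fitting over the generate → simulate → metrics pipeline.

A study is described by a nested config (YAML-compatible dict) with
blocks ``valve`` / ``chordae`` / ``material`` / ``simulation`` /
``metrics``; sweeps address one field by a dotted path such as
``chordae.secondary.density`` and hold everything else (including seeds)
fixed so that only the swept parameter changes the topology.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import chordae_gen, closure_solver, metrics, valve_geometry
from .chordae_gen import CdtClass, ChordParams
from .closure_solver import SimulationConfig
from .mechanics import get_material

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "default_config", "run_pipeline", "run_sweep",
           "normalize_to_baseline", "requantify", "fit_trend", "TrendFit",
           "SweepResult"]

DEFAULT_CONFIG = {
    "valve": {
        "kind": "mv",
        "annulus_dims": [20.0, 15.0, 3.0],
        "leaflet_heights": [15.0, 11.0],
        "mesh_target_elems": 3000,
        "dilate_factor": 1.0,
        "seed": 0,
    },
    "chordae": {
        "edge_band": 1.5,
        "body_band_bounds": [0.2, 0.8],
        "primary": {"density": 2.0, "branch_length": 3.5, "n_branches": 3,
                    "branch_radius": 1.0, "csa": 1.0, "seed": 0},
        "secondary": {"density": 3.0, "branch_length": 3.5, "n_branches": 4,
                      "branch_radius": 1.0, "csa": 1.0, "seed": 0},
    },
    "material": "mv_lee_sacks",
    "simulation": {"pressure_peak": 100.0},
    "metrics": {"grid_spacing": 0.2, "traction_tol": 1e-9},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _get_path(cfg: dict, path: str):
    cur = cfg
    for key in path.split("."):
        try:
            cur = cur[key]
        except (KeyError, TypeError):
            raise KeyError(f"unknown parameter path {path!r} (failed at {key!r})") from None
    return cur


def _set_path(cfg: dict, path: str, value) -> None:
    keys = path.split(".")
    cur = cfg
    for key in keys[:-1]:
        try:
            cur = cur[key]
        except (KeyError, TypeError):
            raise KeyError(f"unknown parameter path {path!r} (failed at {key!r})") from None
    if keys[-1] not in cur:
        raise KeyError(f"unknown parameter path {path!r} (failed at {keys[-1]!r})")
    cur[keys[-1]] = value


def build_valve(config: dict) -> valve_geometry.ValveModel:
    v = config["valve"]
    maker = {"mv": valve_geometry.make_stereotypical_mv,
             "tv": valve_geometry.make_stereotypical_tv}[v.get("kind", "mv")]
    model = maker(
        annulus_dims=tuple(v["annulus_dims"]),
        leaflet_heights=tuple(v["leaflet_heights"]),
        mesh_target_elems=int(v["mesh_target_elems"]),
        seed=int(v.get("seed", 0)),
    )
    factor = float(v.get("dilate_factor", 1.0))
    if factor != 1.0:
        model = valve_geometry.dilate_annulus(model, factor)
    return model


def build_chordae_set(config: dict, model, seed: int = 0) -> chordae_gen.ChordaeSet:
    c = config["chordae"]
    params = []
    for name, cls in (("primary", CdtClass.PRIMARY), ("secondary", CdtClass.SECONDARY)):
        if name in c and c[name]:
            blk = c[name]
            params.append(ChordParams(
                cdt_class=cls,
                density=float(blk["density"]),
                branch_length=float(blk.get("branch_length", 3.5)),
                n_branches=int(blk.get("n_branches", 3)),
                branch_radius=float(blk.get("branch_radius", 1.0)),
                csa=float(blk.get("csa", 1.0)),
                seed=int(blk.get("seed", seed)),
                allow_out_of_range=bool(blk.get("allow_out_of_range", False)),
            ))
    return chordae_gen.build_chordae(
        model, params, edge_band=float(c.get("edge_band", 1.5)),
        body_band_bounds=tuple(c.get("body_band_bounds", (0.2, 0.8))))


def run_pipeline(config: dict, seed: int = 0):
    """generate → simulate → metrics for one configuration.

    Returns (model, chordae, closure, MetricsReport).
    """
    model = build_valve(config)
    mat = get_material(config.get("material", "mv_lee_sacks"))
    ch = build_chordae_set(config, model, seed=seed)
    sim_cfg = SimulationConfig(**{**config.get("simulation", {}), "seed": seed})
    closure = closure_solver.run_closure(model, ch, mat, sim_cfg)
    frame = valve_geometry.annulus_frame(model)
    mcfg = config.get("metrics", {})
    report = metrics.compute_metrics(
        closure, model, frame,
        grid_spacing=float(mcfg.get("grid_spacing", 0.2)),
        traction_tol=float(mcfg.get("traction_tol", 1e-9)),
        parameter_record={"seed": seed},
    )
    return model, ch, closure, report


@dataclass
class SweepResult:
    param_path: str
    table: pd.DataFrame  # one row per swept value; 'baseline' flags the baseline row

    def baseline_row(self) -> pd.Series:
        sel = self.table[self.table["baseline"]]
        if len(sel) != 1:
            raise ValueError(f"expected exactly one baseline row, found {len(sel)}")
        return sel.iloc[0]


METRIC_COLS = ("roa_mm2", "ca_mm2", "billow_mm3")
STRAIN_COLS = ("strain_median", "strain_q25", "strain_q75", "strain_min", "strain_max")


def run_sweep(base_config: dict, param_path: str, values, seed: int = 0) -> SweepResult:
    """One generate→simulate→metrics run per swept value (shared seed).

    The row whose value equals the base config's current value is flagged
    as baseline; if no swept value matches, a baseline run is appended.
    Per-row failures are recorded in an ``error`` column without aborting.
    """
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    baseline_value = _get_path(base_config, param_path)
    run_values = values + ([] if any(np.isclose(v, baseline_value) for v in values)
                           else [baseline_value])
    rows = []
    for v in run_values:
        cfg = copy.deepcopy(base_config)
        _set_path(cfg, param_path, v)
        row = {"param": param_path, "value": v,
               "baseline": bool(np.isclose(v, baseline_value)), "error": ""}
        try:
            model, ch, closure, report = run_pipeline(cfg, seed=seed)
            row.update(chordae_gen.chordae_summary(ch))
            row.update(report.to_row())
            row["primary_csa"] = float(_get_path(cfg, "chordae.primary.csa"))
            row["termination"] = closure.diagnostics["termination"]
        except Exception as exc:  # record and continue
            log.exception("sweep row %s=%s failed", param_path, v)
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return SweepResult(param_path=param_path, table=pd.DataFrame(rows))


def normalize_to_baseline(sweep: SweepResult) -> pd.DataFrame:
    """Divide the functional metrics by their baseline values; strain
    columns stay absolute. Zero-baseline columns stay absolute (warned)."""
    base = sweep.baseline_row()
    out = sweep.table.copy()
    for col in METRIC_COLS:
        b = base[col]
        if b == 0 or not np.isfinite(b):
            log.warning("baseline %s is zero; column left absolute", col)
            out[col + "_norm"] = out[col]
        else:
            out[col + "_norm"] = out[col] / b
    return out


def requantify(sweep: SweepResult | pd.DataFrame, axis: str) -> pd.DataFrame:
    """Re-index sweep rows by 'insertion_points' or 'total_csa', ascending."""
    col = {"insertion_points": "n_insertion_points", "total_csa": "total_csa"}[axis]
    df = sweep.table if isinstance(sweep, SweepResult) else sweep
    out = df.sort_values(col, kind="mergesort").reset_index(drop=True)
    out.insert(0, "axis", out[col])
    return out


@dataclass
class TrendFit:
    form: str
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            return c[0] + c[1] * x
        if self.form == "quadratic":
            return c[0] + c[1] * x + c[2] * x * x
        return np.exp(c[0] + c[1] * x)


def fit_trend(x, y, form: str = "linear") -> TrendFit:
    """OLS fit of a linear/quadratic/exponential trend (statsmodels).

    Exponential is fitted by log-linearization (log y = a + b x), so it
    requires positive y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if form == "linear":
        X = np.column_stack([np.ones_like(x), x])
        target = y
    elif form == "quadratic":
        X = np.column_stack([np.ones_like(x), x, x * x])
        target = y
    elif form == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential form requires positive y")
        X = np.column_stack([np.ones_like(x), x])
        target = np.log(y)
    else:
        raise ValueError(f"unknown trend form {form!r}")
    if len(x) < X.shape[1] + 1:
        raise ValueError(f"{form} fit needs at least {X.shape[1] + 1} points")
    res = sm.OLS(target, X).fit()
    return TrendFit(form=form,
                    coefficients=np.asarray(res.params),
                    std_errors=np.asarray(res.bse),
                    p_values=np.asarray(res.pvalues),
                    r_squared=float(res.rsquared))
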