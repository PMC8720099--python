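"""End-to-end comparison: geodiversity-index models vs environmental-variable
models for every response.

For each response (standardized taxon Shannon diversity or an ecosystem
function) the pipeline (1) picks one predictor per group (climate, habitat,
soil) by univariate-model AIC, (2) rejects predictor combinations whose
pairwise |Pearson r| exceeds 0.6 and moves to the next-best combination,
(3) fits the three-predictor additive model, (4) builds the compound
geodiversity index from the *same three* rasters and fits the univariate
index model, and (5) variance-partitions the environmental model.  The same
selected triple feeds both model families by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .diversity import standardize_table
from .gam import GamFit, fit_gam
from .geodiversity import geodiversity_at_plots
from .models import VPResult, collinearity_screen, variance_partition
from .raster import PlotGeometry, RasterGrid, extract_plot_values, load_plots_csv, read_raster
from .synthetic import LandscapeBundle, ScenarioConfig, generate_landscape

logger = logging.getLogger("geobiodiv")

__all__ = ["StudyConfig", "ComparisonResult", "run_study", "emit_report",
           "DEFAULT_PREDICTOR_GROUPS"]

DEFAULT_PREDICTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "climate": ("temp_mean", "temp_max", "temp_sd", "humidity_sd"),
    "habitat": ("habitat", "tpi"),
    "soil": ("ph", "phosphorus", "organic_layer_depth"),
}


@dataclass
class StudyConfig:
    """What to analyse: either a synthetic scenario or on-disk inputs."""

    scenario: ScenarioConfig | None = None
    raster_paths: dict = field(default_factory=dict)     # name -> GeoTIFF path
    plots_path: str | None = None
    community_paths: dict = field(default_factory=dict)  # taxon -> CSV path
    function_path: str | None = None
    predictor_groups: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_PREDICTOR_GROUPS.items()})
    classes: int = 5
    collinearity_threshold: float = 0.6
    diversity_scale: str = "hill"
    taxon_function_pairs: dict = field(default_factory=lambda: {
        "community": "function"})
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.classes < 1:
            raise ValueError("classes must be >= 1")
        if self.scenario is None and not self.raster_paths:
            raise ValueError("either a scenario or raster paths must be given")

    def fingerprint(self) -> str:
        payload = {
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "raster_paths": {k: str(v) for k, v in self.raster_paths.items()},
            "plots_path": str(self.plots_path) if self.plots_path else None,
            "community_paths": {k: str(v) for k, v in self.community_paths.items()},
            "function_path": str(self.function_path) if self.function_path else None,
            "predictor_groups": self.predictor_groups,
            "classes": self.classes,
            "collinearity_threshold": self.collinearity_threshold,
            "diversity_scale": self.diversity_scale,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "scenario" in data and data["scenario"] is not None:
            data["scenario"] = ScenarioConfig(**{
                k: tuple(v) if k == "elevation_range" else v
                for k, v in data["scenario"].items()})
        return cls(**data)


@dataclass
class ComparisonResult:
    """Both model families for one response, on identical plots."""

    response: str
    selected: dict                 # group -> chosen raster name
    env_fit: GamFit                # three-predictor environmental model
    geodiv_fit: GamFit             # univariate compound-index model
    vp: VPResult
    n_plots: int
    diversity_function_r: float | None = None
    collinearity_note: str | None = None


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------

def _load_bundle(config: StudyConfig):
    """Returns (rasters, plots, communities, functions)."""
    if config.scenario is not None:
        bundle = generate_landscape(config.scenario)
        return bundle.rasters, bundle.plots, bundle.communities, bundle.functions
    rasters = {name: read_raster(p) for name, p in config.raster_paths.items()}
    plots = load_plots_csv(config.plots_path) if config.plots_path else []
    communities = {
        taxon: pd.read_csv(p, index_col="plot_id")
        for taxon, p in config.community_paths.items()
    }
    functions = (pd.read_csv(config.function_path, index_col="plot_id")
                 if config.function_path else pd.DataFrame())
    return rasters, plots, communities, functions


def _extract_predictors(rasters: Mapping[str, RasterGrid],
                        plots: Sequence[PlotGeometry],
                        names: Sequence[str]) -> pd.DataFrame:
    data = {
        name: [extract_plot_values(rasters[name], p) for p in plots]
        for name in names
    }
    return pd.DataFrame(data, index=pd.Index([p.plot_id for p in plots],
                                             name="plot_id"))


def _select_triple(response: np.ndarray, values: pd.DataFrame,
                   groups: Mapping[str, Sequence[str]],
                   threshold: float) -> tuple[dict, str | None]:
    """One predictor per group: rank within-group variants by univariate AIC,
    then walk combinations in total-AIC order until one passes the
    collinearity screen.  Falls back to the best-AIC combination (with a
    note) if every combination is collinear."""
    ranked: dict[str, list[tuple[float, str]]] = {}
    for group, names in groups.items():
        scores = []
        for name in sorted(names):
            try:
                fit = fit_gam(response, {name: values[name].to_numpy()})
                scores.append((fit.aic, name))
            except Exception as exc:  # noqa: BLE001
                logger.warning("variant %s failed: %s", name, exc)
        if not scores:
            raise ValueError(f"no usable predictor in group {group!r}")
        ranked[group] = sorted(scores)

    group_names = list(groups)
    combos = sorted(
        product(*[ranked[g] for g in group_names]),
        key=lambda combo: sum(aic for aic, _ in combo))
    first_choice = None
    for combo in combos:
        chosen = {g: name for g, (aic, name) in zip(group_names, combo)}
        if first_choice is None:
            first_choice = chosen
        cols = {chosen[g]: values[chosen[g]].to_numpy() for g in group_names}
        if not collinearity_screen(cols, threshold=threshold):
            return chosen, None
    note = (f"all predictor combinations exceed |r| > {threshold}; "
            f"using best-AIC combination")
    logger.warning(note)
    return first_choice, note


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig) -> dict[str, ComparisonResult]:
    """Run the full comparison for every response in the study.

    Responses are every taxon's coverage-standardized Shannon diversity and
    every ecosystem-function column.  Failures in one response are logged
    and skipped; the others continue.
    """
    rasters, plots, communities, functions = _load_bundle(config)
    all_names = sorted({n for names in config.predictor_groups.values()
                        for n in names})
    missing = [n for n in all_names if n not in rasters]
    if missing:
        raise ValueError(f"predictor rasters missing from inputs: {missing}")
    values = _extract_predictors(rasters, plots, all_names)
    plot_ids = values.index

    responses: dict[str, pd.Series] = {}
    diversity_by_taxon: dict[str, pd.Series] = {}
    for taxon, table in communities.items():
        table = table.loc[[pid for pid in plot_ids if pid in table.index]]
        std = standardize_table(table, scale=config.diversity_scale)
        responses[f"diversity:{taxon}"] = std["diversity"]
        diversity_by_taxon[taxon] = std["diversity"]
    for col in getattr(functions, "columns", []):
        responses[f"function:{col}"] = functions[col]

    results: dict[str, ComparisonResult] = {}
    classified_cache: dict = {}
    for resp_name, series in responses.items():
        try:
            results[resp_name] = _compare_one(
                resp_name, series, values, rasters, plots, config,
                classified_cache)
        except Exception as exc:  # noqa: BLE001
            logger.error("response %s failed: %s", resp_name, exc)
    # paired taxon/function Pearson r on overlapping plots
    for taxon, func in config.taxon_function_pairs.items():
        key_t, key_f = f"diversity:{taxon}", f"function:{func}"
        if key_t in results and key_f in responses and taxon in diversity_by_taxon:
            div = diversity_by_taxon[taxon]
            fun = responses[key_f]
            common = div.index.intersection(fun.index)
            if len(common) >= 3:
                r = float(np.corrcoef(div.loc[common], fun.loc[common])[0, 1])
                results[key_t].diversity_function_r = r
    return results


def _compare_one(resp_name: str, series: pd.Series, values: pd.DataFrame,
                 rasters: Mapping[str, RasterGrid],
                 plots: Sequence[PlotGeometry],
                 config: StudyConfig,
                 classified_cache: dict | None = None) -> ComparisonResult:
    common = values.index.intersection(series.index)
    if len(common) < 10:
        raise ValueError(f"only {len(common)} plots with both response and predictors")
    vals = values.loc[common]
    y = series.loc[common].to_numpy(dtype=float)

    selected, note = _select_triple(y, vals, config.predictor_groups,
                                    config.collinearity_threshold)
    logger.info("%s: selected %s", resp_name, selected)
    triple = {selected[g]: vals[selected[g]].to_numpy() for g in selected}
    env_fit = fit_gam(y, triple)

    plot_subset = [p for p in plots if p.plot_id in set(common)]
    geo = geodiversity_at_plots(
        {name: rasters[name] for name in selected.values()},
        plot_subset, k=config.classes,
        classified_cache=classified_cache).set_index("plot_id").loc[common]
    geodiv_fit = fit_gam(y, {"compound_G": geo["compound_G"].to_numpy()})

    group_names = list(selected)
    vp = variance_partition(
        y,
        triple[selected[group_names[0]]],
        triple[selected[group_names[1]]],
        triple[selected[group_names[2]]],
        names=tuple(group_names),
    )
    return ComparisonResult(
        response=resp_name, selected=selected, env_fit=env_fit,
        geodiv_fit=geodiv_fit, vp=vp, n_plots=len(common),
        collinearity_note=note)


def _fit_row(resp: str, kind: str, fit: GamFit) -> dict:
    return {
        "response": resp,
        "model": kind,
        "intercept": fit.intercept,
        "edf_total": fit.edf_total,
        "adj_R2": fit.adj_r2,
        "explained_deviance": fit.explained_deviance,
        "aic": fit.aic,
        "gcv": fit.gcv,
        "n": fit.n,
    }


def emit_report(results: Mapping[str, ComparisonResult], out_dir,
                config: StudyConfig | None = None) -> dict[str, Path]:
    """Write the comparison tables (CSV), a JSON bundle and a run log.

    Deterministic given identical results: reruns produce byte-identical
    files.  Returns the paths written.
    """
    if not results:
        raise ValueError("emit_report: no results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model_rows, vp_rows, sel_rows = [], [], []
    for resp, res in sorted(results.items()):
        model_rows.append(_fit_row(resp, "environmental", res.env_fit))
        model_rows.append(_fit_row(resp, "geodiversity", res.geodiv_fit))
        comp = res.vp.components()
        vp_rows.append({"response": resp, **comp,
                        "full_deviance": res.vp.full_deviance})
        sel_rows.append({"response": resp, **res.selected,
                         "n_plots": res.n_plots,
                         "diversity_function_r": res.diversity_function_r,
                         "collinearity_note": res.collinearity_note})

    paths = {}
    fmt = "%.10g"
    for name, rows in (("model_summary", model_rows), ("varpart", vp_rows),
                       ("selected_predictors", sel_rows)):
        p = out / f"{name}.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format=fmt)
        paths[name] = p

    bundle = {
        resp: {
            "selected": res.selected,
            "n_plots": res.n_plots,
            "env": _fit_row(resp, "environmental", res.env_fit),
            "geodiv": _fit_row(resp, "geodiversity", res.geodiv_fit),
            "vp": res.vp.components(),
            "diversity_function_r": res.diversity_function_r,
        }
        for resp, res in sorted(results.items())
    }
    jp = out / "results.json"
    jp.write_text(json.dumps(bundle, indent=2, sort_keys=True, default=float))
    paths["results"] = jp

    log_lines = [f"responses={len(results)}"]
    if config is not None:
        log_lines.insert(0, f"config_fingerprint={config.fingerprint()}")
        log_lines.insert(1, f"seed={config.seed}")
    lp = out / "run.log"
    lp.write_text("\n".join(log_lines) + "\n")
    paths["log"] = lp
    return paths
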