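"""End-to-end pipeline: simulate/load -> indices -> COG -> population
structure -> correlation screen -> GAM, emitting a single CSV+JSON report
bundle with a provenance manifest.

Bundles are deterministic: identical config and seed produce byte-identical
outputs (the manifest records a wall-clock timestamp only on request, so
that determinism is the default contract).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cog, core_data, indices, population_structure, size_gam, stat_screen
from .synthetic_fleet import FleetScenario, default_paper_like_scenario, generate_fleet

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    density_mode: str
    package_version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _run_stage(name: str, fn, *args, **kwargs):
    logger.info("[%s] running", name)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(name, exc) from exc


def _load_inputs(config: dict, seed: int, digests: dict):
    if "hauls" in config:
        hpath, lpath = Path(config["hauls"]), Path(config["lengths"])
        for p, what in ((hpath, "hauls"), (lpath, "lengths")):
            if not p.exists():
                raise FileNotFoundError(f"{what} file not found: {p}")
        digests["hauls"] = _sha256(hpath)
        digests["lengths"] = _sha256(lpath)
        hauls, hissues = core_data.read_hauls(hpath, config.get("dialect"))
        lengths, lissues = core_data.read_lengths(lpath)
        return hauls, lengths, hissues + lissues
    scen = config.get("scenario")
    if isinstance(scen, (str, Path)):
        scenario = FleetScenario.from_yaml(scen)
    elif isinstance(scen, dict):
        scenario = FleetScenario.from_dict(scen)
    else:
        scenario = default_paper_like_scenario()
    scenario.seed = seed
    hauls, lengths, _ = generate_fleet(scenario)
    return hauls, lengths, []


def run_all(config: dict, out_dir: str | Path, include_timestamp: bool = False) -> dict:
    """Run the full analysis and write the report bundle.

    ``config`` keys:

    * ``seed`` (int, default 0)
    * ``hauls`` / ``lengths`` — CSV paths; when absent, a synthetic fleet
      is generated from ``scenario`` (YAML path or dict; default the
      six-season reference scenario)
    * ``density_mode`` — "as_printed" (default) or "unit_consistent"
    * ``cell_deg`` — grid cell size, default 0.1
    * ``gam`` — dict with optional ``k``, ``penalty``, ``method``,
      ``vif_threshold``

    Returns a dict of output table paths.  Any stage error is re-raised
    as :class:`StageError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    density_mode = config.get("density_mode", "as_printed")
    cell_deg = float(config.get("cell_deg", 0.1))
    gam_cfg = config.get("gam", {})
    outputs: dict[str, str] = {}
    digests: dict[str, str] = {}

    hauls, lengths, issues = _run_stage("core_data", _load_inputs, config, seed, digests)

    def inventory_stage():
        rep = core_data.summarize_inventory(hauls, lengths, issues)
        _write_csv(rep.per_year_counts, out_dir / "inventory.csv")
        outputs["inventory"] = str(out_dir / "inventory.csv")

    def indices_stage():
        grid = indices.grid_aggregate(hauls, lengths, cell_deg=cell_deg, mode=density_mode)
        _write_csv(grid, out_dir / "grid.csv")
        annual = indices.annual_index_summary(hauls, mode=density_mode)
        _write_csv(annual, out_dir / "annual_indices.csv")
        outputs["grid"] = str(out_dir / "grid.csv")
        outputs["annual_indices"] = str(out_dir / "annual_indices.csv")

    def cog_stage():
        traj = cog.cog_trajectory(hauls, period="year")
        _write_csv(traj, out_dir / "cog.csv")
        outputs["cog"] = str(out_dir / "cog.csv")

    def popstruct_stage():
        summ = population_structure.annual_summary(lengths, hauls)
        _write_csv(summ, out_dir / "length_summary.csv")
        ages = population_structure.age_composition(lengths, by="year", hauls=hauls)
        _write_csv(ages, out_dir / "ages.csv")
        lf = population_structure.length_frequency(lengths, by="year", hauls=hauls)
        _write_csv(lf, out_dir / "length_frequency.csv")
        anova, tukey = population_structure.anova_tukey(lengths, hauls)
        _write_csv(anova, out_dir / "anova.csv")
        _write_csv(tukey, out_dir / "tukey.csv")
        for name in ("length_summary", "ages", "length_frequency", "anova", "tukey"):
            outputs[name] = str(out_dir / f"{name}.csv")

    def screen_stage():
        hx = indices.haul_indices(hauls, mode=density_mode)
        means = core_data.haul_mean_lengths(hauls, lengths)
        table = stat_screen.screen_table(hx, means)
        corr = stat_screen.correlation_screen(table)
        _write_csv(corr.to_frame(), out_dir / "correlations.csv")
        outputs["correlations"] = str(out_dir / "correlations.csv")

    def gam_stage():
        frame = size_gam.build_model_frame(hauls, lengths, density_mode=density_mode)
        retained, vif_report = size_gam.vif_prescreen(
            frame, threshold=float(gam_cfg.get("vif_threshold", 4.0)))
        _write_csv(vif_report, out_dir / "vif.csv")
        path, fit = size_gam.forward_select(
            frame, retained,
            k=int(gam_cfg.get("k", 10)),
            penalty=gam_cfg.get("penalty", "diff2"),
            method=gam_cfg.get("method", "gcv"),
        )
        _write_csv(path, out_dir / "gam_path.csv")
        outputs["vif"] = str(out_dir / "vif.csv")
        outputs["gam_path"] = str(out_dir / "gam_path.csv")
        if fit is not None:
            _write_csv(fit.term_table, out_dir / "gam_terms.csv")
            outputs["gam_terms"] = str(out_dir / "gam_terms.csv")
            partial_dir = out_dir / "partials"
            partial_dir.mkdir(exist_ok=True)
            for t in fit.terms:
                _write_csv(size_gam.partial_effects(fit, t), partial_dir / f"{t}.csv")
                outputs[f"partial_{t}"] = str(partial_dir / f"{t}.csv")
            diag = size_gam.residual_diagnostics(fit)
            _write_csv(diag["residuals_vs_fitted"], out_dir / "gam_residuals.csv")
            outputs["gam_residuals"] = str(out_dir / "gam_residuals.csv")
            with open(out_dir / "gam_diagnostics.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "bp_stat": diag["bp_stat"],
                        "bp_p": diag["bp_p"],
                        "residual_mean": diag["residual_mean"],
                        "aic": fit.aic,
                        "deviance_explained": fit.deviance_explained,
                        "r2_adj": fit.r2_adj,
                        "edf_by_term": diag["edf_by_term"],
                    },
                    fh, indent=2, sort_keys=True,
                )
            outputs["gam_diagnostics"] = str(out_dir / "gam_diagnostics.json")

    _run_stage("core_data", inventory_stage)
    _run_stage("indices", indices_stage)
    _run_stage("cog", cog_stage)
    _run_stage("population_structure", popstruct_stage)
    _run_stage("stat_screen", screen_stage)
    _run_stage("size_gam", gam_stage)

    cfg_json = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        seed=seed,
        config_hash=hashlib.sha256(cfg_json).hexdigest(),
        density_mode=density_mode,
        input_digests=digests,
        timestamp=datetime.now(timezone.utc).isoformat() if include_timestamp else None,
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    outputs["manifest"] = str(out_dir / "manifest.json")
    return outputs


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
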