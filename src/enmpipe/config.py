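"""Run configuration and end-to-end pipeline orchestration.

A single YAML file (or :class:`RunConfig` built in code) drives the whole
workflow: read the current and future stacks, PCA-reduce both variable
blocks on the current scenario, project the fitted coefficients onto the
future climate layers (edaphic scores are reused unchanged), thin the
occurrences, run the jackknife ensemble, build per-scenario consensus
maps, and compute suitable-area change and polygon overlaps.

One global seed deterministically derives every stage seed, so a rerun
with the same config and seed reproduces every numeric output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import (
    BinaryMap,
    ScenarioComparison,
    change_stats,
    consensus,
    overlap_with_polygons,
    read_polygons_geojson,
    write_binary_map,
)
from .ensemble import registered_families
from .env_layers import (
    EnvStack,
    PCATransform,
    concat_stacks,
    fit_pca,
    project_transform,
    read_stack,
    write_ascii_grid,
)
from .evaluation import JackknifeResult, jackknife_run
from .occurrences import OccurrenceSet, load_records, thin_to_cells
from .utils import derive_seed, logger

DEFAULT_FAMILIES = [
    "GBM",
    "CTA",
    "RF",
    "GLM",
    "GAM",
    "ANN",
    "FDA",
    "MARS",
    "MAXENT",
]


@dataclass
class RunSettings:
    """Validated, path-free pipeline settings (the in-memory contract)."""

    families: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    n_pa_sets: int = 10
    n_runs: int = 10
    pca_climate_axes: int | str = 6
    pca_edaphic_axes: int | str = 2
    climate_vars: list[str] | None = None  # default: layer names starting "bio"
    pa_bounds_km: tuple[float, float] | None = None  # default: presence-pair bounds
    binomial: str = "poisson_binomial"
    consensus_rule: float = 0.5
    alpha: float = 0.05
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = [f for f in self.families if f not in registered_families()]
        if unknown:
            raise ValueError(f"unregistered families: {unknown}")
        if self.n_pa_sets < 1 or self.n_runs < 1:
            raise ValueError("n_pa_sets and n_runs must be >= 1")
        if not 0.0 < self.consensus_rule <= 1.0:
            raise ValueError("consensus_rule must be in (0, 1]")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


@dataclass
class RunConfig:
    """Settings plus the input/output paths of a file-based run."""

    current_dir: Path
    future_dirs: dict[str, Path]
    occurrences: Path
    output_dir: Path
    polygons: Path | None = None
    settings: RunSettings = field(default_factory=RunSettings)

    def validate(self) -> None:
        problems = []
        if not Path(self.current_dir).is_dir():
            problems.append(f"current stack directory missing: {self.current_dir}")
        for label, d in self.future_dirs.items():
            if not Path(d).is_dir():
                problems.append(f"future stack directory missing ({label}): {d}")
        if not Path(self.occurrences).is_file():
            problems.append(f"occurrence file missing: {self.occurrences}")
        if self.polygons is not None and not Path(self.polygons).is_file():
            problems.append(f"polygon file missing: {self.polygons}")
        try:
            self.settings.validate()
        except ValueError as exc:
            problems.append(str(exc))
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))


_SETTINGS_KEYS = {
    "families",
    "n_pa_sets",
    "n_runs",
    "pca",
    "pa",
    "binomial",
    "consensus_rule",
    "alpha",
    "seed",
    "hyperparams",
}
_TOP_KEYS = {"paths", "settings"}
_PATH_KEYS = {"current", "futures", "occurrences", "polygons", "output"}


def load_config(path: str | Path) -> RunConfig:
    """Parse and strictly validate a YAML run configuration.

    Unknown keys are rejected so typos fail fast, before any model fitting.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    paths = raw.get("paths", {})
    unknown = set(paths) - _PATH_KEYS
    if unknown:
        raise ValueError(f"unknown paths keys: {sorted(unknown)}")
    s = raw.get("settings", {})
    unknown = set(s) - _SETTINGS_KEYS
    if unknown:
        raise ValueError(f"unknown settings keys: {sorted(unknown)}")
    pca = s.get("pca", {})
    if set(pca) - {"climate", "edaphic", "climate_vars"}:
        raise ValueError(f"unknown pca keys: {sorted(set(pca) - {'climate', 'edaphic', 'climate_vars'})}")
    pa = s.get("pa", {})
    if set(pa) - {"d_min_km", "d_max_km"}:
        raise ValueError(f"unknown pa keys: {sorted(set(pa) - {'d_min_km', 'd_max_km'})}")
    bounds = None
    if "d_min_km" in pa or "d_max_km" in pa:
        if not {"d_min_km", "d_max_km"} <= set(pa):
            raise ValueError("pa bounds need both d_min_km and d_max_km")
        bounds = (float(pa["d_min_km"]), float(pa["d_max_km"]))
    settings = RunSettings(
        families=list(s.get("families", DEFAULT_FAMILIES)),
        n_pa_sets=int(s.get("n_pa_sets", 10)),
        n_runs=int(s.get("n_runs", 10)),
        pca_climate_axes=pca.get("climate", 6),
        pca_edaphic_axes=pca.get("edaphic", 2),
        climate_vars=pca.get("climate_vars"),
        pa_bounds_km=bounds,
        binomial=s.get("binomial", "poisson_binomial"),
        consensus_rule=float(s.get("consensus_rule", 0.5)),
        alpha=float(s.get("alpha", 0.05)),
        seed=int(s.get("seed", 0)),
        hyperparams=dict(s.get("hyperparams", {})),
    )
    base = Path(path).parent
    def _p(key: str) -> Path:
        if key not in paths:
            raise ValueError(f"paths.{key} is required")
        return (base / paths[key]).resolve()
    futures = {
        label: (base / d).resolve() for label, d in (paths.get("futures") or {}).items()
    }
    cfg = RunConfig(
        current_dir=_p("current"),
        future_dirs=futures,
        occurrences=_p("occurrences"),
        output_dir=(base / paths.get("output", "output")).resolve(),
        polygons=(base / paths["polygons"]).resolve() if paths.get("polygons") else None,
        settings=settings,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Core orchestration (in-memory)
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    climate_transform: PCATransform
    edaphic_transform: PCATransform
    score_stacks: dict[str, EnvStack]
    occurrences: OccurrenceSet
    jackknife: JackknifeResult
    consensus_maps: dict[str, BinaryMap]
    frequency_maps: dict[str, np.ndarray]
    comparison: ScenarioComparison
    settings: RunSettings


def split_blocks(stack: EnvStack, climate_vars: Sequence[str] | None) -> tuple[list[str], list[str]]:
    """Partition layer names into the climate and edaphic/topographic blocks.

    Default rule: names starting with ``bio`` are climate; everything else
    is edaphic/topographic.
    """
    if climate_vars is None:
        climate = [n for n in stack.layer_names if n.startswith("bio")]
    else:
        climate = [n for n in climate_vars if n in stack.layer_names]
        missing = set(climate_vars) - set(stack.layer_names)
        if missing:
            raise ValueError(f"configured climate variables absent: {sorted(missing)}")
    edaphic = [n for n in stack.layer_names if n not in climate]
    if not climate or not edaphic:
        raise ValueError("both a climate and an edaphic block are required")
    return climate, edaphic


def build_score_stacks(
    current: EnvStack,
    futures: Mapping[str, EnvStack],
    settings: RunSettings,
) -> tuple[PCATransform, PCATransform, dict[str, EnvStack]]:
    """PCA-reduce the current stack and project futures with its coefficients.

    The climate transform is fitted once on the current scenario and its
    linear coefficients are applied to each future climate block; the
    edaphic transform (and its scores) are reused unchanged for every
    scenario, since those layers do not change on this time horizon.
    """
    climate_names, edaphic_names = split_blocks(current, settings.climate_vars)
    clim_t, clim_scores = fit_pca(
        current.subset(climate_names), settings.pca_climate_axes, block_label="climate"
    )
    eda_t, eda_scores = fit_pca(
        current.subset(edaphic_names),
        settings.pca_edaphic_axes,
        block_label="edaphic_topographic",
    )
    stacks: dict[str, EnvStack] = {
        "current": concat_stacks([clim_scores, eda_scores], prefixes=("clim", "eda"))
    }
    for label, fut in futures.items():
        fut_clim = project_transform(clim_t, fut.subset(climate_names))
        fut_clim.scenario_label = label
        combined = concat_stacks([fut_clim, eda_scores], prefixes=("clim", "eda"))
        combined.scenario_label = label
        stacks[label] = combined
    return clim_t, eda_t, stacks


def run_enm(
    current: EnvStack,
    futures: Mapping[str, EnvStack],
    occurrences: OccurrenceSet,
    settings: RunSettings,
    polygons: Sequence[tuple[str, object]] = (),
) -> PipelineResult:
    """Run the whole workflow on in-memory inputs and return all products."""
    settings.validate()
    clim_t, eda_t, score_stacks = build_score_stacks(current, futures, settings)
    occ = occurrences if occurrences.thinned else thin_to_cells(occurrences, current.grid)
    logger.info(
        "jackknife over %d unique presence cells, %d families x %d PA sets x %d runs "
        "= %d models per replicate",
        occ.n_cells,
        len(settings.families),
        settings.n_pa_sets,
        settings.n_runs,
        len(settings.families) * settings.n_pa_sets * settings.n_runs,
    )
    jk = jackknife_run(
        occ,
        score_stacks,
        families=settings.families,
        n_pa_sets=settings.n_pa_sets,
        n_runs=settings.n_runs,
        seed=derive_seed(settings.seed, 10),
        bounds=settings.pa_bounds_km,
        binomial=settings.binomial,
        hyperparams=settings.hyperparams or None,
    )
    consensus_maps: dict[str, BinaryMap] = {}
    frequency_maps: dict[str, np.ndarray] = {}
    for label, maps in jk.binary_maps.items():
        cmap, freq = consensus(maps, jk.success_flags, rule=settings.consensus_rule)
        cmap.scenario_label = label
        consensus_maps[label] = cmap
        frequency_maps[label] = freq
    future_labels = [k for k in score_stacks if k != "current"]
    overlaps = None
    if polygons:
        overlaps, _ = overlap_with_polygons(consensus_maps["current"], polygons)
    comparison = change_stats(
        consensus_maps["current"],
        {k: consensus_maps[k] for k in future_labels},
        polygon_overlaps=overlaps,
    )
    return PipelineResult(
        climate_transform=clim_t,
        edaphic_transform=eda_t,
        score_stacks=score_stacks,
        occurrences=occ,
        jackknife=jk,
        consensus_maps=consensus_maps,
        frequency_maps=frequency_maps,
        comparison=comparison,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

def _stack_from_dir(directory: Path, label: str) -> EnvStack:
    paths = sorted(Path(directory).glob("*.asc"))
    if not paths:
        raise ValueError(f"no .asc rasters in {directory}")
    return read_stack(paths, scenario_label=label)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Validated file-based run: read inputs, compute, write all outputs.

    Outputs under ``config.output_dir``: the two PCA transforms (JSON), the
    jackknife report (CSV + JSON), per-scenario consensus and frequency
    maps (ASCII grids), the scenario comparison (JSON) and a manifest with
    the config hash, seed and package versions.
    """
    config.validate()
    current = _stack_from_dir(config.current_dir, "current")
    futures = {label: _stack_from_dir(d, label) for label, d in config.future_dirs.items()}
    occ = load_records(config.occurrences)
    polygons = read_polygons_geojson(config.polygons) if config.polygons else ()
    result = run_enm(current, futures, occ, config.settings, polygons)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pca_transforms.json", "w") as fh:
        json.dump(
            {
                "climate": result.climate_transform.to_dict(),
                "edaphic_topographic": result.edaphic_transform.to_dict(),
            },
            fh,
            indent=2,
        )
    result.jackknife.report.to_csv(out / "jackknife_replicates.csv")
    result.jackknife.report.to_json(out / "jackknife_summary.json")
    for label, cmap in result.consensus_maps.items():
        write_binary_map(cmap, out / f"consensus_{label}.asc")
        write_ascii_grid(out / f"frequency_{label}.asc", cmap.grid, result.frequency_maps[label])
    result.comparison.to_json(out / "scenario_comparison.json")
    if result.comparison.polygon_overlaps is not None:
        result.comparison.polygon_overlaps.to_csv(out / "polygon_overlaps.csv", index=False)

    manifest = {
        "enmpipe_version": __version__,
        "seed": config.settings.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_as_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "config": _config_as_dict(config),
        "n_replicates": result.jackknife.report.n,
        "models_per_replicate": len(config.settings.families)
        * config.settings.n_pa_sets
        * config.settings.n_runs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result


def _config_as_dict(config: RunConfig) -> dict:
    d = {
        "current_dir": str(config.current_dir),
        "future_dirs": {k: str(v) for k, v in config.future_dirs.items()},
        "occurrences": str(config.occurrences),
        "polygons": str(config.polygons) if config.polygons else None,
        "output_dir": str(config.output_dir),
        "settings": asdict(config.settings),
    }
    return d
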