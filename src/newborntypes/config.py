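"""Run configuration: YAML loading, validation and orchestration.

A run config names the input registries and their schemas, the centile
standard and how to extend it, the plausibility limits, the region map, and
the analysis settings.  ``validate_config`` checks every file reference and
numeric range before any data is read; ``run_from_config`` executes the
model end-to-end and writes the standard-named output bundle, removing any
partial outputs if a stage fails.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import yaml

from .exclusions import PlausibilityLimits
from .io import ConfigurationError, RegistrySchema
from .model import NewbornTypeAnalysis
from .standard import EXTENSION_METHODS

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RegistryInput:
    path: str
    schema: RegistrySchema


@dataclasses.dataclass
class RunConfig:
    registries: list[RegistryInput]
    standard_path: str
    output_dir: str
    extend_min_days: int | None = None
    extend_max_days: int | None = None
    extension_method: str = "linear_extrapolate"
    limits: PlausibilityLimits = dataclasses.field(default_factory=PlausibilityLimits)
    region_map_path: str | None = None
    country_metadata: dict = dataclasses.field(default_factory=dict)
    sensitivity_threshold_pct: float = 20.0
    trend_threshold_pp: float = 0.5
    trend_min_years: int = 4
    per_record_output: bool = False
    suppress_small_cells: bool = False
    seed: int = 0


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config into a :class:`RunConfig`."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    base = path.parent

    def resolve(p):
        return str(p) if Path(p).is_absolute() else str(base / p)

    registries = []
    for entry in raw.get("registries", []):
        schema = RegistrySchema(
            columns=entry.get("columns", {}),
            ga_encoding=entry.get("ga_encoding", "weeks_plus_days"),
            sentinels=tuple(entry.get("sentinels", RegistrySchema.sentinels)),
            delimiter=entry.get("delimiter", ","),
        )
        registries.append(RegistryInput(path=resolve(entry["path"]), schema=schema))

    std = raw.get("standard", {})
    limits = PlausibilityLimits(**raw.get("limits", {}))
    extend = std.get("extend", {})
    return RunConfig(
        registries=registries,
        standard_path=resolve(std["path"]) if "path" in std else "",
        extend_min_days=extend.get("min_days"),
        extend_max_days=extend.get("max_days"),
        extension_method=std.get("method", "linear_extrapolate"),
        limits=limits,
        region_map_path=(
            resolve(raw["region_map"]) if raw.get("region_map") else None
        ),
        country_metadata=raw.get("country_metadata", {}),
        sensitivity_threshold_pct=raw.get("sensitivity_threshold_pct", 20.0),
        trend_threshold_pp=raw.get("trend_threshold_pp", 0.5),
        trend_min_years=raw.get("trend_min_years", 4),
        per_record_output=raw.get("per_record_output", False),
        suppress_small_cells=raw.get("suppress_small_cells", False),
        seed=raw.get("seed", 0),
        output_dir=resolve(raw.get("output_dir", "outputs")),
    )


def validate_config(config: RunConfig) -> list[str]:
    """All file references and numeric ranges, checked before reading data.

    Returns the aggregated list of problems; empty means valid.
    """
    problems: list[str] = []
    if not config.registries:
        problems.append("no input registries configured")
    for reg in config.registries:
        if not Path(reg.path).exists():
            problems.append(f"registry file not found: {reg.path}")
    if not config.standard_path:
        problems.append("no standard table configured")
    elif not Path(config.standard_path).exists():
        problems.append(f"standard table not found: {config.standard_path}")
    if config.region_map_path and not Path(config.region_map_path).exists():
        problems.append(f"region map not found: {config.region_map_path}")
    if config.extension_method not in EXTENSION_METHODS:
        problems.append(
            f"unknown extension method {config.extension_method!r}"
        )
    if config.trend_threshold_pp < 0:
        problems.append(
            f"trend threshold must be >= 0, got {config.trend_threshold_pp}"
        )
    if config.trend_min_years < 1:
        problems.append(
            f"trend_min_years must be >= 1, got {config.trend_min_years}"
        )
    if not 0 <= config.sensitivity_threshold_pct <= 100:
        problems.append(
            "sensitivity threshold must be a percentage in [0, 100], got "
            f"{config.sensitivity_threshold_pct}"
        )
    return problems


def run_from_config(config: RunConfig) -> "Path":
    """Execute the full pipeline from a validated config.

    Writes the output bundle into ``config.output_dir`` and returns that
    path.  Any stage error aborts with a stage-tagged message and removes
    the partially written outputs.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("invalid config: " + "; ".join(problems))

    stage = "read"
    written: list[Path] = []
    try:
        extend_to = None
        if config.extend_min_days is not None and config.extend_max_days is not None:
            extend_to = (config.extend_min_days, config.extend_max_days)
        model = NewbornTypeAnalysis.from_files(
            registries=[(r.path, r.schema) for r in config.registries],
            standard_path=config.standard_path,
            extend_to=extend_to,
            extension_method=config.extension_method,
            region_map_path=config.region_map_path,
            limits=config.limits,
            country_metadata=config.country_metadata,
            sensitivity_threshold_pct=config.sensitivity_threshold_pct,
            trend_threshold_pp=config.trend_threshold_pp,
            trend_min_years=config.trend_min_years,
            keep_typed_records=config.per_record_output,
            suppress_small_cells=config.suppress_small_cells,
        )
        stage = "fit"
        results = model.fit()
        stage = "write"
        written = results.save_tables(config.output_dir)
        logger.info("wrote %d output tables to %s", len(written), config.output_dir)
        return Path(config.output_dir)
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
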