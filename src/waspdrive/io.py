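"""Configuration parsing and result serialization.

Configs are YAML (any JSON-compatible subset works) mapping onto
:class:`~waspdrive.scenarios.SimConfig`; species preset names expand to the
built-in parameter sets and explicit fields override them.  Trajectories are
written as long-format RFC-4180 CSV, summaries as JSON, and sweep tables as
CSV — all byte-reproducible from the configuration and seed recorded in the
run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from .genetics import DriveParams, ParameterError
from .lifecycle import MatingDistribution, SpeciesParams, species_preset
from .scenarios import (
    ReleaseSpec,
    ReplicateResult,
    ScenarioSummary,
    SimConfig,
    polyandry_variant,
)

__all__ = [
    "ConfigError",
    "config_from_dict",
    "load_config",
    "write_trajectories",
    "write_summary",
    "RunManifest",
]

TRAJECTORY_COLUMNS = [
    "replicate",
    "generation",
    "n_queens",
    "freq_wt",
    "freq_gd",
    "freq_re",
    "freq_nf",
    "suppressed",
]


class ConfigError(ValueError):
    """A configuration file or flag set failed validation."""


def _mating_from_dict(d: dict, base: MatingDistribution, where: str) -> MatingDistribution:
    if not isinstance(d, dict):
        raise ConfigError(f"{where} must be a mapping, got {d!r}")
    known = {"lambda", "lam", "min", "max"}
    for key in d:
        if key not in known:
            raise ConfigError(f"unknown field {where}.{key}")
    lam = d.get("lambda", d.get("lam", base.lam))
    try:
        return MatingDistribution(
            lam=lam, min=d.get("min", base.min), max=d.get("max", base.max)
        )
    except ParameterError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _species_from_config(node, polyandry: str | None) -> SpeciesParams:
    if node is None:
        node = "hornet"
    if isinstance(node, str):
        try:
            species = species_preset(node)
        except ParameterError as exc:
            raise ConfigError(f"species: {exc}") from exc
        return polyandry_variant(species, polyandry)
    if not isinstance(node, dict):
        raise ConfigError(f"species must be a preset name or mapping, got {node!r}")
    node = dict(node)
    try:
        species = species_preset(node.pop("preset", "hornet"))
    except ParameterError as exc:
        raise ConfigError(f"species.preset: {exc}") from exc
    overrides = {}
    for key in ("offspring_mean_per_sex", "winter_mortality", "r_max", "K", "name"):
        if key in node:
            overrides[key] = node.pop(key)
    for key in ("female_mating", "male_mating"):
        if key in node:
            overrides[key] = _mating_from_dict(
                node.pop(key), getattr(species, key), f"species.{key}"
            )
    if node:
        raise ConfigError(f"unknown field species.{sorted(node)[0]}")
    try:
        species = replace(species, **overrides)
    except ParameterError as exc:
        raise ConfigError(f"species: {exc}") from exc
    return polyandry_variant(species, polyandry)


def _drive_from_config(node) -> DriveParams:
    if node is None:
        return DriveParams()
    if not isinstance(node, dict):
        raise ConfigError(f"drive must be a mapping, got {node!r}")
    known = {"p_cut", "p_nhej", "p_fr", "p_het_mort", "strategy", "resolution"}
    for key in node:
        if key not in known:
            raise ConfigError(f"unknown field drive.{key}")
    try:
        return DriveParams(**node)
    except ParameterError as exc:
        raise ConfigError(f"drive: {exc}") from exc
    except ValueError as exc:  # bad strategy / resolution name
        raise ConfigError(f"drive: {exc}") from exc


def _release_from_config(node) -> ReleaseSpec:
    if node is None:
        return ReleaseSpec()
    if isinstance(node, str):
        node = {"carrier": node}
    if not isinstance(node, dict):
        raise ConfigError(f"release must be a mapping or carrier name, got {node!r}")
    for key in node:
        if key not in {"carrier", "count"}:
            raise ConfigError(f"unknown field release.{key}")
    try:
        return ReleaseSpec(**node)
    except ParameterError as exc:
        raise ConfigError(f"release: {exc}") from exc


def config_from_dict(d: dict | None) -> SimConfig:
    """Build a validated :class:`SimConfig` from a plain mapping.

    An empty mapping yields the full-default configuration: hornet preset,
    female-infertility drive at default efficiencies, female release of 100
    WT/GD queens, 25 generations, 10 replicates.
    """
    d = dict(d or {})
    known = {"species", "drive", "release", "generations", "replicates", "seed",
             "polyandry", "unmated_queens"}
    for key in d:
        if key not in known:
            raise ConfigError(f"unknown field {key}")
    polyandry = d.get("polyandry")
    if polyandry is not None and polyandry not in ("no_polyandry", "doubled"):
        raise ConfigError(
            f"polyandry must be 'no_polyandry' or 'doubled', got {polyandry!r}"
        )
    try:
        return SimConfig(
            species=_species_from_config(d.get("species"), polyandry),
            drive=_drive_from_config(d.get("drive")),
            release=_release_from_config(d.get("release")),
            generations=int(d.get("generations", 25)),
            replicates=int(d.get("replicates", 10)),
            seed=int(d.get("seed", 1)),
            unmated_queens=str(d.get("unmated_queens", "retain")),
        )
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML (or JSON) scenario configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def config_to_dict(config: SimConfig) -> dict:
    """Serialize a config (all resolved parameters) to plain JSON-able data."""
    d = dataclasses.asdict(config)
    d["drive"]["strategy"] = config.drive.strategy.value
    d["drive"]["resolution"] = config.drive.resolution.value
    return d


def write_trajectories(results: list[ReplicateResult], path: str | Path) -> None:
    """Write replicate trajectories as long-format CSV.

    One row per replicate-generation; allele-frequency cells are empty (not
    zero) in extinction generations, and suppressed replicates have no rows
    after their extinction generation.
    """
    if not results:
        raise ValueError("no replicate results to write")
    frame = pd.concat([r.to_frame() for r in results], ignore_index=True)
    frame = frame[TRAJECTORY_COLUMNS]
    frame.to_csv(path, index=False, lineterminator="\r\n")


def write_summary(summary: ScenarioSummary | pd.DataFrame, path: str | Path) -> None:
    """Write a scenario summary as JSON, or a sweep/sensitivity table as CSV."""
    path = Path(path)
    if isinstance(summary, pd.DataFrame):
        summary.to_csv(path, index=False, lineterminator="\r\n")
        return
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: resolved config, seed, outputs."""

    config: dict
    seed: int
    outputs: dict
    version: str = ""
    created: str = ""

    @classmethod
    def for_run(cls, config: SimConfig, outputs: dict) -> "RunManifest":
        from . import __version__

        return cls(
            config=config_to_dict(config),
            seed=config.seed,
            outputs=outputs,
            version=__version__,
            created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
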