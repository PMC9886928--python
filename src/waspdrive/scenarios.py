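"""Release scenarios, replicate execution and population-level statistics.

A scenario is a :class:`SimConfig`: a species, a drive, a release strategy
and a horizon.  Replicates are independent seeded runs of the yearly life
cycle; the headline statistic is the suppression rate, the fraction of
replicates in which the mated-queen population hits zero within the horizon.
Parameter sweeps and one-at-a-time life-history sensitivity scans are thin
loops over scenarios returning tidy pandas tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genetics import Allele, DriveParams, ParameterError
from .lifecycle import (
    MatingDistribution,
    PopulationState,
    SpeciesParams,
    step_year,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReleaseSpec",
    "SimConfig",
    "ReplicateResult",
    "ScenarioSummary",
    "initialize_population",
    "run_replicate",
    "run_scenario",
    "compute_allele_frequencies",
    "sweep_drive_parameters",
    "sensitivity_analysis",
    "polyandry_variant",
    "expected_wt_transmission",
    "SENSITIVITY_PARAMETERS",
]


@dataclass(frozen=True)
class ReleaseSpec:
    """How the drive enters the population.

    Female releases are ``count`` heterozygous (WT/GD) mated queens that are
    part of the initial population.  Male releases are ``count`` hemizygous
    GD males injected into the mating pool of the first generation, so the
    effective introduction frequency is far lower (the wild male cohort is
    offspring-sized, not queen-sized).
    """

    carrier: str = "female"
    count: int = 100

    def __post_init__(self) -> None:
        if self.carrier not in ("female", "male"):
            raise ParameterError(
                f"release carrier must be 'female' or 'male', got {self.carrier!r}"
            )
        if self.count < 0:
            raise ParameterError(f"release count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated scenario.

    ``unmated_queens`` selects whether gynes that fail to find a mate are
    retained as non-reproducing foundresses through winter and density
    regulation (``"retain"``, default) or dropped at the mating step
    (``"discard"``).
    """

    species: SpeciesParams
    drive: DriveParams = DriveParams()
    release: ReleaseSpec = ReleaseSpec()
    generations: int = 25
    replicates: int = 10
    seed: int = 1
    unmated_queens: str = "retain"

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ParameterError("generations must be >= 1")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.unmated_queens not in ("retain", "discard"):
            raise ParameterError(
                f"unmated_queens must be 'retain' or 'discard', got {self.unmated_queens!r}"
            )
        if self.release.carrier == "female" and self.release.count > self.species.K:
            raise ParameterError(
                f"release count {self.release.count} exceeds the initial "
                f"queen population K={self.species.K}"
            )


@dataclass
class ReplicateResult:
    """Per-generation trajectory of one replicate.

    Rows cover simulated generations ``1..G`` (or up to extinction);
    ``allele_freqs`` holds the (WT, GD, RE, NF) frequencies among the
    reproductive queens of each generation, with NaN in the extinction
    generation where frequencies are undefined.
    """

    replicate: int
    generation: np.ndarray
    n_queens: np.ndarray
    allele_freqs: np.ndarray  # (G, 4), NaN rows where the population is extinct
    suppressed: bool
    suppression_generation: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicate,
                "generation": self.generation,
                "n_queens": self.n_queens,
                "freq_wt": self.allele_freqs[:, 0],
                "freq_gd": self.allele_freqs[:, 1],
                "freq_re": self.allele_freqs[:, 2],
                "freq_nf": self.allele_freqs[:, 3],
                "suppressed": self.suppressed,
            }
        )


@dataclass
class ScenarioSummary:
    """Aggregate suppression statistics over the replicates of a scenario."""

    n_replicates: int
    n_suppressed: int
    times_to_suppression: list[int]
    results: list[ReplicateResult] = field(default_factory=list, repr=False)

    @property
    def suppression_rate(self) -> float:
        return self.n_suppressed / self.n_replicates

    @property
    def mean_time_to_suppression(self) -> float | None:
        if not self.times_to_suppression:
            return None
        return float(np.mean(self.times_to_suppression))

    @property
    def sem_time_to_suppression(self) -> float | None:
        if len(self.times_to_suppression) < 2:
            return None
        return float(
            np.std(self.times_to_suppression, ddof=1)
            / np.sqrt(len(self.times_to_suppression))
        )

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_suppressed": self.n_suppressed,
            "suppression_rate": self.suppression_rate,
            "times_to_suppression": list(self.times_to_suppression),
            "mean_time_to_suppression": self.mean_time_to_suppression,
            "sem_time_to_suppression": self.sem_time_to_suppression,
        }


def compute_allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Allele frequencies (WT, GD, RE, NF) among an ``(n, 2)`` queen array.

    Counts run over the ``2n`` allele slots of the diploid queens and are
    normalized to sum to one.  Undefined (raises) for an empty population;
    callers record a missing value instead.
    """
    g = np.asarray(genotypes, dtype=np.int8).reshape(-1, 2)
    if g.shape[0] == 0:
        raise ValueError("allele frequencies are undefined for an empty population")
    counts = np.bincount(g.ravel(), minlength=4)[:4]
    return counts / counts.sum()


def initialize_population(
    config: SimConfig, rng: np.random.Generator
) -> tuple[PopulationState, np.ndarray | None]:
    """Build the starting population of ``K`` mated queens.

    Every queen has exactly one WT mate regardless of polyandry settings
    (polyandry applies from the first simulated mating onwards).  A female
    release replaces ``count`` of the WT/WT queens with WT/GD queens; a male
    release leaves all queens wildtype and returns the GD males to be
    injected into the generation-1 mating pool.
    """
    K = config.species.K
    m = config.species.female_mating.max
    genotypes = np.full((K, 2), Allele.WT, dtype=np.int8)
    pending_males: np.ndarray | None = None
    if config.release.carrier == "female":
        genotypes[: config.release.count, 1] = Allele.GD
    elif config.release.count > 0:
        pending_males = np.full(config.release.count, Allele.GD, dtype=np.int8)
    mate_alleles = np.full((K, m), -1, dtype=np.int8)
    mate_alleles[:, 0] = Allele.WT
    mate_fertile = np.zeros((K, m), dtype=bool)
    mate_fertile[:, 0] = True
    state = PopulationState(
        genotypes=genotypes,
        mate_alleles=mate_alleles,
        mate_fertile=mate_fertile,
        n_mates=np.ones(K, dtype=np.int64),
    )
    return state, pending_males


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """Deterministic per-replicate stream: SeedSequence((seed, replicate))."""
    return np.random.default_rng(np.random.SeedSequence((seed, replicate_index)))


def run_replicate(config: SimConfig, replicate_index: int) -> ReplicateResult:
    """Run one seeded replicate of up to ``config.generations`` years.

    The random stream is fully determined by ``(config.seed,
    replicate_index)``, so any replicate can be reproduced in isolation.
    Iteration stops early once the queen population is extinct.
    """
    rng = _replicate_rng(config.seed, replicate_index)
    state, pending_males = initialize_population(config, rng)

    generations: list[int] = []
    n_queens: list[int] = []
    freqs: list[np.ndarray] = []
    suppressed = False
    suppression_generation: int | None = None

    for gen in range(1, config.generations + 1):
        state = step_year(
            state,
            config.species,
            config.drive,
            rng,
            release_males=pending_males if gen == 1 else None,
            unmated_queens=config.unmated_queens,
        )
        n = len(state)
        generations.append(gen)
        n_queens.append(n)
        if n > 0:
            freqs.append(compute_allele_frequencies(state.genotypes))
        else:
            freqs.append(np.full(4, np.nan))
            suppressed = True
            suppression_generation = gen
            break

    return ReplicateResult(
        replicate=replicate_index,
        generation=np.asarray(generations, dtype=np.int64),
        n_queens=np.asarray(n_queens, dtype=np.int64),
        allele_freqs=np.vstack(freqs),
        suppressed=suppressed,
        suppression_generation=suppression_generation,
    )


def run_scenario(config: SimConfig) -> ScenarioSummary:
    """Run all replicates of a scenario and aggregate suppression statistics."""
    results = []
    for i in range(config.replicates):
        result = run_replicate(config, i)
        logger.debug(
            "replicate %d: %s (final n=%d)",
            i,
            f"suppressed at generation {result.suppression_generation}"
            if result.suppressed
            else "persisted",
            int(result.n_queens[-1]),
        )
        results.append(result)
    times = [r.suppression_generation for r in results if r.suppressed]
    return ScenarioSummary(
        n_replicates=config.replicates,
        n_suppressed=len(times),
        times_to_suppression=times,
        results=results,
    )


# --- parameter sweeps -------------------------------------------------------

_SWEEPABLE = ("p_cut", "p_nhej", "p_fr", "p_het_mort")

#: Drive settings used for non-swept parameters in sweeps: a perfect drive,
#: so each swept parameter is probed in isolation.
_OPTIMAL_DRIVE = {"p_cut": 1.0, "p_nhej": 0.0, "p_fr": 0.0, "p_het_mort": 0.0}

_DEFAULT_PARTNER = {"p_fr": 0.01, "p_nhej": 0.02}


def _sweep_drive(base: DriveParams, swept: dict[str, float]) -> DriveParams:
    """Drive parameters for one sweep cell.

    Non-swept parameters sit at their optimal values, except that when
    exactly one of ``p_fr``/``p_nhej`` is swept alone the partner keeps its
    default (0.01 / 0.02): an optimal partner would zero out the swept
    parameter's effect entirely.
    """
    for name in swept:
        if name not in _SWEEPABLE:
            raise ParameterError(
                f"unknown drive parameter {name!r}; sweepable: {_SWEEPABLE}"
            )
    values = dict(_OPTIMAL_DRIVE)
    if "p_fr" in swept and "p_nhej" not in swept:
        values["p_nhej"] = _DEFAULT_PARTNER["p_nhej"]
    if "p_nhej" in swept and "p_fr" not in swept:
        values["p_fr"] = _DEFAULT_PARTNER["p_fr"]
    values.update(swept)
    return replace(base, **values)


def sweep_drive_parameters(
    base: SimConfig,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]] | None = None,
    generations: int = 50,
) -> pd.DataFrame:
    """Grid-evaluate suppression over one or two drive parameters.

    Each cell runs ``base.replicates`` replicates for ``generations``
    generations (50 by default: the longer horizon lets slow near-threshold
    cells resolve).  Returns one row per cell with the axis values, the
    suppression rate and the mean time to suppression.
    """
    name1, values1 = axis1
    name2, values2 = axis2 if axis2 is not None else (None, [None])
    rows = []
    for v1 in values1:
        for v2 in values2:
            swept = {name1: v1}
            if name2 is not None:
                swept[name2] = v2
            config = replace(
                base, drive=_sweep_drive(base.drive, swept), generations=generations
            )
            summary = run_scenario(config)
            row = {name1: v1}
            if name2 is not None:
                row[name2] = v2
            row.update(
                n_replicates=summary.n_replicates,
                n_suppressed=summary.n_suppressed,
                suppression_rate=summary.suppression_rate,
                mean_time_to_suppression=summary.mean_time_to_suppression,
            )
            logger.info("sweep cell %s: %d/%d suppressed", swept, summary.n_suppressed,
                        summary.n_replicates)
            rows.append(row)
    return pd.DataFrame(rows)


# --- life-history sensitivity ----------------------------------------------

SENSITIVITY_PARAMETERS = (
    "r_max",
    "offspring_mean_per_sex",
    "winter_mortality",
    "female_mating_mean",
    "female_mating_max",
    "male_mating_mean",
    "male_mating_max",
)


def _apply_species_parameter(
    species: SpeciesParams, parameter: str, value: float
) -> SpeciesParams:
    """Return a copy of ``species`` with one life-history field replaced."""
    if parameter in ("r_max", "offspring_mean_per_sex", "winter_mortality"):
        return replace(species, **{parameter: value})
    if parameter == "female_mating_mean":
        return replace(species, female_mating=replace(species.female_mating, lam=value))
    if parameter == "female_mating_max":
        return replace(species, female_mating=replace(species.female_mating, max=int(value)))
    if parameter == "male_mating_mean":
        return replace(species, male_mating=replace(species.male_mating, lam=value))
    if parameter == "male_mating_max":
        return replace(species, male_mating=replace(species.male_mating, max=int(value)))
    raise ParameterError(
        f"unknown life-history parameter {parameter!r}; "
        f"known parameters: {SENSITIVITY_PARAMETERS}"
    )


def sensitivity_analysis(
    base: SimConfig,
    parameter: str,
    values: Iterable[float],
    include_no_drive_control: bool = False,
) -> pd.DataFrame:
    """One-at-a-time life-history sensitivity scan.

    Varies a single species parameter across ``values`` with the drive held
    at the base configuration's settings.  With
    ``include_no_drive_control=True`` each value is additionally run with no
    release at all, flagging settings under which the population collapses
    for purely demographic reasons (a drive "success" there would be
    meaningless).
    """
    rows = []
    for value in values:
        species = _apply_species_parameter(base.species, parameter, value)
        summary = run_scenario(replace(base, species=species))
        row = {
            "parameter": parameter,
            "value": value,
            "n_replicates": summary.n_replicates,
            "n_suppressed": summary.n_suppressed,
            "suppression_rate": summary.suppression_rate,
            "mean_time_to_suppression": summary.mean_time_to_suppression,
        }
        if include_no_drive_control:
            control = run_scenario(
                replace(base, species=species, release=replace(base.release, count=0))
            )
            row["no_drive_extinctions"] = control.n_suppressed
        rows.append(row)
    return pd.DataFrame(rows)


def polyandry_variant(species: SpeciesParams, variant: str | None) -> SpeciesParams:
    """Polyandry manipulation of a species preset.

    ``"no_polyandry"`` caps female matings at 1 (with the zero-truncated
    distribution every queen then has exactly one mate); ``"doubled"``
    doubles the female mating rate and maximum (paper wasp: lambda 0.2 to
    0.4, max 2 to 4).  ``None`` returns the preset unchanged.
    """
    if variant is None:
        return species
    if variant == "no_polyandry":
        return replace(species, female_mating=replace(species.female_mating, max=1))
    if variant == "doubled":
        fm = species.female_mating
        return replace(
            species,
            female_mating=MatingDistribution(lam=fm.lam * 2, min=fm.min, max=fm.max * 2),
        )
    raise ParameterError(
        f"unknown polyandry variant {variant!r}; expected 'no_polyandry' or 'doubled'"
    )


def expected_wt_transmission(
    n_queens: float,
    genotype_class: str,
    offspring_mean: float,
    winter_mortality: float,
    p_cut: float | None = None,
) -> float:
    """Expected WT alleles passed to next year's overwintered queens.

    A deterministic diagnostic of wildtype allele flow:

    * WT/WT queens: ``n * 2 * offspring_mean * (1 - winter_mortality)``
      (two WT alleles each, halved per gamete but carried by both the
      daughter and son cohorts of equal size);
    * WT/GD queens: ``n * (1 - p_cut) * offspring_mean *
      (1 - winter_mortality)`` (only uncut WT alleles survive the germline,
      and a heterozygote transmits the WT copy to half her gametes).
    """
    if min(n_queens, offspring_mean) < 0 or not 0 <= winter_mortality <= 1:
        raise ParameterError("inputs must be nonnegative; mortality a probability")
    key = genotype_class.strip().lower().replace("/", "_")
    if key == "wt_wt":
        return n_queens * 2 * offspring_mean * (1 - winter_mortality)
    if key == "wt_gd":
        if p_cut is None:
            raise ParameterError("p_cut is required for the WT/GD genotype class")
        return n_queens * (1 - p_cut) * offspring_mean * (1 - winter_mortality)
    raise ParameterError(
        f"unknown genotype class {genotype_class!r}; expected 'wt_wt' or 'wt_gd'"
    )
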