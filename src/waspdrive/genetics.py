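"""Single-locus genetics of a CRISPR homing gene drive in a haplodiploid wasp.

The drive locus carries one of four alleles: wildtype (WT), gene drive (GD),
functional resistance (RE), and non-functional (NF).  Females are diploid and
males haploid, so all drive activity (cutting, homing, end-joining repair)
happens in the queen's germline; a male genome is a single inert allele.

In a drive-carrier queen each WT allele is, once per queen before any gamete
is drawn, either converted to GD (cut followed by homology-directed repair),
converted to RE or NF (cut followed by non-homologous end-joining, with or
without restoration of gene function), or left as WT (no cut).  RE, NF and GD
alleles are never modified: RE and NF target sites can no longer be cut, and
GD is the drive itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class ParameterError(ValueError):
    """A drive or species parameter is outside its legal domain."""


class Allele(enum.IntEnum):
    """The four possible states of the drive locus."""

    WT = 0  # wildtype, cuttable target
    GD = 1  # homing gene drive insertion
    RE = 2  # functional, cut-resistant repair product
    NF = 3  # non-functional, cut-resistant repair product


N_ALLELES = 4

ALLELE_NAMES = ("WT", "GD", "RE", "NF")


class Strategy(str, enum.Enum):
    """Which sex, if any, is sterilised by disruption of the target gene."""

    NEUTRAL = "neutral"
    FEMALE_INFERTILITY = "female_infertility"
    MALE_INFERTILITY = "male_infertility"
    BOTH_INFERTILITY = "both_infertility"


class Resolution(str, enum.Enum):
    """Granularity of germline drive resolution.

    ``PER_GAMETE`` (the default) draws the cut/repair outcome independently
    for every gamete that samples a WT allele, so rare resistance alleles
    arise as singletons.  ``PER_QUEEN`` edits each WT allele once per queen,
    before any gamete is drawn, so a rare end-joining event is inherited by
    a block of siblings.  Both granularities give identical per-gamete
    transmission probabilities; they differ in how repair outcomes are
    correlated within a brood.
    """

    PER_QUEEN = "per_queen"
    PER_GAMETE = "per_gamete"


_FEMALE_TARGETING = frozenset({Strategy.FEMALE_INFERTILITY, Strategy.BOTH_INFERTILITY})
_MALE_TARGETING = frozenset({Strategy.MALE_INFERTILITY, Strategy.BOTH_INFERTILITY})


@dataclass(frozen=True)
class DriveParams:
    """Efficiency and cost parameters of the homing drive.

    Parameters
    ----------
    p_cut
        Probability that the nuclease cuts a WT allele in the germline.
    p_nhej
        Probability that a cut is repaired by non-homologous end-joining
        instead of homing.
    p_fr
        Probability that an end-joining repair restores gene function,
        producing a functional resistance (RE) allele rather than a
        non-functional (NF) one.
    p_het_mort
        Probability that a drive carrier (fully dominant: hetero-, homo- and
        hemizygotes alike) dies before mating.
    strategy
        Which sex the disrupted target gene sterilises.
    resolution
        Per-gamete (default) or per-queen germline resolution.
    """

    p_cut: float = 0.95
    p_nhej: float = 0.02
    p_fr: float = 0.01
    p_het_mort: float = 0.0
    strategy: Strategy = Strategy.FEMALE_INFERTILITY
    resolution: Resolution = Resolution.PER_GAMETE

    def __post_init__(self) -> None:
        for name in ("p_cut", "p_nhej", "p_fr", "p_het_mort"):
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        object.__setattr__(self, "resolution", Resolution(self.resolution))

    def outcome_probabilities(self) -> np.ndarray:
        """Fate probabilities of one WT allele in a carrier germline.

        Returns the vector ``[P(WT), P(GD), P(RE), P(NF)]``:
        ``P(GD) = p_cut(1-p_nhej)``, ``P(RE) = p_cut*p_nhej*p_fr``,
        ``P(NF) = p_cut*p_nhej*(1-p_fr)``, ``P(WT) = 1-p_cut``.
        These sum to one for every legal parameter combination.
        """
        p_gd = self.p_cut * (1.0 - self.p_nhej)
        p_re = self.p_cut * self.p_nhej * self.p_fr
        p_nf = self.p_cut * self.p_nhej * (1.0 - self.p_fr)
        return np.array([1.0 - self.p_cut, p_gd, p_re, p_nf])


def _transform_wt(u: np.ndarray, drive: DriveParams) -> np.ndarray:
    """Map uniform variates to germline fates of WT alleles in carriers."""
    p_gd = drive.p_cut * (1.0 - drive.p_nhej)
    p_re = drive.p_cut * drive.p_nhej * drive.p_fr
    p_nf = drive.p_cut * drive.p_nhej * (1.0 - drive.p_fr)
    out = np.full(u.shape, Allele.WT, dtype=np.int8)
    out[u < p_gd] = Allele.GD
    out[(u >= p_gd) & (u < p_gd + p_re)] = Allele.RE
    out[(u >= p_gd + p_re) & (u < p_gd + p_re + p_nf)] = Allele.NF
    return out


def resolve_germline_array(
    genotypes: np.ndarray, drive: DriveParams, rng: np.random.Generator
) -> np.ndarray:
    """Germline-resolve an ``(n, 2)`` array of female genotypes.

    Each WT allele of a GD-carrier queen is independently converted according
    to :meth:`DriveParams.outcome_probabilities`; all other alleles, and all
    alleles of non-carrier queens, are untouched.  Returns a new array; the
    somatic genotypes of the queens themselves are never modified.
    """
    out = np.array(genotypes, dtype=np.int8, copy=True).reshape(-1, 2)
    carrier = (out == Allele.GD).any(axis=1)
    editable = (out == Allele.WT) & carrier[:, None]
    n_edit = int(editable.sum())
    if n_edit:
        out[editable] = _transform_wt(rng.random(n_edit), drive)
    return out


def resolve_germline(
    genotype: tuple[Allele, Allele] | np.ndarray,
    drive: DriveParams,
    rng: np.random.Generator,
) -> tuple[Allele, Allele]:
    """Germline-resolve a single female genotype (allele pair)."""
    resolved = resolve_germline_array(np.asarray(genotype, dtype=np.int8), drive, rng)[0]
    return (Allele(int(resolved[0])), Allele(int(resolved[1])))


def draw_gametes(
    genotypes: np.ndarray, queen_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one Mendelian gamete per entry of ``queen_idx``.

    ``genotypes`` must already be germline-resolved when per-queen resolution
    is in use; each gamete picks either allele of its queen with probability
    one half, independently.
    """
    side = rng.integers(0, 2, size=queen_idx.shape[0])
    return genotypes[queen_idx, side]


def draw_gamete(
    resolved_genotype: tuple[Allele, Allele] | np.ndarray, rng: np.random.Generator
) -> Allele:
    """Draw a single gamete from one resolved female genotype."""
    pair = np.asarray(resolved_genotype, dtype=np.int8).reshape(1, 2)
    return Allele(int(draw_gametes(pair, np.zeros(1, dtype=np.int64), rng)[0]))


def _disrupted(alleles: np.ndarray) -> np.ndarray:
    # The target gene is destroyed both by drive insertion and by mutagenic
    # (non-functional) end-joining repair; WT and RE copies are functional.
    return (alleles == Allele.GD) | (alleles == Allele.NF)


def female_fertile_array(genotypes: np.ndarray, strategy: Strategy) -> np.ndarray:
    """Fertility of each row of an ``(n, 2)`` female genotype array.

    The target gene is haplo-sufficient: one functional copy (WT or RE) keeps
    a female fertile.  Only female-targeting strategies sterilise females.
    """
    strategy = Strategy(strategy)
    g = np.asarray(genotypes, dtype=np.int8).reshape(-1, 2)
    if strategy not in _FEMALE_TARGETING:
        return np.ones(g.shape[0], dtype=bool)
    return ~(_disrupted(g[:, 0]) & _disrupted(g[:, 1]))


def male_fertile_array(alleles: np.ndarray, strategy: Strategy) -> np.ndarray:
    """Fertility of haploid males: hemizygous GD or NF males are sterile
    under male-targeting strategies, everyone else is fertile."""
    strategy = Strategy(strategy)
    a = np.asarray(alleles, dtype=np.int8)
    if strategy not in _MALE_TARGETING:
        return np.ones(a.shape[0], dtype=bool)
    return ~_disrupted(a)


def classify_female_fertility(
    genotype: tuple[Allele, Allele] | np.ndarray, strategy: Strategy
) -> bool:
    """Whether a single female genotype is fertile under ``strategy``."""
    return bool(female_fertile_array(np.asarray(genotype, dtype=np.int8), strategy)[0])


def classify_male_fertility(allele: Allele | int, strategy: Strategy) -> bool:
    """Whether a haploid male carrying ``allele`` is fertile under ``strategy``."""
    return bool(male_fertile_array(np.asarray([allele], dtype=np.int8), strategy)[0])


def fitness_cost_survival_mask(
    is_carrier: np.ndarray, p_het_mort: float, rng: np.random.Generator
) -> np.ndarray:
    """Survival mask for the pre-mating fitness cost of carrying the drive.

    Carriers die with probability ``p_het_mort``; non-carriers always
    survive.  Applied exactly once per individual, at the mating step.
    """
    is_carrier = np.asarray(is_carrier, dtype=bool)
    if p_het_mort <= 0.0:
        return np.ones(is_carrier.shape[0], dtype=bool)
    return ~(is_carrier & (rng.random(is_carrier.shape[0]) < p_het_mort))


def survives_fitness_cost(
    carrier: tuple[Allele, Allele] | Allele | int | np.ndarray,
    drive: DriveParams,
    rng: np.random.Generator,
) -> bool:
    """Whether one individual (female genotype or male allele) survives the
    pre-mating fitness cost of the drive."""
    alleles = np.atleast_1d(np.asarray(carrier, dtype=np.int8))
    is_carrier = np.array([(alleles == Allele.GD).any()])
    return bool(fitness_cost_survival_mask(is_carrier, drive.p_het_mort, rng)[0])
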