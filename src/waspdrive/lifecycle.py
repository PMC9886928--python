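"""One simulated year of a social wasp population.

The model is discrete-generation: each year the current mated queens produce
gynes (reproductive daughters) and males, the new cohort mates randomly with
polyandry, gynes overwinter, infertile pairings are discarded, and a
logistic density-dependent cull regulates the survivors around the carrying
capacity.  Only females are tracked between years; males exist transiently
within the mating step.

Gynes that fail to find a mate (male mating slots are limited and male
mating numbers are not zero-truncated) are by default retained as
non-reproducing foundresses: they overwinter and compete for nest sites in
the density cull like everyone else, but produce no offspring.  This keeps
the visible population at carrying capacity while a suppression drive
quietly shrinks the reproductive core — set ``unmated_queens="discard"`` to
drop them at the mating step instead.

Populations are stored column-wise in :class:`PopulationState` numpy arrays
so that a year of a hornet-sized population (hundreds of thousands of
offspring) costs a handful of vectorized operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genetics import (
    Allele,
    DriveParams,
    ParameterError,
    Resolution,
    _transform_wt,
    draw_gametes,
    female_fertile_array,
    fitness_cost_survival_mask,
    male_fertile_array,
    resolve_germline_array,
)

__all__ = [
    "MatingDistribution",
    "SpeciesParams",
    "PopulationState",
    "HORNET",
    "PAPER_WASP",
    "species_preset",
    "sample_truncated_poisson",
    "logistic_mean",
    "generate_offspring",
    "mate_population",
    "apply_winter_mortality",
    "remove_infertile_pairings",
    "regulate_density",
    "step_year",
]


@dataclass(frozen=True)
class MatingDistribution:
    """Truncated-Poisson distribution of mating numbers.

    ``lam`` is the untruncated Poisson parameter; the pmf is renormalized
    over the integer support ``{min, ..., max}``.  Female distributions are
    zero-truncated (``min = 1``: a female always finds a mate if one is
    available), male distributions are not (``min = 0``: many males never
    mate).
    """

    lam: float
    min: int
    max: int

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ParameterError(
                f"mating distribution has empty support: min={self.min} > max={self.max}"
            )
        if self.lam < 0:
            raise ParameterError(f"mating rate lambda must be >= 0, got {self.lam}")
        if self.min < 0:
            raise ParameterError(f"mating minimum must be >= 0, got {self.min}")

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Support values and renormalized probabilities."""
        values = np.arange(self.min, self.max + 1)
        weights = stats.poisson.pmf(values, self.lam)
        total = weights.sum()
        if total <= 0.0:
            raise ParameterError(
                f"truncated Poisson(lam={self.lam}) has zero mass on "
                f"[{self.min}, {self.max}]"
            )
        return values, weights / total

    def mean(self) -> float:
        values, probs = self.pmf()
        return float(values @ probs)


def sample_truncated_poisson(
    n: int, lam: float, min: int, max: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. variates from a truncated Poisson distribution.

    The Poisson(``lam``) pmf is renormalized over ``{min, ..., max}``
    (truncation by renormalization; ``lam`` is the untruncated parameter).
    """
    values, probs = MatingDistribution(lam, min, max).pmf()
    if len(values) == 1:
        return np.full(n, values[0], dtype=np.int64)
    cdf = np.cumsum(probs)
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    return values[np.minimum(idx, len(values) - 1)]


@dataclass(frozen=True)
class SpeciesParams:
    """Life-history parameters of one wasp species.

    ``offspring_mean_per_sex`` is the Poisson mean of reproductive offspring
    a queen produces of *each* sex (a 1:1 sex ratio is assumed).  ``K`` is
    the carrying capacity in overwintered queens, enforced by logistic
    density regulation with maximum yearly growth rate ``r_max``.
    """

    offspring_mean_per_sex: float
    winter_mortality: float
    r_max: float
    female_mating: MatingDistribution
    male_mating: MatingDistribution
    K: int = 1000
    name: str = ""

    def __post_init__(self) -> None:
        if self.offspring_mean_per_sex < 0:
            raise ParameterError("offspring_mean_per_sex must be >= 0")
        if not 0.0 <= self.winter_mortality <= 1.0:
            raise ParameterError(
                f"winter_mortality must be a probability in [0, 1], got {self.winter_mortality}"
            )
        if self.r_max <= 0:
            raise ParameterError("r_max must be > 0")
        if self.K < 1:
            raise ParameterError("carrying capacity K must be >= 1")


#: Asian hornet (Vespa velutina nigrithorax): ~300 gynes and 300 males per
#: successful nest, very high overwintering mortality, highly polyandrous
#: queens (zero- and max-truncated Poisson, mean realised demand ~2.6 mates).
HORNET = SpeciesParams(
    offspring_mean_per_sex=300,
    winter_mortality=0.97,
    r_max=10,
    female_mating=MatingDistribution(lam=3.275, min=1, max=4),
    male_mating=MatingDistribution(lam=0.9, min=0, max=3),
    K=1000,
    name="hornet",
)

#: European paper wasp (Polistes dominula): small nests (~20 offspring of
#: each sex), milder winters, near-monandrous queens (realised mating rate
#: between 1 and 1.1).
PAPER_WASP = SpeciesParams(
    offspring_mean_per_sex=20,
    winter_mortality=0.5,
    r_max=10,
    female_mating=MatingDistribution(lam=0.2, min=1, max=2),
    male_mating=MatingDistribution(lam=0.9, min=0, max=3),
    K=1000,
    name="paper_wasp",
)

_PRESETS = {"hornet": HORNET, "paper_wasp": PAPER_WASP}


def species_preset(name: str) -> SpeciesParams:
    """Return the named species preset (``"hornet"`` or ``"paper_wasp"``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown species preset {name!r}; known presets: {sorted(_PRESETS)}"
        ) from None


@dataclass
class PopulationState:
    """Queen population, stored column-wise.

    ``genotypes`` holds the diploid genotype of each queen, ``mate_alleles``
    the haploid allele of each of her stored mates (padded with ``-1``
    beyond ``n_mates``; all ``-1`` for an unmated queen), and
    ``mate_fertile`` whether each mate is fertile under the drive strategy
    in force.  Sperm shares are implicit: at offspring generation every
    fertilised egg picks one of its mother's mates uniformly at random,
    which divides her brood randomly over her mates.
    """

    genotypes: np.ndarray  # (n, 2) int8
    mate_alleles: np.ndarray  # (n, m) int8, -1 padding
    mate_fertile: np.ndarray  # (n, m) bool
    n_mates: np.ndarray  # (n,) int64

    def __len__(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_reproductive(self) -> int:
        """Queens with at least one fertile mate (the productive core)."""
        return int((self.mate_fertile.any(axis=1)).sum())

    def subset(self, keep: np.ndarray) -> "PopulationState":
        return PopulationState(
            genotypes=self.genotypes[keep],
            mate_alleles=self.mate_alleles[keep],
            mate_fertile=self.mate_fertile[keep],
            n_mates=self.n_mates[keep],
        )

    @staticmethod
    def empty(max_mates: int) -> "PopulationState":
        return PopulationState(
            genotypes=np.empty((0, 2), dtype=np.int8),
            mate_alleles=np.empty((0, max_mates), dtype=np.int8),
            mate_fertile=np.empty((0, max_mates), dtype=bool),
            n_mates=np.empty(0, dtype=np.int64),
        )


def generate_offspring(
    state: PopulationState,
    species: SpeciesParams,
    drive: DriveParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce this year's gynes and males from the successfully mated queens.

    Per mated queen, the number of daughters and the number of sons are
    independent Poisson(``offspring_mean_per_sex``) draws; unmated queens
    produce nothing.  Each daughter combines one maternal gamete with the
    sperm of a mate picked uniformly at random among the queen's mates;
    eggs allocated to infertile mates are not produced and not reallocated.
    Sons arise from unfertilised eggs and carry a single maternal gamete.

    Drive dynamics happen here, in the queen's germline: under per-gamete
    resolution (default) every gamete that samples a WT allele of a carrier
    queen is independently exposed to cutting and repair; under per-queen
    resolution each WT allele's fate is decided once per queen before any
    gamete is drawn.

    Returns ``(gynes, males)``: an ``(F, 2)`` genotype array and an ``(M,)``
    allele array.
    """
    nq = len(state)
    if nq == 0:
        return np.empty((0, 2), dtype=np.int8), np.empty(0, dtype=np.int8)

    mated = state.n_mates > 0
    f_counts = rng.poisson(species.offspring_mean_per_sex, nq) * mated
    m_counts = rng.poisson(species.offspring_mean_per_sex, nq) * mated

    per_queen = drive.resolution is Resolution.PER_QUEEN
    if per_queen:
        germline = resolve_germline_array(state.genotypes, drive, rng)
    else:
        germline = state.genotypes
        carrier = (state.genotypes == Allele.GD).any(axis=1)

    # Daughters: random sperm-share allocation over mates; infertile sires
    # produce nothing.
    qidx = np.repeat(np.arange(nq), f_counts)
    mate_pick = (rng.random(qidx.shape[0]) * state.n_mates[qidx]).astype(np.int64)
    sired_ok = state.mate_fertile[qidx, mate_pick]
    sperm = state.mate_alleles[qidx, mate_pick][sired_ok]
    qidx = qidx[sired_ok]
    eggs_f = draw_gametes(germline, qidx, rng)
    if not per_queen:
        cut = carrier[qidx] & (eggs_f == Allele.WT)
        eggs_f = eggs_f.copy()
        eggs_f[cut] = _transform_wt(rng.random(int(cut.sum())), drive)
    gynes = np.stack([eggs_f, sperm], axis=1).astype(np.int8)

    # Sons: unfertilised eggs, one maternal gamete each.
    qidx_m = np.repeat(np.arange(nq), m_counts)
    males = draw_gametes(germline, qidx_m, rng)
    if not per_queen:
        cut = carrier[qidx_m] & (males == Allele.WT)
        males = males.copy()
        males[cut] = _transform_wt(rng.random(int(cut.sum())), drive)
    return gynes, np.asarray(males, dtype=np.int8)


def _repair_duplicate_mates(
    mate_idx: np.ndarray, n_mates: np.ndarray, leftover_pool: np.ndarray
) -> None:
    """Replace duplicate males within a queen's mate list where possible.

    Mating slots are dealt consecutively from a shuffled pool in which a male
    appears once per mating he can perform, so a queen can occasionally be
    dealt the same male twice.  Each duplicate is swapped against an unused
    pool slot holding a male she has not mated; if no such slot exists the
    duplicate is kept (mating the same male twice is then genetically
    equivalent to giving him a double sperm share).
    """
    width = mate_idx.shape[1]
    if width < 2 or mate_idx.shape[0] == 0:
        return
    s = np.sort(mate_idx, axis=1)
    dup_rows = np.nonzero(((s[:, 1:] == s[:, :-1]) & (s[:, 1:] >= 0)).any(axis=1))[0]
    if dup_rows.size == 0:
        return
    # A short slice of the unused pool is ample: duplicates are rare.
    spare = list(leftover_pool[:1024])
    for r in dup_rows:
        row = mate_idx[r]
        k = int(n_mates[r])
        seen: set[int] = set()
        for j in range(k):
            male = int(row[j])
            if male in seen:
                taken = seen | set(int(x) for x in row[j + 1 : k])
                for t in range(len(spare) - 1, -1, -1):
                    cand = int(spare[t])
                    if cand not in taken:
                        spare[t] = male  # hand his slot back
                        row[j] = cand
                        male = cand
                        break
            seen.add(male)


def mate_population(
    gynes: np.ndarray,
    male_alleles: np.ndarray,
    species: SpeciesParams,
    drive: DriveParams,
    rng: np.random.Generator,
    unmated_queens: str = "retain",
) -> PopulationState:
    """Randomly mate this year's gynes with this year's males.

    Drive carriers of both sexes first pay the pre-mating fitness cost
    (``p_het_mort``).  Each surviving female then demands a zero- and
    max-truncated Poisson number of matings and each male offers a
    max-truncated Poisson number of mating slots (zero allowed).  The slots
    are shuffled into a single pool and dealt to females in random order;
    each female receives ``min(demand, remaining slots)`` distinct males
    where possible.  Genotype plays no role in pairing.

    Females left without a mate are retained as unmated queens by default
    (``unmated_queens="retain"``); with ``"discard"`` they are dropped here.
    """
    if unmated_queens not in ("retain", "discard"):
        raise ParameterError(
            f"unmated_queens must be 'retain' or 'discard', got {unmated_queens!r}"
        )
    gynes = np.asarray(gynes, dtype=np.int8).reshape(-1, 2)
    male_alleles = np.asarray(male_alleles, dtype=np.int8)
    max_mates = species.female_mating.max

    if drive.p_het_mort > 0.0:
        keep_f = fitness_cost_survival_mask(
            (gynes == Allele.GD).any(axis=1), drive.p_het_mort, rng
        )
        gynes = gynes[keep_f]
        keep_m = fitness_cost_survival_mask(
            male_alleles == Allele.GD, drive.p_het_mort, rng
        )
        male_alleles = male_alleles[keep_m]

    nf = gynes.shape[0]
    nm = male_alleles.shape[0]
    if nf == 0:
        return PopulationState.empty(max_mates)

    mate_idx = np.full((nf, max_mates), -1, dtype=np.int64)
    n_mates = np.zeros(nf, dtype=np.int64)
    if nm > 0:
        fm, mm = species.female_mating, species.male_mating
        demands = sample_truncated_poisson(nf, fm.lam, fm.min, fm.max, rng)
        capacities = sample_truncated_poisson(nm, mm.lam, mm.min, mm.max, rng)
        pool = np.repeat(np.arange(nm, dtype=np.int64), capacities)
        rng.shuffle(pool)
        if pool.shape[0]:
            order = rng.permutation(nf)
            d = demands[order]
            cum = np.cumsum(d)
            ends = np.minimum(cum, pool.shape[0])
            starts = np.minimum(cum - d, pool.shape[0])
            counts = ends - starts
            n_used = int(ends[-1])
            slot_fem = np.repeat(np.arange(nf), counts)  # row in `order` per slot
            col = np.arange(n_used) - np.repeat(starts, counts)
            mate_idx[order[slot_fem], col] = pool[:n_used]
            n_mates[order] = counts
            _repair_duplicate_mates(mate_idx, n_mates, pool[n_used:])

    valid = mate_idx >= 0
    safe_idx = np.where(valid, mate_idx, 0)
    mate_alleles = np.where(
        valid, male_alleles[safe_idx] if nm else np.int8(-1), np.int8(-1)
    ).astype(np.int8)
    state = PopulationState(
        genotypes=gynes,
        mate_alleles=mate_alleles,
        mate_fertile=valid.copy(),  # fertility is classified after winter
        n_mates=n_mates,
    )
    if unmated_queens == "discard":
        return state.subset(n_mates > 0)
    return state


def apply_winter_mortality(
    queens: PopulationState, winter_mortality: float, rng: np.random.Generator
) -> PopulationState:
    """Uniform overwintering mortality of queens, blind to genotype."""
    if not 0.0 <= winter_mortality <= 1.0:
        raise ParameterError(
            f"winter_mortality must be a probability in [0, 1], got {winter_mortality}"
        )
    n = len(queens)
    if n == 0 or winter_mortality == 0.0:
        return queens
    return queens.subset(rng.random(n) >= winter_mortality)


def remove_infertile_pairings(queens: PopulationState, strategy) -> PopulationState:
    """Discard queens whose colonies are doomed by drive-induced infertility.

    A queen is removed if she is herself infertile under the drive strategy,
    or if she mated but none of her mates is fertile.  A queen with at least
    one fertile mate is retained (any viable sperm can raise workers, though
    eggs allocated to infertile mates are lost), and unmated queens are
    untouched here — they carry no infertile pairing.  This cull happens
    before density-dependent mortality: these foundresses fail too early to
    compete for nest sites.
    """
    n = len(queens)
    if n == 0:
        return queens
    valid = queens.mate_alleles >= 0
    mate_fertile = valid & male_fertile_array(
        np.where(valid, queens.mate_alleles, Allele.WT).ravel(), strategy
    ).reshape(valid.shape)
    unmated = queens.n_mates == 0
    keep = female_fertile_array(queens.genotypes, strategy) & (
        unmated | mate_fertile.any(axis=1)
    )
    out = queens.subset(keep)
    out.mate_fertile = mate_fertile[keep]
    return out


def logistic_mean(n_prev: float, K: float, r_max: float) -> float:
    """Expected queen count from the logistic growth map.

    ``K / (1 + ((K - n_prev) / n_prev) / r_max)``: equals ``K`` at
    ``n_prev = K`` and approaches ``n_prev * r_max`` when ``n_prev << K``.
    """
    if n_prev <= 0:
        return 0.0
    return max(K / (1.0 + ((K - n_prev) / n_prev) / r_max), 0.0)


def regulate_density(
    n_candidates: int,
    n_prev: int,
    species: SpeciesParams,
    rng: np.random.Generator,
    n_cohort: int | None = None,
) -> np.ndarray:
    """Density-dependent survival mask over the candidate queens.

    The target population size is ``N_t ~ Poisson(logistic_mean(n_prev))``
    with ``n_prev`` the queen count of the generation that just ended.  Each
    candidate then survives independently with probability
    ``min(1, N_t / n_cohort)`` — per-queen mortality ``1 - N_t / n_cohort``
    clamped to [0, 1].  ``n_cohort`` is the size of the overwintered female
    cohort the mortality rate is computed against; when omitted it defaults
    to ``n_candidates`` (every female competing is a candidate).
    """
    if n_prev <= 0 or n_candidates == 0:
        return np.zeros(n_candidates, dtype=bool)
    if n_cohort is None:
        n_cohort = n_candidates
    if n_cohort <= 0:
        return np.zeros(n_candidates, dtype=bool)
    n_t = rng.poisson(logistic_mean(n_prev, species.K, species.r_max))
    p_survive = min(1.0, n_t / n_cohort)
    if p_survive >= 1.0:
        return np.ones(n_candidates, dtype=bool)
    return rng.random(n_candidates) < p_survive


def step_year(
    state: PopulationState,
    species: SpeciesParams,
    drive: DriveParams,
    rng: np.random.Generator,
    release_males: np.ndarray | None = None,
    unmated_queens: str = "retain",
) -> PopulationState:
    """Advance the population by one year.

    Pipeline order: offspring generation -> mating (with any released drive
    males injected into the pool) -> winter mortality -> removal of
    infertile pairings -> density-dependent regulation.  The density
    mortality rate is computed against the whole overwintered female cohort
    (the foundresses competing for nest sites), and applied to the
    candidates that survive the infertility cull.  Returns next year's
    queens; an empty result marks complete suppression.
    """
    n_prev = len(state)
    gynes, males = generate_offspring(state, species, drive, rng)
    if release_males is not None and len(release_males):
        males = np.concatenate([males, np.asarray(release_males, dtype=np.int8)])
    mated = mate_population(gynes, males, species, drive, rng, unmated_queens)
    overwintered = apply_winter_mortality(mated, species.winter_mortality, rng)
    candidates = remove_infertile_pairings(overwintered, drive.strategy)
    keep = regulate_density(
        len(candidates), n_prev, species, rng, n_cohort=len(overwintered)
    )
    return candidates.subset(keep)
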