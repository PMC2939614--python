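"""Forward-time Wright-Fisher engine.

Implements demography schedules, diffusion-style λ-scaling, map-based
recombination (Haldane), symmetric diallelic mutation, fitness-weighted
mating, stepping-stone and continuous-gene-flow migration, and assortative
admixture with ancestry tracking.

Scaling follows the diffusion argument: a run of size N for t generations is
replaced by a run of size N/λ for t/λ generations with λ-magnified mutation,
recombination and selection intensities.  The approximation is only valid
for weak, additive forces; :func:`scale_config` applies the additive form
w' = 1 + λ(w - 1) to fitness and caps scaled recombination at 1/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .popmodel import FEMALE, MALE, Individual, Locus, Population, SubPopulation

logger = logging.getLogger(__name__)

__all__ = [
    "DemographicModel",
    "FitnessTriple",
    "SelectionModel",
    "MigrationModel",
    "AdmixtureConfig",
    "EvolutionConfig",
    "SummaryLog",
    "size_schedule",
    "scale_config",
    "interval_recomb_probs",
    "recombine_gamete",
    "mutate_haplotype",
    "genotype_fitness",
    "random_mating_generation",
    "migrate",
    "admixture_generation",
    "evolve",
]


@dataclass(frozen=True)
class DemographicModel:
    """Total population size over time.

    ``schedule`` is one of ``linear`` (the same number of individuals added
    each generation), ``exponential``, or ``constant``.  ``sizes``, if given,
    is an explicit per-generation size list overriding the analytic schedule
    (used by :func:`scale_config`).
    """

    N0: int
    NT: int
    T: int
    schedule: str = "linear"
    sizes: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.N0 < 1 or self.NT < 1:
            raise ValueError("population sizes must be >= 1")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.schedule not in ("linear", "exponential", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass(frozen=True)
class FitnessTriple:
    """Relative fitness of genotypes with 0, 1, 2 copies of the alt allele."""

    w11: float = 1.0
    w12: float = 1.0
    w22: float = 1.0

    def __post_init__(self):
        if min(self.w11, self.w12, self.w22) < 0:
            raise ValueError("fitness values must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.w11, self.w12, self.w22], dtype=np.float64)

    def is_neutral(self) -> bool:
        return self.w11 == self.w12 == self.w22

    def is_additive(self, tol: float = 1e-9) -> bool:
        """Heterozygote fitness exactly intermediate (required for λ-scaling)."""
        return abs(2 * self.w12 - (self.w11 + self.w22)) <= tol


@dataclass(frozen=True)
class SelectionModel:
    """Multiplicative multilocus viability selection."""

    loci: tuple[tuple[int, FitnessTriple], ...]

    def __post_init__(self):
        idx = [l for l, _ in self.loci]
        if len(set(idx)) != len(idx):
            raise ValueError("selected locus indices must be distinct")


@dataclass(frozen=True)
class MigrationModel:
    """Stepping-stone exchange or one-way continuous gene flow.

    Stepping stone moves ``round(m * N_i)`` uniformly chosen individuals from
    each deme to each neighbour on a 1-D chain, reciprocally and
    simultaneously.  Gene flow replaces ``round(p * N_sink)`` uniformly
    chosen sink individuals per generation with copies of individuals drawn
    (with replacement) from the source.
    """

    kind: str  # "stepping_stone" | "gene_flow"
    m: float = 0.0
    p: float = 0.0
    source: int = 0
    sink: int = 1
    duration: int | None = None

    def __post_init__(self):
        if self.kind not in ("stepping_stone", "gene_flow"):
            raise ValueError(f"unknown migration kind {self.kind!r}")
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ValueError("migration fractions must lie in [0, 1]")


@dataclass(frozen=True)
class AdmixtureConfig:
    """Positive assortative mating by ancestry group.

    A fraction ``assort_within`` of matings draw both parents from one
    ancestry group (ancestry >= ``threshold`` vs below); the rest draw both
    parents from the whole population.
    """

    assort_within: float = 0.8
    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.assort_within <= 1.0:
            raise ValueError("assort_within must lie in [0, 1]")


@dataclass(frozen=True)
class EvolutionConfig:
    """Everything that determines a run given a seed."""

    demographic: DemographicModel
    mu: float = 0.0
    selection: SelectionModel | None = None
    migration: MigrationModel | None = None
    admixture: AdmixtureConfig | None = None
    lam: float = 1.0
    recomb_scale: float = 1.0  # set by scale_config; multiplies interval probs
    seed: int = 0
    summary_every: int = 10
    watched_loci: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.lam < 1.0:
            raise ValueError("scaling factor must be >= 1")


@dataclass
class SummaryLog:
    """Per-checkpoint record of sizes and watched-locus frequencies."""

    records: list[dict] = field(default_factory=list)

    def add(self, generation: int, pop: Population, watched: tuple[int, ...]):
        from .popmodel import allele_frequency

        for s, sp in enumerate(pop.subpops):
            rec = {"generation": generation, "subpop": s, "size": sp.size}
            for l in watched:
                rec[f"freq_{l}"] = (
                    allele_frequency(pop, l, s) if sp.size else float("nan")
                )
            self.records.append(rec)

    def write_tsv(self, path) -> None:
        if not self.records:
            return
        cols = list(self.records[0])
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for rec in self.records:
                fh.write("\t".join(str(rec[c]) for c in cols) + "\n")


# ---------------------------------------------------------------- demography


def size_schedule(dem: DemographicModel) -> list[int]:
    """Per-generation total sizes N_0 .. N_T (length T + 1), endpoints exact."""
    if dem.sizes is not None:
        return list(dem.sizes)
    N0, NT, T = dem.N0, dem.NT, dem.T
    if T == 0:
        if N0 != NT:
            raise ValueError("T=0 but N0 != NT")
        return [N0]
    if dem.schedule == "constant":
        if N0 != NT:
            raise ValueError("constant schedule requires N0 == NT")
        return [N0] * (T + 1)
    t = np.arange(T + 1)
    if dem.schedule == "linear":
        sizes = np.round(N0 + t * (NT - N0) / T)
    else:  # exponential
        sizes = np.round(N0 * (NT / N0) ** (t / T))
    return [int(s) for s in sizes]


def scale_config(cfg: EvolutionConfig) -> EvolutionConfig:
    """Fold the scaling factor λ into an executable λ=1 configuration.

    The schedule is shortened to round(T/λ) generations with sizes
    round(N_{round(t'·λ)}/λ); mutation becomes λ·μ; per-interval recombination
    probabilities are multiplied by λ (capped at 1/2 at transmission time);
    fitness deviations become w' = 1 + λ(w-1), clipped at 0 with a warning.
    """
    lam = cfg.lam
    if lam == 1.0:
        return cfg
    full = size_schedule(cfg.demographic)
    T = len(full) - 1
    T_s = max(1, round(T / lam))
    scaled_sizes = tuple(
        max(1, round(full[min(round(t * lam), T)] / lam)) for t in range(T_s + 1)
    )
    dem = replace(
        cfg.demographic,
        N0=scaled_sizes[0],
        NT=scaled_sizes[-1],
        T=T_s,
        sizes=scaled_sizes,
    )
    sel = cfg.selection
    if sel is not None:
        scaled = []
        for l, f in sel.loci:
            w = 1.0 + lam * (f.as_array() - 1.0)
            if (w < 0).any():
                logger.warning(
                    "scaled fitness at locus %d fell below 0; clipped", l
                )
                w = np.clip(w, 0.0, None)
            scaled.append((l, FitnessTriple(*w)))
        sel = SelectionModel(tuple(scaled))
    return replace(
        cfg,
        demographic=dem,
        mu=min(1.0, lam * cfg.mu),
        selection=sel,
        lam=1.0,
        recomb_scale=cfg.recomb_scale * lam,
    )


# ------------------------------------------------------------- transmission


def interval_recomb_probs(loci: list[Locus], scale: float = 1.0) -> np.ndarray:
    """Recombination probability for each of the L-1 adjacent intervals.

    Within a chromosome Haldane's map function converts the cM interval to a
    recombination fraction, r = (1 - exp(-2d)) / 2 with d in Morgans; a
    chromosome boundary recombines freely (r = 1/2).  ``scale`` multiplies
    the probability (not the distance) and the result is capped at 1/2.
    """
    L = len(loci)
    r = np.empty(max(L - 1, 0), dtype=np.float64)
    for i in range(L - 1):
        a, b = loci[i], loci[i + 1]
        if a.chrom != b.chrom:
            r[i] = 0.5
        else:
            d = (b.cm - a.cm) / 100.0  # Morgans
            r[i] = 0.5 * (1.0 - math.exp(-2.0 * d))
    return np.minimum(scale * r, 0.5)


def _gametes_for(
    haps: np.ndarray, parents: np.ndarray, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per parent index (vectorised meiosis).

    ``haps`` is the (2n, L) subpopulation matrix, ``parents`` the individual
    indices.  The copied strand starts from a fair coin and switches at
    interval i with probability probs[i].
    """
    k = len(parents)
    L = haps.shape[1]
    start = rng.integers(0, 2, size=(k, 1), dtype=np.int8)
    if L > 1:
        switches = (rng.random((k, L - 1)) < probs).astype(np.int8)
        strand = (start + np.cumsum(switches, axis=1, dtype=np.int32)[:, :] % 2) % 2
        strand = np.concatenate([start, strand], axis=1)
    else:
        strand = start
    h0 = haps[2 * parents]
    h1 = haps[2 * parents + 1]
    return np.where(strand == 0, h0, h1)


def recombine_gamete(
    ind: Individual, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Standard meiosis for a single individual; returns the recombinant."""
    haps = np.vstack([ind.hap0, ind.hap1])
    return _gametes_for(haps, np.array([0]), probs, rng)[0]


def mutate_haplotype(
    hap: np.ndarray, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric diallelic mutation: each site flips 0<->1 with probability mu."""
    if mu == 0.0:
        return hap
    flips = rng.random(hap.shape) < mu
    return np.bitwise_xor(hap, flips.astype(np.uint8))


# ---------------------------------------------------------------- selection


def _fitness_vector(sp: SubPopulation, sel: SelectionModel | None) -> np.ndarray:
    """Relative fitness of every individual (multiplicative across loci)."""
    n = sp.size
    w = np.ones(n, dtype=np.float64)
    if sel is None:
        return w
    for l, triple in sel.loci:
        g = sp.genotype(l)
        w *= triple.as_array()[g]
    return w


def genotype_fitness(ind: Individual, sel: SelectionModel | None) -> float:
    """Whole-genotype relative fitness w (product over selected loci)."""
    if sel is None:
        return 1.0
    w = 1.0
    for l, triple in sel.loci:
        w *= triple.as_array()[ind.genotype(l)]
    return float(w)


def _parent_pools(
    sp: SubPopulation, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(father pool, father probs, mother pool, mother probs).

    Falls back to ignoring sex (both pools = everyone) when a subpopulation
    lacks one sex, which can happen at tiny scaled sizes.
    """
    males = np.flatnonzero(sp.sex == MALE)
    females = np.flatnonzero(sp.sex == FEMALE)
    if len(males) == 0 or len(females) == 0:
        logger.warning("subpopulation lacks one sex; mating ignores sex")
        males = females = np.arange(sp.size)
    wm = w[males]
    wf = w[females]
    sm, sf = wm.sum(), wf.sum()
    if sm <= 0 or sf <= 0:
        raise ValueError("total parental fitness is zero; no viable parents")
    return males, wm / sm, females, wf / sf


def _make_offspring(
    sp: SubPopulation,
    fathers: np.ndarray,
    mothers: np.ndarray,
    probs: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> SubPopulation:
    """Build a new subpopulation from chosen parent index arrays."""
    n = len(fathers)
    child = SubPopulation.empty(n, sp.haps.shape[1])
    gf = _gametes_for(sp.haps, fathers, probs, rng)
    gm = _gametes_for(sp.haps, mothers, probs, rng)
    if mu > 0.0:
        gf = mutate_haplotype(gf, mu, rng)
        gm = mutate_haplotype(gm, mu, rng)
    child.haps[0::2] = gf
    child.haps[1::2] = gm
    child.sex[:] = rng.integers(0, 2, size=n)
    child.ancestry[:] = 0.5 * (sp.ancestry[fathers] + sp.ancestry[mothers])
    return child


def random_mating_generation(
    pop: Population,
    target_sizes: list[int],
    sel: SelectionModel | None,
    probs: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> Population:
    """One generation of fitness-weighted random mating within subpopulations.

    For each offspring a father and a mother are drawn independently with
    replacement, with probability proportional to fitness; the child receives
    one recombined and mutated gamete from each, a fair-coin sex, and the
    mean of the parental ancestries.
    """
    if len(target_sizes) != len(pop.subpops):
        raise ValueError("one target size per subpopulation required")
    new_subpops = []
    for sp, n in zip(pop.subpops, target_sizes):
        if n < 1:
            raise ValueError("target subpopulation size must be >= 1")
        if sp.size == 0:
            raise ValueError("cannot breed from an empty subpopulation")
        w = _fitness_vector(sp, sel)
        males, pm, females, pf = _parent_pools(sp, w)
        if sel is None:  # uniform parent choice, skip the weighted sampler
            fathers = males[rng.integers(0, len(males), size=n)]
            mothers = females[rng.integers(0, len(females), size=n)]
        else:
            fathers = rng.choice(males, size=n, p=pm)
            mothers = rng.choice(females, size=n, p=pf)
        new_subpops.append(_make_offspring(sp, fathers, mothers, probs, mu, rng))
    return Population(new_subpops, pop.loci, pop.generation + 1, pop.rng_state)


# ---------------------------------------------------------------- migration


def migrate(
    pop: Population, mig: MigrationModel, rng: np.random.Generator
) -> Population:
    """Apply one generation of migration; returns a new Population."""
    if len(pop.subpops) < 2:
        raise ValueError("migration requires at least two subpopulations")
    if mig.kind == "stepping_stone":
        return _stepping_stone(pop, mig.m, rng)
    return _gene_flow(pop, mig.p, mig.source, mig.sink, rng)


def _stepping_stone(pop: Population, m: float, rng) -> Population:
    if m == 0.0:
        return pop
    k = len(pop.subpops)
    # choose emigrants from a frozen pre-migration state, move simultaneously
    leaving: list[dict[int, np.ndarray]] = [dict() for _ in range(k)]
    for i, sp in enumerate(pop.subpops):
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < k]
        n_mig = round(m * sp.size)
        if n_mig == 0:
            logger.info("stepping stone: deme %d sends no migrants (m*N < 0.5)", i)
            continue
        n_mig = min(n_mig, sp.size // max(len(neighbours), 1))
        pool = rng.permutation(sp.size)
        off = 0
        for j in neighbours:
            leaving[i][j] = pool[off : off + n_mig]
            off += n_mig
    new_subpops = []
    for i, sp in enumerate(pop.subpops):
        gone = (
            np.concatenate(list(leaving[i].values()))
            if leaving[i]
            else np.array([], dtype=np.int64)
        )
        stay = np.setdiff1d(np.arange(sp.size), gone)
        parts = [_take(sp, stay)]
        for j in range(k):
            if i in leaving[j]:
                parts.append(_take(pop.subpops[j], leaving[j][i]))
        new_subpops.append(_concat(parts))
    return Population(new_subpops, pop.loci, pop.generation, pop.rng_state)


def _gene_flow(pop: Population, p: float, source: int, sink: int, rng) -> Population:
    src = pop.subpops[source]
    snk = pop.subpops[sink]
    n_mig = round(p * snk.size)
    if n_mig == 0:
        logger.info("gene flow: p*N < 0.5, no migrants this generation")
        return pop
    displaced = rng.choice(snk.size, size=n_mig, replace=False)
    migrants = rng.choice(src.size, size=n_mig, replace=True)
    new_snk = snk.copy()
    for arr, sarr in (
        (new_snk.sex, src.sex),
        (new_snk.ancestry, src.ancestry),
        (new_snk.affected, src.affected),
        (new_snk.env, src.env),
    ):
        arr[displaced] = sarr[migrants]
    hap_rows = np.empty(2 * n_mig, dtype=np.int64)
    hap_rows[0::2] = 2 * displaced
    hap_rows[1::2] = 2 * displaced + 1
    src_rows = np.empty(2 * n_mig, dtype=np.int64)
    src_rows[0::2] = 2 * migrants
    src_rows[1::2] = 2 * migrants + 1
    new_snk.haps[hap_rows] = src.haps[src_rows]
    subpops = list(pop.subpops)
    subpops[sink] = new_snk
    return Population(subpops, pop.loci, pop.generation, pop.rng_state)


def _take(sp: SubPopulation, idx: np.ndarray) -> SubPopulation:
    rows = np.empty(2 * len(idx), dtype=np.int64)
    rows[0::2] = 2 * idx
    rows[1::2] = 2 * idx + 1
    return SubPopulation(
        sp.haps[rows], sp.sex[idx], sp.ancestry[idx], sp.affected[idx], sp.env[idx]
    )


def _concat(parts: list[SubPopulation]) -> SubPopulation:
    return SubPopulation(
        np.vstack([p.haps for p in parts]),
        np.concatenate([p.sex for p in parts]),
        np.concatenate([p.ancestry for p in parts]),
        np.concatenate([p.affected for p in parts]),
        np.concatenate([p.env for p in parts]),
    )


# ----------------------------------------------------------------- admixture


def admixture_generation(
    pop: Population,
    adm: AdmixtureConfig,
    target_size: int,
    probs: np.ndarray,
    mu: float,
    rng: np.random.Generator,
    sel: SelectionModel | None = None,
) -> Population:
    """One generation of assortative mating by ancestry group.

    With probability ``assort_within`` a mating draws both parents
    (fitness-weighted) from the ancestry group of a uniformly chosen index
    parent; otherwise both parents come from the whole population.  Child
    ancestry is the parental mean, so mating alone conserves the population
    mean ancestry in expectation.
    """
    if len(pop.subpops) != 1:
        raise ValueError("admixture mating expects a single merged subpopulation")
    sp = pop.subpops[0]
    w = _fitness_vector(sp, sel)
    hi = np.flatnonzero(sp.ancestry >= adm.threshold)
    lo = np.flatnonzero(sp.ancestry < adm.threshold)
    if len(hi) == 0 or len(lo) == 0:
        logger.warning("one ancestry group is empty; all matings population-wide")
        within = np.zeros(target_size, dtype=bool)
    else:
        within = rng.random(target_size) < adm.assort_within
    fathers = np.empty(target_size, dtype=np.int64)
    mothers = np.empty(target_size, dtype=np.int64)
    n_within = int(within.sum())
    if n_within:
        # index parent uniform; its group supplies both parents
        idx_parent = rng.integers(0, sp.size, size=n_within)
        in_hi = sp.ancestry[idx_parent] >= adm.threshold
        slots = np.flatnonzero(within)
        for grp, members in ((True, hi), (False, lo)):
            sl = slots[in_hi == grp]
            if len(sl) == 0:
                continue
            pw = w[members]
            pw = pw / pw.sum()
            fathers[sl] = rng.choice(members, size=len(sl), p=pw)
            mothers[sl] = rng.choice(members, size=len(sl), p=pw)
    n_global = target_size - n_within
    if n_global:
        slots = np.flatnonzero(~within)
        pw = w / w.sum()
        fathers[slots] = rng.choice(sp.size, size=n_global, p=pw)
        mothers[slots] = rng.choice(sp.size, size=n_global, p=pw)
    child = _make_offspring(sp, fathers, mothers, probs, mu, rng)
    return Population([child], pop.loci, pop.generation + 1, pop.rng_state)


# ------------------------------------------------------------------- evolve


def _split_total(total: int, fractions: np.ndarray) -> list[int]:
    """Largest-remainder apportionment of a total size across subpopulations."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return [int(max(b, 1)) for b in base]


def evolve(
    pop: Population,
    cfg: EvolutionConfig,
    controlled=None,
) -> tuple[Population, SummaryLog]:
    """Run the configured number of generations and return (population, log).

    Each generation chains migration (if configured) and one mating step:
    controlled mating when a ``controlled`` hook is given (see the trajectory
    module), assortative admixture mating when ``cfg.admixture`` is set, and
    fitness-weighted random mating otherwise.  Fully reproducible from
    ``cfg.seed``; ``scale_config`` must already have been applied (λ = 1).

    The ``controlled`` hook has signature
    ``controlled(pop, generation_index, target_size, probs, mu, sel, rng)``
    and returns the offspring Population.
    """
    if cfg.lam != 1.0:
        raise ValueError("apply scale_config before evolving (lam must be 1)")
    sizes = size_schedule(cfg.demographic)
    T = len(sizes) - 1
    if any(s <= 0 for s in sizes):
        raise ValueError("schedule contains a non-positive population size")
    probs = interval_recomb_probs(pop.loci, scale=cfg.recomb_scale)
    root = np.random.SeedSequence(cfg.seed)
    gen_seeds = root.spawn(max(T, 1))
    log = SummaryLog()
    frac = np.array([sp.size for sp in pop.subpops], dtype=np.float64)
    frac = frac / frac.sum()
    log.add(pop.generation, pop, cfg.watched_loci)
    for t in range(T):
        rng = np.random.default_rng(gen_seeds[t])
        if cfg.migration is not None and len(pop.subpops) > 1:
            dur = cfg.migration.duration
            if dur is None or t < dur:
                pop = migrate(pop, cfg.migration, rng)
        n_next = sizes[t + 1]
        if controlled is not None:
            pop = controlled(pop, t, n_next, probs, cfg.mu, cfg.selection, rng)
        elif cfg.admixture is not None:
            pop = admixture_generation(
                pop, cfg.admixture, n_next, probs, cfg.mu, rng, cfg.selection
            )
        else:
            targets = (
                [n_next]
                if len(pop.subpops) == 1
                else _split_total(n_next, frac)
            )
            pop = random_mating_generation(
                pop, targets, cfg.selection, probs, cfg.mu, rng
            )
        if (t + 1) % cfg.summary_every == 0 or t + 1 == T:
            log.add(pop.generation, pop, cfg.watched_loci)
        if (t + 1) % 100 == 0:
            logger.info("generation %d / %d, sizes %s", t + 1, T, pop.sizes)
    pop.rng_state = {"seed": cfg.seed, "generations": T}
    return pop, log
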