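"""Core data model: loci, haplotype panels, individuals and populations.

Haplotypes are stored as dense ``uint8`` matrices with alleles coded 0/1
(1 = alternate allele of the input panel).  A :class:`Population` keeps one
matrix per subpopulation with two consecutive rows per diploid individual,
which lets the mating engine operate on whole generations with vectorised
numpy arithmetic instead of per-individual Python loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MALE = 0
FEMALE = 1

__all__ = [
    "Locus",
    "HaplotypePanel",
    "Individual",
    "SubPopulation",
    "Population",
    "allele_frequency",
    "select_markers",
    "initialize_population",
]


@dataclass(frozen=True)
class Locus:
    """A biallelic marker.

    Parameters
    ----------
    name : marker identifier (e.g. an rs number).
    chrom : chromosome label.
    pos_bp : physical position, 1-based basepairs.
    cm : cumulative genetic position in centimorgans.
    index : 0-based column index into the haplotype matrix.
    alleles : optional (ref, alt) letters kept as metadata only.
    """

    name: str
    chrom: str
    pos_bp: int
    cm: float = 0.0
    index: int = 0
    alleles: tuple[str, str] = ("A", "B")


def _check_loci(loci: list[Locus]) -> None:
    for a, b in zip(loci, loci[1:]):
        if a.chrom == b.chrom:
            if b.pos_bp <= a.pos_bp:
                raise ValueError(
                    f"positions not strictly increasing on {a.chrom}: "
                    f"{a.pos_bp} then {b.pos_bp}"
                )
            if b.cm < a.cm:
                raise ValueError(
                    f"genetic positions decrease on {a.chrom}: {a.cm} then {b.cm}"
                )


@dataclass
class HaplotypePanel:
    """Phased haplotypes plus locus metadata; the seed of every simulation.

    ``haplotypes`` has one row per haplotype (H rows, L columns); consecutive
    row pairs (2i, 2i+1) belong to diploid source individual ``sample_ids[i]``.
    """

    loci: list[Locus]
    haplotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.loci):
            raise ValueError(
                f"{self.haplotypes.shape[1]} haplotype columns for "
                f"{len(self.loci)} loci"
            )
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be coded 0/1")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.haplotypes.shape[0] // 2)]
        _check_loci(self.loci)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per locus (exact integer counts, one
        correctly-rounded division)."""
        s = self.haplotypes.sum(axis=0, dtype=np.int64)
        H = self.haplotypes.shape[0]
        return np.minimum(s, H - s) / H

    def _reindexed(self, keep: np.ndarray) -> "HaplotypePanel":
        loci = [
            replace(loc, index=i) for i, loc in enumerate(self.loci[j] for j in keep)
        ]
        return HaplotypePanel(loci, self.haplotypes[:, keep], list(self.sample_ids))


@dataclass
class SubPopulation:
    """Array-backed storage for the individuals of one subpopulation."""

    haps: np.ndarray  # (2n, L) uint8
    sex: np.ndarray  # (n,) uint8, MALE/FEMALE
    ancestry: np.ndarray  # (n,) float64 in [0, 1]
    affected: np.ndarray  # (n,) int8: -1 unassigned, 0 unaffected, 1 affected
    env: np.ndarray  # (n,) int8: -1 unset, else 0/1 environmental exposure

    @classmethod
    def empty(cls, n: int, n_loci: int) -> "SubPopulation":
        return cls(
            haps=np.zeros((2 * n, n_loci), dtype=np.uint8),
            sex=np.zeros(n, dtype=np.uint8),
            ancestry=np.zeros(n, dtype=np.float64),
            affected=np.full(n, -1, dtype=np.int8),
            env=np.full(n, -1, dtype=np.int8),
        )

    @property
    def size(self) -> int:
        return len(self.sex)

    def genotype(self, locus_index: int) -> np.ndarray:
        """Alt-allele count (0/1/2) per individual at one locus."""
        return (
            self.haps[0::2, locus_index].astype(np.int64)
            + self.haps[1::2, locus_index]
        )

    def copy(self) -> "SubPopulation":
        return SubPopulation(
            self.haps.copy(),
            self.sex.copy(),
            self.ancestry.copy(),
            self.affected.copy(),
            self.env.copy(),
        )


class Individual:
    """Read/write view of a single diploid individual within a subpopulation."""

    def __init__(self, subpop: SubPopulation, i: int):
        self._sp = subpop
        self._i = i

    @property
    def hap0(self) -> np.ndarray:
        return self._sp.haps[2 * self._i]

    @property
    def hap1(self) -> np.ndarray:
        return self._sp.haps[2 * self._i + 1]

    @property
    def sex(self) -> int:
        return int(self._sp.sex[self._i])

    @property
    def ancestry(self) -> float:
        return float(self._sp.ancestry[self._i])

    @property
    def affected(self):
        a = int(self._sp.affected[self._i])
        return None if a < 0 else bool(a)

    def genotype(self, locus_index: int) -> int:
        return int(self.hap0[locus_index]) + int(self.hap1[locus_index])


@dataclass
class Population:
    """Diploid individuals in ordered subpopulations; the evolving state."""

    subpops: list[SubPopulation]
    loci: list[Locus]
    generation: int = 0
    rng_state: dict | None = None

    @property
    def size(self) -> int:
        return sum(sp.size for sp in self.subpops)

    @property
    def sizes(self) -> list[int]:
        return [sp.size for sp in self.subpops]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def individual(self, subpop: int, i: int) -> Individual:
        return Individual(self.subpops[subpop], i)

    def all_haplotypes(self) -> np.ndarray:
        """Stacked (2N, L) haplotype matrix over all subpopulations."""
        return np.vstack([sp.haps for sp in self.subpops])

    def merged(self) -> "Population":
        """Single-subpopulation copy with all individuals concatenated."""
        sp = SubPopulation(
            np.vstack([s.haps for s in self.subpops]),
            np.concatenate([s.sex for s in self.subpops]),
            np.concatenate([s.ancestry for s in self.subpops]),
            np.concatenate([s.affected for s in self.subpops]),
            np.concatenate([s.env for s in self.subpops]),
        )
        return Population([sp], self.loci, self.generation, self.rng_state)

    def copy(self) -> "Population":
        return Population(
            [sp.copy() for sp in self.subpops],
            list(self.loci),
            self.generation,
            dict(self.rng_state) if self.rng_state else None,
        )


def allele_frequency(
    pop: Population, locus_index: int, subpop: int | None = None
) -> float:
    """Frequency of allele 1 at ``locus_index`` over the chosen scope.

    Raises ``ValueError`` on an empty scope rather than returning 0/0.
    """
    if not 0 <= locus_index < pop.n_loci:
        raise IndexError(f"locus index {locus_index} out of range")
    if subpop is None:
        haps = pop.all_haplotypes()
    else:
        haps = pop.subpops[subpop].haps
    if haps.shape[0] == 0:
        raise ValueError("allele frequency of an empty population is undefined")
    return float(haps[:, locus_index].mean())


def select_markers(
    panel: HaplotypePanel,
    region: tuple[str, int, int] | None = None,
    maf_min: float | None = None,
    keep_names: list[str] | None = None,
    max_markers: int | None = None,
) -> HaplotypePanel:
    """Filter panel loci by region, minor allele frequency and/or name.

    The region filter is a closed interval on 1-based physical positions
    (both endpoints included); the MAF filter keeps loci with minor-allele
    frequency >= ``maf_min``.  Filters compose; locus order is preserved and
    haplotype rows are untouched.  An empty result warns but is not an error.
    """
    keep = np.ones(panel.n_loci, dtype=bool)
    if region is not None:
        chrom, start, end = region
        for j, loc in enumerate(panel.loci):
            keep[j] &= loc.chrom == str(chrom) and start <= loc.pos_bp <= end
    if maf_min is not None:
        keep &= panel.maf() >= maf_min
    if keep_names is not None:
        names = set(keep_names)
        for j, loc in enumerate(panel.loci):
            keep[j] &= loc.name in names
    idx = np.flatnonzero(keep)
    if max_markers is not None:
        idx = idx[:max_markers]
    if idx.size == 0:
        warnings.warn("marker selection produced an empty panel", stacklevel=2)
    return panel._reindexed(idx)


def initialize_population(
    panel: HaplotypePanel, copies: int = 1, ancestry: float = 0.0
) -> Population:
    """Build a generation-0 diploid population from a phased panel.

    Each source individual (one consecutive haplotype row pair) becomes
    ``copies`` identical diploid individuals carrying its two phased
    haplotypes, so every per-locus allele frequency of the panel is preserved
    exactly.  Sexes alternate male/female in construction order so both sexes
    always exist; ancestry is initialised to ``ancestry`` for everyone.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    h = panel.n_haplotypes
    if h % 2 != 0:
        raise ValueError(f"panel has an odd number of haplotypes ({h}); cannot pair")
    n_src = h // 2
    n = n_src * copies
    sp = SubPopulation.empty(n, panel.n_loci)
    # individual order: all copies of source 0, then source 1, ...
    src = np.repeat(np.arange(n_src), copies)
    sp.haps[0::2] = panel.haplotypes[2 * src]
    sp.haps[1::2] = panel.haplotypes[2 * src + 1]
    sp.sex[:] = np.arange(n) % 2  # alternate MALE, FEMALE
    sp.ancestry[:] = ancestry
    return Population([sp], list(panel.loci), generation=0)
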