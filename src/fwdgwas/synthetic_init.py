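"""Synthetic haplotype panels with human-like block structure.

The generator builds a mosaic-of-blocks panel: loci are partitioned into
haplotype blocks of geometric length, each block carries a small set of
founder haplotypes drawn from a shared block-frequency distribution, and
every output haplotype chains one founder haplotype per block,
independently across blocks.  This forces the two properties the forward
simulator relies on — strong within-block linkage disequilibrium with near
independence between blocks, and a minor-allele-frequency floor — without
claiming genealogical realism.  The companion genetic map puts a hotspot
rate between blocks and a low background rate inside them, emulating the
fine-scale recombination landscape that concentrates crossovers at block
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GeneticMapTable
from .popmodel import HaplotypePanel, Locus

__all__ = ["SyntheticPanelSpec", "generate_panel"]


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Parameters of the block-mosaic panel generator.

    Defaults emulate the scale of a dense SNP panel: ~2 kb marker spacing,
    blocks of ~10 markers with 4 distinct haplotypes each, and a 0.05 MAF
    floor (the usual GWAS marker-selection threshold).
    """

    n_haplotypes: int = 200
    n_loci: int = 200
    block_len: float = 10.0
    n_block_haps: int = 4
    maf_min: float = 0.05
    spacing_bp: int = 2000
    hotspot_rate: float = 10.0  # cM/Mb at block boundaries
    background_rate: float = 0.1  # cM/Mb inside blocks
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self):
        if self.n_haplotypes % 2 != 0:
            raise ValueError("n_haplotypes must be even (paired into diploids)")
        if self.n_block_haps < 2:
            raise ValueError("need at least two distinct haplotypes per block")
        if not 0.0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in (0, 0.5]")


def _block_lengths(spec: SyntheticPanelSpec, rng) -> list[int]:
    lengths = []
    left = spec.n_loci
    while left > 0:
        ln = min(int(rng.geometric(1.0 / spec.block_len)), left)
        lengths.append(ln)
        left -= ln
    return lengths


def _draw_block(
    ln: int, spec: SyntheticPanelSpec, rng, max_block_tries: int = 100,
    max_col_tries: int = 200,
) -> np.ndarray:
    """Haplotype rows (H x ln) of one block.

    Block haplotype frequencies come from a symmetric Dirichlet(1); each of
    the H output rows picks one founder.  Founder allele columns are
    resampled until the *realised* MAF of every locus clears the floor;
    if the realised founder usage makes that impossible (one founder
    carries nearly everyone), the whole block is redrawn, and after bounded
    retries the constraint is declared infeasible.
    """
    k = spec.n_block_haps
    H = spec.n_haplotypes
    # integer allele-count window equivalent to the MAF floor, so the
    # emitted matrix satisfies it exactly (no float-summation slack)
    c_min = int(np.ceil(spec.maf_min * H - 1e-9))
    c_max = H - c_min
    for _ in range(max_block_tries):
        freqs = rng.dirichlet(np.ones(k))
        choice = rng.choice(k, size=H, p=freqs)
        counts = np.bincount(choice, minlength=k)
        founders = np.empty((k, ln), dtype=np.uint8)
        ok = True
        for l in range(ln):
            for _ in range(max_col_tries):
                col = rng.integers(0, 2, size=k, dtype=np.uint8)
                c = int(counts @ col)
                if c_min <= c <= c_max:
                    founders[:, l] = col
                    break
            else:
                ok = False
                break
        if ok:
            return founders[choice]
    raise ValueError(
        f"cannot satisfy MAF >= {spec.maf_min} with {k} block haplotypes "
        f"after {max_block_tries} block redraws; increase n_block_haps or "
        "lower maf_min"
    )


def generate_panel(
    spec: SyntheticPanelSpec,
) -> tuple[HaplotypePanel, GeneticMapTable]:
    """Generate a (panel, genetic map) pair; fully deterministic in the seed.

    Every locus of the returned panel has minor-allele frequency
    >= ``spec.maf_min`` exactly (checked on the realised matrix), at most
    ``spec.n_block_haps`` distinct haplotypes exist within any block, and
    different blocks are independent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _block_lengths(spec, rng)
    H = spec.n_haplotypes
    haps = np.empty((H, spec.n_loci), dtype=np.uint8)
    boundary_after = np.zeros(spec.n_loci, dtype=bool)
    col = 0
    for ln in lengths:
        haps[:, col : col + ln] = _draw_block(ln, spec, rng)
        col += ln
        if col < spec.n_loci:
            boundary_after[col - 1] = True
    # positions: jittered around the mean spacing, strictly increasing
    gaps = rng.integers(
        max(1, spec.spacing_bp // 2), spec.spacing_bp * 3 // 2 + 1,
        size=spec.n_loci,
    )
    pos = np.cumsum(gaps) + 1000
    # cumulative cM: background rate inside blocks, hotspot rate across
    # block boundaries
    cm = np.empty(spec.n_loci, dtype=np.float64)
    cm[0] = 0.0
    for j in range(1, spec.n_loci):
        rate = spec.hotspot_rate if boundary_after[j - 1] else spec.background_rate
        cm[j] = cm[j - 1] + rate * (pos[j] - pos[j - 1]) * 1e-6
    loci = [
        Locus(
            name=f"snp{j + 1}",
            chrom=spec.chrom,
            pos_bp=int(pos[j]),
            cm=float(cm[j]),
            index=j,
        )
        for j in range(spec.n_loci)
    ]
    panel = HaplotypePanel(loci, haps)
    rates = np.empty(spec.n_loci)
    rates[:-1] = np.where(
        boundary_after[:-1], spec.hotspot_rate, spec.background_rate
    )
    rates[-1] = spec.background_rate
    gmap = GeneticMapTable(
        chrom=[spec.chrom] * spec.n_loci,
        pos_bp=pos,
        rate_cm_mb=rates,
        cumulative_cm=cm,
    )
    return panel, gmap
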