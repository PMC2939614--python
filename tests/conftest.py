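import numpy as np
import pytest

from fwdgwas.popmodel import HaplotypePanel, Locus, initialize_population
from fwdgwas.synthetic_init import SyntheticPanelSpec, generate_panel


@pytest.fixture
def tiny_panel():
    """4 haplotypes x 3 loci with hand-checkable frequencies."""
    loci = [
        Locus("rs1", "2", 100, 0.0, 0, ("A", "G")),
        Locus("rs2", "2", 500, 0.5, 1, ("C", "T")),
        Locus("rs3", "2", 900, 1.0, 2, ("G", "A")),
    ]
    haps = np.array(
        [
            [0, 1, 1],
            [1, 0, 1],
            [0, 0, 1],
            [1, 1, 0],
        ],
        dtype=np.uint8,
    )
    return HaplotypePanel(loci, haps, sample_ids=["S1", "S2"])


@pytest.fixture
def synth_panel():
    panel, gmap = generate_panel(SyntheticPanelSpec(seed=11))
    return panel, gmap


def single_locus_population(n_diploid: int, p: float, rng, n_loci: int = 1):
    """Population with exactly round(2N p) copies of allele 1 at locus 0
    (and at every locus), randomly placed on haplotypes."""
    H = 2 * n_diploid
    haps = np.zeros((H, n_loci), dtype=np.uint8)
    k = int(round(H * p))
    for l in range(n_loci):
        col = np.zeros(H, dtype=np.uint8)
        col[:k] = 1
        rng.shuffle(col)
        haps[:, l] = col
    loci = [Locus(f"m{l + 1}", "1", 1000 * (l + 1), 0.0, l) for l in range(n_loci)]
    return initialize_population(HaplotypePanel(loci, haps))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
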