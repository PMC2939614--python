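"""Population and sample statistics.

Allele frequencies, two-locus linkage disequilibrium (D, D', r^2) from
phased haplotypes, LD-decay profiles by physical distance, Weir-Cockerham
F_ST between subpopulations, haplotype diversity over a locus window, the
harmonic-mean effective size of a varying-size history, and the allele-based
chi-square association test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .popmodel import Population
from .sampling import Sample

__all__ = [
    "LDStats",
    "ld_pair",
    "ld_decay_profile",
    "fst",
    "haplotype_summary",
    "harmonic_ne",
    "chi2_allele_test",
    "association_scan",
]


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium between two biallelic loci.

    ``defined`` is False when either locus is monomorphic, in which case
    D, D' and r^2 carry NaN and the pair is excluded from decay profiles.
    """

    D: float
    Dprime: float
    r2: float
    defined: bool = True


def _hap_matrix(obj) -> np.ndarray:
    if isinstance(obj, Population):
        return obj.all_haplotypes()
    if isinstance(obj, Sample):
        return obj.haps
    return np.asarray(obj)


def ld_pair(obj, l1: int, l2: int) -> LDStats:
    """LD between two loci from phased haplotype counts (no EM needed).

    D = p11 - p1 q1; D' = D / Dmax with the sign-dependent Dmax bound;
    r^2 = D^2 / (p1 p0 q1 q0).
    """
    haps = _hap_matrix(obj)
    a = haps[:, l1].astype(np.float64)
    b = haps[:, l2].astype(np.float64)
    p1 = a.mean()
    q1 = b.mean()
    p0, q0 = 1.0 - p1, 1.0 - q1
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        return LDStats(float("nan"), float("nan"), float("nan"), defined=False)
    p11 = (a * b).mean()
    D = p11 - p1 * q1
    if D > 0:
        dmax = min(p1 * q0, p0 * q1)
    else:
        dmax = min(p1 * q1, p0 * q0)
    dprime = 0.0 if D == 0.0 else D / dmax
    r2 = D * D / (p1 * p0 * q1 * q0)
    return LDStats(float(D), float(dprime), float(r2), defined=True)


def ld_decay_profile(
    obj, max_dist_bp: int, bin_bp: int = 10_000, loci=None
) -> list[dict]:
    """Mean r^2 (and mean |D'|) of marker pairs binned by physical distance.

    Pairs at distance d fall in the half-open bin [k*bin_bp, (k+1)*bin_bp)
    with k = d // bin_bp; only same-chromosome pairs closer than
    ``max_dist_bp`` are used and monomorphic loci are excluded.  Empty bins
    are reported with NaN means.
    """
    haps = _hap_matrix(obj).astype(np.float64)
    if loci is None:
        loci = obj.loci
    freqs = haps.mean(axis=0)
    poly = np.flatnonzero((freqs > 0) & (freqs < 1))
    pos = np.array([loci[j].pos_bp for j in poly])
    chrom = np.array([loci[j].chrom for j in poly])
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums_r2 = np.zeros(n_bins)
    sums_dp = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    H = haps.shape[0]
    sub = haps[:, poly]
    p = freqs[poly]
    # pairwise covariance via one matrix product over polymorphic columns
    cov = (sub.T @ sub) / H - np.outer(p, p)
    var = p * (1.0 - p)
    for i in range(len(poly)):
        same = chrom[i + 1 :] == chrom[i]
        d = pos[i + 1 :] - pos[i]
        ok = same & (d < max_dist_bp)
        js = np.flatnonzero(ok) + i + 1
        if len(js) == 0:
            continue
        bins = (pos[js] - pos[i]) // bin_bp
        D = cov[i, js]
        r2 = D * D / (var[i] * var[js])
        dmax = np.where(
            D > 0,
            np.minimum(p[i] * (1 - p[js]), (1 - p[i]) * p[js]),
            np.minimum(p[i] * p[js], (1 - p[i]) * (1 - p[js])),
        )
        dp = np.where(D == 0, 0.0, np.abs(D / dmax))
        np.add.at(sums_r2, bins, r2)
        np.add.at(sums_dp, bins, dp)
        np.add.at(counts, bins, 1)
    out = []
    for k in range(n_bins):
        out.append(
            {
                "bin_start": k * bin_bp,
                "bin_end": (k + 1) * bin_bp,
                "n_pairs": int(counts[k]),
                "mean_r2": float(sums_r2[k] / counts[k]) if counts[k] else float("nan"),
                "mean_absDprime": float(sums_dp[k] / counts[k])
                if counts[k]
                else float("nan"),
            }
        )
    return out


def fst(pop: Population, loci=None) -> float:
    """Weir & Cockerham (1984) multi-locus F_ST (theta-hat) between subpops.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed per locus from
    genotype counts and combined as a ratio of sums over loci; loci
    monomorphic across all subpopulations are skipped.  Returns NaN when
    every locus is monomorphic.
    """
    subpops = [sp for sp in pop.subpops if sp.size > 0]
    r = len(subpops)
    if r < 2:
        raise ValueError("FST requires at least two non-empty subpopulations")
    if loci is None:
        loci = range(pop.n_loci)
    n_i = np.array([sp.size for sp in subpops], dtype=np.float64)
    nbar = n_i.mean()
    nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    num = 0.0
    den = 0.0
    for l in loci:
        p_i = np.array([sp.haps[:, l].mean() for sp in subpops])
        # observed heterozygote fraction per subpop
        h_i = np.array(
            [np.mean(sp.haps[0::2, l] != sp.haps[1::2, l]) for sp in subpops]
        )
        pbar = (n_i * p_i).sum() / n_i.sum()
        if pbar in (0.0, 1.0):
            continue
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_i.sum()
        a = (nbar / nc) * (
            s2
            - 1.0
            / (nbar - 1)
            * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        num += a
        den += a + b + c
    if den == 0.0:
        return float("nan")
    return float(num / den)


def haplotype_summary(obj, locus_window: tuple[int, int]) -> tuple[int, float]:
    """(number of distinct haplotypes, frequency of the most common one)
    over the half-open column window [start, stop)."""
    haps = _hap_matrix(obj)
    start, stop = locus_window
    if not (0 <= start < stop <= haps.shape[1]):
        raise ValueError("locus window out of bounds")
    sub = np.ascontiguousarray(haps[:, start:stop])
    _, counts = np.unique(sub, axis=0, return_counts=True)
    return len(counts), float(counts.max() / sub.shape[0])


def harmonic_ne(sizes: list[int]) -> float:
    """Harmonic-mean effective size of a varying-size history.

    For a schedule N_0 .. N_T the final census is excluded:
    Ne = T / sum_{t=0}^{T-1} 1/N_t.  For a constant schedule this returns N.
    """
    if len(sizes) == 0:
        raise ValueError("empty size list")
    use = sizes[:-1] if len(sizes) > 1 else sizes
    if any(s < 1 for s in use):
        raise ValueError("population sizes must be >= 1")
    return float(len(use) / sum(1.0 / s for s in use))


def chi2_allele_test(
    case_sample, control_sample, locus: int
) -> tuple[float, float]:
    """Allele-based 2x2 Pearson chi-square test (1 df, no continuity
    correction) between cases and controls at one locus.

    Each individual contributes two alleles.  A zero margin (monomorphic
    locus or empty stratum table) gives chi2 = 0, p = 1.
    """
    if isinstance(case_sample, Sample):
        a, b = case_sample.allele_counts(locus)
        c, d = control_sample.allele_counts(locus)
    else:  # raw haplotype matrices
        col = np.asarray(case_sample)[:, locus]
        a = int(col.sum())
        b = len(col) - a
        col = np.asarray(control_sample)[:, locus]
        c = int(col.sum())
        d = len(col) - c
    n = a + b + c + d
    if n == 0:
        raise ValueError("both samples are empty")
    r1, r2_, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2_, c1, c2):
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2_ * c1 * c2)
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


def association_scan(case_sample, control_sample, loci=None) -> list[dict]:
    """Per-locus chi-square scan; rows carry -log10 p for plotting."""
    if loci is None:
        loci = range(len(case_sample.loci))
    out = []
    for l in loci:
        chi2, p = chi2_allele_test(case_sample, control_sample, l)
        loc = case_sample.loci[l]
        out.append(
            {
                "chrom": loc.chrom,
                "pos_bp": loc.pos_bp,
                "name": loc.name,
                "chi2": chi2,
                "p": p,
                "neg_log10_p": float(-np.log10(p)) if p > 0 else float("inf"),
            }
        )
    return out
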