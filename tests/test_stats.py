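import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from fwdgwas.popmodel import HaplotypePanel, Locus, Population, initialize_population
from fwdgwas.stats import (
    chi2_allele_test,
    fst,
    haplotype_summary,
    harmonic_ne,
    ld_decay_profile,
    ld_pair,
)

from conftest import single_locus_population


def _hap_set(counts: dict[str, int]) -> np.ndarray:
    rows = []
    for pattern, k in counts.items():
        rows += [[int(c) for c in pattern]] * k
    return np.array(rows, dtype=np.uint8)


class TestLdPair:
    def test_perfect_coupling(self):
        haps = _hap_set({"11": 50, "00": 50})
        ld = ld_pair(haps, 0, 1)
        assert ld.D == pytest.approx(0.25)
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_independent_loci_zero(self):
        haps = _hap_set({"11": 25, "10": 25, "01": 25, "00": 25})
        ld = ld_pair(haps, 0, 1)
        assert ld.D == pytest.approx(0.0, abs=1e-12)
        assert ld.r2 == pytest.approx(0.0, abs=1e-12)

    def test_locus_with_itself(self):
        haps = _hap_set({"11": 30, "00": 70})
        ld = ld_pair(haps, 0, 0)
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_monomorphic_flagged(self):
        haps = _hap_set({"01": 50, "00": 50})
        assert not ld_pair(haps, 0, 1).defined

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n11=st.integers(0, 30),
        n10=st.integers(0, 30),
        n01=st.integers(0, 30),
        n00=st.integers(0, 30),
    )
    def test_r2_bounded_by_absdprime(self, n11, n10, n01, n00):
        counts = {"11": n11, "10": n10, "01": n01, "00": n00}
        if sum(counts.values()) == 0:
            return
        haps = _hap_set(counts)
        ld = ld_pair(haps, 0, 1)
        if ld.defined:
            assert abs(ld.Dprime) <= 1.0 + 1e-12
            assert -1e-12 <= ld.r2 <= 1.0 + 1e-12
            assert ld.r2 <= abs(ld.Dprime) + 1e-9


class TestLdDecayProfile:
    def _pop(self, positions, haps):
        loci = [Locus(f"m{i}", "1", p, 0.0, i) for i, p in enumerate(positions)]
        return initialize_population(HaplotypePanel(loci, haps))

    def test_single_pair_one_bin(self):
        haps = _hap_set({"11": 5, "00": 5})
        pop = self._pop([1000, 6000], haps)
        prof = ld_decay_profile(pop, 20_000)
        assert prof[0]["n_pairs"] == 1
        assert prof[0]["mean_r2"] == pytest.approx(1.0)
        assert prof[1]["n_pairs"] == 0

    def test_bin_boundary_half_open(self):
        haps = _hap_set({"11": 5, "00": 5})
        pop = self._pop([1000, 11_000], haps)  # exactly 10 kb apart
        prof = ld_decay_profile(pop, 30_000)
        assert prof[0]["n_pairs"] == 0
        assert prof[1]["n_pairs"] == 1

    def test_synthetic_panel_profile_decays(self, synth_panel):
        panel, _ = synth_panel
        pop = initialize_population(panel)
        prof = ld_decay_profile(pop, 100_000)
        vals = [b["mean_r2"] for b in prof if b["n_pairs"] > 10]
        assert vals[0] > vals[-1]


def _wc_fst_oracle(counts_per_pop):
    """Independent Weir-Cockerham theta for one locus from explicit
    (n individuals, p freq, h observed het fraction) tuples."""
    r = len(counts_per_pop)
    n = np.array([c[0] for c in counts_per_pop], dtype=float)
    p = np.array([c[1] for c in counts_per_pop], dtype=float)
    h = np.array([c[2] for c in counts_per_pop], dtype=float)
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


class TestFst:
    def _two_pop(self, haps_a, haps_b):
        loci = [
            Locus(f"m{i}", "1", 100 * (i + 1), 0.0, i)
            for i in range(haps_a.shape[1])
        ]
        pa = initialize_population(HaplotypePanel(loci, haps_a))
        pb = initialize_population(HaplotypePanel(loci, haps_b))
        return Population([pa.subpops[0], pb.subpops[0]], loci, 0)

    def test_fixed_difference_is_one(self):
        a = np.ones((20, 3), dtype=np.uint8)
        b = np.zeros((20, 3), dtype=np.uint8)
        assert fst(self._two_pop(a, b)) == pytest.approx(1.0)

    def test_duplicated_subpop_near_zero(self, rng):
        haps = (rng.random((400, 10)) < 0.4).astype(np.uint8)
        val = fst(self._two_pop(haps, haps.copy()))
        # Weir-Cockerham carries an O(1/n) finite-sample term for identical
        # demes; with n=200 individuals it is a few parts in a thousand
        assert abs(val) < 0.01

    def test_matches_independent_oracle(self, rng):
        """Printed-count comparison: 12/20 vs 4/20 alt alleles, 10+10 people."""
        a = np.zeros((20, 1), dtype=np.uint8)
        a[:12, 0] = 1
        rng.shuffle(a)
        b = np.zeros((20, 1), dtype=np.uint8)
        b[:4, 0] = 1
        rng.shuffle(b)
        pop = self._two_pop(a, b)
        ha = np.mean(a[0::2, 0] != a[1::2, 0])
        hb = np.mean(b[0::2, 0] != b[1::2, 0])
        expected = _wc_fst_oracle([(10, 0.6, ha), (10, 0.2, hb)])
        assert fst(pop) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_relabeling(self, rng):
        a = (rng.random((40, 6)) < 0.3).astype(np.uint8)
        b = (rng.random((60, 6)) < 0.6).astype(np.uint8)
        pop = self._two_pop(a, b)
        v1 = fst(pop)
        # swap subpopulation order
        pop_sw = Population([pop.subpops[1], pop.subpops[0]], pop.loci, 0)
        assert fst(pop_sw) == pytest.approx(v1, abs=1e-12)
        # flip allele labels at every locus
        pop_fl = self._two_pop(1 - a, 1 - b)
        assert fst(pop_fl) == pytest.approx(v1, abs=1e-12)


class TestHaplotypeSummary:
    def test_all_identical(self):
        haps = np.ones((10, 4), dtype=np.uint8)
        assert haplotype_summary(haps, (0, 4)) == (1, 1.0)

    def test_all_distinct(self):
        haps = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8
        )
        n, top = haplotype_summary(haps, (0, 2))
        assert n == 4 and top == pytest.approx(0.25)

    def test_hand_counted_fixture(self):
        haps = _hap_set({"110": 3, "001": 2, "111": 1})
        n, top = haplotype_summary(haps, (0, 3))
        assert n == 3 and top == pytest.approx(0.5)


class TestHarmonicNe:
    def test_constant(self):
        assert harmonic_ne([50] * 10) == pytest.approx(50.0)

    def test_excludes_final_census(self):
        # generations 0..T-1 enter the harmonic mean; the census at T does not
        assert harmonic_ne([10, 10, 1000]) == pytest.approx(10.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            harmonic_ne([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 10_000), min_size=2, max_size=50))
    def test_bounded_by_arithmetic_mean(self, sizes):
        assert harmonic_ne(sizes) <= np.mean(sizes[:-1]) + 1e-9


class TestChi2AlleleTest:
    def test_identical_counts_null(self):
        cases = _hap_set({"1": 30, "0": 70})
        controls = _hap_set({"1": 30, "0": 70})
        chi2, p = chi2_allele_test(cases, controls, 0)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_value(self):
        # cases 30 alt / 70 ref, controls 10 alt / 90 ref -> chi2 = 12.5
        cases = _hap_set({"1": 30, "0": 70})
        controls = _hap_set({"1": 10, "0": 90})
        chi2, p = chi2_allele_test(cases, controls, 0)
        assert chi2 == pytest.approx(12.5)

    def test_zero_margin_flagged(self):
        cases = _hap_set({"0": 100})
        controls = _hap_set({"0": 100})
        chi2, p = chi2_allele_test(cases, controls, 0)
        assert p == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.integers(1, 200),
        b=st.integers(1, 200),
        c=st.integers(1, 200),
        d=st.integers(1, 200),
    )
    def test_matches_scipy_contingency(self, a, b, c, d):
        cases = _hap_set({"1": a, "0": b})
        controls = _hap_set({"1": c, "0": d})
        chi2, p = chi2_allele_test(cases, controls, 0)
        ref = chi2_contingency([[a, b], [c, d]], correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
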