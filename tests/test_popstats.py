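"""Diversity, Tajima's D, Weir-Cockerham FST, windows, inbreeding.

Each estimator is checked against an independent brute-force recomputation
written directly from first principles (pairwise Hamming over allele copies,
straight transcription of the Tajima 1989 constants, the W&C 1984 algebra
worked for the general r-population form).
"""
import numpy as np
import pytest

from popgenscan.errors import RegionError
from popgenscan.popstats import (fst_wc, harmonic, inbreeding_coefficient,
                                 tajima_d, theta_pi, theta_w, window_grid,
                                 windowed_scan)

from conftest import make_table, random_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_bruteforce(gt, length):
    """Mean pairwise difference over all pairs of non-missing allele copies,
    summed over sites, per bp."""
    total = 0.0
    for site in gt:
        copies = []
        for g in site:
            if g >= 0:
                copies += [1, 1] if g == 2 else [0, 1] if g == 1 else [0, 0]
        m = len(copies)
        if m < 2:
            continue
        diff = sum(1 for i in range(m) for j in range(i + 1, m)
                   if copies[i] != copies[j])
        total += diff / (m * (m - 1) / 2)
    return total / length


def watterson_bruteforce(gt, length):
    total = 0.0
    for site in gt:
        obs = [g for g in site if g >= 0]
        m = 2 * len(obs)
        k = sum(obs)
        if m >= 2 and 0 < k < m:
            total += 1.0 / sum(1.0 / i for i in range(1, m))
    return total / length


def tajima_bruteforce(gt):
    """Straight transcription of the 1989 constants, modal sample size."""
    pi_sum = 0.0
    S = 0
    ms = []
    for site in gt:
        obs = [g for g in site if g >= 0]
        m = 2 * len(obs)
        k = sum(obs)
        if m < 2 or k == 0 or k == m:
            continue
        S += 1
        ms.append(m)
        pi_sum += 2.0 * k * (m - k) / (m * (m - 1))
    if S == 0:
        return None
    vals, counts = np.unique(ms, return_counts=True)
    n = int(vals[np.argmax(counts)])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def fst_wc_bruteforce(ga, gb):
    """W&C 1984 per-site a, b, c summed; written in the general r-pop form."""
    num = den = 0.0
    for sa, sb in zip(ga, gb):
        pops = []
        for site in (sa, sb):
            obs = [g for g in site if g >= 0]
            if not obs:
                pops = []
                break
            n = len(obs)
            pops.append((n, sum(obs) / (2.0 * n),
                         sum(1 for g in obs if g == 1) / n))
        if len(pops) != 2:
            continue
        r = 2.0
        ns = [p[0] for p in pops]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n**2 for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
        hbar = sum(n * h for n, _, h in pops) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


# ---------------------------------------------------------------------------
# hand-computed examples
# ---------------------------------------------------------------------------

class TestThetaPi:
    def test_identical_samples_zero(self):
        t = make_table([[2, 2], [0, 0]], contig_len=100)
        assert theta_pi(t, None, ("chr1", 0, 100)) == 0.0

    def test_single_site_hand_value(self):
        # k=2 of m=4 copies, length 100: 2*2*2/(4*3)/100 = 1/150
        t = make_table([[1, 1]], contig_len=100)
        assert theta_pi(t, None, ("chr1", 0, 100)) == pytest.approx(
            2 * 2 * 2 / (4 * 3) / 100, rel=1e-12)

    def test_normalization_halves_with_double_length(self):
        t = make_table([[1, 1]], contig_len=200)
        a = theta_pi(t, None, ("chr1", 0, 100))
        b = theta_pi(t, None, ("chr1", 0, 200))
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_empty_region_raises(self):
        t = make_table([[1, 1]])
        with pytest.raises(RegionError):
            theta_pi(t, None, ("chr1", 50, 50))


class TestThetaW:
    def test_no_segregating_sites(self):
        t = make_table([[0, 0], [2, 2]], contig_len=100)
        assert theta_w(t, None, ("chr1", 0, 100)) == 0.0

    def test_hand_value_m8(self):
        # S=5 complete sites with 4 diploids (m=8), L=1000:
        # a_8 = 2.592857..., theta_w = 5/a_8/1000
        g = [[1, 0, 0, 0]] * 5
        t = make_table(g, contig_len=1000)
        a8 = sum(1.0 / i for i in range(1, 8))
        assert theta_w(t, None, ("chr1", 0, 1000)) == pytest.approx(
            5 / a8 / 1000, rel=1e-12)
        assert a8 == pytest.approx(2.5928571428571425, rel=1e-12)


class TestTajimaD:
    def test_zero_when_pi_equals_watterson(self):
        # 2 diploids (m=4, a1=1+1/2+1/3): one het site in each sample gives
        # pi_sum = 2*(2*1*3/(4*3)) = 1.0; S=2 -> S/a1 = 1.0909...; build a
        # case where pi_sum == S/a1 instead via direct construction:
        # simplest exact-zero case is S=0 handled as undefined, so check the
        # identity numerically through the oracle on random data instead.
        t = make_table([[1, 0], [0, 1], [1, 1]])
        d, flag = tajima_d(t, None, ("chr1", 0, 50))
        assert d == pytest.approx(tajima_bruteforce(t.gt), rel=1e-12)

    def test_undefined_without_segregating_sites(self):
        t = make_table([[0, 0]])
        d, flag = tajima_d(t, None, ("chr1", 0, 50))
        assert np.isnan(d)
        assert flag == "no_segregating"

    def test_matches_independent_transcription(self, rng):
        for _ in range(20):
            t = random_table(rng, n_sites=int(rng.integers(5, 60)),
                             n_samples=int(rng.integers(3, 12)),
                             missing_rate=0.0)
            d, _ = tajima_d(t, None, ("chr1", 0, int(t.pos.max()) + 1))
            assert d == pytest.approx(tajima_bruteforce(t.gt), rel=1e-12)


class TestFst:
    def test_fixed_difference_is_one(self):
        t = make_table([[0, 0, 2, 2]] * 3)
        w = fst_wc(t, ["s1", "s2"], ["s3", "s4"], ("chr1", 0, 50))
        assert w.fst == pytest.approx(1.0, abs=1e-12)

    def test_identical_pops_near_zero(self, rng):
        g = np.repeat(rng.integers(0, 3, size=(40, 1)), 20, axis=1)
        t = make_table(g.astype(np.int8))
        w = fst_wc(t, [f"s{i}" for i in range(1, 11)],
                   [f"s{i}" for i in range(11, 21)],
                   ("chr1", 0, int(t.pos.max()) + 1))
        assert abs(w.fst) < 1e-9

    def test_single_site_hand_algebra(self):
        # pop1: 0/0, 0/0, 0/1; pop2: 1/1, 1/1, 0/1
        # worked by hand: a = 7/36, b = 0, c = 6/36 -> FST = 7/13
        t = make_table([[0, 0, 1, 2, 2, 1]])
        w = fst_wc(t, ["s1", "s2", "s3"], ["s4", "s5", "s6"], ("chr1", 0, 50))
        assert w.fst == pytest.approx(7.0 / 13.0, rel=1e-12)

    def test_symmetric(self, rng):
        t = random_table(rng, n_sites=30, n_samples=12)
        a = [f"s{i}" for i in range(1, 7)]
        b = [f"s{i}" for i in range(7, 13)]
        region = ("chr1", 0, int(t.pos.max()) + 1)
        assert fst_wc(t, a, b, region).fst == fst_wc(t, b, a, region).fst

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            t = random_table(rng, n_sites=40, n_samples=14)
            a = [f"s{i}" for i in range(1, 8)]
            b = [f"s{i}" for i in range(8, 15)]
            region = ("chr1", 0, int(t.pos.max()) + 1)
            ia = [t.samples.index(s) for s in a]
            ib = [t.samples.index(s) for s in b]
            expect = fst_wc_bruteforce(t.gt[:, ia], t.gt[:, ib])
            assert fst_wc(t, a, b, region).fst == pytest.approx(
                expect, rel=1e-12)


class TestInvariance:
    def test_sample_reordering(self, rng):
        t = random_table(rng, n_sites=30, n_samples=8)
        region = ("chr1", 0, int(t.pos.max()) + 1)
        shuffled = list(rng.permutation(t.samples))
        assert theta_pi(t, shuffled, region) == theta_pi(t, t.samples, region)
        assert theta_w(t, shuffled, region) == theta_w(t, t.samples, region)

    def test_ref_alt_swap(self, rng):
        t = random_table(rng, n_sites=30, n_samples=8)
        region = ("chr1", 0, int(t.pos.max()) + 1)
        swapped = t.take_sites(np.arange(t.n_sites))
        g = swapped.gt
        miss = g == -1
        swapped.gt = (2 - g).astype(np.int8)
        swapped.gt[miss] = -1
        assert theta_pi(swapped, None, region) == pytest.approx(
            theta_pi(t, None, region), rel=1e-12)
        assert theta_w(swapped, None, region) == pytest.approx(
            theta_w(t, None, region), rel=1e-12)

    def test_matches_bruteforce_small_instances(self, rng):
        for _ in range(10):
            t = random_table(rng, n_sites=int(rng.integers(10, 200)),
                             n_samples=int(rng.integers(4, 20)))
            L = int(t.pos.max()) + 1
            region = ("chr1", 0, L)
            assert theta_pi(t, None, region) == pytest.approx(
                pi_bruteforce(t.gt, L), rel=1e-12)
            assert theta_w(t, None, region) == pytest.approx(
                watterson_bruteforce(t.gt, L), rel=1e-12)


class TestWindowGrid:
    def test_91_full_windows(self):
        grid = window_grid(1_000_000, 100_000, 10_000)
        full = [w for w in grid if not w[2]]
        assert len(full) == 91

    def test_nonoverlapping_tiling_covers(self):
        grid = window_grid(1_000_000, 100_000, 100_000)
        assert all(not p for _, _, p in grid)
        assert grid[0][0] == 0 and grid[-1][1] == 1_000_000
        for (s1, e1, _), (s2, e2, _) in zip(grid, grid[1:]):
            assert e1 == s2

    def test_empty_window_flagged(self):
        t = make_table([[0, 1]], pos=[5], contig_len=300)
        div, _ = windowed_scan(t, {"p": ["s1", "s2"]}, 100, 100,
                               statistics=("diversity",))
        empty = [w for w in div if w.start == 100]
        assert empty[0].S == 0
        assert empty[0].d_flag == "no_segregating"


class TestInbreeding:
    def test_fully_homozygous_sample_is_one(self):
        g = [[2, 1, 0, 1], [0, 1, 2, 1], [2, 1, 1, 0]]
        rec = inbreeding_coefficient(make_table(g), "s1")
        assert rec.f == pytest.approx(1.0)

    def test_direct_formula(self):
        # F = (O - E) / (N - E) with O=80, E=60, N=100
        assert (80 - 60) / (100 - 60) == 0.5

    def test_hardy_weinberg_mean_near_zero(self, rng):
        # genotypes drawn exactly at HWE proportions
        n_sites, n_samples = 400, 30
        p = rng.uniform(0.1, 0.9, n_sites)
        u = rng.random((n_sites, n_samples, 2))
        g = ((u[..., 0] < p[:, None]).astype(int)
             + (u[..., 1] < p[:, None]).astype(int))
        t = make_table(g.astype(np.int8),
                       pos=np.arange(1, n_sites + 1) * 3)
        fs = [inbreeding_coefficient(t, s).f for s in t.samples]
        assert abs(np.mean(fs)) < 0.05
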