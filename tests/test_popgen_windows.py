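import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riceeco import popgen_windows as pw
from riceeco.genotype_io import MISSING

from conftest import build_gm


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_pi(calls, window_length):
    """Mean pairwise difference over every pair of called alleles, per site,
    summed and divided by window length."""
    total = 0.0
    for j in range(calls.shape[1]):
        alleles = []
        for code in calls[:, j]:
            if code == MISSING:
                continue
            alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(code)]
        if len(alleles) < 2:
            continue
        diffs = sum(a != b for a, b in itertools.combinations(alleles, 2))
        pairs = len(alleles) * (len(alleles) - 1) / 2
        total += diffs / pairs
    return total / window_length


def wc_oracle_site(callsA, callsB):
    """Textbook Weir & Cockerham (1984) a, b, c for one site, two pops,
    written as straight-line scalar arithmetic."""
    def summarize(calls):
        called = [c for c in calls if c != MISSING]
        n = len(called)
        if n == 0:
            return 0, 0.0, 0.0
        p = sum(called) / (2 * n)
        h = sum(1 for c in called if c == 1) / n
        return n, p, h

    n1, p1, h1 = summarize(callsA)
    n2, p2, h2 = summarize(callsB)
    if n1 == 0 or n2 == 0:
        return None
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if (pbar == 0 or pbar == 1) and hbar == 0:
        return None  # monomorphic across both populations
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# make_windows
# ---------------------------------------------------------------------------

class TestMakeWindows:
    def test_sliding_enumeration(self):
        grid = pw.make_windows({"chr1": 250_000}, 100_000, 50_000)
        assert list(map(tuple, grid[["start", "end"]].to_numpy())) == [
            (0, 100_000), (50_000, 150_000), (100_000, 200_000), (150_000, 250_000)
        ]

    def test_short_chromosome_single_window(self):
        grid = pw.make_windows({"chr1": 80_000}, 100_000, 50_000)
        assert len(grid) == 1
        assert (grid["start"].iloc[0], grid["end"].iloc[0]) == (0, 80_000)

    def test_non_overlapping_tiling(self):
        grid = pw.make_windows({"chr1": 200_000}, 50_000, 50_000)
        assert grid["start"].tolist() == [0, 50_000, 100_000, 150_000]
        assert (grid["end"] - grid["start"]).eq(50_000).all()

    def test_step_gt_size_rejected(self):
        with pytest.raises(ValueError):
            pw.make_windows({"chr1": 100_000}, 10_000, 20_000)


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

class TestPi:
    def test_no_segregating_sites(self):
        G = build_gm(np.zeros((4, 3), dtype=np.int8), pos=[5, 15, 25])
        grid = pw.make_windows({"chr1": 100}, 100, 100)
        out = pw.pi_windowed(G, G.samples, grid)
        assert out["value"].iloc[0] == 0.0
        # monomorphic sites still have >= 2 called alleles
        assert out["n_snps"].iloc[0] == 3

    def test_single_site_hand_value(self):
        # 2 alt / 2 ref alleles among n=4: per-site 2*2*2/(4*3) = 2/3
        G = build_gm(np.array([[2], [0]], dtype=np.int8), pos=[50])
        grid = pw.make_windows({"chr1": 100}, 100, 100)
        out = pw.pi_windowed(G, G.samples, grid)
        assert out["value"].iloc[0] == pytest.approx(2 / 3 / 100, abs=1e-12)
        assert out["value"].iloc[0] == pytest.approx(0.0066667, abs=1e-7)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 1, 2, MISSING], size=(20, 50),
                           p=[0.45, 0.1, 0.35, 0.1]).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 5001), size=50, replace=False))
        G = build_gm(calls, pos=pos)
        grid = pw.make_windows({"chr1": 5000}, 5000, 5000)
        out = pw.pi_windowed(G, G.samples, grid)
        assert out["value"].iloc[0] == pytest.approx(
            brute_force_pi(calls, 5000), abs=1e-12
        )

    def test_empty_samples_error(self):
        G = build_gm(np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            pw.pi_windowed(G, [], pw.make_windows({"chr1": 100}, 100, 100))

    def test_invariant_to_sample_order_and_allele_swap(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        G = build_gm(calls)
        grid = pw.make_windows({"chr1": 400}, 400, 400)
        base = pw.pi_windowed(G, G.samples, grid)["value"].iloc[0]
        shuffled = list(G.samples)
        rng.shuffle(shuffled)
        assert pw.pi_windowed(G, shuffled, grid)["value"].iloc[0] == pytest.approx(base)
        flipped = build_gm((2 - calls).astype(np.int8))
        assert pw.pi_windowed(flipped, flipped.samples, grid)["value"].iloc[0] == (
            pytest.approx(base)
        )


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestFst:
    def _two_pop(self, callsA, callsB):
        calls = np.vstack([callsA, callsB]).astype(np.int8)
        nA = callsA.shape[0]
        G = build_gm(calls)
        A = G.samples[:nA]
        B = G.samples[nA:]
        return G, A, B

    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, size=100)
        callsA = (rng.random((20, 100)) < p).astype(np.int8) + (
            rng.random((20, 100)) < p
        ).astype(np.int8)
        callsB = (rng.random((20, 100)) < p).astype(np.int8) + (
            rng.random((20, 100)) < p
        ).astype(np.int8)
        G, A, B = self._two_pop(callsA, callsB)
        grid = pw.make_windows({"chr1": 1010}, 1010, 1010)
        out, mean = pw.fst_windowed(G, A, B, grid)
        assert abs(out["value"].iloc[0]) < 0.05
        assert abs(mean) < 0.05

    def test_fixed_difference_is_one(self):
        callsA = np.full((10, 3), 2, dtype=np.int8)
        callsB = np.zeros((10, 3), dtype=np.int8)
        G, A, B = self._two_pop(callsA, callsB)
        grid = pw.make_windows({"chr1": 100}, 100, 100)
        out, mean = pw.fst_windowed(G, A, B, grid)
        assert out["value"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(8)
        callsA = rng.choice([0, 1, 2, MISSING], size=(12, 3),
                            p=[0.4, 0.2, 0.3, 0.1]).astype(np.int8)
        callsB = rng.choice([0, 1, 2, MISSING], size=(7, 3),
                            p=[0.2, 0.2, 0.5, 0.1]).astype(np.int8)
        G, A, B = self._two_pop(callsA, callsB)
        grid = pw.make_windows({"chr1": 100}, 100, 100)
        out, mean = pw.fst_windowed(G, A, B, grid)
        num = den = 0.0
        for j in range(3):
            comp = wc_oracle_site(callsA[:, j].tolist(), callsB[:, j].tolist())
            if comp is None:
                continue
            a, b, c = comp
            num += a
            den += a + b + c
        assert out["value"].iloc[0] == pytest.approx(num / den, abs=1e-10)
        assert mean == pytest.approx(num / den, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        callsA = rng.integers(0, 3, size=(8, 20)).astype(np.int8)
        callsB = rng.integers(0, 3, size=(9, 20)).astype(np.int8)
        G, A, B = self._two_pop(callsA, callsB)
        grid = pw.make_windows({"chr1": 300}, 300, 300)
        ab, mean_ab = pw.fst_windowed(G, A, B, grid)
        ba, mean_ba = pw.fst_windowed(G, B, A, grid)
        assert ab["value"].iloc[0] == pytest.approx(ba["value"].iloc[0], abs=1e-12)
        assert mean_ab == pytest.approx(mean_ba, abs=1e-12)

    def test_random_split_of_one_population_near_zero(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.1, 0.9, size=300)
        calls = ((rng.random((60, 300)) < p).astype(np.int8)
                 + (rng.random((60, 300)) < p).astype(np.int8))
        G = build_gm(calls)
        half = rng.permutation(60)
        A = [G.samples[i] for i in half[:30]]
        B = [G.samples[i] for i in half[30:]]
        grid = pw.make_windows({"chr1": 3010}, 3010, 3010)
        _, mean = pw.fst_windowed(G, A, B, grid)
        assert abs(mean) < 0.02

    def test_single_site_window_equals_site_value(self):
        rng = np.random.default_rng(11)
        callsA = rng.integers(0, 3, size=(6, 1)).astype(np.int8)
        callsB = rng.integers(0, 3, size=(6, 1)).astype(np.int8)
        G, A, B = self._two_pop(callsA, callsB)
        grid = pw.make_windows({"chr1": 100}, 100, 100)
        out, _ = pw.fst_windowed(G, A, B, grid)
        comp = wc_oracle_site(callsA[:, 0].tolist(), callsB[:, 0].tolist())
        if comp is None:
            assert np.isnan(out["value"].iloc[0])
        else:
            a, b, c = comp
            assert out["value"].iloc[0] == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_window_without_usable_sites_flagged(self):
        callsA = np.zeros((5, 1), dtype=np.int8)  # monomorphic everywhere
        callsB = np.zeros((5, 1), dtype=np.int8)
        G, A, B = self._two_pop(callsA, callsB)
        grid = pw.make_windows({"chr1": 100}, 100, 100)
        out, mean = pw.fst_windowed(G, A, B, grid)
        assert np.isnan(out["value"].iloc[0])
        assert np.isnan(mean)

    def test_small_population_rejected(self):
        G = build_gm(np.zeros((3, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            pw.fst_windowed(G, G.samples[:1], G.samples[1:],
                            pw.make_windows({"chr1": 100}, 100, 100))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 32 - 1))
def test_pi_property_nonnegative_and_bounded(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 12)
    m = rng.integers(1, 25)
    calls = rng.choice([0, 1, 2, MISSING], size=(n, m)).astype(np.int8)
    G = build_gm(calls, pos=np.arange(1, m + 1))
    grid = pw.make_windows({"chr1": int(m + 1)}, int(m + 1), int(m + 1))
    v = pw.pi_windowed(G, G.samples, grid)["value"].iloc[0]
    # per-site pairwise diversity is at most n/(2(n-1)) <= 1 for n >= 2 alleles
    assert 0.0 <= v <= m / (m + 1) + 1e-9
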