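"""Two-point engine: map functions, pair estimators, phase handling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from agmap.linkage import (
    haldane_cm,
    kosambi_cm,
    kosambi_inverse,
    no_information_pair,
    paternal_alleles,
    rf_intercross_pair,
    rf_mixed_pair,
    rf_testcross_pair,
)


class TestMapFunctions:
    def test_reference_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.1) == pytest.approx(25.0 * np.log(1.5), abs=1e-12)
        assert kosambi_inverse(25.0 * np.log(1.5)) == pytest.approx(0.1, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=0.49))
    def test_round_trip_identity(self, r):
        assert kosambi_inverse(kosambi_cm(r)) == pytest.approx(r, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=0.499))
    def test_bracketed_by_morgan_and_haldane(self, r):
        # complete interference lower bound, no interference upper bound
        d = kosambi_cm(r)
        assert 100.0 * r <= d + 1e-12
        assert d <= haldane_cm(r) + 1e-12

    def test_rejects_unlinked(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)


class TestTestcrossPair:
    def test_perfect_linkage_lod(self):
        a = np.zeros(20, dtype=np.int8)
        pl = rf_testcross_pair(a, a)
        assert pl.r_hat == 0.0
        assert pl.lod == pytest.approx(20 * np.log10(2.0), abs=1e-9)
        assert pl.phase == "coupling"

    def test_independent_markers(self):
        a = np.zeros(20, dtype=np.int8)
        b = a.copy()
        b[:10] = 1
        pl = rf_testcross_pair(a, b)
        assert pl.r_hat == 0.5
        assert pl.lod == 0.0

    def test_repulsion_phase_flip(self):
        a = np.zeros(20, dtype=np.int8)
        b = 1 - a
        b[:2] = 0  # 18 mismatches of 20
        pl = rf_testcross_pair(a, b)
        assert pl.phase == "repulsion"
        assert pl.r_hat == pytest.approx(0.1)

    def test_label_swap_leaves_r_and_lod(self, rng):
        a = rng.integers(0, 2, 60).astype(np.int8)
        b = rng.integers(0, 2, 60).astype(np.int8)
        p1 = rf_testcross_pair(a, b)
        p2 = rf_testcross_pair(a, (1 - b).astype(np.int8))
        assert p1.r_hat == pytest.approx(p2.r_hat, abs=1e-12)
        assert p1.lod == pytest.approx(p2.lod, abs=1e-9)
        assert {p1.phase, p2.phase} == {"coupling", "repulsion"} or p1.r_hat == 0.5

    def test_lod_increases_with_n_at_fixed_ratio(self):
        lods = []
        for n in (20, 40, 80):
            a = np.zeros(n, dtype=np.int8)
            b = a.copy()
            b[: n // 10] = 1  # R/N = 0.1
            lods.append(rf_testcross_pair(a, b).lod)
        assert lods[0] < lods[1] < lods[2]


def _enum_intercross_cells(r, phase_f, phase_m):
    """Independent enumeration of the 3x3 table for an hkxhk pair."""
    cells = np.zeros((3, 3))
    for x1 in (0, 1):
        for x2 in (0, 1):
            pf = (1 - r if x1 == x2 else r) / 2.0
            if phase_f == "r":
                pf = (r if x1 == x2 else 1 - r) / 2.0
            for y1 in (0, 1):
                for y2 in (0, 1):
                    pm = (1 - r if y1 == y2 else r) / 2.0
                    if phase_m == "r":
                        pm = (r if y1 == y2 else 1 - r) / 2.0
                    cells[x1 + y1, x2 + y2] += pf * pm
    return cells.ravel()


def _enum_mixed_cells(r, phase):
    """Independent enumeration of the 2x3 table for a testcross/hk pair."""
    cells = np.zeros((2, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            same = a1 == a2
            p = (1 - r if same else r) / 2.0
            if phase == "r":
                p = (r if same else 1 - r) / 2.0
            for m in (0, 1):
                cells[a1, a2 + m] += p * 0.5
    return cells.ravel()


GRID = np.arange(0.0, 0.5 + 1e-12, 1e-4)


@pytest.fixture(scope="module")
def intercross_grid():
    tables = np.stack(
        [
            np.stack([_enum_intercross_cells(r, pf, pm) for r in GRID])
            for pf, pm in (("c", "c"), ("c", "r"), ("r", "c"), ("r", "r"))
        ]
    )  # (4, n_grid, 9)
    return np.log(np.maximum(tables, 1e-300))


@pytest.fixture(scope="module")
def mixed_grid():
    tables = np.stack(
        [np.stack([_enum_mixed_cells(r, ph) for r in GRID]) for ph in ("c", "r")]
    )
    return np.log(np.maximum(tables, 1e-300))


class TestGridSearchOracles:
    """r_hat must match exhaustive grid maximisation of the likelihood."""

    def test_intercross_matches_grid(self, rng, intercross_grid):
        for _ in range(200):
            n = int(rng.integers(30, 200))
            r_true = float(rng.uniform(0.0, 0.5))
            probs = _enum_intercross_cells(r_true, "c", "c")
            counts = rng.multinomial(n, probs)
            ll = np.einsum("c,pgc->pg", counts, intercross_grid)
            r_grid = GRID[ll.max(axis=0).argmax()]
            a, b = _counts_to_calls(counts, 3, rng)
            est = rf_intercross_pair(a, b)
            assert abs(est.r_hat - r_grid) <= 1e-3

    def test_mixed_matches_grid(self, rng, mixed_grid):
        for _ in range(200):
            n = int(rng.integers(30, 200))
            r_true = float(rng.uniform(0.0, 0.5))
            counts = rng.multinomial(n, _enum_mixed_cells(r_true, "c"))
            ll = np.einsum("c,pgc->pg", counts, mixed_grid)
            r_grid = GRID[ll.max(axis=0).argmax()]
            a, b = _counts_to_calls(counts, (2, 3), rng)
            est = rf_mixed_pair(a, b)
            assert abs(est.r_hat - r_grid) <= 1e-3

    def test_testcross_closed_form_is_exact(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 200))
            a = rng.integers(0, 2, n).astype(np.int8)
            b = rng.integers(0, 2, n).astype(np.int8)
            est = rf_testcross_pair(a, b)
            mism = int((a != b).sum())
            assert est.r_hat == min(mism, n - mism) / n


def _counts_to_calls(counts, shape, rng):
    """Expand a joint count table into two aligned call vectors."""
    if isinstance(shape, int):
        shape = (shape, shape)
    counts = np.asarray(counts).reshape(shape)
    a, b = [], []
    for i in range(shape[0]):
        for j in range(shape[1]):
            a += [i] * counts[i, j]
            b += [j] * counts[i, j]
    return np.array(a, dtype=np.int8), np.array(b, dtype=np.int8)


class TestIntercrossPair:
    def test_cosegregating_pair(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 1, 0, 2], dtype=np.int8)
        pl = rf_intercross_pair(g, g)
        assert pl.r_hat == pytest.approx(0.0, abs=1e-9)
        assert pl.phase == "cc"

    def test_recovers_simulated_r(self, rng):
        r_true, n = 0.2, 10000
        counts = rng.multinomial(n, _enum_intercross_cells(r_true, "c", "c"))
        a, b = _counts_to_calls(counts, 3, rng)
        pl = rf_intercross_pair(a, b)
        se = np.sqrt(r_true * (1 - r_true) / (2 * n))
        assert abs(pl.r_hat - r_true) < 3 * se
        assert pl.phase == "cc"

    def test_independence_table_gives_half(self):
        # exact outer product of 1:2:1 margins, scaled to integers
        marg = np.array([1, 2, 1])
        counts = np.outer(marg, marg) * 4
        a, b = _counts_to_calls(counts, 3, np.random.default_rng(0))
        pl = rf_intercross_pair(a, b)
        assert pl.r_hat == pytest.approx(0.5, abs=1e-6)
        assert pl.lod == pytest.approx(0.0, abs=1e-6)


class TestMixedPair:
    def test_recovers_simulated_r(self, rng):
        r_true, n = 0.1, 5000
        counts = rng.multinomial(n, _enum_mixed_cells(r_true, "c"))
        a, b = _counts_to_calls(counts, (2, 3), rng)
        pl = rf_mixed_pair(a, b)
        se = np.sqrt(r_true * (1 - r_true) / n)
        assert abs(pl.r_hat - r_true) < 3 * se

    def test_heterozygous_offspring_carry_no_information(self, rng):
        # all-AB hk calls: likelihood flat in r, LOD 0
        a = rng.integers(0, 2, 50).astype(np.int8)
        b = np.ones(50, dtype=np.int8)
        pl = rf_mixed_pair(a, b)
        assert pl.lod == pytest.approx(0.0, abs=1e-9)

    def test_unlinked_pair_null_lod_distribution(self, rng):
        # at n=119 an unlinked testcross/hk pair should look unlinked:
        # maximising over r and phase leaves a small null LOD (about 2%
        # of draws exceed 1; none approach the grouping threshold)
        lods = []
        for _ in range(200):
            a = rng.integers(0, 2, 119).astype(np.int8)
            b = (rng.integers(0, 2, 119) + rng.integers(0, 2, 119)).astype(np.int8)
            lods.append(rf_mixed_pair(a, b).lod)
        lods = np.asarray(lods)
        assert (lods < 1.0).mean() >= 0.95
        assert lods.max() < 4.0

    def test_opposite_parent_testcross_pair_flagged(self):
        pl = no_information_pair("m1", "m2")
        assert pl.lod == 0.0
        assert pl.phase == "not-applicable"
        assert pl.flag


class TestPaternalAlleles:
    def test_mother_aa_mapping(self):
        calls = np.array([0, 1, 2, -1], dtype=np.int8)  # AA, AB, BB, NC
        out = paternal_alleles(calls, 0)
        assert out.tolist() == [0, 1, -1, -1]

    def test_mother_bb_mapping(self):
        calls = np.array([2, 1, 0, -1], dtype=np.int8)
        out = paternal_alleles(calls, 2)
        assert out.tolist() == [1, 0, -1, -1]
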