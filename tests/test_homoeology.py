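"""Hit filtering, homoeologous-group assignment, collinearity blocks."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from agmap.datatypes import GeneticMap
from agmap.homoeology import (
    HomoeologyAssigner,
    assign_homoeology,
    detect_synteny_blocks,
    filter_hits,
    longest_monotone_chain,
    scale_map_for_comparison,
)


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["marker_id", "wheat_chromosome", "bp_position", "e_value", "identity"]
    )


def _map_table(entries, origin="integrated"):
    rows = [
        {"lg": lg, "locus_index": i, "marker_id": mid, "position_cM": cm,
         "pattern": "hkxhk", "phase": "na"}
        for lg, i, mid, cm in entries
    ]
    return GeneticMap(origin, pd.DataFrame(rows))


class TestFilterHits:
    def test_e_cutoff_drops_weak_hits(self):
        df = filter_hits(_hits([("m1", "1A", 100, 1e-3, 0.9)]))
        assert df.empty

    def test_top_per_subgenome_and_overall(self):
        df = filter_hits(
            _hits(
                [
                    ("m1", "1A", 10, 1e-30, 0.99),
                    ("m1", "1B", 20, 1e-25, 0.98),
                    ("m1", "1D", 30, 1e-20, 0.97),
                    ("m1", "3B", 40, 1e-08, 0.90),
                ]
            )
        )
        top_sub = df[df["top_subgenome"]]
        assert sorted(top_sub["wheat_chromosome"]) == ["1A", "1B", "1D"]
        assert df[df["top_overall"]]["wheat_chromosome"].tolist() == ["1A"]

    def test_empty_table(self):
        assert filter_hits(_hits([])).empty

    def test_malformed_row_rejected_with_position(self):
        with pytest.raises(ValueError, match="row 0"):
            filter_hits(_hits([("m1", "8Z", 10, 1e-30, 0.9)]))


class TestAssignment:
    def _uniform_map(self, n=100):
        return _map_table([(1, i, f"m{i}", float(i)) for i in range(n)])

    def test_dominant_group_assigned_unambiguously(self, rng):
        gmap = self._uniform_map(200)
        rows = []
        for i in range(200):
            grp = 1 if i < 157 else int(rng.integers(2, 8))  # 78.5% group 1
            sub = "ABD"[i % 3]
            rows.append((f"m{i}", f"{grp}{sub}", 1000 * i + 1, 1e-20, 0.95))
        res = assign_homoeology(gmap, _hits(rows))
        row = res.iloc[0]
        assert row["assigned_P"] == "1P"
        assert row["primary_proportion"] == pytest.approx(0.785)
        assert not row["ambiguous"]

    def test_rearranged_group_flags_ambiguity(self):
        gmap = self._uniform_map(100)
        rows = []
        for i in range(100):
            grp = 4 if i < 45 else (2 if i < 85 else 7)
            rows.append((f"m{i}", f"{grp}A", 1000 * i + 1, 1e-20, 0.95))
        res = assign_homoeology(gmap, _hits(rows))
        row = res.iloc[0]
        assert row["assigned_group"] == 4
        assert row["secondary_group"] == 2
        assert row["ambiguous"]

    def test_uniform_hits_tie_break_deterministic(self):
        gmap = self._uniform_map(14)
        rows = [(f"m{i}", f"{(i % 7) + 1}A", 1000 * i + 1, 1e-20, 0.95) for i in range(14)]
        r1 = assign_homoeology(gmap, _hits(rows))
        r2 = assign_homoeology(gmap, _hits(rows))
        assert r1.iloc[0]["assigned_group"] == r2.iloc[0]["assigned_group"] == 1
        assert r1.iloc[0]["ambiguous"]

    def test_proportions_sum_to_one(self, rng):
        gmap = self._uniform_map(60)
        rows = [
            (f"m{i}", f"{int(rng.integers(1, 8))}{'ABD'[int(rng.integers(3))]}",
             1000 * i + 1, 1e-20, 0.95)
            for i in range(60)
        ]
        res = assign_homoeology(gmap, _hits(rows))
        props = res[[f"prop_group{g}" for g in range(1, 8)]].iloc[0]
        assert props.sum() == pytest.approx(1.0)

    def test_lg_without_hits_unassigned(self):
        gmap = self._uniform_map(5)
        res = assign_homoeology(gmap, _hits([("zz", "1A", 1, 1e-20, 0.9)]))
        assert pd.isna(res.iloc[0]["assigned_group"])


def _oracle_longest(values, gap):
    """Exhaustive longest monotone chain with bounded skips."""
    n = len(values)
    step = gap + 1
    for L in range(n, 0, -1):
        for subset in combinations(range(n), L):
            ok_idx = all(b - a <= step for a, b in zip(subset, subset[1:]))
            if not ok_idx:
                continue
            vals = [values[k] for k in subset]
            inc = all(0 < b - a <= step for a, b in zip(vals, vals[1:]))
            dec = all(0 < a - b <= step for a, b in zip(vals, vals[1:]))
            if inc or dec:
                return L
    return 0


class TestChainOracle:
    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(150):
            n = int(rng.integers(4, 13))
            gap = int(rng.integers(1, 4))
            perm = rng.permutation(n)
            fwd = longest_monotone_chain(perm, gap, decreasing=False)
            rev = longest_monotone_chain(perm, gap, decreasing=True)
            assert max(len(fwd), len(rev)) == _oracle_longest(perm.tolist(), gap)


class TestSyntenyBlocks:
    def _collinear_case(self, reverse=False):
        gmap = _map_table([(1, i, f"m{i}", float(i)) for i in range(20)])
        bp = list(range(20)) if not reverse else list(range(20))[::-1]
        rows = [(f"m{i}", "3B", 1_000_000 * (bp[i] + 1), 1e-20, 0.95) for i in range(20)]
        return gmap, _hits(rows)

    def test_single_forward_block(self):
        gmap, hits = self._collinear_case()
        blocks, rearr, frags = detect_synteny_blocks(gmap, hits)
        assert len(blocks) == 1
        assert blocks.iloc[0]["n_markers"] == 20
        assert blocks.iloc[0]["orientation"] == "forward"
        assert rearr.empty and frags.empty

    def test_single_reverse_block(self):
        gmap, hits = self._collinear_case(reverse=True)
        blocks, _, _ = detect_synteny_blocks(gmap, hits)
        assert len(blocks) == 1
        assert blocks.iloc[0]["orientation"] == "reverse"

    def test_rearranged_segment_reported(self):
        # 30 markers: first 18 collinear on 4A, last 12 collinear on 2A
        gmap = _map_table([(1, i, f"m{i}", float(i)) for i in range(30)])
        rows = [(f"m{i}", "4A", 1_000_000 * (i + 1), 1e-20, 0.95) for i in range(18)]
        rows += [(f"m{i}", "2A", 1_000_000 * (i - 17), 1e-20, 0.95) for i in range(18, 30)]
        blocks, rearr, _ = detect_synteny_blocks(gmap, _hits(rows))
        assert set(blocks["wheat_chromosome"]) == {"4A", "2A"}
        assert rearr["wheat_chromosome"].tolist() == ["2A"]

    def test_clean_simulation_fully_covered_by_blocks(self):
        from agmap.simulate import default_map_truth, simulate_hit_table

        truth = default_map_truth(n_markers_per_chromosome=40, seed=13)
        hits, _ = simulate_hit_table(truth, noise_rate=0.0, rearrangements=[], seed=13)
        entries = []
        for lg, chrom in enumerate(truth.chromosomes, start=1):
            for i, m in enumerate(truth.markers_on(chrom.name)):
                entries.append((lg, i, m.id, m.true_cM))
        gmap = _map_table(entries)
        blocks, rearr, frags = detect_synteny_blocks(gmap, hits)
        assert rearr.empty
        covered = sum(blocks["n_markers"])
        top = filter_hits(hits)
        assert covered == int(top["top_overall"].sum())


class TestScaling:
    def test_linear_scaling(self):
        gmap = _map_table(
            [(1, 0, "a", 0.0), (1, 1, "b", 50.0), (1, 2, "c", 100.0)]
        )
        out = scale_map_for_comparison(gmap, target_bp=500e6)
        assert out["position_bp"].tolist() == [0, 250_000_000, 500_000_000]

    def test_endpoint_maps_to_target(self):
        gmap = _map_table([(1, 0, "a", 0.0), (1, 1, "b", 87.0)])
        out = scale_map_for_comparison(gmap)
        assert out["position_bp"].iloc[-1] == 500_000_000

    def test_zero_length_lg_collapses(self):
        gmap = _map_table([(1, 0, "a", 0.0), (1, 1, "b", 0.0)])
        out = scale_map_for_comparison(gmap)
        assert (out["position_bp"] == 0).all()


class TestAssignerEstimator:
    def test_override_does_not_touch_argmax_silently(self):
        gmap = _map_table([(1, i, f"m{i}", float(i)) for i in range(10)])
        rows = [(f"m{i}", "2A", 1_000_000 * (i + 1), 1e-20, 0.95) for i in range(10)]
        est = HomoeologyAssigner().fit(gmap, _hits(rows), overrides={1: 4})
        row = est.assignments_.iloc[0]
        assert row["assigned_group"] == 4 and row["override_group"] == 4
        assert row["prop_group2"] == pytest.approx(1.0)
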