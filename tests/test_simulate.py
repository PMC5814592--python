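"""Synthetic-data generators: validity, Mendelian behaviour, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agmap.datatypes import AB, BB, NC
from agmap.linkage import kosambi_inverse
from agmap.simulate import (
    Rearrangement,
    SimChromosome,
    SimCrossConfig,
    SimLineSpec,
    SimMapTruth,
    SimMarker,
    default_map_truth,
    default_wheat_marker_map,
    reference_panel_specs,
    simulate_cp_cross,
    simulate_hit_table,
    simulate_introgression_lines,
)


def _two_marker_truth(d_cm, pattern="hkxhk", length=None):
    length = d_cm if length is None else length
    return SimMapTruth(
        [SimChromosome("1P", length)],
        [
            SimMarker("m1", "1P", 0.0, pattern),
            SimMarker("m2", "1P", d_cm, "lmxll" if pattern == "hkxhk" else "hkxhk"),
        ],
    )


class TestTruthValidation:
    def test_rejects_duplicate_marker_ids(self):
        with pytest.raises(ValueError, match="unique"):
            SimMapTruth(
                [SimChromosome("1P", 10.0)],
                [SimMarker("m", "1P", 1.0, "hkxhk"), SimMarker("m", "1P", 2.0, "lmxll")],
            )

    def test_rejects_marker_outside_chromosome(self):
        with pytest.raises(ValueError, match="outside"):
            SimMapTruth(
                [SimChromosome("1P", 10.0)],
                [SimMarker("a", "1P", 11.0, "hkxhk"), SimMarker("b", "1P", 2.0, "lmxll")],
            )

    def test_rejects_single_pattern_chromosome(self):
        with pytest.raises(ValueError, match="single segregation pattern"):
            SimMapTruth(
                [SimChromosome("1P", 10.0)],
                [SimMarker("a", "1P", 1.0, "hkxhk"), SimMarker("b", "1P", 2.0, "hkxhk")],
            )

    def test_rejects_negative_length(self):
        with pytest.raises(ValueError, match="negative"):
            SimMapTruth([SimChromosome("1P", -1.0)], [])

    def test_rejects_tiny_population(self):
        with pytest.raises(ValueError, match="n_progeny"):
            SimCrossConfig(n_progeny=1)


class TestCpCross:
    def test_zero_length_chromosome_forbids_recombination(self):
        truth = _two_marker_truth(0.0, length=0.0)
        cfg = SimCrossConfig(
            n_progeny=50, genotyping_error_rate=0.0, missing_rate=0.0, seed=5
        )
        gm, st = simulate_cp_cross(truth, cfg)
        # no crossovers: each progeny's haplotype origin is constant per parent
        assert (st["paternal_origin"].nunique(axis=0) == 1).all()
        assert (st["maternal_origin"].nunique(axis=0) == 1).all()

    def test_testcross_marker_never_shows_other_homozygote(self):
        truth = _two_marker_truth(5.0, pattern="lmxll")
        cfg = SimCrossConfig(n_progeny=200, genotyping_error_rate=0.0, missing_rate=0.0, seed=3)
        gm, _ = simulate_cp_cross(truth, cfg)
        row = gm.calls[0, gm.progeny_indices]  # lmxll marker, mother AA
        assert set(row.tolist()) <= {0, 1}

    def test_parent_calls_follow_pattern(self):
        truth = default_map_truth(n_markers_per_chromosome=20, seed=0)
        gm, _ = simulate_cp_cross(truth, SimCrossConfig(seed=0))
        fi, mi = gm.father_index, gm.mother_index
        for i, m in enumerate(truth.markers):
            f, mo = gm.calls[i, fi], gm.calls[i, mi]
            if m.pattern == "hkxhk":
                assert (f, mo) == (AB, AB)
            elif m.pattern == "lmxll":
                assert f == AB and mo != AB
            else:
                assert mo == AB and f != AB

    def test_recombinant_fraction_matches_kosambi_inverse(self):
        # two markers 10 cM apart; r = kosambi_inverse(10) approx 0.0987
        truth = SimMapTruth(
            [SimChromosome("1P", 10.0)],
            [SimMarker("a", "1P", 0.0, "hkxhk"), SimMarker("b", "1P", 10.0, "lmxll")],
        )
        cfg = SimCrossConfig(n_progeny=2000, genotyping_error_rate=0.0, missing_rate=0.0, seed=7)
        _, st = simulate_cp_cross(truth, cfg)
        po = st["paternal_origin"].to_numpy()
        frac = float((po[0] != po[1]).mean())
        # the generator's Poisson process realises Haldane r; at 10 cM the
        # Kosambi inverse differs from it by far less than sampling noise
        r_expect = kosambi_inverse(10.0)
        se = np.sqrt(r_expect * (1 - r_expect) / 2000)
        assert abs(frac - r_expect) < 3 * se

    def test_mendelian_segregation_when_clean(self):
        truth = default_map_truth(n_markers_per_chromosome=150, seed=4)
        cfg = SimCrossConfig(
            n_progeny=119, genotyping_error_rate=0.0, missing_rate=0.0, seed=4
        )
        gm, _ = simulate_cp_cross(truth, cfg)
        prog = gm.progeny_indices
        pvals = []
        for i, m in enumerate(truth.markers):
            calls = gm.calls[i, prog]
            if m.pattern == "hkxhk":
                obs = [(calls == g).sum() for g in (0, 1, 2)]
                exp = np.array([0.25, 0.5, 0.25]) * len(calls)
                chi2 = (((np.array(obs) - exp) ** 2) / exp).sum()
                pvals.append(stats.chi2.sf(chi2, 2))
            else:
                n_ab = (calls == AB).sum()
                chi2 = (2 * n_ab - len(calls)) ** 2 / len(calls)
                pvals.append(stats.chi2.sf(chi2, 1))
        rej = np.mean(np.asarray(pvals) < 0.05)
        m = len(pvals)
        assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m) + 0.01

    def test_byte_identical_for_fixed_seed(self):
        truth = default_map_truth(n_markers_per_chromosome=10, seed=9)
        cfg = SimCrossConfig(n_progeny=30, seed=9)
        gm1, _ = simulate_cp_cross(truth, cfg)
        gm2, _ = simulate_cp_cross(truth, cfg)
        assert gm1 == gm2


class TestHitTable:
    def test_clean_hits_fall_in_true_group(self):
        truth = default_map_truth(n_markers_per_chromosome=30, seed=2)
        hits, ht = simulate_hit_table(truth, noise_rate=0.0, rearrangements=[], seed=2)
        assert (ht["hit_group"] == ht["true_group"]).all()

    def test_noise_rate_expectation(self):
        truth = default_map_truth(n_markers_per_chromosome=80, seed=3)
        _, ht = simulate_hit_table(truth, noise_rate=0.2, rearrangements=[], seed=3)
        # noise hits land in the true group by chance 3/21 of the time
        p = 0.8 + 0.2 * 3 / 21
        frac = (ht["hit_group"] == ht["true_group"]).mean()
        n = len(ht)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_default_rearrangement_bookkeeping(self):
        truth = default_map_truth(n_markers_per_chromosome=100, seed=4)
        _, ht = simulate_hit_table(truth, noise_rate=0.0, seed=4)
        lg4 = ht[ht["chromosome"] == "4P"]
        frac_group2 = (lg4["hit_group"] == 2).mean()
        # default event: the proximal 40% of 4P hits group 2; marker
        # positions are uniform so the fraction is binomial around 0.4
        assert abs(frac_group2 - 0.4) < 3 * np.sqrt(0.4 * 0.6 / len(lg4))

    def test_rejects_overlapping_segments(self):
        truth = default_map_truth(n_markers_per_chromosome=10, seed=5)
        with pytest.raises(ValueError, match="overlap"):
            simulate_hit_table(
                truth,
                rearrangements=[
                    Rearrangement("4P", 0.0, 50.0, 2),
                    Rearrangement("4P", 40.0, 60.0, 7),
                ],
            )

    def test_retained_evalues_below_cutoff(self):
        truth = default_map_truth(n_markers_per_chromosome=20, seed=6)
        hits, _ = simulate_hit_table(truth, junk_hit_rate=0.0, seed=6)
        assert (hits["e_value"] <= 1e-5).all()


class TestIntrogressionLines:
    def test_addition_and_substitution_rates(self):
        mm = default_wheat_marker_map(seed=1)
        spec = SimLineSpec("L1", {"6P"}, {("6P", "6D")})
        gm, _ = simulate_introgression_lines([spec], mm, seed=1)
        calls = gm.calls[:, 0]
        chroms = mm["chromosome"].to_numpy()
        for chrom, expect in (("6A", 0.15), ("6B", 0.15), ("1A", 0.01)):
            on = chroms == chrom
            c = calls[on]
            rate = (c == AB).sum() / (c != NC).sum()
            se = np.sqrt(expect * (1 - expect) / on.sum())
            assert abs(rate - expect) < 4 * se, chrom
        on = chroms == "6D"
        miss = (calls[on] == NC).mean()
        assert abs(miss - 0.6) < 4 * np.sqrt(0.6 * 0.4 / on.sum())

    def test_null_line_stays_at_baseline(self):
        mm = default_wheat_marker_map(seed=2)
        spec = SimLineSpec("null", frozenset(), frozenset())
        gm, _ = simulate_introgression_lines([spec], mm, seed=2)
        calls = gm.calls[:, 0]
        for chrom in np.unique(mm["chromosome"]):
            on = mm["chromosome"].to_numpy() == chrom
            c = calls[on]
            het = (c == AB).sum() / (c != NC).sum()
            assert het < 0.01 + 3 * np.sqrt(0.01 * 0.99 / on.sum())

    def test_rejects_non_homoeologous_substitution(self):
        with pytest.raises(ValueError, match="homoeologous"):
            simulate_introgression_lines(
                [SimLineSpec("bad", {"6P"}, {("6P", "5D")})],
                default_wheat_marker_map(n_per_chromosome=10),
            )

    def test_rejects_unknown_chromosome(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate_introgression_lines(
                [SimLineSpec("bad", {"9P"})],
                default_wheat_marker_map(n_per_chromosome=10),
            )

    def test_reference_panel_shape(self):
        specs = reference_panel_specs()
        assert len(specs) == 35
        comps = pd.Series([s.composition for s in specs]).value_counts()
        # 26 single additions, 3 double additions, 5 substitutions,
        # 1 double addition with one chromosome substituting
        assert comps["42W + 2P"] == 26
        assert comps["42W + 4P"] == 3
        assert comps["40W + 2P"] == 5
        assert comps["40W + 4P"] == 1
        ii31 = next(s for s in specs if s.line_id == "II-3-1")
        assert ii31.additions == frozenset({"1P", "2P"})
        assert ii31.substitutions == frozenset({("1P", "1A")})
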