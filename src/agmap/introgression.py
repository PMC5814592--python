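"""Detection of alien addition/substitution chromosomes in wheat lines.

An added pair of alien (P-genome) chromosomes does not genotype directly
on a wheat SNP array; instead its probes cross-hybridise with the three
wheat homoeologs of the added chromosome, inflating heterozygous calls
there.  A substituted wheat chromosome is physically absent, so its
genome-specific markers fail, inflating missingness.  The caller turns
these two signals into deterministic chromosome calls:

* a wheat chromosome is *het-hot* when its heterozygosity ratio exceeds
  the line's median by ``het_z_min`` robust standard deviations
  (MAD-scaled across the 21 chromosomes);
* hot chromosomes vote for their homoeologous group; groups are ranked
  by (number of hot homoeologs, mean excess heterozygosity) and mapped
  to P chromosomes through the homoeology table;
* a chromosome whose genome-specific missing rate exceeds the analogous
  robust threshold is a substitution candidate, called only when it is
  homoeologous to a called addition.

If a cytological chromosome count is available (GISH), the expected
number of alien pairs selects exactly that many top groups, mirroring
how single and double additions are disambiguated in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import AB, NC, GenotypeMatrix, WHEAT_CHROMOSOMES

__all__ = [
    "EvidenceTrack",
    "het_profile",
    "call_additions",
    "call_substitutions",
    "compose_label",
    "batch_report",
    "IntrogressionCaller",
]


@dataclass
class EvidenceTrack:
    """Per-line heterozygosity and missingness evidence.

    ``chromosomes``: per wheat chromosome het_ratio (AB / called, all
    markers) and missing_rate (NC / total, genome-specific markers only).
    ``windows``: sliding-window het ratios along each chromosome;
    windows with fewer than ``min_window_markers`` called markers are
    flagged uninformative.
    """

    line_id: str
    chromosomes: pd.DataFrame
    windows: pd.DataFrame


def _chromosome_stats(calls, marker_map):
    chroms = marker_map["chromosome"].to_numpy()
    specific = marker_map["genome_specific"].to_numpy(bool)
    rows = []
    for chrom in WHEAT_CHROMOSOMES:
        on = chroms == chrom
        c = calls[on]
        called = c != NC
        n_called = int(called.sum())
        het = float((c == AB).sum() / n_called) if n_called else np.nan
        sp = calls[on & specific]
        missing = float((sp == NC).mean()) if len(sp) else np.nan
        rows.append(
            {
                "chromosome": chrom,
                "n_markers": int(on.sum()),
                "n_called": n_called,
                "het_ratio": het,
                "n_specific": int((on & specific).sum()),
                "missing_rate": missing,
            }
        )
    return pd.DataFrame(rows)


def _window_track(calls, marker_map, window_bp, step_bp, min_window_markers):
    rows = []
    for chrom in WHEAT_CHROMOSOMES:
        on = marker_map["chromosome"].to_numpy() == chrom
        bp = marker_map.loc[on, "bp_position"].to_numpy()
        order = np.argsort(bp, kind="stable")
        bp = bp[order]
        c = calls[on][order]
        if len(bp) == 0:
            continue
        chrom_end = int(bp.max()) + 1
        called = (c != NC).astype(np.int64)
        het = (c == AB).astype(np.int64)
        cum_called = np.concatenate(([0], np.cumsum(called)))
        cum_het = np.concatenate(([0], np.cumsum(het)))
        starts = np.arange(0, chrom_end, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, chrom_end)
        lo = np.searchsorted(bp, starts, side="left")
        hi = np.searchsorted(bp, ends, side="left")
        n_called = cum_called[hi] - cum_called[lo]
        n_het = cum_het[hi] - cum_het[lo]
        with np.errstate(invalid="ignore"):
            ratio = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start_bp": starts,
                    "end_bp": ends,
                    "n_called": n_called,
                    "het_ratio": ratio,
                    "informative": n_called >= min_window_markers,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chromosome", "start_bp", "end_bp", "n_called", "het_ratio", "informative"]
    )


def het_profile(
    line_calls,
    marker_map: pd.DataFrame,
    window_mb: float = 50.0,
    step_mb: float = 1.0,
    min_window_markers: int = 10,
    line_id: str = "",
) -> EvidenceTrack:
    """Evidence track for one line.

    ``line_calls`` is the encoded call vector aligned with
    ``marker_map`` rows (columns: marker_id, chromosome, bp_position,
    genome_specific).  Windows are half-open ``[start, start + window)``
    advancing by ``step``, the last clipped at the chromosome end.
    """
    if window_mb < step_mb:
        raise ValueError("window must be at least the step")
    calls = np.asarray(line_calls, dtype=np.int8)
    if len(calls) != len(marker_map):
        raise ValueError("call vector does not match the marker map")
    chrom_table = _chromosome_stats(calls, marker_map)
    windows = _window_track(
        calls, marker_map, int(window_mb * 1e6), int(step_mb * 1e6), min_window_markers
    )
    return EvidenceTrack(line_id, chrom_table, windows)


def _robust_threshold(values, counts, z_min, spread_floor):
    """Median + z robust-sigma threshold across the 21 chromosomes.

    The spread is the MAD-scaled deviation, floored by the binomial
    sampling error of the median rate at the median marker count: with
    most chromosomes sharing one true rate, the between-chromosome MAD
    underestimates the per-chromosome sampling noise.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    v = v[ok]
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    n_med = float(np.median(np.asarray(counts, dtype=float)[ok]))
    binom_se = np.sqrt(max(med * (1.0 - med), 1e-6) / max(n_med, 1.0))
    spread = max(1.4826 * mad, binom_se, spread_floor)
    return med + z_min * spread, med, spread


def call_additions(
    track: EvidenceTrack,
    group_to_p: dict,
    expected_alien_count: int | None = None,
    het_z_min: float = 5.0,
    spread_floor: float = 0.005,
):
    """Added P chromosomes from the line's chromosome heterozygosity.

    Returns ``(added, detail)`` where ``added`` is a sorted list of P
    chromosome names and ``detail`` a DataFrame of group-level evidence.
    With an expected alien pair count, exactly the top-ranked groups up
    to that count (among groups with at least one hot homoeolog) are
    called; otherwise every group with at least two hot homoeologs.
    """
    tab = track.chromosomes.dropna(subset=["het_ratio"])
    thr, med, spread = _robust_threshold(
        tab["het_ratio"], tab["n_called"], het_z_min, spread_floor
    )
    hot = tab[tab["het_ratio"] > thr]
    votes = []
    for g in range(1, 8):
        members = hot[hot["chromosome"].str[0].astype(int) == g]
        if len(members):
            votes.append(
                {
                    "group": g,
                    "n_hot": len(members),
                    "mean_excess": float((members["het_ratio"] - med).mean()),
                    "hot_chromosomes": ",".join(members["chromosome"]),
                }
            )
    detail = pd.DataFrame(votes, columns=["group", "n_hot", "mean_excess", "hot_chromosomes"])
    if len(detail):
        detail = detail.sort_values(
            ["n_hot", "mean_excess", "group"], ascending=[False, False, True], kind="stable"
        ).reset_index(drop=True)
    if expected_alien_count is not None:
        called = detail.head(expected_alien_count)["group"].tolist()
    else:
        called = detail[detail["n_hot"] >= 2]["group"].tolist()
    added = sorted(group_to_p.get(g, f"{g}P") for g in called)
    return added, detail


def call_substitutions(
    track: EvidenceTrack,
    added_p: list,
    group_to_p: dict,
    missing_z_min: float = 5.0,
    spread_floor: float = 0.005,
):
    """Substituted wheat chromosomes from genome-specific missingness.

    A candidate (missing rate above the robust threshold) is called only
    when its homoeologous P chromosome is among the line's additions;
    otherwise it is reported as unexplained missingness.
    Returns ``(substitutions, unexplained)`` with substitutions as
    (P chromosome, wheat chromosome) pairs.
    """
    tab = track.chromosomes.dropna(subset=["missing_rate"])
    thr, _, _ = _robust_threshold(
        tab["missing_rate"], tab["n_specific"], missing_z_min, spread_floor
    )
    candidates = tab[tab["missing_rate"] > thr]["chromosome"].tolist()
    p_of_group = {int(p[0]): p for p in added_p}
    subs, unexplained = [], []
    for chrom in candidates:
        g = int(chrom[0])
        if g in p_of_group:
            subs.append((p_of_group[g], chrom))
        else:
            unexplained.append(chrom)
    return sorted(subs), sorted(unexplained)


def compose_label(added_p, substitutions) -> str:
    """Human-readable identification in the conventional form.

    Examples: ``1P addition line``, ``2P and 5P addition line``,
    ``6P/6D substitution line``, ``2P addition and 1P/1A substitution
    line``.
    """
    sub_p = {p for p, _ in substitutions}
    pure = sorted(set(added_p) - sub_p)
    parts = []
    if pure:
        parts.append(" and ".join(pure) + " addition")
    for p, w in sorted(substitutions):
        parts.append(f"{p}/{w} substitution")
    if not parts:
        return "no introgression detected"
    return " and ".join(parts) + " line"


class IntrogressionCaller(BaseEstimator):
    """Call added P and substituted wheat chromosomes per line.

    ``fit`` takes the homoeology table (group -> P chromosome name, e.g.
    from :meth:`agmap.homoeology.HomoeologyAssigner.group_to_p`); with no
    table the canonical 1..7 -> 1P..7P correspondence is used.
    ``predict`` profiles each line of a genotype matrix and returns the
    call table; evidence tracks are kept in ``tracks_``.

    Parameters
    ----------
    window_mb, step_mb : sliding-window size and step (megabases).
    het_z_min, missing_z_min : robust-z thresholds for hot chromosomes.
    min_window_markers : windows with fewer called markers are flagged.
    spread_floor : lower bound on the MAD-scaled spread, guarding
        against degenerate zero-spread lines.
    """

    def __init__(
        self,
        window_mb: float = 50.0,
        step_mb: float = 1.0,
        het_z_min: float = 5.0,
        missing_z_min: float = 5.0,
        min_window_markers: int = 10,
        spread_floor: float = 0.005,
    ):
        self.window_mb = window_mb
        self.step_mb = step_mb
        self.het_z_min = het_z_min
        self.missing_z_min = missing_z_min
        self.min_window_markers = min_window_markers
        self.spread_floor = spread_floor

    def fit(self, group_to_p: dict | None = None, y=None):
        self.group_to_p_ = dict(group_to_p) if group_to_p else {
            g: f"{g}P" for g in range(1, 8)
        }
        return self

    def predict(
        self,
        lines: GenotypeMatrix,
        marker_map: pd.DataFrame,
        expected_counts: dict | None = None,
    ) -> pd.DataFrame:
        if not hasattr(self, "group_to_p_"):
            self.fit()
        order = marker_map["marker_id"]
        gm = lines.subset_markers(order)
        self.tracks_ = {}
        rows = []
        for j, line_id in enumerate(gm.sample_ids):
            calls = gm.calls[:, j]
            track = het_profile(
                calls,
                marker_map,
                self.window_mb,
                self.step_mb,
                self.min_window_markers,
                line_id=str(line_id),
            )
            self.tracks_[str(line_id)] = track
            expected = None if expected_counts is None else expected_counts.get(line_id)
            added, detail = call_additions(
                track, self.group_to_p_, expected, self.het_z_min, self.spread_floor
            )
            subs, unexplained = call_substitutions(
                track, added, self.group_to_p_, self.missing_z_min, self.spread_floor
            )
            n_w = 42 - 2 * len(subs)
            n_p = 2 * len(added)
            rows.append(
                {
                    "line_id": line_id,
                    "composition": f"{n_w}W + {n_p}P" if added else "",
                    "added_P": "+".join(added),
                    "missing_chromosome": "+".join(w for _, w in subs),
                    "substitutions": "+".join(f"{p}/{w}" for p, w in subs),
                    "identification": compose_label(added, subs),
                    "unexplained_missing": "+".join(unexplained),
                    "expected_alien_count": expected if expected is not None else pd.NA,
                }
            )
        self.calls_ = pd.DataFrame(rows)
        return self.calls_


def batch_report(
    lines: GenotypeMatrix,
    marker_map: pd.DataFrame,
    group_to_p: dict | None = None,
    expected_counts: dict | None = None,
    **params,
):
    """Profile and call every line; returns ``(report, caller)``.

    The report has one row per line with composition, added P
    chromosome(s), missing wheat chromosome(s) and the identification
    string; window tracks for plotting sit on the returned caller.
    """
    caller = IntrogressionCaller(**params).fit(group_to_p)
    report = caller.predict(lines, marker_map, expected_counts)
    return report, caller
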