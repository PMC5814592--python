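"""Homoeologous-group assignment and synteny blocks for linkage groups.

Wheat chromosomes come in homoeologous groups 1..7 across the A, B and D
subgenomes; a wild relative's chromosome (here 1P..7P) corresponds to one
group.  Each linkage group is assigned to the group that receives the
largest share of its markers' best alignment hits; rearranged segments
(e.g. a 4P segment whose markers hit group 2) show up as a strong
secondary group and as collinear blocks on off-group chromosomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import GeneticMap, WHEAT_CHROMOSOMES

__all__ = [
    "filter_hits",
    "assign_homoeology",
    "detect_synteny_blocks",
    "scale_map_for_comparison",
    "longest_monotone_chain",
    "HomoeologyAssigner",
]

_HIT_COLUMNS = ["marker_id", "wheat_chromosome", "bp_position", "e_value", "identity"]


def filter_hits(raw: pd.DataFrame, e_cutoff: float = 1e-5) -> pd.DataFrame:
    """Filter an alignment-hit table and flag top hits.

    Rows with e-value above ``e_cutoff`` are dropped.  Among retained
    rows, the best hit per marker (smallest e-value, ties broken by
    chromosome name then position) is flagged ``top_overall`` and the
    best per subgenome ``top_subgenome``.  Malformed rows are rejected
    with their row number.
    """
    missing = [c for c in _HIT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"hit table lacks columns {missing}")
    df = raw.copy()
    for row_no, row in enumerate(df.itertuples(index=False)):
        chrom = str(row.wheat_chromosome)
        if chrom not in WHEAT_CHROMOSOMES:
            raise ValueError(f"row {row_no}: unknown wheat chromosome {chrom!r}")
        if not np.isfinite(row.e_value) or row.e_value <= 0:
            raise ValueError(f"row {row_no}: invalid e-value {row.e_value!r}")
        if row.bp_position < 0:
            raise ValueError(f"row {row_no}: negative bp position")
    df = df[df["e_value"] <= e_cutoff].copy()
    if df.empty:
        df["subgenome"] = pd.Series(dtype=object)
        df["top_overall"] = pd.Series(dtype=bool)
        df["top_subgenome"] = pd.Series(dtype=bool)
        return df.reset_index(drop=True)
    df["subgenome"] = df["wheat_chromosome"].str[-1]
    df = df.sort_values(
        ["marker_id", "e_value", "wheat_chromosome", "bp_position"], kind="stable"
    ).reset_index(drop=True)
    df["top_overall"] = ~df.duplicated("marker_id")
    df["top_subgenome"] = ~df.duplicated(["marker_id", "subgenome"])
    return df


def _group_of(chrom_series) -> np.ndarray:
    return chrom_series.astype(str).str[0].astype(int).to_numpy()


def assign_homoeology(
    genetic_map: GeneticMap,
    hits: pd.DataFrame,
    ambiguity_ratio: float = 0.5,
    use_all_subgenome_tops: bool = False,
) -> pd.DataFrame:
    """Assign each linkage group to a wheat homoeologous group.

    For every LG the distribution of its markers' top-hit groups (A/B/D
    pooled by the chromosome's leading digit) is computed; the assigned
    group is the argmax and the corresponding P chromosome is
    ``"<group>P"``.  The ambiguity flag fires when the runner-up group
    reaches ``ambiguity_ratio`` of the winner — the signature of a
    large interchromosomal rearrangement.  Ties break towards the group
    supported by more distinct wheat chromosomes, then the smaller group
    number.  Per-chromosome orientation is the sign of the Spearman
    correlation between cM and bp.
    """
    if "top_overall" not in hits.columns:
        hits = filter_hits(hits)
    top = hits[hits["top_subgenome" if use_all_subgenome_tops else "top_overall"]]
    rows = []
    for lg in genetic_map.lg_ids:
        sub = genetic_map.group(lg)
        merged = sub.merge(top, on="marker_id", how="inner")
        if merged.empty:
            rows.append(
                {
                    "lg": lg, "assigned_group": pd.NA, "assigned_P": pd.NA,
                    "n_hits": 0, "primary_proportion": np.nan,
                    "secondary_group": pd.NA, "secondary_proportion": np.nan,
                    "ambiguous": pd.NA,
                    **{f"prop_group{g}": np.nan for g in range(1, 8)},
                }
            )
            continue
        groups = _group_of(merged["wheat_chromosome"])
        counts = np.bincount(groups, minlength=8)[1:8].astype(float)
        props = counts / counts.sum()
        support = [
            merged.loc[groups == g, "wheat_chromosome"].nunique() for g in range(1, 8)
        ]
        ranking = sorted(
            range(1, 8), key=lambda g: (-props[g - 1], -support[g - 1], g)
        )
        primary, secondary = ranking[0], ranking[1]
        ambiguous = bool(
            props[secondary - 1] > 0
            and props[secondary - 1] >= ambiguity_ratio * props[primary - 1]
        )
        row = {
            "lg": lg,
            "assigned_group": primary,
            "assigned_P": f"{primary}P",
            "n_hits": int(counts.sum()),
            "primary_proportion": float(props[primary - 1]),
            "secondary_group": secondary if props[secondary - 1] > 0 else pd.NA,
            "secondary_proportion": float(props[secondary - 1]),
            "ambiguous": ambiguous,
        }
        row.update({f"prop_group{g}": float(props[g - 1]) for g in range(1, 8)})
        rows.append(row)
    return pd.DataFrame(rows)


def _orientation_table(genetic_map, top_hits) -> pd.DataFrame:
    rows = []
    for lg in genetic_map.lg_ids:
        merged = genetic_map.group(lg).merge(top_hits, on="marker_id", how="inner")
        for chrom, sub in merged.groupby("wheat_chromosome"):
            if len(sub) < 3:
                orient = "undetermined"
            else:
                rho = stats.spearmanr(sub["position_cM"], sub["bp_position"]).statistic
                orient = "forward" if rho >= 0 else "reverse"
            rows.append({"lg": lg, "wheat_chromosome": chrom, "orientation": orient,
                         "n_hits": len(sub)})
    return pd.DataFrame(rows, columns=["lg", "wheat_chromosome", "orientation", "n_hits"])


# ---------------------------------------------------------------------------
# Collinearity blocks
# ---------------------------------------------------------------------------

def longest_monotone_chain(bp_rank, max_rank_gap: int = 3, decreasing: bool = False):
    """Longest chain monotone in both coordinates with bounded skips.

    ``bp_rank`` lists bp ranks in cM-rank order.  Consecutive chain
    members may skip at most ``max_rank_gap`` markers in the cM ranking
    and at most ``max_rank_gap`` ranks in the bp ranking.  Returns the
    indices of one longest chain (earliest-start tie-break).
    """
    v = np.asarray(bp_rank)
    if decreasing:
        v = -v
    n = len(v)
    if n == 0:
        return []
    step = max_rank_gap + 1
    best_len = np.ones(n, dtype=int)
    parent = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(max(0, i - step), i):
            if v[j] < v[i] and v[i] - v[j] <= step and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                parent[i] = j
    end = int(np.argmax(best_len))
    chain = []
    while end >= 0:
        chain.append(end)
        end = parent[end]
    return chain[::-1]


def detect_synteny_blocks(
    genetic_map: GeneticMap,
    hits: pd.DataFrame,
    min_block: int = 5,
    max_rank_gap: int = 3,
    assignments: pd.DataFrame | None = None,
):
    """Collinear marker chains per (LG, wheat chromosome) and rearrangements.

    For every LG x wheat chromosome with top hits, maximal chains
    monotone in cM rank and bp rank (forward or reverse) are extracted
    greedily (longest first, members removed, repeat); chains shorter
    than ``min_block`` are discarded.  Retained blocks on a chromosome
    outside the LG's assigned group are reported as rearrangements;
    off-group hits in no block are small-fragment noise.

    Returns ``(blocks, rearrangements, small_fragments)`` DataFrames.
    """
    if "top_overall" not in hits.columns:
        hits = filter_hits(hits)
    top = hits[hits["top_overall"]]
    if assignments is None:
        assignments = assign_homoeology(genetic_map, top)
    assigned = assignments.set_index("lg")["assigned_group"].to_dict()

    blocks, fragments = [], []
    for lg in genetic_map.lg_ids:
        sub = genetic_map.group(lg).merge(top, on="marker_id", how="inner")
        sub = sub.sort_values(["position_cM", "marker_id"], kind="stable")
        for chrom, grp in sub.groupby("wheat_chromosome"):
            grp = grp.sort_values(["position_cM", "marker_id"], kind="stable")
            bp_rank = grp["bp_position"].rank(method="first").to_numpy(int) - 1
            alive = np.arange(len(grp))
            block_no = 0
            while len(alive) >= min_block:
                sub_rank = pd.Series(bp_rank[alive]).rank(method="first").to_numpy(int) - 1
                fwd = longest_monotone_chain(sub_rank, max_rank_gap, decreasing=False)
                rev = longest_monotone_chain(sub_rank, max_rank_gap, decreasing=True)
                chain, orient = (
                    (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
                )
                if len(chain) < min_block:
                    break
                members = alive[np.asarray(chain)]
                rows = grp.iloc[members]
                block_no += 1
                blocks.append(
                    {
                        "lg": lg,
                        "wheat_chromosome": chrom,
                        "block": f"LG{lg}:{chrom}:{block_no}",
                        "n_markers": len(members),
                        "orientation": orient,
                        "cM_start": float(rows["position_cM"].min()),
                        "cM_end": float(rows["position_cM"].max()),
                        "bp_start": int(rows["bp_position"].min()),
                        "bp_end": int(rows["bp_position"].max()),
                        "group": int(chrom[0]),
                        "off_group": int(chrom[0]) != assigned.get(lg),
                        "marker_ids": ",".join(rows["marker_id"]),
                    }
                )
                alive = np.setdiff1d(alive, members)
            for k in alive:
                if int(chrom[0]) != assigned.get(lg):
                    fragments.append(
                        {
                            "lg": lg,
                            "wheat_chromosome": chrom,
                            "marker_id": grp.iloc[k]["marker_id"],
                            "bp_position": int(grp.iloc[k]["bp_position"]),
                        }
                    )
    blocks = pd.DataFrame(
        blocks,
        columns=[
            "lg", "wheat_chromosome", "block", "n_markers", "orientation",
            "cM_start", "cM_end", "bp_start", "bp_end", "group", "off_group",
            "marker_ids",
        ],
    )
    rearrangements = blocks[blocks["off_group"]].reset_index(drop=True)
    fragments = pd.DataFrame(
        fragments, columns=["lg", "wheat_chromosome", "marker_id", "bp_position"]
    )
    return blocks, rearrangements, fragments


def scale_map_for_comparison(genetic_map: GeneticMap, target_bp: float = 500e6) -> pd.DataFrame:
    """Linearly rescale each LG to a fixed pseudo-physical length.

    Every chromosome of the mapped genome is set to ``target_bp``
    (default 500 Mbp) so genetic maps can be drawn against physical wheat
    coordinates: position_bp = position_cM / length_cM * target_bp.  A
    zero-length LG collapses to position 0.
    """
    out = genetic_map.table.copy()
    out["position_bp"] = 0.0
    for lg in genetic_map.lg_ids:
        mask = out["lg"] == lg
        length = out.loc[mask, "position_cM"].max()
        if length > 0:
            out.loc[mask, "position_bp"] = out.loc[mask, "position_cM"] / length * target_bp
    out["position_bp"] = out["position_bp"].round().astype(np.int64)
    return out


class HomoeologyAssigner(BaseEstimator):
    """Assign LGs to wheat homoeologous groups and extract synteny blocks.

    Parameters mirror the underlying operations: ``e_cutoff`` for hit
    filtering, ``ambiguity_ratio`` for the two-group rearrangement flag,
    ``min_block``/``max_rank_gap`` for collinear chaining, and
    ``target_bp`` for pseudo-physical scaling.  An optional override
    table (lg -> group) lets external evidence resolve a flagged
    ambiguity without silently changing the argmax.

    Attributes
    ----------
    hits_ : filtered hit table with top-hit flags.
    assignments_ : per-LG proportions, assigned group/P, ambiguity flags.
    orientation_ : per (LG, wheat chromosome) orientation calls.
    blocks_, rearrangements_, small_fragments_ : collinearity results.
    scaled_map_ : map table with pseudo-bp coordinates.
    """

    def __init__(
        self,
        e_cutoff: float = 1e-5,
        ambiguity_ratio: float = 0.5,
        min_block: int = 5,
        max_rank_gap: int = 3,
        target_bp: float = 500e6,
        use_all_subgenome_tops: bool = False,
    ):
        self.e_cutoff = e_cutoff
        self.ambiguity_ratio = ambiguity_ratio
        self.min_block = min_block
        self.max_rank_gap = max_rank_gap
        self.target_bp = target_bp
        self.use_all_subgenome_tops = use_all_subgenome_tops

    def fit(self, genetic_map: GeneticMap, hits: pd.DataFrame, overrides: dict | None = None):
        self.hits_ = filter_hits(hits, self.e_cutoff)
        self.assignments_ = assign_homoeology(
            genetic_map, self.hits_, self.ambiguity_ratio, self.use_all_subgenome_tops
        )
        if overrides:
            self.assignments_["override_group"] = self.assignments_["lg"].map(overrides)
            use = self.assignments_["override_group"].notna()
            self.assignments_.loc[use, "assigned_group"] = self.assignments_.loc[
                use, "override_group"
            ].astype(int)
            self.assignments_.loc[use, "assigned_P"] = (
                self.assignments_.loc[use, "assigned_group"].astype(int).astype(str) + "P"
            )
        top = self.hits_[self.hits_["top_overall"]]
        self.orientation_ = _orientation_table(genetic_map, top)
        self.blocks_, self.rearrangements_, self.small_fragments_ = detect_synteny_blocks(
            genetic_map, self.hits_, self.min_block, self.max_rank_gap, self.assignments_
        )
        self.scaled_map_ = scale_map_for_comparison(genetic_map, self.target_bp)
        return self

    def group_to_p(self) -> dict:
        """Mapping wheat group -> P chromosome name from the assignments."""
        out = {}
        for _, row in self.assignments_.iterrows():
            if pd.notna(row["assigned_group"]):
                out[int(row["assigned_group"])] = row["assigned_P"]
        return out
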