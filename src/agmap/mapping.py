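"""Linkage-group construction: grouping, ordering, binning, map assembly.

The mapper consumes a QC-filtered CP genotype matrix and produces male,
female and integrated genetic maps:

1. every marker pair is scored with the two-point engines of
   :mod:`agmap.linkage` (testcross, intercross or mixed likelihood,
   depending on the two segregation patterns);
2. markers are grouped by single-linkage transitive closure over pairs
   with LOD above ``lod_limit`` (default 11); groups with at most
   ``min_group_size`` (default 15) markers are discarded;
3. markers with identical informative calls are binned into loci
   (zero observed recombination);
4. loci are ordered by spectral seriation of the Kosambi distance matrix
   followed by ``n_iterations`` rounds of 2-opt segment reversals and
   single-locus ripple reinsertion, minimising the sum of adjacent
   distances;
5. positions are the cumulative Kosambi distances between adjacent loci.

The male map uses lmxll + hkxhk markers (paternal meioses), the female
map nnxnp + hkxhk (maternal), the integrated map all three patterns with
hkxhk markers bridging the parental meioses through mixed-pair
likelihoods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import linalg as sla
from sklearn.base import BaseEstimator

from .datatypes import NC, GeneticMap, GenotypeMatrix
from .linkage import (
    INTERCROSS_PHASES,
    TESTCROSS_PHASES,
    _intercross_cells,
    _mixed_cells,
    _testcross_cells,
    fit_pairs,
    kosambi_cm,
    paternal_alleles,
)
from .qc import MarkerQC

__all__ = ["LinkageMapper", "group_markers", "order_markers", "build_maps"]

_KIND_MALE_TC, _KIND_FEMALE_TC, _KIND_INTERCROSS = 0, 1, 2
_PATTERN_KIND = {"lmxll": _KIND_MALE_TC, "nnxnp": _KIND_FEMALE_TC, "hkxhk": _KIND_INTERCROSS}
_MAX_R = 0.49999


def _encode_markers(gm: GenotypeMatrix, patterns: pd.Series):
    """Per-marker informative-state matrix (state or -1) plus kind vector."""
    fi, mi = gm.father_index, gm.mother_index
    prog = gm.progeny_indices
    data = np.full((gm.n_markers, len(prog)), -1, dtype=np.int8)
    kind = np.full(gm.n_markers, -1, dtype=np.int8)
    for i, mid in enumerate(gm.marker_ids):
        pat = patterns.get(mid)
        if pat not in _PATTERN_KIND:
            continue
        kind[i] = _PATTERN_KIND[pat]
        calls = gm.calls[i, prog]
        if pat == "hkxhk":
            data[i] = calls
        elif pat == "lmxll":
            data[i] = paternal_alleles(calls, int(gm.calls[i, mi]))
        else:
            data[i] = paternal_alleles(calls, int(gm.calls[i, fi]))
    return data, kind


def _pair_state_counts(data):
    """3x3 joint-state counts for every marker pair via one-hot products."""
    m = data.shape[0]
    H = [(data == s).astype(np.float32) for s in range(3)]
    C = np.empty((3, 3, m, m), dtype=np.float32)
    for a in range(3):
        for b in range(3):
            C[a, b] = H[a] @ H[b].T
    return C  # (3, 3, m, m)


def _all_pairwise(data, kind, error_rate, min_informative):
    """Two-point estimates for all upper-triangle marker pairs.

    Returns a dict of flat arrays (i, j, r, lod, phase label, n, type).
    """
    m = data.shape[0]
    C = _pair_state_counts(data)
    iu, ju = np.triu_indices(m, k=1)
    ki, kj = kind[iu], kind[ju]
    n_pair = C.sum(axis=(0, 1))[iu, ju]

    r = np.full(len(iu), 0.5)
    lod = np.zeros(len(iu))
    phase = np.full(len(iu), "not-applicable", dtype=object)
    ptype = np.full(len(iu), "none", dtype=object)

    # same-parent testcross pairs
    tt = ((ki <= 1) & (kj <= 1) & (ki == kj))
    if tt.any():
        ii, jj = iu[tt], ju[tt]
        counts = np.stack([C[a, b, ii, jj] for a in (0, 1) for b in (0, 1)], axis=1)
        if error_rate == 0.0:
            n = counts.sum(axis=1)
            mismatch = counts[:, 1] + counts[:, 2]
            match = counts[:, 0] + counts[:, 3]
            coupling = match >= mismatch
            R = np.where(coupling, mismatch, match)
            with np.errstate(divide="ignore", invalid="ignore"):
                rh = np.where(n > 0, R / np.maximum(n, 1), 0.5)
                l1 = np.where(R > 0, R * np.log10(2.0 * np.maximum(rh, 1e-300)), 0.0)
                l2 = np.where(n - R > 0, (n - R) * np.log10(2.0 * (1.0 - rh)), 0.0)
            r[tt] = rh
            lod[tt] = np.maximum(l1 + l2, 0.0)
            phase[tt] = np.where(coupling, "coupling", "repulsion")
        else:
            rh, ld, pi = fit_pairs(counts, "testcross", error_rate)
            r[tt], lod[tt] = rh, ld
            phase[tt] = np.array(TESTCROSS_PHASES, dtype=object)[pi]
        ptype[tt] = "testcross"

    # intercross pairs
    xx = (ki == 2) & (kj == 2)
    if xx.any():
        ii, jj = iu[xx], ju[xx]
        counts = np.stack([C[a, b, ii, jj] for a in range(3) for b in range(3)], axis=1)
        rh, ld, pi = fit_pairs(counts, "intercross", error_rate)
        r[xx], lod[xx] = rh, ld
        phase[xx] = np.array(INTERCROSS_PHASES, dtype=object)[pi]
        ptype[xx] = "intercross"

    # mixed pairs (testcross x hkxhk), testcross states first
    mix = ((ki <= 1) & (kj == 2)) | ((ki == 2) & (kj <= 1))
    if mix.any():
        ii, jj = iu[mix], ju[mix]
        swap = kind[ii] == 2
        ti = np.where(swap, jj, ii)
        hi = np.where(swap, ii, jj)
        counts = np.stack([C[a, b, ti, hi] for a in (0, 1) for b in range(3)], axis=1)
        rh, ld, pi = fit_pairs(counts, "mixed", error_rate)
        r[mix], lod[mix] = rh, ld
        phase[mix] = np.array(TESTCROSS_PHASES, dtype=object)[pi]
        ptype[mix] = "mixed"

    # opposite-parent testcross pairs share no meiosis: LOD 0, no estimate
    unreliable = n_pair < min_informative
    lod = np.where(unreliable, 0.0, lod)
    phase_idx = np.full(len(iu), -1, dtype=np.int8)
    for lab, k in [("coupling", 0), ("repulsion", 1)]:
        phase_idx[(phase == lab)] = k
    for k, lab in enumerate(INTERCROSS_PHASES):
        phase_idx[(phase == lab) & (ptype == "intercross")] = k
    return {
        "i": iu, "j": ju, "r_hat": r, "lod": lod, "phase": phase,
        "phase_idx": phase_idx,
        "n_informative": n_pair.astype(int), "pair_type": ptype,
        "usable": (~unreliable) & (ptype != "none"),
    }


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_markers(pairs: pd.DataFrame, lod_limit=11.0, min_group_size=15, linkage="single"):
    """Linkage groups by transitive closure over LOD > ``lod_limit`` edges.

    ``pairs`` needs columns marker_i, marker_j, lod.  Groups with at most
    ``min_group_size`` markers are discarded; retained groups are numbered
    1..k by descending size, ties by smallest member id.  ``linkage`` may
    be ``single`` (join if any pair exceeds the limit) or ``complete``
    (agglomerate only while all cross pairs exceed it).
    """
    strong = pairs[pairs["lod"] > lod_limit]
    members = pd.unique(pairs[["marker_i", "marker_j"]].to_numpy().ravel())
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(members)
        g.add_edges_from(strong[["marker_i", "marker_j"]].itertuples(index=False, name=None))
        comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    elif linkage == "complete":
        from scipy.cluster import hierarchy

        idx = pd.Index(members)
        n = len(idx)
        sim = np.zeros((n, n))
        ii = idx.get_indexer(pairs["marker_i"])
        jj = idx.get_indexer(pairs["marker_j"])
        sim[ii, jj] = sim[jj, ii] = pairs["lod"].to_numpy()
        dist = 1.0 / (1.0 + sim)
        z = hierarchy.linkage(dist[np.triu_indices(n, 1)], method="complete")
        labels = hierarchy.fcluster(z, t=1.0 / (1.0 + lod_limit), criterion="distance")
        comps = [sorted(idx[labels == k], key=str) for k in np.unique(labels)]
    else:
        raise ValueError("linkage must be 'single' or 'complete'")
    comps = [c for c in comps if len(c) > min_group_size]
    comps.sort(key=lambda c: (-len(c), str(min(c, key=str))))
    return {lg + 1: list(c) for lg, c in enumerate(comps)}


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

def _floyd_fill(D):
    """Fill missing entries with shortest-path distances (observed kept)."""
    n = D.shape[0]
    filled = np.where(np.isnan(D), np.inf, D)
    np.fill_diagonal(filled, 0.0)
    sp = filled.copy()
    for k in range(n):
        sp = np.minimum(sp, sp[:, k : k + 1] + sp[k : k + 1, :])
    out = np.where(np.isnan(D), sp, D)
    out[np.isinf(out)] = 100.0  # disconnected: fall back to a long gap
    return out


def _spectral_order(D):
    n = D.shape[0]
    if n <= 2:
        return np.arange(n)
    W = np.exp(-D / 25.0)
    np.fill_diagonal(W, 0.0)
    L = np.diag(W.sum(axis=1)) - W
    _, vecs = sla.eigh(L, subset_by_index=[1, 1])
    f = vecs[:, 0]
    if abs(f.min()) > abs(f.max()):  # deterministic sign
        f = -f
    return np.argsort(f, kind="stable")


def _two_opt_sweep(order, D):
    """One best-improvement 2-opt sweep; reverses segments in place."""
    n = len(order)
    improved = False
    for i in range(n - 1):
        j = np.arange(i + 1, n)
        left = D[order[i - 1], order[i]] if i > 0 else 0.0
        right = np.where(j < n - 1, D[order[j], order[np.minimum(j + 1, n - 1)]], 0.0)
        new_left = D[order[i - 1], order[j]] if i > 0 else 0.0
        new_right = np.where(j < n - 1, D[order[i], order[np.minimum(j + 1, n - 1)]], 0.0)
        delta = (new_left + new_right) - (left + right)
        k = int(np.argmin(delta))
        if delta[k] < -1e-12:
            jj = i + 1 + k
            order[i : jj + 1] = order[i : jj + 1][::-1]
            improved = True
    return improved


def _ripple_sweep(order, D):
    """One pass of removing each locus and reinserting it at its best slot."""
    improved = False
    n = len(order)
    for p in range(n):
        loc = order[p]
        rest = np.delete(order, p)
        # inserting at slot s (0..n-1) adds edges (rest[s-1], loc) and
        # (loc, rest[s]) and removes edge (rest[s-1], rest[s])
        prev_d = np.concatenate(([0.0], D[rest, loc]))
        next_d = np.concatenate((D[loc, rest], [0.0]))
        removed = np.concatenate(([0.0], D[rest[:-1], rest[1:]], [0.0]))
        cost = prev_d + next_d - removed
        s = int(np.argmin(cost))
        if cost[s] < cost[p] - 1e-12:
            order = np.insert(rest, s, loc)
            improved = True
    return order, improved


def order_markers(loci, D, n_iterations=40):
    """Order loci on a Kosambi distance matrix.

    Parameters
    ----------
    loci : sequence of locus labels (used for the orientation rule).
    D : (n, n) distance matrix in cM; NaN entries are imputed by shortest
        paths through observed entries.
    n_iterations : improvement rounds of 2-opt + ripple polishing.

    Returns ``(order, positions_cM)``; the orientation is normalised so
    the lexicographically smallest locus label sits in the first half.
    """
    n = len(loci)
    if n == 0:
        return np.array([], dtype=int), np.array([])
    if n == 1:
        return np.array([0]), np.array([0.0])
    Df = _floyd_fill(np.asarray(D, dtype=float))
    order = _spectral_order(Df)
    for _ in range(n_iterations):
        imp1 = _two_opt_sweep(order, Df)
        order, imp2 = _ripple_sweep(order, Df)
        if not (imp1 or imp2):
            break
    # canonical orientation
    labels = [str(loci[k]) for k in order]
    anchor = labels.index(min(labels))
    if anchor >= (n + 1) // 2:
        order = order[::-1]
    gaps = Df[order[:-1], order[1:]]
    pos = np.concatenate(([0.0], np.cumsum(gaps)))
    return order, pos


# ---------------------------------------------------------------------------
# Coordinate fitting: weighted 1D MDS for the order, composite-likelihood
# gap estimation for the positions
# ---------------------------------------------------------------------------

def _kosambi_var(r, n):
    """Approximate sampling variance of a Kosambi distance estimate."""
    return (100.0 / (1.0 - 4.0 * r**2)) ** 2 * r * (1.0 - r) / np.maximum(n, 1)


def _smacof_1d(D, W, x0, max_iter=300, tol=1e-9):
    """Weighted metric MDS on the line by SMACOF majorisation.

    Minimises sum w_ij (d_ij - |x_i - x_j|)^2; deterministic given the
    starting configuration.
    """
    n = len(x0)
    x = np.asarray(x0, dtype=float).copy()
    V = np.diag(W.sum(axis=1)) - W
    Vp = np.linalg.pinv(V + np.ones((n, n)) / n)
    old = None
    for _ in range(max_iter):
        diff = x[:, None] - x[None, :]
        ad = np.abs(diff)
        ad[ad < 1e-9] = 1e-9
        B = -W * D / ad
        np.fill_diagonal(B, 0.0)
        B += np.diag(-B.sum(axis=1))
        x = Vp @ (B @ x)
        stress = float((W * (D - np.abs(x[:, None] - x[None, :])) ** 2).sum())
        if old is not None and abs(old - stress) < tol * max(old, 1.0):
            break
        old = stress
    return x


_TYPE_CODE = {"testcross": 0, "intercross": 1, "mixed": 2}


def _composite_gaps(order, counts_by_pair, lo, hi, error_rate, g0, max_iter=200):
    """Adjacent-gap estimates by composite maximum likelihood.

    Given a locus order, every informative pair constrains the gaps it
    spans: the pair's recombination fraction is the Haldane composition
    of the spanned gaps (crossovers accumulate without interference at
    the two-point level), and its likelihood is the same cell model used
    for the pairwise estimates.  The summed pairwise log-likelihood is
    maximised over the non-negative gap vector with L-BFGS-B; gradients
    come from per-pair dlogL/dr (central differences) and the chain rule.
    """
    from scipy.optimize import minimize

    n = len(order)
    if n < 2:
        return np.zeros(0)
    type_groups = []
    for kindname, code in _TYPE_CODE.items():
        rows = [k for k, entry in enumerate(counts_by_pair) if entry[0] == code]
        if rows:
            cnts = np.stack([counts_by_pair[k][1] for k in rows])
            ph = np.array([counts_by_pair[k][2] for k in rows])
            fn = {
                "testcross": _testcross_cells,
                "intercross": _intercross_cells,
                "mixed": _mixed_cells,
            }[kindname]
            type_groups.append((np.array(rows), cnts, ph, fn))
    n_pairs = len(counts_by_pair)

    def objective(g):
        cum = np.concatenate(([0.0], np.cumsum(g)))
        h = cum[hi] - cum[lo]
        r = np.clip(0.5 * (1.0 - np.exp(-h / 50.0)), 1e-7, 0.5 - 1e-7)
        ll = 0.0
        dll = np.zeros(n_pairs)
        for rows, cnts, ph, fn in type_groups:
            rg = r[rows]
            delta = np.minimum(1e-5, np.minimum(rg, 0.5 - rg) / 2.0)
            lp = np.log(np.maximum(fn(rg + delta, ph, error_rate), 1e-320))
            lm = np.log(np.maximum(fn(rg - delta, ph, error_rate), 1e-320))
            l0 = np.log(np.maximum(fn(rg, ph, error_rate), 1e-320))
            ll += float((cnts * l0).sum())
            dll[rows] = ((cnts * (lp - lm)).sum(axis=1)) / (2.0 * delta)
        s = dll * (1.0 - 2.0 * r) / 100.0
        acc = np.zeros(n + 1)
        np.add.at(acc, lo, s)
        np.add.at(acc, hi, -s)
        grad = np.cumsum(acc)[: n - 1]
        return -ll, -grad

    res = minimize(
        objective,
        np.maximum(g0, 1e-3),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (n - 1),
        options={"maxiter": max_iter, "ftol": 1e-12},
    )
    return res.x


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class LinkageMapper(BaseEstimator):
    """Build male, female and integrated linkage maps from a CP cross.

    Parameters
    ----------
    lod_limit : float, default 11
        Minimum pairwise LOD for joining markers into a linkage group.
    min_group_size : int, default 15
        Groups with at most this many markers are discarded.
    n_iterations : int, default 40
        Improvement rounds (2-opt + ripple) when ordering each group.
    error_rate : float, default 0.01
        Genotyping-error rate assumed by the two-point likelihoods.  With
        array data the apparent recombination between tightly linked
        markers is dominated by miscalls; modelling the error keeps
        adjacent distances, and hence map length, consistent.
    min_informative : int, default 20
        Pairs observed in fewer progeny are excluded.
    linkage : 'single' (default) or 'complete' grouping.

    Attributes
    ----------
    pairs_ : DataFrame of all two-point estimates.
    groups_ : dict lg_id -> list of marker ids.
    maps_ : dict origin -> :class:`~agmap.datatypes.GeneticMap`.
    summary_ : per-origin, per-LG map statistics.
    """

    def __init__(
        self,
        lod_limit: float = 11.0,
        min_group_size: int = 15,
        n_iterations: int = 40,
        error_rate: float = 0.01,
        min_informative: int = 20,
        linkage: str = "single",
    ):
        self.lod_limit = lod_limit
        self.min_group_size = min_group_size
        self.n_iterations = n_iterations
        self.error_rate = error_rate
        self.min_informative = min_informative
        self.linkage = linkage

    # -- internal helpers --------------------------------------------------

    def _pattern_table(self, gm, qc_table):
        if qc_table is None:
            qc = MarkerQC().fit(gm)
            qc_table = qc.table_
        kept = qc_table.index[qc_table["kept"]] if "kept" in qc_table else qc_table.index
        return qc_table.loc[kept, "pattern"]

    def fit(self, gm: GenotypeMatrix, y=None, qc_table: pd.DataFrame | None = None):
        patterns = self._pattern_table(gm, qc_table)
        sub = gm.subset_markers(patterns.index)
        data, kind = _encode_markers(sub, patterns)
        res = _all_pairwise(data, kind, self.error_rate, self.min_informative)
        ids = sub.marker_ids.to_numpy()
        pairs = pd.DataFrame(
            {
                "marker_i": ids[res["i"]],
                "marker_j": ids[res["j"]],
                "pair_type": res["pair_type"],
                "r_hat": res["r_hat"],
                "lod": res["lod"],
                "phase": res["phase"],
                "n_informative": res["n_informative"],
                "usable": res["usable"],
            }
        )
        self.pairs_ = pairs
        self.patterns_ = patterns
        self._data = data
        self._kind = kind
        self._ids = ids
        self._index = pd.Index(ids)
        self._res = res
        self._row_lut = {
            (int(a), int(b)): k
            for k, (a, b, u) in enumerate(zip(res["i"], res["j"], res["usable"]))
            if u
        }

        self.groups_ = group_markers(
            pairs, self.lod_limit, self.min_group_size, self.linkage
        )
        self.bins_ = {lg: self._bin(members) for lg, members in self.groups_.items()}
        self.maps_ = {origin: self._build_map(origin) for origin in ("male", "female", "integrated")}
        summaries = {o: m.summary() for o, m in self.maps_.items()}
        non_empty = {o: s for o, s in summaries.items() if not s.empty}
        if non_empty:
            self.summary_ = pd.concat(non_empty, names=["origin", None]).reset_index(level=0)
        else:
            self.summary_ = pd.DataFrame(
                columns=["origin", "lg", "n_markers", "n_loci", "length_cM",
                         "mean_gap_cM", "max_gap_cM", "gap_le_5"]
            )
        return self

    def _bin(self, members):
        """Group markers with identical informative calls into loci."""
        pos = self._index.get_indexer(members)
        seen = {}
        for mid, p in sorted(zip(members, pos), key=lambda t: str(t[0])):
            key = (int(self._kind[p]), self._data[p].tobytes())
            seen.setdefault(key, []).append(mid)
        bins = sorted(seen.values(), key=lambda b: str(b[0]))
        return bins

    def _condensed(self, reps):
        """Pairwise r/N/phase/type matrices for a locus-representative set."""
        pos = self._index.get_indexer(reps)
        n = len(pos)
        R = np.full((n, n), np.nan)
        N = np.zeros((n, n))
        PH = np.full((n, n), -1, dtype=np.int8)
        PT = np.full((n, n), -1, dtype=np.int8)
        np.fill_diagonal(R, 0.0)
        res = self._res
        for x in range(n):
            for y in range(x + 1, n):
                a, b = int(pos[x]), int(pos[y])
                k = self._row_lut.get((a, b) if a < b else (b, a))
                if k is None:
                    continue
                R[x, y] = R[y, x] = res["r_hat"][k]
                N[x, y] = N[y, x] = res["n_informative"][k]
                PH[x, y] = PH[y, x] = res["phase_idx"][k]
                PT[x, y] = PT[y, x] = _TYPE_CODE[res["pair_type"][k]]
        return pos, R, N, PH, PT

    def _order_and_position(self, reps):
        """Order locus representatives and estimate their cM positions.

        The order comes from spectral seriation refined by weighted 1D MDS
        of the Kosambi distance matrix (weights are inverse sampling
        variances; distances floored at the resolution 1/(2N)); positions
        come from the composite-likelihood gap fit along that order.
        """
        pos, R, N, PH, PT = self._condensed(reps)
        n = len(reps)
        if n == 1:
            return np.array([0]), np.array([0.0])
        usable = PT >= 0
        np.fill_diagonal(usable, False)
        r_clip = np.clip(
            np.nan_to_num(R, nan=0.5), 1.0 / (2.0 * np.maximum(N, 1.0)), _MAX_R
        )
        D = kosambi_cm(np.minimum(r_clip, _MAX_R))
        Df = _floyd_fill(np.where(usable, D, np.nan))
        order0 = _spectral_order(Df)
        x0 = np.empty(n)
        x0[order0] = np.arange(n, dtype=float)
        W = np.where(usable, 1.0 / np.maximum(_kosambi_var(r_clip, N), 1e-2), 0.0)
        x = _smacof_1d(np.where(usable, D, 0.0), W, x0, max_iter=10 * self.n_iterations)
        order = np.argsort(x, kind="stable")

        # counts per informative pair, oriented testcross-marker-first
        sub_data = self._data[pos]
        sub_kind = self._kind[pos]
        C = _pair_state_counts(sub_data)
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        counts_by_pair, lo, hi = [], [], []
        for xx in range(n):
            for yy in range(xx + 1, n):
                code = PT[xx, yy]
                if code < 0:
                    continue
                if code == _TYPE_CODE["intercross"]:
                    cells = C[:, :, xx, yy].ravel()
                elif code == _TYPE_CODE["mixed"]:
                    t, hmk = (xx, yy) if sub_kind[xx] <= 1 else (yy, xx)
                    cells = C[:2, :, t, hmk].ravel()
                else:
                    cells = C[:2, :2, xx, yy].ravel()
                counts_by_pair.append((int(code), cells, int(PH[xx, yy])))
                lo.append(min(rank[xx], rank[yy]))
                hi.append(max(rank[xx], rank[yy]))
        lo = np.asarray(lo)
        hi = np.asarray(hi)
        xs = np.sort(x)
        g0 = np.maximum(np.diff(xs), 1e-3)
        g = _composite_gaps(order, counts_by_pair, lo, hi, self.error_rate, g0)
        r_adj = 0.5 * (1.0 - np.exp(-g / 50.0))
        positions = np.concatenate(([0.0], np.cumsum(kosambi_cm(np.minimum(r_adj, _MAX_R)))))
        return order, positions

    def _build_map(self, origin) -> GeneticMap:
        keep_kinds = {
            "male": (_KIND_MALE_TC, _KIND_INTERCROSS),
            "female": (_KIND_FEMALE_TC, _KIND_INTERCROSS),
            "integrated": (_KIND_MALE_TC, _KIND_FEMALE_TC, _KIND_INTERCROSS),
        }[origin]
        kind_of = dict(zip(self._ids, self._kind))
        rows = []
        for lg, bins in self.bins_.items():
            bins_o = [b for b in bins if kind_of[b[0]] in keep_kinds]
            if not bins_o:
                continue
            reps = [b[0] for b in bins_o]
            order, positions = self._order_and_position(reps)
            # canonical orientation: smallest marker id in the first half
            labels = [str(reps[k]) for k in order]
            anchor = labels.index(min(labels))
            if anchor >= (len(order) + 1) // 2:
                order = order[::-1]
                positions = positions[-1] - positions[::-1]
            for locus_index, (k, cm) in enumerate(zip(order, positions)):
                for mid in bins_o[k]:
                    rows.append(
                        {
                            "lg": lg,
                            "locus_index": locus_index,
                            "marker_id": mid,
                            "position_cM": float(cm),
                            "pattern": self.patterns_.get(mid),
                            "phase": self._phase_vs_anchor(mid, bins_o[order[0]][0]),
                        }
                    )
        table = pd.DataFrame(
            rows, columns=["lg", "locus_index", "marker_id", "position_cM", "pattern", "phase"]
        )
        return GeneticMap(origin, table)

    def _phase_vs_anchor(self, mid, anchor):
        if mid == anchor:
            return "anchor"
        if not hasattr(self, "_phase_lut"):
            sub = self.pairs_[self.pairs_["usable"]]
            self._phase_lut = {
                (a, b): ph
                for a, b, ph in zip(sub["marker_i"], sub["marker_j"], sub["phase"])
            }
        return self._phase_lut.get((anchor, mid)) or self._phase_lut.get((mid, anchor)) or "na"

    # convenience
    def map_summary(self, origin="integrated") -> pd.DataFrame:
        return self.maps_[origin].summary()


def build_maps(gm: GenotypeMatrix, qc_table=None, **params):
    """Fit a :class:`LinkageMapper` and return its three maps and summary."""
    mapper = LinkageMapper(**params).fit(gm, qc_table=qc_table)
    return mapper.maps_, mapper.summary_
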