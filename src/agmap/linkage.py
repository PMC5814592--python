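"""Two-point recombination-fraction and LOD estimation for CP crosses.

In a cross-pollinated (CP) F1 population each marker segregates according
to which parent is heterozygous:

* ``lmxll`` — father AB, mother homozygous: only the paternal meiosis is
  observed (a testcross marker for the male map);
* ``nnxnp`` — mother AB, father homozygous: maternal testcross marker;
* ``hkxhk`` — both parents AB: both meioses segregate, but the AB progeny
  class is ambiguous in parental origin.

The recombination fraction r between two markers is estimated by
maximising the joint likelihood of the observed two-locus genotype table
over r and the parental phase(s).  The likelihood optionally includes a
genotyping-error term: each observed call equals the true call with
probability 1 - e and one of the two other calls with probability e/2.
The LOD score is log10 L(r_hat) - log10 L(1/2).

All estimators exist in two forms: scalar functions operating on one pair
(the public API below) and vectorised kernels operating on stacked count
tables (used by :class:`agmap.mapping.LinkageMapper`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "kosambi_cm",
    "kosambi_inverse",
    "haldane_cm",
    "PairwiseLinkage",
    "rf_testcross_pair",
    "rf_intercross_pair",
    "rf_mixed_pair",
    "paternal_alleles",
]

_LN10 = np.log(10.0)
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0
_R_GRID = np.linspace(0.0, 0.5, 257)
_SNAP = 1e-9

# Phase codes.  Testcross/mixed pairs have a single informative meiosis
# (coupling/repulsion); intercross pairs combine a father and a mother
# phase (cc, cr, rc, rr).
TESTCROSS_PHASES = ("coupling", "repulsion")
INTERCROSS_PHASES = ("cc", "cr", "rc", "rr")


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def kosambi_cm(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans.

    Accepts scalars or arrays with 0 <= r < 0.5; r >= 0.5 corresponds to
    unlinked loci (infinite distance) and is rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cm):
    """Inverse Kosambi: r = (exp(d/25) - 1) / (2 (exp(d/25) + 1)) = tanh(d/50)/2."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane_cm(r):
    """Haldane reference distance -50 ln(1-2r), used only for sanity bounds."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# Cell-probability models
# ---------------------------------------------------------------------------
# A parental gamete at two loci carries allele x1 at the first locus and
# x2 at the second (0 = A, 1 = B).  Under coupling the parental haplotypes
# are (A,A)/(B,B) so P(x1 == x2) = 1 - r; under repulsion P(x1 == x2) = r.


def _gamete_same_prob(r, phase_is_repulsion):
    r = np.asarray(r, dtype=float)
    return np.where(phase_is_repulsion, r, 1.0 - r)


def _err2(e):
    # Observation matrix for a transmitted allele at a testcross marker:
    # rows observed, cols true.  The third (impossible) genotype class is
    # screened out upstream, which removes e/2 of the mass; the matrix is
    # deliberately unnormalised (the deficit is independent of r).
    return np.array([[1.0 - e, e / 2.0], [e / 2.0, 1.0 - e]])


def _err3(e):
    E = np.full((3, 3), e / 2.0)
    np.fill_diagonal(E, 1.0 - e)
    return E


def _testcross_cells(r, phase, error_rate=0.0):
    """Cell probabilities for (allele_i, allele_j), flattened row-major.

    ``r`` and ``phase`` broadcast; returns shape broadcast(r, phase) + (4,).
    """
    r = np.asarray(r, dtype=float)
    phase = np.asarray(phase)
    same = _gamete_same_prob(r, phase == 1) / 2.0
    diff = (1.0 - 2.0 * same)  # = r/2 + r/2 or (1-r)/2 *2 complement
    diff = diff / 2.0
    cells = np.stack([same, diff, diff, same], axis=-1)
    if error_rate > 0:
        E = _err2(error_rate)
        t = cells.reshape(cells.shape[:-1] + (2, 2))
        t = np.einsum("oa,...ab,pb->...op", E, t, E)
        cells = t.reshape(cells.shape)
    return cells


def _intercross_cells(r, phase, error_rate=0.0):
    """Cell probabilities for the 3x3 genotype table of an hkxhk pair.

    ``phase`` indexes (father, mother) phase combinations cc/cr/rc/rr.
    Genotypes are coded as B-allele counts; cell order is
    (g_i, g_j) row-major.
    """
    r = np.asarray(r, dtype=float)
    phase = np.asarray(phase)
    pf_rep = (phase // 2) == 1  # rc, rr
    pm_rep = (phase % 2) == 1  # cr, rr
    shape = np.broadcast_shapes(r.shape, phase.shape)
    cells = np.zeros(shape + (9,))
    sf = _gamete_same_prob(r, pf_rep)
    sm = _gamete_same_prob(r, pm_rep)
    for x1 in (0, 1):
        for x2 in (0, 1):
            pf = (sf if x1 == x2 else 1.0 - sf) / 2.0
            for y1 in (0, 1):
                for y2 in (0, 1):
                    pm = (sm if y1 == y2 else 1.0 - sm) / 2.0
                    cell = (x1 + y1) * 3 + (x2 + y2)
                    cells[..., cell] += pf * pm
    if error_rate > 0:
        E = _err3(error_rate)
        t = cells.reshape(shape + (3, 3))
        t = np.einsum("oa,...ab,pb->...op", E, t, E)
        cells = t.reshape(shape + (9,))
    return cells


def _mixed_cells(r, phase, error_rate=0.0):
    """Cells (testcross allele, hk genotype), shape ... + (6,).

    Only the meiosis of the parent heterozygous at the testcross marker
    links the pair; the other parent transmits 1:1 at the hk marker, so
    heterozygous offspring at the hk marker are uninformative.
    """
    r = np.asarray(r, dtype=float)
    phase = np.asarray(phase)
    same = _gamete_same_prob(r, phase == 1)
    shape = np.broadcast_shapes(r.shape, phase.shape)
    cells = np.zeros(shape + (6,))
    for a1 in (0, 1):
        for a2 in (0, 1):
            p_gam = (same if a1 == a2 else 1.0 - same) / 2.0
            # mother allele m uniform: g2 = a2 + m
            for m in (0, 1):
                g2 = a2 + m
                cells[..., a1 * 3 + g2] += p_gam * 0.5
    if error_rate > 0:
        E2 = _err2(error_rate)
        E3 = _err3(error_rate)
        t = cells.reshape(shape + (2, 3))
        t = np.einsum("oa,...ab,pb->...op", E2, t, E3)
        cells = t.reshape(shape + (6,))
    return cells


_CELL_MODELS = {
    "testcross": (_testcross_cells, 2, 4),
    "intercross": (_intercross_cells, 4, 9),
    "mixed": (_mixed_cells, 2, 6),
}


# ---------------------------------------------------------------------------
# Vectorised maximum-likelihood kernel
# ---------------------------------------------------------------------------

def _loglik(counts, cells):
    return np.einsum("...c,...c->...", counts, np.log(np.maximum(cells, 1e-320)))


def fit_pairs(counts, kind, error_rate=0.0, r_grid=_R_GRID, refine_iters=60):
    """Maximise the two-point likelihood for stacked pair count tables.

    Parameters
    ----------
    counts : (n_pairs, n_cells) array of progeny counts per joint class.
    kind : 'testcross', 'intercross' or 'mixed'.

    Returns
    -------
    r_hat, lod, phase_idx : arrays of length n_pairs.

    A coarse grid scan over r in [0, 1/2] x phases brackets the optimum;
    golden-section refinement then localises r_hat to well below 1e-6.
    """
    cell_fn, n_phases, n_cells = _CELL_MODELS[kind]
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    n_pairs = counts.shape[0]
    if counts.shape[1] != n_cells:
        raise ValueError(f"expected {n_cells} cells for kind={kind!r}")

    phases = np.arange(n_phases)
    # grid cells: (n_r, n_phases, n_cells)
    grid_cells = cell_fn(r_grid[:, None], phases[None, :], error_rate)
    logp = np.log(np.maximum(grid_cells, 1e-320)).reshape(-1, n_cells)
    r_hat = np.empty(n_pairs)
    lod = np.empty(n_pairs)
    phase_idx = np.empty(n_pairs, dtype=np.int64)
    ll_half = _loglik(counts, cell_fn(np.array(0.5), np.array(0), error_rate))

    step = max(1, int(2e7 // max(logp.shape[0], 1)))
    h = r_grid[1] - r_grid[0]
    for lo_i in range(0, n_pairs, step):
        sl = slice(lo_i, lo_i + step)
        ll = counts[sl] @ logp.T  # (chunk, n_r * n_phases)
        best = np.argmax(ll, axis=1)
        gi, pi = best // n_phases, best % n_phases
        phase_idx[sl] = pi
        a = np.maximum(r_grid[gi] - h, 0.0)
        b = np.minimum(r_grid[gi] + h, 0.5)

        def f(x):
            return _loglik(counts[sl], cell_fn(np.asarray(x), pi, error_rate))

        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc, fd = f(c), f(d)
        for _ in range(refine_iters):
            left = fc > fd  # maximum lies in [a, d]
            b = np.where(left, d, b)
            a = np.where(left, a, c)
            new_c = np.where(left, b - _INVPHI * (b - a), d)
            new_d = np.where(left, c, a + _INVPHI * (b - a))
            probe = np.where(left, new_c, new_d)
            fprobe = f(probe)
            new_fc = np.where(left, fprobe, fd)
            new_fd = np.where(left, fc, fprobe)
            c, d, fc, fd = new_c, new_d, new_fc, new_fd
        r_best = 0.5 * (a + b)
        r_best[r_best < _SNAP] = 0.0
        r_best[r_best > 0.5 - _SNAP] = 0.5
        ll_best = f(r_best)
        r_hat[sl] = r_best
        lod[sl] = np.maximum(ll_best - ll_half[sl], 0.0) / _LN10
    return r_hat, lod, phase_idx


# ---------------------------------------------------------------------------
# Scalar public API
# ---------------------------------------------------------------------------

@dataclass
class PairwiseLinkage:
    """Two-point linkage estimate between two markers.

    ``phase`` is ``coupling``/``repulsion`` for pairs with one informative
    meiosis, one of ``cc``/``cr``/``rc``/``rr`` for hkxhk pairs, and
    ``not-applicable`` for pairs sharing no meiosis (opposite-parent
    testcross markers), which carry no two-point information.
    """

    marker_i: object
    marker_j: object
    r_hat: float
    lod: float
    phase: str
    n_informative: int
    flag: str = ""


def paternal_alleles(calls, mother_call):
    """Transmitted paternal allele (0/1/-1) for an lmxll marker.

    With the mother homozygous, each called offspring genotype reveals the
    paternal gamete; genotypes impossible under the pattern (the opposite
    homozygote) are flagged as -1 together with NC.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if mother_call == 0:  # mother AA: offspring AA -> A, AB -> B
        out = np.where(calls == 0, 0, np.where(calls == 1, 1, -1))
    elif mother_call == 2:  # mother BB: offspring BB -> B, AB -> A
        out = np.where(calls == 2, 1, np.where(calls == 1, 0, -1))
    else:
        raise ValueError("homozygous parent call must be AA or BB")
    return out.astype(np.int8)


def _pair_counts(x, y, n_states_x, n_states_y):
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x >= 0) & (y >= 0)
    counts = np.bincount(
        x[ok] * n_states_y + y[ok], minlength=n_states_x * n_states_y
    ).astype(float)
    return counts, int(ok.sum())


def rf_testcross_pair(alleles_i, alleles_j, error_rate=0.0, marker_i=None, marker_j=None):
    """Two-point estimate for two same-parent testcross markers.

    ``alleles_*`` are transmitted-allele arrays (0/1, -1 missing) from the
    shared informative parent.  With no error model the maximum-likelihood
    estimate is the closed form r_hat = min(R, N-R)/N with
    LOD = R log10(2 r_hat) + (N-R) log10(2 (1 - r_hat)).
    """
    counts, n = _pair_counts(alleles_i, alleles_j, 2, 2)
    if n == 0:
        return PairwiseLinkage(marker_i, marker_j, 0.5, 0.0, "not-applicable", 0,
                               "no shared informative progeny")
    if error_rate == 0.0:
        match = counts[0] + counts[3]
        mismatch = counts[1] + counts[2]
        coupling = match >= mismatch
        R = mismatch if coupling else match
        r_hat = R / n
        with np.errstate(divide="ignore"):
            lod = 0.0
            if R > 0:
                lod += R * np.log10(2.0 * r_hat)
            if n - R > 0:
                lod += (n - R) * np.log10(2.0 * (1.0 - r_hat))
        phase = "coupling" if coupling else "repulsion"
        return PairwiseLinkage(marker_i, marker_j, float(r_hat), float(max(lod, 0.0)),
                               phase, n)
    r, lod, pi = fit_pairs(counts, "testcross", error_rate)
    return PairwiseLinkage(marker_i, marker_j, float(r[0]), float(lod[0]),
                           TESTCROSS_PHASES[pi[0]], n)


def rf_intercross_pair(calls_i, calls_j, error_rate=0.0, marker_i=None, marker_j=None):
    """Two-point estimate for two hkxhk markers from their 3x3 table.

    The likelihood is maximised over r for each of the four parental phase
    combinations; both meioses are assumed to recombine at the same rate.
    """
    counts, n = _pair_counts(calls_i, calls_j, 3, 3)
    if n == 0:
        return PairwiseLinkage(marker_i, marker_j, 0.5, 0.0, "not-applicable", 0,
                               "no shared informative progeny")
    r, lod, pi = fit_pairs(counts, "intercross", error_rate)
    return PairwiseLinkage(marker_i, marker_j, float(r[0]), float(lod[0]),
                           INTERCROSS_PHASES[pi[0]], n)


def rf_mixed_pair(alleles_i, calls_j, error_rate=0.0, marker_i=None, marker_j=None):
    """Two-point estimate between a testcross marker and an hkxhk marker.

    Only the meiosis of the testcross marker's heterozygous parent is
    informative; heterozygous offspring at the hk marker are ambiguous in
    allele origin and contribute a constant factor.
    """
    counts, n = _pair_counts(alleles_i, calls_j, 2, 3)
    if n == 0:
        return PairwiseLinkage(marker_i, marker_j, 0.5, 0.0, "not-applicable", 0,
                               "no shared informative progeny")
    r, lod, pi = fit_pairs(counts, "mixed", error_rate)
    return PairwiseLinkage(marker_i, marker_j, float(r[0]), float(lod[0]),
                           TESTCROSS_PHASES[pi[0]], n)


def no_information_pair(marker_i=None, marker_j=None):
    """Pair of opposite-parent testcross markers: no shared meiosis."""
    return PairwiseLinkage(marker_i, marker_j, 0.5, 0.0, "not-applicable", 0,
                           "no two-point information")
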