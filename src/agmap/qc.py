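"""SNP performance categories, CP segregation patterns and marker filters.

Mirrors the post-genotyping workflow of array-based mapping in a wild
cross: call-rate thresholds (80% rather than the array default), SNP
performance categories re-expressed at genotype level, classification of
markers into the three CP segregation patterns usable in an F1 of two
heterozygous parents, a chi-square segregation-distortion test, and the
marker filter that feeds the mapping stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import AA, AB, BB, NC, GenotypeMatrix

__all__ = [
    "CATEGORIES",
    "call_rates",
    "classify_category",
    "classify_pattern",
    "distortion_test",
    "filter_markers",
    "MarkerQC",
]

CATEGORIES = (
    "PolyHighResolution",
    "NoMinorHomozygote",
    "MonoHighResolution",
    "CallRateBelowThreshold",
    "OffTargetVariant",
    "Other",
)

#: Expected segregation of called progeny classes per pattern.
#: hkxhk segregates 1 AA : 2 AB : 1 BB; the testcross patterns segregate
#: 1:1 on their two possible classes.
_EXPECTED = {
    "hkxhk": {AA: 0.25, AB: 0.5, BB: 0.25},
    "lmxll": None,  # 1:1 on the two observed classes
    "nnxnp": None,
}


def call_rates(gm: GenotypeMatrix, marker_threshold=0.8, sample_threshold=0.8):
    """Per-marker and per-sample call rates with below-threshold flags.

    The call rate is the fraction of non-NC calls; the marker rate is
    computed over all samples, matching the array-level variant call rate.
    """
    if gm.n_markers == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    called = gm.calls != NC
    marker_rate = called.mean(axis=1)
    sample_rate = called.mean(axis=0)
    markers = pd.DataFrame(
        {
            "call_rate": marker_rate,
            "below_threshold": marker_rate < marker_threshold,
        },
        index=gm.marker_ids,
    )
    samples = pd.DataFrame(
        {
            "call_rate": sample_rate,
            "below_threshold": sample_rate < sample_threshold,
            "role": gm.roles.to_numpy(),
        },
        index=gm.sample_ids,
    )
    return markers, samples


def classify_category(calls, call_rate_threshold=0.8, min_minor_carriers=2, otv_label=None):
    """SNP performance category from a marker's calls across all samples.

    ``OffTargetVariant`` cannot be derived from genotype calls (it needs
    intensity clusters) and is honoured only as a pass-through label.
    """
    if otv_label == "OffTargetVariant":
        return "OffTargetVariant"
    calls = np.asarray(calls, dtype=np.int8)
    bad = ~np.isin(calls, (AA, AB, BB, NC))
    if bad.any():
        raise ValueError(f"unknown call code at positions {np.flatnonzero(bad)[:5]}")
    called = calls[calls != NC]
    if len(calls) == 0 or len(called) / len(calls) < call_rate_threshold:
        return "CallRateBelowThreshold"
    n_aa = int((called == AA).sum())
    n_ab = int((called == AB).sum())
    n_bb = int((called == BB).sum())
    n_classes = sum(x > 0 for x in (n_aa, n_ab, n_bb))
    if n_classes <= 1:
        return "MonoHighResolution"
    if n_aa > 0 and n_bb > 0:
        # carriers of the minor allele: the minor homozygote class plus hets
        minor_carriers = min(n_aa, n_bb) + n_ab
        if minor_carriers >= min_minor_carriers:
            return "PolyHighResolution"
        return "Other"
    if n_classes == 2:
        return "NoMinorHomozygote"
    return "Other"


def _consistent_patterns(father, mother, progeny):
    """Informative patterns consistent with observed parent/progeny calls."""
    progeny = np.asarray(progeny, dtype=np.int8)
    classes = set(int(c) for c in progeny[progeny != NC])
    out = []
    # hkxhk: both parents AB, any progeny class possible
    if father in (AB, NC) and mother in (AB, NC):
        out.append("hkxhk")
    # lmxll: father AB, mother homozygous; progeny in {mother hom, AB}
    if father in (AB, NC):
        for hom in (AA, BB):
            if mother in (hom, NC) and classes <= {hom, AB}:
                out.append("lmxll")
                break
    if mother in (AB, NC):
        for hom in (AA, BB):
            if father in (hom, NC) and classes <= {hom, AB}:
                out.append("nnxnp")
                break
    return out


def classify_pattern(father_call, mother_call, progeny_calls):
    """CP segregation pattern of a marker plus inconsistency count.

    Returns ``(pattern, n_inconsistent)``.  ``pattern`` is one of
    ``hkxhk``/``lmxll``/``nnxnp``, ``uninformative`` (both parents
    homozygous: no segregation in the F1) or ``other``.  Progeny calls
    impossible under the pattern (e.g. the opposite homozygote in a
    testcross) are counted, not fatal.  If a parent call is missing the
    pattern is accepted only when the progeny classes force a unique one.
    """
    father_call = int(father_call)
    mother_call = int(mother_call)
    progeny = np.asarray(progeny_calls, dtype=np.int8)
    called = progeny[progeny != NC]

    if father_call == NC or mother_call == NC:
        candidates = _consistent_patterns(father_call, mother_call, progeny)
        if len(candidates) != 1:
            return "other", 0
        pattern = candidates[0]
    elif father_call == AB and mother_call == AB:
        pattern = "hkxhk"
    elif father_call == AB and mother_call in (AA, BB):
        pattern = "lmxll"
    elif mother_call == AB and father_call in (AA, BB):
        pattern = "nnxnp"
    else:
        return "uninformative", 0

    if pattern == "hkxhk":
        n_bad = 0
    elif pattern == "lmxll":
        hom = mother_call if mother_call in (AA, BB) else (AA if (called != BB).all() else BB)
        bad_class = BB if hom == AA else AA
        n_bad = int((called == bad_class).sum())
    else:
        hom = father_call if father_call in (AA, BB) else (AA if (called != BB).all() else BB)
        bad_class = BB if hom == AA else AA
        n_bad = int((called == bad_class).sum())
    return pattern, n_bad


def distortion_test(pattern, progeny_calls):
    """Chi-square goodness of fit against the pattern's Mendelian ratio.

    hkxhk is tested against 1:2:1 (df=2); the testcross patterns against
    1:1 on their two segregating classes (df=1).  NC calls are excluded;
    genotypes impossible under the pattern are excluded from the test.
    Returns ``(chi2, p_value)``; with zero called progeny the marker is
    untestable and ``(nan, nan)`` is returned.
    """
    progeny = np.asarray(progeny_calls, dtype=np.int8)
    called = progeny[progeny != NC]
    if len(called) == 0:
        return float("nan"), float("nan")
    if pattern == "hkxhk":
        obs = np.array([(called == g).sum() for g in (AA, AB, BB)], dtype=float)
        exp = obs.sum() * np.array([0.25, 0.5, 0.25])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(chi2, df=2))
    elif pattern in ("lmxll", "nnxnp"):
        n_ab = int((called == AB).sum())
        n_aa = int((called == AA).sum())
        n_bb = int((called == BB).sum())
        hom = n_aa if n_aa >= n_bb else n_bb  # the pattern's homozygous class
        n = n_ab + hom
        if n == 0:
            return float("nan"), float("nan")
        exp = n / 2.0
        chi2 = float((n_ab - exp) ** 2 / exp + (hom - exp) ** 2 / exp)
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        raise ValueError(f"pattern {pattern!r} is not informative")
    return chi2, max(p, np.nextafter(0, 1))


class MarkerQC(BaseEstimator, TransformerMixin):
    """Per-marker QC classifier and filter for a CP genotype matrix.

    ``fit`` computes call rates, performance categories, segregation
    patterns and distortion tests; ``transform`` returns the genotype
    matrix restricted to kept markers.  A marker is kept when it is
    PolyHighResolution or NoMinorHomozygote, carries an informative
    pattern, its distortion p-value is at least ``data_tolerance`` and its
    missing fraction among progeny is at most ``missing_limit``.

    Parameters
    ----------
    call_rate_threshold : float, default 0.8
        Variant call-rate threshold (the relaxed array threshold used for
        wild-relative hybridisations, instead of the 0.97 default).
    data_tolerance : float, default 0.001
        Minimum segregation-distortion p-value.
    missing_limit : float, default 0.2
        Maximum missing-call fraction among progeny.

    Attributes
    ----------
    table_ : DataFrame
        marker_id-indexed QC table (call_rate, category, pattern, chi2,
        p_value, n_inconsistent, kept, reason).
    kept_ : Index of retained marker ids.
    attrition_ : Series of counts per removal reason, in filter order.
    """

    def __init__(
        self,
        call_rate_threshold: float = 0.8,
        sample_call_rate_threshold: float = 0.8,
        data_tolerance: float = 0.001,
        missing_limit: float = 0.2,
        min_minor_carriers: int = 2,
    ):
        self.call_rate_threshold = call_rate_threshold
        self.sample_call_rate_threshold = sample_call_rate_threshold
        self.data_tolerance = data_tolerance
        self.missing_limit = missing_limit
        self.min_minor_carriers = min_minor_carriers

    def fit(self, gm: GenotypeMatrix, y=None, otv_labels=None):
        if gm.n_markers == 0:
            self.table_ = pd.DataFrame(
                columns=[
                    "call_rate", "category", "pattern", "chi2", "p_value",
                    "n_inconsistent", "kept", "reason",
                ]
            )
            self.kept_ = pd.Index([], name="marker_id")
            self.attrition_ = pd.Series(dtype=int)
            self.sample_table_ = pd.DataFrame(columns=["call_rate", "below_threshold", "role"])
            return self
        fi, mi = gm.father_index, gm.mother_index
        prog = gm.progeny_indices
        marker_rates, sample_rates = call_rates(
            gm, self.call_rate_threshold, self.sample_call_rate_threshold
        )
        self.sample_table_ = sample_rates
        rows = []
        for i, mid in enumerate(gm.marker_ids):
            calls = gm.calls[i]
            category = classify_category(
                calls,
                self.call_rate_threshold,
                self.min_minor_carriers,
                None if otv_labels is None else otv_labels.get(mid),
            )
            pattern, n_bad = classify_pattern(calls[fi], calls[mi], calls[prog])
            informative = pattern in ("hkxhk", "lmxll", "nnxnp")
            if informative:
                chi2, p = distortion_test(pattern, calls[prog])
            else:
                chi2, p = float("nan"), float("nan")
            missing_frac = float((calls[prog] == NC).mean()) if len(prog) else 1.0
            reason = ""
            if category not in ("PolyHighResolution", "NoMinorHomozygote"):
                reason = f"category:{category}"
            elif not informative:
                if calls[fi] == NC or calls[mi] == NC:
                    reason = "parent NoCall"
                else:
                    reason = f"pattern:{pattern}"
            elif missing_frac > self.missing_limit:
                reason = "missing"
            elif np.isnan(p):
                reason = "untestable"
            elif p < self.data_tolerance:
                reason = "distortion"
            rows.append(
                {
                    "call_rate": float(marker_rates["call_rate"].iloc[i]),
                    "category": category,
                    "pattern": pattern,
                    "chi2": chi2,
                    "p_value": p,
                    "n_inconsistent": n_bad,
                    "kept": reason == "",
                    "reason": reason,
                }
            )
        self.table_ = pd.DataFrame(rows, index=gm.marker_ids)
        self.kept_ = self.table_.index[self.table_["kept"]]
        dropped = self.table_.loc[~self.table_["kept"], "reason"]
        order = ["category:", "parent NoCall", "pattern:", "missing", "untestable", "distortion"]
        counts = dropped.value_counts()
        counts = counts.reindex(
            sorted(counts.index, key=lambda r: next((k for k, o in enumerate(order) if r.startswith(o)), 99))
        )
        self.attrition_ = pd.concat(
            [pd.Series({"input": gm.n_markers}), counts, pd.Series({"kept": len(self.kept_)})]
        ).astype(int)
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "table_"):
            raise RuntimeError("MarkerQC must be fitted before transform")
        return gm.subset_markers(self.kept_)


def filter_markers(gm: GenotypeMatrix, data_tolerance=0.001, missing_limit=0.2, **kwargs):
    """Functional wrapper over :class:`MarkerQC`.

    Returns ``(kept_marker_index, qc_table, attrition)``.
    """
    qc = MarkerQC(data_tolerance=data_tolerance, missing_limit=missing_limit, **kwargs).fit(gm)
    return qc.kept_, qc.table_, qc.attrition_
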