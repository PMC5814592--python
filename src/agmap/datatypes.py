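"""Core containers shared across the pipeline.

Genotype calls are biallelic SNP-array calls ``AA``/``AB``/``BB`` plus
``NC`` (no call).  Internally they are encoded as ``int8``: 0, 1, 2 for the
three genotype classes and -1 for missing; the encoding is the number of
copies of the B allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALLS = ("AA", "AB", "BB", "NC")
AA, AB, BB, NC = 0, 1, 2, -1

_CALL_TO_CODE = {"AA": AA, "AB": AB, "BB": BB, "NC": NC, "NoCall": NC}
_CODE_TO_CALL = {AA: "AA", AB: "AB", BB: "BB", NC: "NC"}

ROLES = ("father", "mother", "progeny", "line")

#: JoinMap-style segregation codes for a cross-pollinated (CP) F1 cross.
#: ``hkxhk``: both parents heterozygous; ``lmxll``: father only;
#: ``nnxnp``: mother only.
PATTERNS = ("hkxhk", "lmxll", "nnxnp")

WHEAT_SUBGENOMES = ("A", "B", "D")
WHEAT_CHROMOSOMES = tuple(
    f"{g}{s}" for g in range(1, 8) for s in WHEAT_SUBGENOMES
)
P_CHROMOSOMES = tuple(f"{g}P" for g in range(1, 8))


def encode_calls(values) -> np.ndarray:
    """Map an array-like of call strings to the int8 code matrix."""
    arr = np.asarray(values, dtype=object)
    out = np.empty(arr.shape, dtype=np.int8)
    flat_in = arr.ravel()
    flat_out = out.ravel()
    for i, v in enumerate(flat_in):
        try:
            flat_out[i] = _CALL_TO_CODE[v]
        except KeyError:
            raise ValueError(f"unknown call symbol {v!r}") from None
    return out


def decode_calls(codes: np.ndarray) -> np.ndarray:
    out = np.empty(codes.shape, dtype=object)
    for code, call in _CODE_TO_CALL.items():
        out[codes == code] = call
    return out


@dataclass
class GenotypeMatrix:
    """Markers x samples genotype calls with per-sample roles.

    Parameters
    ----------
    calls : (n_markers, n_samples) int8 array
        Encoded calls (0=AA, 1=AB, 2=BB, -1=NC).
    marker_ids, sample_ids : sequences of unique identifiers.
    roles : sequence aligned with ``sample_ids``; each role is one of
        ``father``, ``mother``, ``progeny`` or ``line``.
    """

    calls: np.ndarray
    marker_ids: pd.Index
    sample_ids: pd.Index
    roles: pd.Series

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.marker_ids = pd.Index(self.marker_ids, name="marker_id")
        self.sample_ids = pd.Index(self.sample_ids, name="sample_id")
        self.roles = pd.Series(
            np.asarray(self.roles, dtype=object), index=self.sample_ids, name="role"
        )
        if self.calls.ndim != 2 or self.calls.shape != (
            len(self.marker_ids),
            len(self.sample_ids),
        ):
            raise ValueError("calls shape does not match marker/sample ids")
        if not self.marker_ids.is_unique:
            raise ValueError("duplicate marker ids")
        if not self.sample_ids.is_unique:
            raise ValueError("duplicate sample ids")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        valid = np.isin(self.calls, (AA, AB, BB, NC))
        if not valid.all():
            raise ValueError("calls contain codes outside {AA, AB, BB, NC}")

    # -- convenience -------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.roles == role).to_numpy())

    @property
    def father_index(self) -> int:
        idx = self.samples_with_role("father")
        if len(idx) != 1:
            raise ValueError(f"expected exactly one father, found {len(idx)}")
        return int(idx[0])

    @property
    def mother_index(self) -> int:
        idx = self.samples_with_role("mother")
        if len(idx) != 1:
            raise ValueError(f"expected exactly one mother, found {len(idx)}")
        return int(idx[0])

    @property
    def progeny_indices(self) -> np.ndarray:
        return self.samples_with_role("progeny")

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        pos = self.marker_ids.get_indexer(pd.Index(marker_ids))
        if (pos < 0).any():
            missing = pd.Index(marker_ids)[pos < 0].tolist()
            raise KeyError(f"unknown markers: {missing[:5]}")
        return GenotypeMatrix(
            self.calls[pos], pd.Index(marker_ids), self.sample_ids, self.roles.values
        )

    def to_frame(self) -> pd.DataFrame:
        """Decoded calls as a markers x samples DataFrame of strings."""
        return pd.DataFrame(
            decode_calls(self.calls), index=self.marker_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, roles) -> "GenotypeMatrix":
        roles = pd.Series(roles)
        roles = roles.reindex(frame.columns)
        if roles.isna().any():
            missing = frame.columns[roles.isna()].tolist()
            raise ValueError(f"samples without a role: {missing[:5]}")
        return cls(
            encode_calls(frame.to_numpy()),
            frame.index,
            frame.columns,
            roles.to_numpy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.marker_ids.equals(other.marker_ids)
            and self.sample_ids.equals(other.sample_ids)
            and self.roles.equals(other.roles)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class GeneticMap:
    """Ordered loci per linkage group with cumulative Kosambi positions.

    ``table`` columns: ``lg``, ``locus_index``, ``marker_id``,
    ``position_cM``, ``pattern``, ``phase``.  A locus is a bin of
    co-segregating markers mapped to a single position; positions are
    non-decreasing within each group and start at 0.
    """

    origin: str  # male / female / integrated
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["lg", "locus_index", "marker_id", "position_cM", "pattern", "phase"]
        )
    )

    @property
    def lg_ids(self) -> list:
        return sorted(self.table["lg"].unique().tolist())

    def group(self, lg) -> pd.DataFrame:
        return self.table[self.table["lg"] == lg]

    def summary(self) -> pd.DataFrame:
        """Per-LG map statistics: markers, loci, length, gap structure.

        ``gap_le_5`` is the fraction of adjacent-locus gaps of at most
        5 cM, the conventional measure of map saturation.
        """
        rows = []
        for lg in self.lg_ids:
            sub = self.group(lg)
            pos = sub.groupby("locus_index")["position_cM"].first().sort_index()
            gaps = np.diff(pos.to_numpy()) if len(pos) > 1 else np.array([])
            rows.append(
                {
                    "lg": lg,
                    "n_markers": len(sub),
                    "n_loci": len(pos),
                    "length_cM": float(pos.iloc[-1]) if len(pos) else 0.0,
                    "mean_gap_cM": float(gaps.mean()) if gaps.size else 0.0,
                    "max_gap_cM": float(gaps.max()) if gaps.size else 0.0,
                    "gap_le_5": float((gaps <= 5.0).mean()) if gaps.size else 1.0,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "lg",
                "n_markers",
                "n_loci",
                "length_cM",
                "mean_gap_cM",
                "max_gap_cM",
                "gap_le_5",
            ],
        )
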