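"""Readers and writers for the pipeline's plain-text formats.

The canonical genotype format is a TSV with a ``marker_id`` header row
listing sample ids, one ``role`` row (father/mother/progeny/line) and one
row per marker with calls in {AA, AB, BB, NC}.  All writers prepend a
``#`` comment embedding the tool version and a parameter hash so every
artifact is traceable; readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import CALLS, GenotypeMatrix, ROLES

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_table",
    "write_table",
    "read_hit_table",
    "params_hash",
    "genotype_matrix_from_vcf",
]


def params_hash(params: dict) -> str:
    payload = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(phash: str | None) -> str:
    return f"# agmap {__version__}" + (f" params={phash}" if phash else "")


def write_genotype_matrix(gm: GenotypeMatrix, path, phash: str | None = None):
    path = Path(path)
    frame = gm.to_frame()
    with open(path, "w") as fh:
        fh.write(_header_comment(phash) + "\n")
        fh.write("marker_id\t" + "\t".join(map(str, gm.sample_ids)) + "\n")
        fh.write("role\t" + "\t".join(gm.roles) + "\n")
        for mid, row in zip(frame.index, frame.to_numpy()):
            fh.write(str(mid) + "\t" + "\t".join(row) + "\n")


def read_genotype_matrix(path) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated genotype file")
    header = lines[0].split("\t")
    if header[0] != "marker_id":
        raise ValueError(f"{path}: first header field must be 'marker_id'")
    sample_ids = header[1:]
    role_row = lines[1].split("\t")
    if role_row[0] != "role":
        raise ValueError(f"{path}: line 2 must be the 'role' row")
    roles = role_row[1:]
    if len(roles) != len(sample_ids):
        raise ValueError(f"{path}: role row width does not match header")
    bad_roles = set(roles) - set(ROLES)
    if bad_roles:
        raise ValueError(f"{path}: unknown roles {sorted(bad_roles)}")
    marker_ids, rows = [], []
    valid = set(CALLS)
    for lineno, ln in enumerate(lines[2:], start=3):
        fields = ln.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ValueError(f"{path}:{lineno}: expected {len(sample_ids) + 1} columns")
        for col, call in enumerate(fields[1:], start=2):
            if call not in valid:
                raise ValueError(
                    f"{path}:{lineno}: unknown call {call!r} in column {col} "
                    f"(marker {fields[0]}, sample {sample_ids[col - 2]})"
                )
        marker_ids.append(fields[0])
        rows.append(fields[1:])
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError(f"{path}: duplicate marker ids")
    frame = pd.DataFrame(rows, index=marker_ids, columns=sample_ids)
    return GenotypeMatrix.from_frame(frame, pd.Series(roles, index=sample_ids))


def write_table(df: pd.DataFrame, path, phash: str | None = None):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(phash) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_hit_table(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"marker_id", "wheat_chromosome", "bp_position", "e_value", "identity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: hit table lacks columns {sorted(missing)}")
    return df


def genotype_matrix_from_vcf(path, roles: dict) -> GenotypeMatrix:
    """Import biallelic genotypes from a VCF (GT field).

    0/0 -> AA, 0/1 or 1/0 -> AB, 1/1 -> BB, missing -> NC.  ``roles``
    maps sample names to father/mother/progeny/line.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import needs the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, rows = [], []
    for var in vcf:
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.asarray(var.gt_types)
        row = np.full(len(samples), -1, dtype=np.int8)
        row[codes == 0] = 0
        row[codes == 1] = 1
        row[codes == 3] = 2
        marker_ids.append(mid)
        rows.append(row)
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    role_list = [roles[s] for s in samples]
    return GenotypeMatrix(calls, pd.Index(marker_ids), pd.Index(samples), role_list)
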