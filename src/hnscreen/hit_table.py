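"""Normalized structural hit-pair tables and Foldseek-style tabular parsing.

The normalized schema used everywhere downstream has one row per structural
hit pair:

    rice_gene_id, rice_accession, human_accession, qcov, tcov, avg_lddt
    [, seq_similarity_pct, seq_identity_pct, ...passthrough]

Foldseek easy-search tabular output (1-based inclusive alignment coordinates)
is converted on read; internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FOLDSEEK_DEFAULT_COLUMNS = (
    "query,target,fident,alnlen,qstart,qend,tstart,tend,qlen,tlen,evalue,bits,lddt"
)

REQUIRED_COLUMNS = ("rice_gene_id", "rice_accession", "human_accession", "qcov", "tcov", "avg_lddt")

_BOUNDS = {
    "qcov": (0.0, 1.0),
    "tcov": (0.0, 1.0),
    "avg_lddt": (0.0, 1.0),
    "seq_similarity_pct": (0.0, 100.0),
    "seq_identity_pct": (0.0, 100.0),
}


def validate_hit_table(hits: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and declared numeric ranges; returns the table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in hits.columns]
    if missing:
        raise KeyError(f"hit table missing required columns: {missing}")
    for col, (lo, hi) in _BOUNDS.items():
        if col in hits.columns and len(hits):
            vals = pd.to_numeric(hits[col], errors="coerce")
            bad = vals.isna() | (vals < lo) | (vals > hi)
            if bad.any():
                rows = hits.index[bad].tolist()
                raise ValueError(f"column {col} outside [{lo}, {hi}] at rows {rows[:5]}")
    return hits


def read_hit_table(
    path,
    column_spec: str | dict | None = None,
    gene_of_accession: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a Foldseek-style whitespace/tab table into the normalized schema.

    ``column_spec`` names the file's columns in order (comma-joined string or
    logical-name -> file-column mapping); defaults to the Foldseek convention
    ``query,target,fident,...,lddt``.  ``qcov``/``tcov`` are taken directly if
    present, otherwise derived from the 1-based inclusive alignment spans.
    ``gene_of_accession`` maps rice accessions to gene ids; without it the
    accession doubles as the gene id.
    """
    if column_spec is None:
        column_spec = FOLDSEEK_DEFAULT_COLUMNS
    if isinstance(column_spec, str):
        names = [c.strip() for c in column_spec.split(",")]
    else:
        names = list(column_spec)
    raw = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    if raw.empty:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))

    for col in ("query", "target"):
        if col not in raw.columns:
            raise KeyError(f"hit table missing required column: {col}")
    if "lddt" not in raw.columns:
        raise KeyError("hit table missing required column: lddt")

    have_cov = {"qcov", "tcov"} <= set(raw.columns)
    span_cols = ("qstart", "qend", "tstart", "tend", "qlen", "tlen")
    if not have_cov and not set(span_cols) <= set(raw.columns):
        raise KeyError("hit table needs qcov/tcov or alignment spans " + str(span_cols))

    numeric = ["lddt"] + (["qcov", "tcov"] if have_cov else list(span_cols))
    for col in numeric:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(raw.index[bad][0])
            raise ValueError(f"row {row}: non-numeric value in column {col!r}")
        raw[col] = vals

    if have_cov:
        qcov, tcov = raw["qcov"].to_numpy(float), raw["tcov"].to_numpy(float)
    else:
        for start, end in (("qstart", "qend"), ("tstart", "tend")):
            bad = raw[end] < raw[start]
            if bad.any():
                row = int(raw.index[bad][0])
                raise ValueError(f"row {row}: {end} < {start}")
        if (raw["qlen"] < 1).any() or (raw["tlen"] < 1).any():
            raise ValueError("protein lengths must be >= 1")
        # 1-based inclusive spans -> aligned residue counts
        qcov = (raw["qend"] - raw["qstart"] + 1) / raw["qlen"]
        tcov = (raw["tend"] - raw["tstart"] + 1) / raw["tlen"]

    rice_acc = raw["query"].astype(str)
    out = pd.DataFrame(
        {
            "rice_gene_id": (
                rice_acc.map(gene_of_accession) if gene_of_accession else rice_acc
            ),
            "rice_accession": rice_acc,
            "human_accession": raw["target"].astype(str),
            "qcov": np.asarray(qcov, float),
            "tcov": np.asarray(tcov, float),
            "avg_lddt": raw["lddt"].to_numpy(float),
        }
    )
    if gene_of_accession is not None and out["rice_gene_id"].isna().any():
        row = int(out.index[out["rice_gene_id"].isna()][0])
        raise ValueError(f"row {row}: accession {rice_acc.iloc[row]!r} not in gene map")
    for extra in ("fident", "evalue", "bits"):
        if extra in raw.columns:
            out[extra] = raw[extra]
    return validate_hit_table(out)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    validate_hit_table(hits).to_csv(path, sep="\t", index=False)
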