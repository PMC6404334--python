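"""Readers and writers for the toolkit's plain-text interchange formats.

Counts: TSV/CSV, genes in rows, samples in columns, header row of sample IDs.
Sample table: delimited with header sample_id, condition, short_label.
Gene sets: two-column mapping (gene_id, term_id) plus two-column names table
(term_id, term_name).  Delimiter is auto-detected from the header line, tab
preferred over comma.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .model import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    SampleTable,
    ValidationError,
    _find_duplicates,
)

logger = logging.getLogger("gsepd")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValidationError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples raw count matrix.

    The first column holds gene IDs; the header row holds sample IDs.  Column
    order is preserved.  Duplicate IDs, negative or non-integer cells are hard
    errors naming the offender.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValidationError(f"{path}: no data rows/columns")
    df.index = df.index.astype(str)
    dup = _find_duplicates(list(df.index))
    if dup:
        raise ValidationError(f"{path}: duplicate gene ID(s): {dup}")
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for s in df.columns:
        col = pd.to_numeric(df[s], errors="coerce")
        bad = col.isna() | (col < 0) | (col != col.round())
        if bad.any():
            g = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: cell at gene {g!r}, sample {s!r} is not a "
                f"non-negative integer (value {df.at[g, s]!r})"
            )
        parsed[s] = col
    return CountMatrix(parsed.astype("int64"))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path: str | Path, counts: CountMatrix | None = None) -> SampleTable:
    """Read the sample metadata table; optionally validate every sample
    appears in *counts*."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    st = SampleTable(df)
    if counts is not None:
        st.validate_against(counts)
    return st


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(mapping_path: str | Path, names_path: str | Path | None = None) -> GeneSetCollection:
    """Read a gene-set annotation.

    *mapping_path*: two columns (gene_id, term_id), header optional but
    recommended.  *names_path*: two columns (term_id, term_name).  Terms with
    no entry in the names table fall back to the term ID with a warning.
    Duplicate (gene, term) pairs are deduplicated.
    """
    mapping_path = Path(mapping_path)
    sep = _sniff_sep(mapping_path)
    mapping = pd.read_csv(mapping_path, sep=sep, dtype=str)
    if mapping.shape[1] < 2:
        raise ValidationError(f"{mapping_path}: expected two columns (gene_id, term_id)")
    # tolerate headerless files: a header is assumed, but if the two column
    # names look like data (no recognizable names), re-read without header
    cols = [c.lower() for c in mapping.columns[:2]]
    if not ({"gene_id", "gene"} & set(cols) or {"term_id", "term", "go_id"} & set(cols)):
        mapping = pd.read_csv(mapping_path, sep=sep, dtype=str, header=None)
    mapping = mapping.iloc[:, :2]
    mapping.columns = ["gene_id", "term_id"]
    mapping = mapping.dropna()
    if mapping.empty:
        raise ValidationError(f"{mapping_path}: empty gene-to-term mapping")

    names: dict[str, str] = {}
    if names_path is not None:
        names_path = Path(names_path)
        nsep = _sniff_sep(names_path)
        ndf = pd.read_csv(names_path, sep=nsep, dtype=str)
        ncols = [c.lower() for c in ndf.columns[:2]]
        if not ({"term_id", "term", "go_id"} & set(ncols)):
            ndf = pd.read_csv(names_path, sep=nsep, dtype=str, header=None)
        ndf = ndf.iloc[:, :2].dropna()
        names = dict(zip(ndf.iloc[:, 0], ndf.iloc[:, 1]))

    sets: dict[str, GeneSet] = {}
    for tid, grp in mapping.groupby("term_id", sort=True):
        name = names.get(tid)
        if name is None:
            if names_path is not None:
                logger.warning("term %s has no name in the names table; using its ID", tid)
            name = tid
        sets[str(tid)] = GeneSet(str(tid), str(name), frozenset(grp["gene_id"]))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, mapping_path: str | Path, names_path: str | Path) -> None:
    rows = [
        {"gene_id": g, "term_id": gs.term_id}
        for gs in collection
        for g in sorted(gs.members)
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(mapping_path, sep="\t", index=False)
    nrows = [{"term_id": gs.term_id, "term_name": gs.term_name} for gs in collection]
    pd.DataFrame(nrows, columns=["term_id", "term_name"]).to_csv(names_path, sep="\t", index=False)
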