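"""Two-group differential expression on log2-normalized counts.

The internal test is Welch's unequal-variance t-test per gene, with
Benjamini-Hochberg adjustment across all tested genes.  It is a deliberately
simple default: studies wanting a negative-binomial GLM (DESeq2 and the like)
run that externally and feed the result table in through ``load_de_table``,
which recognizes DESeq2's column names.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Contrast, CountMatrix, SampleTable, ValidationError

logger = logging.getLogger("gsepd")

DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "pvalue", "padj"]

# DESeq2-style header names auto-recognized by load_de_table
_COLUMN_ALIASES = {
    "gene_id": ("gene_id", "gene", "id", "row.names", ""),
    "base_mean": ("base_mean", "basemean", "baseMean"),
    "log2fc": ("log2fc", "log2foldchange", "log2FoldChange", "lfc"),
    "pvalue": ("pvalue", "p_value", "pval", "p"),
    "padj": ("padj", "p_adj", "fdr", "qvalue"),
}


def run_de(norm: pd.DataFrame, samples: SampleTable, contrast: Contrast) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test on the log2-normalized matrix.

    log2fc is mean(group_b) - mean(group_a), so positive values mean higher
    expression in group B.  Genes constant across both groups get p = 1.
    Returns a DataFrame with columns gene_id, base_mean, log2fc, pvalue, padj.
    """
    a_ids = samples.samples_in(contrast.group_a)
    b_ids = samples.samples_in(contrast.group_b)
    for label, ids in ((contrast.group_a, a_ids), (contrast.group_b, b_ids)):
        if len(ids) < 2:
            raise ValidationError(
                f"group {label!r} has {len(ids)} sample(s); the internal test needs >= 2 "
                "per group — use load_de_table with an externally computed table instead"
            )
    a = norm.loc[:, a_ids].to_numpy()
    b = norm.loc[:, b_ids].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_b - mean_a
    base_mean = norm.loc[:, a_ids + b_ids].to_numpy().mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    # zero variance in both groups: equal means -> p = 1, else p = 0
    degenerate = np.isnan(p)
    p = np.where(degenerate, np.where(log2fc == 0.0, 1.0, 0.0), p)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": norm.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "pvalue": p,
            "padj": padj,
        }
    ).reset_index(drop=True)


def load_de_table(path: str | Path, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Load an externally computed DE table (e.g. DESeq2 results written as
    CSV/TSV).  Genes absent from *counts* are dropped with a logged count;
    'NA' p-values are kept as NaN and excluded from DE calls downstream."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    colmap: dict[str, str] = {}
    lowered = {c.lower(): c for c in df.columns}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias.lower() in lowered:
                colmap[canon] = lowered[alias.lower()]
                break
    if "gene_id" not in colmap:
        # fall back to an unnamed first column (DESeq2 row names)
        colmap["gene_id"] = df.columns[0]
    if "pvalue" not in colmap:
        raise ValidationError(f"{path}: no p-value column found (looked for {_COLUMN_ALIASES['pvalue']})")
    out = pd.DataFrame({"gene_id": df[colmap["gene_id"]].astype(str)})
    for canon in ("base_mean", "log2fc", "pvalue", "padj"):
        if canon in colmap:
            out[canon] = pd.to_numeric(df[colmap[canon]], errors="coerce")
        else:
            out[canon] = np.nan
    if counts is not None:
        keep = out["gene_id"].isin(set(counts.gene_ids))
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("%d gene(s) in the DE table absent from the count matrix; dropped", n_drop)
        out = out.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValidationError(f"{path}: no usable DE rows")
    return out


def call_de_genes(
    de: pd.DataFrame, threshold: float = 0.05, use_padj: bool = False
) -> dict[str, list[str]]:
    """Split the DE table into the three gene lists used for enrichment.

    all  = genes with p < threshold (raw p by default, padj if use_padj);
    up   = all with log2fc > 0; down = all with log2fc < 0.  Genes with
    log2fc exactly 0 appear in 'all' only.  NaN p-values never qualify.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    col = "padj" if use_padj else "pvalue"
    sig = de[col].notna() & (de[col] < threshold)
    all_genes = de.loc[sig, "gene_id"].tolist()
    up = de.loc[sig & (de["log2fc"] > 0), "gene_id"].tolist()
    down = de.loc[sig & (de["log2fc"] < 0), "gene_id"].tolist()
    return {"all": all_genes, "up": up, "down": down}


def write_de_table(de: pd.DataFrame, calls: dict[str, list[str]], path: str | Path) -> None:
    out = de.copy()
    up, down = set(calls["up"]), set(calls["down"])
    out["call_up"] = out["gene_id"].isin(up)
    out["call_down"] = out["gene_id"].isin(down)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
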