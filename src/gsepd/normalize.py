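"""Median-of-ratios size-factor normalization and the log2 transform.

Size factor for sample j is the median over reference genes of
counts[i, j] / geomean_i, where geomean_i is the geometric mean of gene i's
counts across samples.  Genes with any zero count are excluded from the
reference (their geometric mean is zero and the log is undefined) — the
standard median-of-ratios convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CountMatrix, ValidationError


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample positive scalar multipliers (median-of-ratios)."""
    arr = counts.counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; filter all-zero-containing "
            "genes or supply size factors explicitly"
        )
    ref = arr[all_positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    s = np.median(ref / geomean[:, None], axis=0)
    return pd.Series(s, index=counts.sample_ids, name="size_factor")


def normalize_log(
    counts: CountMatrix, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Element-wise log2(count / s_j + pseudocount); same shape and IDs as the
    count matrix, all finite."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    s = size_factors.reindex(counts.sample_ids)
    if s.isna().any() or (s <= 0).any():
        raise ValidationError("size factors must be positive and cover every sample")
    norm = counts.counts.to_numpy(dtype=float) / s.to_numpy()[None, :]
    out = pd.DataFrame(
        np.log2(norm + pseudocount), index=counts.gene_ids, columns=counts.sample_ids
    )
    if not np.isfinite(out.to_numpy()).all():
        raise ValidationError("normalized matrix contains non-finite values")
    return out
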