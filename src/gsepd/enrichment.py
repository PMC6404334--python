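"""Over-representation testing of DE gene lists against gene sets.

For each (term, direction) pair, the upper-tail hypergeometric probability
P(X >= k) of drawing at least the observed overlap k between the term's
members and the DE list when n = |DE list| genes are drawn without
replacement from the universe of N tested genes, K = |term| of which are in
the set.  BH adjustment is applied separately within each direction.

The test deliberately ignores gene length: a per-gene weight hook is exposed
for a future biased-urn (Wallenius) mode but the default is the plain
hypergeometric tail.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Config, GeneSetCollection, ValidationError

DIRECTIONS = ("up", "down", "all")


def overrepresentation_test(
    set_members: Iterable[str],
    de_list: Iterable[str],
    universe: Iterable[str],
    weights: dict[str, float] | None = None,
) -> float:
    """Upper-tail hypergeometric p-value for the overlap of a gene set with a
    DE list inside *universe*.  *weights* is accepted for interface stability
    (a length-bias-aware mode) but currently unused."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    set_members = set(set_members) & universe
    de_list = set(de_list) & universe
    k = len(set_members & de_list)
    K = len(set_members)
    n = len(de_list)
    N = len(universe)
    # P(X >= k); sf(k-1) is the survival function exclusive of k-1
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_all(
    collection: GeneSetCollection,
    de_calls: dict[str, list[str]],
    universe: Sequence[str],
    config: Config | None = None,
) -> pd.DataFrame:
    """One row per (term, direction) with columns term_id, term_name,
    set_size, de_in_set, direction, pvalue, padj.  set_size is the size of the
    term's membership intersected with *universe*; BH runs within direction."""
    config = config or Config()
    uni = set(universe)
    rows = []
    for gs in collection:
        members = gs.members & uni
        for direction in DIRECTIONS:
            de = set(de_calls[direction]) & uni
            k = len(members & de)
            p = overrepresentation_test(members, de, uni)
            rows.append(
                {
                    "term_id": gs.term_id,
                    "term_name": gs.term_name,
                    "set_size": len(members),
                    "de_in_set": k,
                    "direction": direction,
                    "pvalue": p,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["term_id", "term_name", "set_size", "de_in_set", "direction", "pvalue", "padj"]
        )
    df["padj"] = 1.0
    for direction in DIRECTIONS:
        mask = df["direction"] == direction
        if mask.any():
            df.loc[mask, "padj"] = multipletests(df.loc[mask, "pvalue"], method="fdr_bh")[1]
    return df.sort_values(["pvalue", "term_id", "direction"]).reset_index(drop=True)


def significant_terms(enrichment: pd.DataFrame, config: Config | None = None) -> list[str]:
    """Terms passing the significance gate for the clustering stage: the
    'all'-direction p-value (raw by default, padj if configured) below
    go_p_threshold."""
    config = config or Config()
    col = "padj" if config.use_padj_go else "pvalue"
    sub = enrichment.loc[enrichment["direction"] == "all"]
    sig = sub.loc[sub[col] < config.go_p_threshold]
    return sig.sort_values([col, "term_id"])["term_id"].tolist()


def write_enrichment(enrichment: pd.DataFrame, path) -> None:
    enrichment.to_csv(path, sep="\t", index=False, float_format="%.6g")
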