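"""Core data model: counts, sample metadata, contrasts, gene sets, configuration.

All downstream stages consume these validated containers.  The count matrix is
genes x samples; gene and sample identifiers are opaque strings (no accession
validation) so the toolkit stays annotation-agnostic.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gsepd")


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer RNA-seq counts, genes in rows, samples in columns.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers with unique gene identifiers as the
        index and unique sample identifiers as columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"count matrix needs at least 2 genes and 2 samples, got {df.shape}"
            )
        dup_g = _find_duplicates(list(df.index))
        if dup_g:
            raise ValidationError(f"duplicate gene IDs: {dup_g}")
        dup_s = _find_duplicates(list(df.columns))
        if dup_s:
            raise ValidationError(f"duplicate sample IDs: {dup_s}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self._first_bad_cell(df, lambda v: not _is_count(v))
            raise ValidationError(f"non-numeric count at {bad}")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr != np.floor(arr)):
            bad = self._first_bad_cell(df, lambda v: not _is_count(v))
            raise ValidationError(f"counts must be non-negative integers; offending cell at {bad}")
        object.__setattr__(self, "counts", df.astype(np.int64))

    @staticmethod
    def _first_bad_cell(df: pd.DataFrame, pred) -> str:
        for g in df.index:
            for s in df.columns:
                if pred(df.at[g, s]):
                    return f"gene {g!r}, sample {s!r} (value {df.at[g, s]!r})"
        return "<unknown>"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def _is_count(v) -> bool:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return False
    return np.isfinite(f) and f >= 0 and f == int(f)


@dataclass(frozen=True)
class SampleTable:
    """Sample metadata linking sample IDs to condition labels and short plot labels."""

    table: pd.DataFrame  # columns: sample_id, condition, short_label

    REQUIRED = ("sample_id", "condition", "short_label")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing column(s): {missing}")
        df = df.loc[:, list(self.REQUIRED)].astype(str).reset_index(drop=True)
        dup = _find_duplicates(list(df["sample_id"]))
        if dup:
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        dup_l = _find_duplicates(list(df["short_label"]))
        if dup_l:
            raise ValidationError(f"duplicate short_label(s): {dup_l}")
        too_long = [l for l in df["short_label"] if len(l) > 8]
        if too_long:
            raise ValidationError(f"short_label(s) longer than 8 characters: {too_long}")
        object.__setattr__(self, "table", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["condition"].iloc[0])

    def short_label_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["short_label"].iloc[0])

    def samples_in(self, condition: str) -> list[str]:
        return list(self.table.loc[self.table["condition"] == condition, "sample_id"])

    def validate_against(self, counts: CountMatrix) -> None:
        absent = [s for s in self.sample_ids if s not in set(counts.sample_ids)]
        if absent:
            raise ValidationError(f"sample(s) not present in the count matrix: {absent}")


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison.  Samples in neither group are "non-tested":
    they are clustered and projected but carry no class label."""

    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValidationError("contrast groups must differ")

    def tested_samples(self, samples: SampleTable) -> list[str]:
        return samples.samples_in(self.group_a) + samples.samples_in(self.group_b)

    def validate_against(self, samples: SampleTable) -> None:
        for g in (self.group_a, self.group_b):
            n = len(samples.samples_in(g))
            if n == 0:
                raise ValidationError(f"contrast group {g!r} has no samples")
            if n < 2:
                logger.warning("contrast group %r has only %d sample", g, n)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def intersect(self, gene_ids: Sequence[str]) -> "GeneSet":
        return GeneSet(self.term_id, self.term_name, self.members & set(gene_ids))


@dataclass(frozen=True)
class GeneSetCollection:
    """Gene-set annotation: term ID -> (name, member gene IDs).

    Membership used downstream is always the intersection with the count
    matrix's gene IDs; ``intersect_with`` performs that restriction once.
    """

    sets: Mapping[str, GeneSet]

    def __post_init__(self) -> None:
        for tid, gs in self.sets.items():
            if tid != gs.term_id:
                raise ValidationError(f"key {tid!r} does not match term_id {gs.term_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def term_ids(self) -> list[str]:
        return list(self.sets)

    def intersect_with(self, gene_ids: Sequence[str]) -> "GeneSetCollection":
        """Restrict every term's members to genes present in the matrix.
        Terms whose intersection is empty are dropped."""
        universe = set(gene_ids)
        out = {}
        for tid, gs in self.sets.items():
            inter = gs.members & universe
            if inter:
                out[tid] = GeneSet(tid, gs.term_name, frozenset(inter))
        dropped = len(self.sets) - len(out)
        if dropped:
            logger.info("dropped %d term(s) with no genes in the count matrix", dropped)
        return GeneSetCollection(out)


@dataclass
class Config:
    """Pipeline parameters.

    m is the maximum gene-set size: terms whose intersected size is >= m are
    excluded from clustering ("less than m genes" is strict).  B is the
    permutation budget for the adaptive empirical p-value.
    """

    m: int = 31
    min_set_size: int = 2
    de_p_threshold: float = 0.05
    go_p_threshold: float = 0.05
    vmeasure_p_threshold: float = 0.01
    max_permutations: int = 400
    pseudocount: float = 1.0
    seed: int = 0
    normalize_alpha: bool = True
    use_padj_de: bool = False
    use_padj_go: bool = False
    strict_exceedance: bool = False
    kmeans_restarts: int = 10
    top_n_hma: int | None = None
    figure_format: str = "png"
    output_dir: str = "gsepd_out"

    def __post_init__(self) -> None:
        if not (2 <= self.min_set_size < self.m):
            raise ValidationError(
                f"need 2 <= min_set_size < m, got min_set_size={self.min_set_size}, m={self.m}"
            )
        for name in ("de_p_threshold", "go_p_threshold", "vmeasure_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.max_permutations < 1:
            raise ValidationError("max_permutations must be >= 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.kmeans_restarts < 1:
            raise ValidationError("kmeans_restarts must be >= 1")
        if self.figure_format not in ("png", "pdf"):
            raise ValidationError("figure_format must be 'png' or 'pdf'")

    def replace(self, **kw) -> "Config":
        return dataclasses.replace(self, **kw)
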