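"""Alpha/beta projection of samples onto the centroid axis of a gene set.

In a gene set's expression subspace the two contrast groups define centroids
A and B.  Each sample P is orthogonally projected onto the axis from A to B:
alpha is its coordinate along the axis (0 at A, 1 at B when normalized by
|AB|; in raw form it is the signed distance (P-A)·(B-A)/|B-A| in log2
expression units) and beta is the Euclidean distance from P to its projection
— a goodness-of-fit measure for the two-group linear contrast.  Non-tested
samples are scored too, showing which group they "behave" like per term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Config, Contrast, GeneSetCollection, SampleTable, ValidationError


@dataclass(frozen=True)
class Centroids:
    """Group centroids in a gene set's subspace; the axis points from A to B."""

    genes: tuple[str, ...]
    centroid_a: np.ndarray
    centroid_b: np.ndarray

    @property
    def axis(self) -> np.ndarray:
        return self.centroid_b - self.centroid_a

    @property
    def axis_norm(self) -> float:
        return float(np.linalg.norm(self.axis))


def compute_centroids(
    norm: pd.DataFrame,
    set_genes: list[str],
    samples: SampleTable,
    contrast: Contrast,
) -> Centroids:
    """Mean expression vector of *set_genes* over each contrast group."""
    genes = [g for g in set_genes if g in norm.index]
    if len(genes) != len(set_genes):
        missing = sorted(set(set_genes) - set(genes))
        raise ValidationError(f"gene(s) not in the normalized matrix: {missing}")
    a_ids = samples.samples_in(contrast.group_a)
    b_ids = samples.samples_in(contrast.group_b)
    if not a_ids or not b_ids:
        raise ValidationError("both contrast groups must be non-empty")
    ca = norm.loc[genes, a_ids].to_numpy().mean(axis=1)
    cb = norm.loc[genes, b_ids].to_numpy().mean(axis=1)
    return Centroids(tuple(genes), ca, cb)


def project_sample(p: np.ndarray, cent: Centroids, normalize: bool = True) -> dict:
    """Project one sample point onto the centroid axis.

    Returns alpha (normalized coordinate if *normalize*), alpha_raw (signed
    distance along the axis in log2 units), beta (perpendicular distance) and
    a degenerate flag set when the two centroids coincide.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != cent.centroid_a.shape:
        raise ValidationError(
            f"dimension mismatch: point has {p.shape}, centroids have {cent.centroid_a.shape}"
        )
    ap = p - cent.centroid_a
    d = cent.axis_norm
    if d == 0.0:
        return {
            "alpha": 0.0,
            "alpha_raw": 0.0,
            "beta": float(np.linalg.norm(ap)),
            "degenerate": True,
        }
    alpha_raw = float(ap @ cent.axis) / d
    foot = (alpha_raw / d) * cent.axis
    beta = float(np.linalg.norm(ap - foot))
    alpha = alpha_raw / d if normalize else alpha_raw
    return {"alpha": alpha, "alpha_raw": alpha_raw, "beta": beta, "degenerate": False}


def project_all(
    norm: pd.DataFrame,
    term_ids: list[str],
    collection: GeneSetCollection,
    samples: SampleTable,
    contrast: Contrast,
    config: Config | None = None,
) -> pd.DataFrame:
    """Alpha/beta score for EVERY sample against every qualifying term.

    Columns: term_id, sample_id, tested, alpha, alpha_raw, beta,
    degenerate_flag.  'tested' marks samples belonging to one of the two
    contrast groups.
    """
    config = config or Config()
    tested_set = set(contrast.tested_samples(samples))
    rows = []
    for tid in term_ids:
        genes = sorted(collection[tid].members & set(norm.index))
        cent = compute_centroids(norm, genes, samples, contrast)
        for sid in norm.columns:
            score = project_sample(
                norm.loc[genes, sid].to_numpy(), cent, normalize=config.normalize_alpha
            )
            rows.append(
                {
                    "term_id": tid,
                    "sample_id": sid,
                    "tested": sid in tested_set,
                    "alpha": score["alpha"],
                    "alpha_raw": score["alpha_raw"],
                    "beta": score["beta"],
                    "degenerate_flag": score["degenerate"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["term_id", "sample_id", "tested", "alpha", "alpha_raw", "beta", "degenerate_flag"],
    )


def write_projection(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.10g")
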