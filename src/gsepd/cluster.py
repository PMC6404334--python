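"""Per-gene-set sample clustering and cluster-validity scoring.

For each admissible gene set, every sample is a point in the set's expression
subspace (one dimension per member gene, log2-normalized units).  Samples are
split by 2-means; concordance between the split and the contrast's class
labels is scored by the V-measure, the harmonic mean of homogeneity and
completeness, both defined through conditional entropies of the 2x2
class-by-cluster contingency table.  Significance is an empirical permutation
p-value: class labels are shuffled (clusters stay fixed — they do not depend
on the labels) and the V-measure recomputed.

Small contrasts are enumerated exhaustively: when the number of distinct
label assignments is within the permutation budget, every assignment is
scored once and the p-value is the exact exceedance proportion.  Otherwise
uniform random permutations are drawn with adaptive early stopping — once 10
exceedances accumulate, the p-value can no longer resolve below the default
0.01 gate, so further permutations are not spent.
"""

from __future__ import annotations

import hashlib
import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .model import Config, Contrast, GeneSetCollection, SampleTable, ValidationError

logger = logging.getLogger("gsepd")

# exact 2-means by bipartition enumeration up to this many points
_EXACT_KMEANS_MAX_N = 12
# sampling mode stops once this many exceedances are seen
_EARLY_STOP_EXCEEDANCES = 10


# ---------------------------------------------------------------- k-means

def _partition_ss(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Centroids and total within-cluster sum of squares for a 2-way labeling."""
    cents = np.empty((2, points.shape[1]))
    ss = 0.0
    for k in (0, 1):
        pk = points[labels == k]
        if len(pk) == 0:
            cents[k] = np.nan
            continue
        cents[k] = pk.mean(axis=0)
        ss += float(((pk - cents[k]) ** 2).sum())
    return cents, ss


def _lloyd(points: np.ndarray, centroids: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """Standard Lloyd iterations with k=2 and Euclidean distance.  If an
    assignment step empties a cluster, the previous state is kept."""
    cents = centroids.copy()
    labels = None
    for _ in range(max_iter):
        d = ((points[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        if len(np.unique(new_labels)) < 2 and labels is not None:
            break
        labels = new_labels
        for k in (0, 1):
            pk = points[labels == k]
            if len(pk):
                cents[k] = pk.mean(axis=0)
    if labels is None:
        labels = np.zeros(len(points), dtype=int)
    cents, ss = _partition_ss(points, labels)
    return labels, cents, ss


def kmeans2(points: np.ndarray, seed: int, restarts: int = 10) -> dict:
    """2-means clustering of sample points, deterministic given *seed*.

    Small instances (n <= 12) are solved exactly by enumerating every
    bipartition and refining the best one with Lloyd steps; larger instances
    use *restarts* seeded Lloyd runs initialized from distinct data points,
    tie-broken by lowest within-SS then lowest restart index.

    Returns a dict with 'labels' (per-sample cluster index in {0,1}),
    'centroids' (2 x N), and 'within_ss'.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be a 2-D array (n_samples x n_genes)")
    n = points.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples to cluster")
    if np.allclose(points, points[0]):
        logger.warning("all points identical; clustering is degenerate")
        cents = np.vstack([points[0], points[0]])
        return {"labels": np.zeros(n, dtype=int), "centroids": cents, "within_ss": 0.0}

    if n <= _EXACT_KMEANS_MAX_N:
        best_labels, best_ss = None, np.inf
        # fix point 0 in cluster 0 to halve the enumeration
        for mask in range(1, 2 ** (n - 1)):
            labels = np.zeros(n, dtype=int)
            for j in range(n - 1):
                if mask >> j & 1:
                    labels[j + 1] = 1
            _, ss = _partition_ss(points, labels)
            if ss < best_ss - 1e-15:
                best_labels, best_ss = labels, ss
        cents, _ = _partition_ss(points, best_labels)
        labels, cents, ss = _lloyd(points, cents)
        if ss > best_ss or len(np.unique(labels)) < 2:
            labels = best_labels
            cents, ss = _partition_ss(points, best_labels)
        return {"labels": labels, "centroids": cents, "within_ss": ss}

    rng = np.random.default_rng(seed)
    best = None
    for r in range(restarts):
        idx = rng.choice(n, size=2, replace=False)
        labels, cents, ss = _lloyd(points, points[idx])
        if best is None or ss < best[2] - 1e-12:
            best = (labels, cents, ss)
    labels, cents, ss = best
    return {"labels": labels, "centroids": cents, "within_ss": ss}


# ---------------------------------------------------------------- V-measure

def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of a count vector; 0*log0 = 0."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def v_measure(class_labels, cluster_labels) -> tuple[float, float, float]:
    """Homogeneity, completeness and V-measure of a clustering against class
    labels.

    h = 1 - H(C|K)/H(C) (1 if H(C) = 0), c = 1 - H(K|C)/H(K) symmetrically,
    v = 2hc/(h+c) (0 if h + c = 0).  The value does not depend on the
    logarithm base because the entropies appear only as ratios.
    """
    class_labels = np.asarray(class_labels)
    cluster_labels = np.asarray(cluster_labels)
    if class_labels.shape != cluster_labels.shape:
        raise ValidationError("class and cluster label vectors must have equal length")
    if class_labels.size < 2:
        raise ValidationError("need at least 2 labeled samples")
    classes, ci = np.unique(class_labels, return_inverse=True)
    clusters, ki = np.unique(cluster_labels, return_inverse=True)
    n = class_labels.size
    cont = np.zeros((len(classes), len(clusters)))
    np.add.at(cont, (ci, ki), 1)

    h_c = _entropy(cont.sum(axis=1))
    h_k = _entropy(cont.sum(axis=0))
    # H(C|K) = sum_k (n_k/n) * H(C within cluster k)
    h_c_given_k = sum(
        (cont[:, k].sum() / n) * _entropy(cont[:, k]) for k in range(len(clusters))
    )
    h_k_given_c = sum(
        (cont[c, :].sum() / n) * _entropy(cont[c, :]) for c in range(len(classes))
    )
    h = 1.0 if h_c == 0.0 else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k == 0.0 else 1.0 - h_k_given_c / h_k
    v = 0.0 if h + c == 0.0 else 2.0 * h * c / (h + c)
    return float(h), float(c), float(v)


# ------------------------------------------------------- permutation p-value

def _n_distinct_assignments(class_labels: np.ndarray) -> int:
    from math import comb, factorial

    _, counts = np.unique(class_labels, return_counts=True)
    n = counts.sum()
    total = factorial(int(n))
    for c in counts:
        total //= factorial(int(c))
    return total


def permutation_pvalue(
    cluster_labels,
    class_labels,
    observed_v: float,
    config: Config | None = None,
    seed: int = 0,
) -> tuple[float, int]:
    """Empirical p-value of the observed V-measure under label permutation.

    The clustering is held fixed; only the class-label vector is permuted.
    An exceedance is a permuted V-measure >= the observed one (> in strict
    mode).  When the number of distinct label assignments is within the
    permutation budget, all of them are enumerated and the p-value is the
    exact exceedance proportion (the observed assignment is itself one of the
    enumerated ones, so the proportion is never zero under the default rule);
    otherwise p = (exceedances + 1) / (draws + 1) with early stopping.

    Returns (p_empirical, n_permutations_used).
    """
    config = config or Config()
    cluster_labels = np.asarray(cluster_labels)
    class_labels = np.asarray(class_labels)
    if cluster_labels.shape != class_labels.shape:
        raise ValidationError("label vectors must have equal length")
    B = config.max_permutations
    strict = config.strict_exceedance
    tol = 1e-12

    def exceeds(v_perm: float) -> bool:
        return v_perm > observed_v + tol if strict else v_perm >= observed_v - tol

    n_distinct = _n_distinct_assignments(class_labels)
    if n_distinct <= B:
        # exhaustive: enumerate every distinct placement of the label multiset
        values, counts = np.unique(class_labels, return_counts=True)
        n = class_labels.size
        e = 0
        total = 0
        labels_template = np.empty(n, dtype=class_labels.dtype)
        if len(values) == 2:
            for pos in combinations(range(n), int(counts[0])):
                labels_template[:] = values[1]
                labels_template[list(pos)] = values[0]
                _, _, v = v_measure(labels_template, cluster_labels)
                total += 1
                if exceeds(v):
                    e += 1
        else:  # general multiset (more than two classes never occurs in a contrast)
            from sympy.utilities.iterables import multiset_permutations

            for perm in multiset_permutations(list(class_labels)):
                _, _, v = v_measure(np.array(perm), cluster_labels)
                total += 1
                if exceeds(v):
                    e += 1
        p = max(e, 1) / total
        return float(p), total

    rng = np.random.default_rng(seed)
    e = 0
    b = 0
    while b < B:
        perm = rng.permutation(class_labels)
        _, _, v = v_measure(perm, cluster_labels)
        b += 1
        if exceeds(v):
            e += 1
            if e >= _EARLY_STOP_EXCEEDANCES:
                break
    return (e + 1) / (b + 1), b


# -------------------------------------------------------------- orchestration

def derive_term_seed(seed: int, term_id: str) -> int:
    """Stable per-term RNG seed: hashing keeps each term's permutation stream
    independent of which other terms are evaluated."""
    digest = hashlib.sha256(f"{seed}:{term_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def evaluate_terms(
    term_ids: list[str],
    collection: GeneSetCollection,
    norm: pd.DataFrame,
    samples: SampleTable,
    contrast: Contrast,
    config: Config | None = None,
) -> pd.DataFrame:
    """Cluster and score every candidate term.

    Terms with intersected size >= m or < min_set_size are skipped with a
    recorded reason.  Clustering uses ALL samples in the matrix (tested and
    non-tested); the V-measure and the permutations use only the tested
    samples, which are the only ones carrying class labels.  A term
    "segregates" when p_empirical < vmeasure_p_threshold.
    """
    config = config or Config()
    all_samples = [s for s in norm.columns if s in set(samples.sample_ids)]
    tested = [s for s in all_samples if samples.condition_of(s) in (contrast.group_a, contrast.group_b)]
    tested_idx = [all_samples.index(s) for s in tested]
    class_labels = np.array([samples.condition_of(s) for s in tested])

    rows = []
    assignments: dict[str, np.ndarray] = {}
    for tid in term_ids:
        gs = collection[tid]
        genes = sorted(gs.members & set(norm.index))
        size = len(genes)
        row = {
            "term_id": tid,
            "term_name": gs.term_name,
            "set_size": size,
            "h": np.nan,
            "c": np.nan,
            "v": np.nan,
            "p_empirical": np.nan,
            "n_permutations_used": 0,
            "segregates": False,
            "skip_reason": "",
        }
        if size >= config.m:
            row["skip_reason"] = f"size >= m ({size} >= {config.m})"
            rows.append(row)
            continue
        if size < config.min_set_size:
            row["skip_reason"] = f"below min_set_size ({size} < {config.min_set_size})"
            rows.append(row)
            continue
        points = norm.loc[genes, all_samples].to_numpy().T  # samples x genes
        term_seed = derive_term_seed(config.seed, tid)
        km = kmeans2(points, seed=term_seed, restarts=config.kmeans_restarts)
        assignments[tid] = km["labels"]
        clusters_tested = km["labels"][tested_idx]
        h, c, v = v_measure(class_labels, clusters_tested)
        p, n_used = permutation_pvalue(clusters_tested, class_labels, v, config, seed=term_seed)
        row.update(
            h=h, c=c, v=v, p_empirical=p, n_permutations_used=n_used,
            segregates=bool(p < config.vmeasure_p_threshold),
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=[
        "term_id", "term_name", "set_size", "h", "c", "v",
        "p_empirical", "n_permutations_used", "segregates", "skip_reason",
    ])
    df.attrs["assignments"] = assignments
    return df


def write_validity(validity: pd.DataFrame, path) -> None:
    validity.to_csv(path, sep="\t", index=False, float_format="%.6g")
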