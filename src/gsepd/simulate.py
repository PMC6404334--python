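"""Synthetic two-group RNA-seq studies with gene-set-structured effects.

Counts are negative-binomial: gene i, sample j has mean
s_j * mu_i * 2^(effect_i) where s_j is a per-sample size factor drawn
uniformly from a configurable range, mu_i is a gene-wise baseline mean drawn
log-uniformly (default 20-2000, typical bulk RNA-seq depth), and effect_i is
the log2 fold-change carried by genes of "affected" sets in group B samples.
Dispersion is gene-shared (default 0.1, variance mu + 0.1*mu^2).

Non-tested samples form a third pool whose means interpolate the two group
means with a configurable mixing weight, so their projection alpha scores
have a known expected intermediate value.

Everything derives from a single integer seed; a fixed seed reproduces the
study byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CountMatrix, GeneSet, GeneSetCollection, SampleTable, ValidationError


@dataclass
class SimSpec:
    n_genes: int = 200
    n_per_group: tuple[int, int] = (6, 6)
    n_nontested: int = 0
    nb_mean_range: tuple[float, float] = (20.0, 2000.0)
    nb_dispersion: float = 0.1
    # (term_id, member gene ids, log2 effect in group B)
    affected_sets: list[tuple[str, list[str], float]] = field(default_factory=list)
    # (term_id, member gene ids)
    decoy_sets: list[tuple[str, list[str]]] = field(default_factory=list)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    nontested_mix_weight: float = 0.5
    group_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        genes = set(self.gene_ids())
        for tid, members, eff in self.affected_sets:
            extra = set(members) - genes
            if extra:
                raise ValidationError(f"affected set {tid}: genes not generated: {sorted(extra)}")
            if not np.isfinite(eff):
                raise ValidationError(f"affected set {tid}: non-finite effect size")
        for tid, members in self.decoy_sets:
            extra = set(members) - genes
            if extra:
                raise ValidationError(f"decoy set {tid}: genes not generated: {sorted(extra)}")


def simulate_study(spec: SimSpec):
    """Generate (CountMatrix, SampleTable, GeneSetCollection, truth table).

    The truth table records, per term, whether it carries an effect and the
    log2 effect size; per-gene effects are recoverable from the affected
    sets' memberships.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    n_a, n_b = spec.n_per_group
    la, lb = spec.group_labels
    sample_ids = (
        [f"{la}{i+1}" for i in range(n_a)]
        + [f"{lb}{i+1}" for i in range(n_b)]
        + [f"NT{i+1}" for i in range(spec.n_nontested)]
    )
    conditions = [la] * n_a + [lb] * n_b + ["nontested"] * spec.n_nontested

    lo, hi = spec.nb_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_genes))
    s = rng.uniform(*spec.size_factor_range, size=len(sample_ids))

    effect = np.zeros(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for _, members, eff in spec.affected_sets:
        for g in members:
            effect[gene_index[g]] += eff

    # per-sample effect multiplier exponent: 0 in A, 1 in B, w for non-tested
    group_w = np.array([0.0] * n_a + [1.0] * n_b + [spec.nontested_mix_weight] * spec.n_nontested)
    mean = s[None, :] * mu[:, None] * np.power(2.0, effect[:, None] * group_w[None, :])

    if spec.nb_dispersion > 0:
        r = 1.0 / spec.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    st = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "condition": conditions,
                "short_label": sample_ids,  # already short by construction
            }
        )
    )
    sets = {}
    truth_rows = []
    for tid, members, eff in spec.affected_sets:
        sets[tid] = GeneSet(tid, f"affected set {tid}", frozenset(members))
        truth_rows.append({"term_id": tid, "affected": eff != 0.0, "effect": eff})
    for tid, members in spec.decoy_sets:
        sets[tid] = GeneSet(tid, f"decoy set {tid}", frozenset(members))
        truth_rows.append({"term_id": tid, "affected": False, "effect": 0.0})
    collection = GeneSetCollection(sets)
    truth = pd.DataFrame(truth_rows, columns=["term_id", "affected", "effect"])
    return cm, st, collection, truth


def simulate_null(spec: SimSpec):
    """Same generative model with every effect forced to zero: all terms
    become decoys and the truth table records no affected term."""
    null = SimSpec(**{**spec.__dict__})
    null.affected_sets = [(tid, members, 0.0) for tid, members, _ in spec.affected_sets]
    cm, st, collection, truth = simulate_study(null)
    truth["affected"] = False
    truth["effect"] = 0.0
    return cm, st, collection, truth


def golden_spec(seed: int = 20240) -> SimSpec:
    """The bundled end-to-end study: 60 genes, 6 tested samples per group
    plus 4 non-tested interpolating samples, one strongly affected 10-gene
    term (log2 effect 4) and four 10-gene decoy terms."""
    width = len(str(60))
    genes = [f"G{i:0{width}d}" for i in range(1, 61)]
    affected = [("GO:0000001", genes[:10], 4.0)]
    decoys = [
        (f"GO:000000{k}", genes[10 * (k - 1) : 10 * k]) for k in range(2, 6)
    ]
    return SimSpec(
        n_genes=60,
        n_per_group=(6, 6),
        n_nontested=4,
        affected_sets=affected,
        decoy_sets=decoys,
        seed=seed,
    )
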