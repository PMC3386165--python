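"""Pair-set enrichment: is a set of gene pairs concentrated at the top of
a posterior-probability ranking?

The statistic is the weighted Kolmogorov-Smirnov running sum familiar from
gene-set enrichment analysis, applied to gene *pairs*: pairs are ranked by
a per-pair phenotype (e.g. the posterior probability of positive
association), the running sum steps up by the phenotype weight at each set
member and down uniformly at each non-member, and the enrichment score is
the signed maximal deviation.  Significance comes from permuting set
membership over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationSet
from .errors import ValidationError
from .screens import PriorNetwork

__all__ = ["EnrichmentResult", "pairset_enrichment", "running_sum"]


@dataclass
class EnrichmentResult:
    es: float
    p_value: float
    n_perm: int
    n_hits: int
    hit_positions: np.ndarray = field(repr=False)
    curve: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, self.curve.size + 1), "running_sum": self.curve}
        )


def running_sum(phenotype_sorted: np.ndarray, is_hit: np.ndarray) -> np.ndarray:
    """KS running sum over a descending ranking with weighted hit steps."""
    n = phenotype_sorted.size
    n_hits = int(is_hit.sum())
    n_miss = n - n_hits
    if n_hits == 0:
        raise ValidationError("pair set is empty after restriction to scored pairs")
    if n_miss == 0:
        return np.zeros(n)  # degenerate: the set is all pairs
    weights = np.abs(phenotype_sorted)
    hit_total = weights[is_hit].sum()
    steps = np.where(
        is_hit,
        weights / hit_total if hit_total > 0 else 1.0 / n_hits,
        -1.0 / n_miss,
    )
    return np.cumsum(steps)


def _es(curve: np.ndarray) -> float:
    if not curve.any():
        return 0.0
    i = int(np.argmax(np.abs(curve)))
    return float(curve[i])


def pairset_enrichment(
    phenotype: np.ndarray,
    assoc: AssociationSet,
    pair_set: PriorNetwork,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation enrichment of a pair set in a per-pair phenotype.

    The p-value is the add-one-smoothed fraction of membership
    permutations whose enrichment score reaches the observed one, so it is
    always positive and invariant to strictly monotone transforms of the
    phenotype ranking.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.shape != (assoc.n_pairs,):
        raise ValidationError("phenotype must hold one value per association pair")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = assoc.pair_membership(pair_set)
    if not hits.any():
        raise ValidationError("pair set is empty after restriction to scored pairs")
    order = np.argsort(-phenotype, kind="stable")
    pheno_sorted = phenotype[order]
    hits_sorted = hits[order]
    curve = running_sum(pheno_sorted, hits_sorted)
    observed = _es(curve)
    n_hits = int(hits.sum())
    count = 0
    for _ in range(n_perm):
        perm_hits = np.zeros(phenotype.size, dtype=bool)
        perm_hits[rng.choice(phenotype.size, size=n_hits, replace=False)] = True
        if _es(running_sum(pheno_sorted, perm_hits)) >= observed:
            count += 1
    p_value = (1 + count) / (1 + n_perm)
    return EnrichmentResult(
        es=observed,
        p_value=float(p_value),
        n_perm=n_perm,
        n_hits=n_hits,
        hit_positions=np.flatnonzero(hits_sorted) + 1,
        curve=curve,
    )
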