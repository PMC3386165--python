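"""Functional-module search: hierarchical clustering of association
profiles, multiscale bootstrap support, and the four-step module filter.

Genes are clustered on their association profiles (the vector of cosine
similarities to every other screened gene) with correlation distance and
average linkage by default.  Cluster uncertainty is assessed by multiscale
bootstrap resampling of replicate columns: bootstrap probabilities (BP)
are recorded at sample-size scales r in [0.5, 1.4], and an approximately
unbiased (AU) probability is obtained per cluster from the signed-distance
/ curvature regression Phi^-1(1 - BP_r) = v*sqrt(r) + c/sqrt(r); the
module p-value is 1 - AU = Phi(v - c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .association import AssociationSet, cosine_matrix
from .errors import ConfigurationError, ValidationError
from .network import PAN, density
from .screens import ScreenMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterSupport",
    "FunctionalModule",
    "profile_distance",
    "hcluster",
    "multiscale_bootstrap",
    "au_pvalue",
    "filter_modules",
    "DEFAULT_SCALES",
]

#: Bootstrap sample sizes relative to the real replicate count.
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))

_LINKAGES = ("average", "complete", "ward")


class Dendrogram:
    """Agglomerative merge tree over genes (wraps a scipy linkage matrix)."""

    def __init__(self, genes: list[str], merge: np.ndarray):
        self.genes = list(genes)
        self.merge = np.asarray(merge, dtype=float)

    def clusters(self) -> list[tuple[frozenset, float]]:
        """Member set and merge height of every internal node, root included."""
        n = len(self.genes)
        members: dict[int, frozenset] = {i: frozenset([self.genes[i]]) for i in range(n)}
        out = []
        for step, (a, b, height, _) in enumerate(self.merge):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            out.append((merged, float(height)))
        return out

    def cluster_sets(self) -> list[frozenset]:
        return [m for m, _ in self.clusters()]


def profile_distance(assoc: AssociationSet) -> np.ndarray:
    """Correlation distance between genes' association profiles.

    The profile of gene u is cc(u, .) over all other genes; when comparing
    u and v the entries involving either gene are excluded from both
    vectors so the two profiles cover the same index set.
    """
    cc = assoc.square_cc()
    return _profile_distance_from_cc(cc, assoc.genes)


def _profile_distance_from_cc(cc: np.ndarray, genes: list[str]) -> np.ndarray:
    """Leave-two-out correlation distance, vectorised.

    For genes u, v the Pearson correlation of rows cc[u] and cc[v] is
    taken over the n-2 columns excluding u and v themselves; the exclusion
    terms are subtracted from full-row sums so everything stays in BLAS.
    """
    n = cc.shape[0]
    if n < 3:
        raise ValidationError("profile distances need at least 3 genes")
    m = n - 2
    row_sum = cc.sum(axis=1)
    row_sq = (cc * cc).sum(axis=1)
    cross = cc @ cc.T
    diag = np.diag(cc)
    # per-pair sums over the shared index set (all w except u and v)
    s_u = row_sum[:, None] - diag[:, None] - cc  # sum_w cc[u,w], w != u,v
    s_v = row_sum[None, :] - cc - diag[None, :]
    q_u = row_sq[:, None] - diag[:, None] ** 2 - cc**2
    q_v = row_sq[None, :] - cc**2 - diag[None, :] ** 2
    dot = cross - cc * diag[:, None] - cc * diag[None, :]  # minus w=u and w=v terms
    var_u = q_u - s_u**2 / m
    var_v = q_v - s_v**2 / m
    off = ~np.eye(n, dtype=bool)
    bad = (var_u <= 1e-14) & off
    if bad.any():
        u = int(np.flatnonzero(bad.any(axis=1))[0])
        raise ValidationError(f"gene {genes[u]!r} has a constant profile")
    with np.errstate(invalid="ignore"):
        r = (dot - s_u * s_v / m) / np.sqrt(var_u * var_v)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, 2.0, out=dist)
    return (dist + dist.T) / 2.0  # exact symmetry against rounding


def hcluster(dist: np.ndarray, genes: list[str], linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    condensed = squareform(dist, checks=False)
    return Dendrogram(genes, _scipy_linkage(condensed, method=linkage))


@dataclass
class ClusterSupport:
    """Bootstrap support of one original cluster across resampling scales."""

    members: frozenset
    scales: np.ndarray
    hits: np.ndarray
    trials: np.ndarray
    height: float = float("nan")
    v: float = float("nan")
    c: float = float("nan")
    au: float = float("nan")
    p_value: float = float("nan")

    @property
    def bp(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.trials > 0, self.hits / np.maximum(self.trials, 1), np.nan)


def _pipeline_clusters(screen: ScreenMatrix, linkage: str) -> Dendrogram:
    assoc = cosine_matrix(screen)
    dist = profile_distance(assoc)
    return hcluster(dist, screen.genes, linkage=linkage)


def _index_cluster_sets(values: np.ndarray, genes: list[str], linkage: str) -> list[frozenset]:
    """Cosine -> profile distance -> dendrogram, as frozensets of row indices.

    Fast path for the bootstrap inner loop; identical pipeline to
    :func:`_pipeline_clusters` without container construction.
    """
    norms = np.linalg.norm(values, axis=1)
    if np.any(norms == 0):
        raise ValidationError("all-zero phenotype profile in resample")
    xn = values / norms[:, None]
    cc = np.clip(xn @ xn.T, -1.0, 1.0)
    np.fill_diagonal(cc, 1.0)
    dist = _profile_distance_from_cc(cc, genes)
    merge = _scipy_linkage(squareform(dist, checks=False), method=linkage)
    n = values.shape[0]
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(merge):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def multiscale_bootstrap(
    screen: ScreenMatrix,
    scales=DEFAULT_SCALES,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    linkage: str = "average",
) -> list[ClusterSupport]:
    """Bootstrap probabilities of the original dendrogram's clusters.

    For each scale r, B resamples of round(r * q) replicate columns (with
    replacement) rerun the full cosine-profile / distance / clustering
    pipeline; a cluster's BP at scale r is the fraction of replicates
    whose dendrogram contains an identical member set.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    scales = np.asarray(sorted(scales), dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = screen.n_columns
    values = screen.values
    original_idx = _index_cluster_sets(values, screen.genes, linkage)
    heights = [h for _, h in _pipeline_clusters(screen, linkage).clusters()]
    index = {m: i for i, m in enumerate(original_idx)}
    hits = np.zeros((len(original_idx), len(scales)), dtype=float)
    trials = np.zeros(len(scales), dtype=float)
    for s, r in enumerate(scales):
        m_cols = int(round(r * q))
        if m_cols < 2:
            logger.warning("scale %.2f gives %d columns; skipped", r, m_cols)
            continue
        for _ in range(B):
            cols = rng.integers(0, q, size=m_cols)
            try:
                boot_sets = _index_cluster_sets(values[:, cols], screen.genes, linkage)
            except ValidationError:
                continue  # degenerate resample (zero profile/constant column)
            trials[s] += 1
            for m in boot_sets:
                i = index.get(m)
                if i is not None:
                    hits[i, s] += 1
    supports = [
        ClusterSupport(
            members=frozenset(screen.genes[i] for i in m),
            scales=scales.copy(),
            hits=hits[k],
            trials=trials.copy(),
            height=heights[k],
        )
        for k, m in enumerate(original_idx)
    ]
    return [au_pvalue(s) for s in supports]


def au_pvalue(support: ClusterSupport) -> ClusterSupport:
    """Fit the multiscale-bootstrap regression and attach the AU p-value.

    Weighted least squares of Phi^-1(1 - BP_r) on (sqrt(r), 1/sqrt(r)) with
    binomial weights; AU = 1 - Phi(v - c) and p = 1 - AU.  Degenerate
    support falls back to p = 0 (BP identically 1), p = 1 (identically 0),
    or the plain BP at the scale nearest 1.
    """
    bp = support.bp
    ok = (support.trials > 0) & np.isfinite(bp)
    usable = ok & (bp > 0) & (bp < 1)
    if ok.any() and np.all(bp[ok] >= 1):
        support.au, support.p_value = 1.0, 0.0
        support.v = support.c = 0.0
        return support
    if ok.any() and np.all(bp[ok] <= 0):
        support.au, support.p_value = 0.0, 1.0
        support.v = support.c = 0.0
        return support
    if usable.sum() < 2:
        near1 = int(np.argmin(np.abs(support.scales - 1.0)))
        fallback = bp[near1] if np.isfinite(bp[near1]) else np.nanmean(bp[ok])
        logger.warning(
            "cluster of %d genes: <2 usable scales; p-value falls back to BP",
            len(support.members),
        )
        support.au = float(fallback)
        support.p_value = float(1.0 - fallback)
        return support
    r = support.scales[usable]
    z = stats.norm.ppf(1.0 - bp[usable])
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = support.trials[usable] * stats.norm.pdf(z) ** 2 / (bp[usable] * (1.0 - bp[usable]))
    try:
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, wx.T @ z)
    except np.linalg.LinAlgError:
        near1 = int(np.argmin(np.abs(support.scales - 1.0)))
        logger.warning("singular AU design; p-value falls back to BP at r~1")
        support.au = float(bp[near1])
        support.p_value = float(1.0 - bp[near1])
        return support
    support.v, support.c = float(beta[0]), float(beta[1])
    support.au = float(1.0 - stats.norm.cdf(support.v - support.c))
    support.p_value = float(stats.norm.cdf(support.v - support.c))
    return support


@dataclass
class FunctionalModule:
    """A significant, size-bounded, densely connected gene module."""

    genes: frozenset
    p_value: float
    density: float
    mean_effect: float
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    def to_row(self, module_id: int) -> dict:
        return {
            "module": module_id,
            "genes": ",".join(sorted(self.genes)),
            "n_genes": len(self.genes),
            "p_value": self.p_value,
            "density": self.density,
            "mean_effect": self.mean_effect,
            "parent": self.parent if self.parent is not None else "",
        }


def filter_modules(
    supports: list[ClusterSupport],
    pan: PAN,
    p_max: float = 0.05,
    min_size: int = 5,
    max_frac: float = 0.5,
    density_min: float = 0.5,
    effect_sign: str = "any",
) -> list[FunctionalModule]:
    """Apply the four independent module filters and nest the survivors.

    Keep clusters that are (1) significant (p < p_max), (2) neither tiny
    nor spanning more than ``max_frac`` of the screen, (3) densely
    connected in the PAN (density >= density_min), and (4) matching the
    phenotype sign of interest.  Surviving modules are linked by set
    inclusion (children point at their smallest enclosing survivor).
    """
    if min_size < 2:
        raise ConfigurationError("min_size must be >= 2")
    if effect_sign not in ("any", "positive", "negative"):
        raise ConfigurationError("effect_sign must be 'any', 'positive' or 'negative'")
    n_total = len(pan.nodes)
    max_size = int(max_frac * n_total)
    survivors: list[FunctionalModule] = []
    for sup in supports:
        genes = sup.members
        if not (np.isfinite(sup.p_value) and sup.p_value < p_max):
            continue
        if not (min_size <= len(genes) <= max_size):
            continue
        dens = density(genes, pan)
        if dens < density_min:
            continue
        effect = pan.mean_phenotype(genes)
        if effect_sign == "positive" and not effect > 0:
            continue
        if effect_sign == "negative" and not effect < 0:
            continue
        survivors.append(
            FunctionalModule(genes=genes, p_value=sup.p_value, density=dens, mean_effect=effect)
        )
    # nest by set inclusion: parent = smallest strictly-enclosing survivor
    order = sorted(range(len(survivors)), key=lambda i: len(survivors[i].genes))
    for pos, i in enumerate(order):
        gi = survivors[i].genes
        best, best_size = None, None
        for j in order[pos + 1 :]:
            gj = survivors[j].genes
            if gi < gj and (best_size is None or len(gj) < best_size):
                best, best_size = j, len(gj)
        survivors[i].parent = best
        if best is not None:
            survivors[best].children.append(i)
    return survivors


def modules_frame(modules: list[FunctionalModule]) -> pd.DataFrame:
    return pd.DataFrame(
        [m.to_row(i) for i, m in enumerate(modules)],
        columns=["module", "genes", "n_genes", "p_value", "density", "mean_effect", "parent"],
    )
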