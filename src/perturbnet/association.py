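"""Association profiling: cosine similarity, its beta-support transform,
and the permutation null.

The association score between two perturbed genes is the cosine similarity
(uncentered correlation) of their phenotype vectors.  Scores are mapped
from [-1, 1] to the beta support [0, 1] by a' = (cc + 1)/2 before mixture
modelling.  The no-association (null) component is fixed by permuting the
screen, refitting a single beta distribution to the permuted scores, and
taking coordinate-wise medians of the fitted shapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._betafit import fit_beta_ml
from .errors import ValidationError
from .screens import PriorNetwork, ScreenMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationSet",
    "NullBeta",
    "cosine_matrix",
    "transform_scores",
    "inverse_transform_scores",
    "permute_screen",
    "fit_null",
    "null_pvalue",
]

CLIP_DELTA = 1e-6  # keeps transformed scores off the beta-support boundary


def transform_scores(cc: np.ndarray) -> np.ndarray:
    """Linear bijection [-1, 1] -> [0, 1]."""
    return (np.asarray(cc, dtype=float) + 1.0) / 2.0


def inverse_transform_scores(a: np.ndarray) -> np.ndarray:
    return 2.0 * np.asarray(a, dtype=float) - 1.0


class AssociationSet:
    """All unordered gene pairs with raw and transformed association scores.

    Pairs are stored in canonical (i < j) row-major order of the gene list.
    ``stratum`` holds an integer label per pair (0..K-1); with no prior it
    is all zeros and the stratified model degenerates to the global one.
    """

    def __init__(self, genes: list[str], cc: np.ndarray, stratum: np.ndarray | None = None):
        self.genes = list(genes)
        n = len(self.genes)
        self.i_idx, self.j_idx = np.triu_indices(n, k=1)
        cc = np.asarray(cc, dtype=float)
        if cc.shape != self.i_idx.shape:
            raise ValidationError(
                f"expected {self.i_idx.size} pair scores for {n} genes, got {cc.size}"
            )
        if np.any(np.abs(cc) > 1 + 1e-12):
            raise ValidationError("cosine similarities must lie in [-1, 1]")
        self.cc = np.clip(cc, -1.0, 1.0)
        if stratum is None:
            stratum = np.zeros(self.cc.size, dtype=int)
        self.stratum = np.asarray(stratum, dtype=int)
        if self.stratum.shape != self.cc.shape:
            raise ValidationError("stratum labels must align with pairs")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_pairs(self) -> int:
        return self.cc.size

    @property
    def a(self) -> np.ndarray:
        """Transformed scores on the beta support."""
        return transform_scores(self.cc)

    @property
    def n_strata(self) -> int:
        return int(self.stratum.max()) + 1 if self.n_pairs else 1

    def pairs(self) -> list[tuple[str, str]]:
        return [(self.genes[i], self.genes[j]) for i, j in zip(self.i_idx, self.j_idx)]

    def pair_membership(self, prior: PriorNetwork) -> np.ndarray:
        """Boolean mask of pairs present in a prior network."""
        mask = np.zeros(self.n_pairs, dtype=bool)
        for k, (i, j) in enumerate(zip(self.i_idx, self.j_idx)):
            mask[k] = (self.genes[i], self.genes[j]) in prior
        return mask

    def set_strata_from_prior(self, prior: PriorNetwork) -> None:
        """Stratum 1 = pairs with prior evidence, stratum 0 = the rest.

        An empty prior leaves a single stratum (the global model).
        """
        mask = self.pair_membership(prior)
        self.stratum = mask.astype(int)
        if not mask.any():
            logger.info("prior has no pairs among screened genes; single stratum kept")

    def square_cc(self) -> np.ndarray:
        """Full symmetric similarity matrix with unit diagonal."""
        n = self.n_genes
        mat = np.eye(n)
        mat[self.i_idx, self.j_idx] = self.cc
        mat[self.j_idx, self.i_idx] = self.cc
        return mat

    def to_frame(self) -> pd.DataFrame:
        g = np.asarray(self.genes)
        return pd.DataFrame(
            {
                "gene1": g[self.i_idx],
                "gene2": g[self.j_idx],
                "cosine": self.cc,
                "transformed": self.a,
                "stratum": self.stratum,
            }
        )


@dataclass
class NullBeta:
    """Shapes of the fixed no-association beta component.

    (alpha0, beta0) are the coordinate-wise medians of per-permutation
    maximum-likelihood fits.
    """

    alpha0: float
    beta0: float
    n_perm: int = 0
    per_perm_shapes: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise ValidationError("null beta shapes must be positive")


def cosine_matrix(screen: ScreenMatrix) -> AssociationSet:
    """Cosine similarity of every unordered gene pair's phenotype profile."""
    x = screen.values
    if x.shape[1] < 2:
        raise ValidationError("need >=2 replicate columns for association profiling")
    norms = np.linalg.norm(x, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(
            f"gene {screen.genes[zero[0]]!r} has an all-zero phenotype profile"
        )
    xn = x / norms[:, None]
    cc_full = np.clip(xn @ xn.T, -1.0, 1.0)
    iu, ju = np.triu_indices(screen.n_genes, k=1)
    return AssociationSet(screen.genes, cc_full[iu, ju])


def permute_screen(
    screen: ScreenMatrix,
    n_perm: int,
    seed: int | np.random.Generator | None = None,
    mode: str = "within_condition",
) -> list[ScreenMatrix]:
    """Generate permuted screens that destroy cross-gene association.

    Modes
    -----
    within_condition
        For each condition block, one random permutation of genes is
        applied to the whole block, re-matching gene rows to other genes'
        replicate sub-rows while keeping a condition's replicates together.
        Requires >=2 condition blocks to actually break associations
        (with one block it is a pure relabelling of genes).
    whole_row
        A single permutation re-assigns entire rows (all conditions at
        once); a pure gene relabelling, kept for diagnostic comparisons.
    per_column
        Every replicate column is shuffled independently across genes;
        the appropriate null for single-condition screens.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if mode not in ("within_condition", "whole_row", "per_column"):
        raise ValidationError(f"unknown permutation mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = screen.n_genes
    out = []
    for _ in range(n_perm):
        vals = screen.values.copy()
        if mode == "within_condition":
            for cond in screen.conditions:
                cols = screen.condition_columns(cond)
                perm = rng.permutation(n)
                vals[:, cols] = vals[np.ix_(perm, cols)]
        elif mode == "whole_row":
            vals = vals[rng.permutation(n), :]
        else:  # per_column
            for col in range(vals.shape[1]):
                vals[:, col] = vals[rng.permutation(n), col]
        out.append(ScreenMatrix(screen.genes, vals, screen.replicate_map))
    return out


def fit_null(perms: list[ScreenMatrix], tol: float = 1e-8) -> NullBeta:
    """Fit the no-association beta component from permuted screens.

    One beta is fitted per permutation by maximum likelihood on the
    transformed cosine similarities; the component is fixed at the
    coordinate-wise medians of the fitted shape pairs.
    """
    if not perms:
        raise ValidationError("need at least one permuted screen")
    shapes = []
    for k, perm in enumerate(perms):
        scores = np.clip(cosine_matrix(perm).a, CLIP_DELTA, 1 - CLIP_DELTA)
        a, b, ok = fit_beta_ml(scores, tol=tol)
        if not ok:
            logger.warning("null fit did not converge on permutation %d; skipped", k)
            continue
        shapes.append((a, b))
    if not shapes:
        raise ValidationError("beta fit failed on every permutation")
    arr = np.asarray(shapes)
    return NullBeta(
        alpha0=float(np.median(arr[:, 0])),
        beta0=float(np.median(arr[:, 1])),
        n_perm=len(shapes),
        per_perm_shapes=[(float(a), float(b)) for a, b in shapes],
    )


def null_pvalue(score: float | np.ndarray, null: NullBeta) -> float | np.ndarray:
    """Two-sided tail probability of a transformed score under the null beta."""
    score = np.asarray(score, dtype=float)
    if np.any((score < 0) | (score > 1)):
        raise ValidationError("transformed scores must lie in [0, 1]")
    cdf = stats.beta.cdf(score, null.alpha0, null.beta0)
    p = np.minimum(2.0 * np.minimum(cdf, 1.0 - cdf), 1.0)
    p = np.maximum(p, np.finfo(float).tiny)
    return float(p) if p.ndim == 0 else p
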