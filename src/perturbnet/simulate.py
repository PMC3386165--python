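"""Synthetic perturbation screens with planted module structure.

The generator plants two interacting modules among N genes: a group G+
with positive perturbation effects, a group G- with negative effects, and
a background group G0 with random effects.  A "signal" correlation matrix
(+1 within G+ and G-, -1 between them, 0 elsewhere) is blended with a
random correlation matrix R as C = (1 - eps) * S + eps * R, where eps is
the proportion of noise.  Gene means and standard deviations are drawn
from configurable surrogate distributions, C is scaled to a covariance
matrix, and replicate screens are drawn from the multivariate normal.

The gold standard labels within- and cross-module pairs as true edges and
every pair touching G0 as a non-edge; prediction quality is summarised by
the rank-based AUC of the posterior-odds ranking against this standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import cosine_matrix, fit_null, permute_screen
from .errors import ValidationError
from .mixture import fit_map
from .screens import PriorNetwork, ScreenMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "GoldStandard",
    "make_signal",
    "random_correlation",
    "make_correlation",
    "sample_screen",
    "make_prior",
    "auc",
    "simulate_auc",
    "run_grid",
    "calibrate_noise",
]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic screen.

    Defaults are the reference design: 100 genes split 30/30/40 into
    G+/G-/G0.  ``mean_model`` holds (location, scale) pairs, one per group
    in G+/G-/G0 order, of the normal whose absolute value gives a gene's
    mean-effect *magnitude*; the sign is + for G+, - for G-, and random
    for G0 (background genes show positive or negative loss of function at
    random).  Gene standard deviations are |Normal(sd_model)|.  All groups
    share one magnitude distribution by default: because association is
    measured by the uncentered cosine, any group-specific magnitude would
    by itself separate planted edges from background pairs, and a
    pure-noise correlation matrix must carry no edge information at all
    (baseline AUC 1/2).  These distributions are surrogates for the
    empirical means/sds of a real plate-standardised screen.
    """

    n_genes: int = 100
    sizes: tuple[int, int, int] = (30, 30, 40)
    noise: float = 0.5
    n_rep: int = 8
    mean_model: tuple[tuple[float, float], ...] = ((1.5, 0.5), (1.5, 0.5), (1.5, 0.5))
    sd_model: tuple[float, float] = (1.0, 0.25)
    seed: int | None = None

    def __post_init__(self) -> None:
        if sum(self.sizes) != self.n_genes:
            raise ValidationError("group sizes must sum to n_genes")
        if not 0.0 <= self.noise <= 1.0:
            raise ValidationError("noise proportion must lie in [0, 1]")
        if self.n_rep < 2:
            raise ValidationError("need at least 2 replicates")
        if len(self.mean_model) != 3:
            raise ValidationError("mean_model needs one (loc, scale) pair per group")

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def groups(self) -> np.ndarray:
        """Per-gene group code: +1 (G+), -1 (G-), 0 (G0)."""
        n_pos, n_neg, n_rand = self.sizes
        return np.concatenate(
            [np.ones(n_pos), -np.ones(n_neg), np.zeros(n_rand)]
        ).astype(int)


@dataclass
class GoldStandard:
    """Planted truth: associated pairs versus pairs touching G0."""

    genes: list[str]
    groups: np.ndarray
    include_cross_module: bool = True
    _labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = self.groups
        iu, ju = np.triu_indices(len(self.genes), k=1)
        both = (g[iu] != 0) & (g[ju] != 0)
        if self.include_cross_module:
            self._labels = both
        else:
            self._labels = both & (g[iu] == g[ju])

    def edge_labels(self) -> np.ndarray:
        """True/false per pair in canonical (i < j) row-major order."""
        return self._labels.copy()

    @property
    def n_true(self) -> int:
        return int(self._labels.sum())

    @property
    def n_non(self) -> int:
        return int((~self._labels).sum())

    def true_pairs(self) -> set[tuple[str, str]]:
        iu, ju = np.triu_indices(len(self.genes), k=1)
        g = np.asarray(self.genes)
        return {
            (g[i], g[j]) for i, j in zip(iu[self._labels], ju[self._labels])
        }

    def non_pairs(self) -> set[tuple[str, str]]:
        iu, ju = np.triu_indices(len(self.genes), k=1)
        g = np.asarray(self.genes)
        keep = ~self._labels
        return {(g[i], g[j]) for i, j in zip(iu[keep], ju[keep])}


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_signal(spec: SimulationSpec) -> np.ndarray:
    """Signal correlation matrix: +1 within G+/G-, -1 across, 0 at G0."""
    g = spec.groups
    s = np.outer(g, g).astype(float)
    np.fill_diagonal(s, 1.0)
    return s


def random_correlation(
    n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Random correlation matrix R = W W' with rows of W uniform on the sphere.

    The Marsaglia-Olkin construction: each row of W is a standard normal
    vector scaled to unit length, giving a symmetric PSD matrix with unit
    diagonal and off-diagonal entries that concentrate near 0 as n grows.
    """
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = _as_rng(seed)
    w = rng.standard_normal((n, n))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    r = w @ w.T
    np.fill_diagonal(r, 1.0)
    return r


def make_correlation(
    spec: SimulationSpec, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Blend of signal and noise: C = (1 - eps) * S + eps * R."""
    rng = _as_rng(seed if seed is not None else spec.seed)
    c = (1.0 - spec.noise) * make_signal(spec) + spec.noise * random_correlation(
        spec.n_genes, rng
    )
    min_eig = float(np.linalg.eigvalsh(c).min())
    if min_eig < -1e-10:
        # convex combinations of PSD matrices are PSD; this is a numerical guard
        logger.info("correlation matrix repaired (min eigenvalue %.3e)", min_eig)
        vals, vecs = np.linalg.eigh(c)
        c = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
    return c


def sample_screen(
    spec: SimulationSpec,
    correlation: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[ScreenMatrix, GoldStandard]:
    """Draw a replicate screen from the planted-module normal model."""
    rng = _as_rng(seed if seed is not None else spec.seed)
    if correlation is None:
        correlation = make_correlation(spec, rng)
    g = spec.groups
    means = np.empty(spec.n_genes)
    for code, (loc, scale) in zip((1, -1, 0), spec.mean_model):
        mask = g == code
        magnitude = np.abs(rng.normal(loc, scale, size=mask.sum()))
        if code == 1:
            sign = 1.0
        elif code == -1:
            sign = -1.0
        else:  # background genes: positive or negative effect at random
            sign = rng.choice([-1.0, 1.0], size=mask.sum())
        means[mask] = sign * magnitude
    sds = np.abs(rng.normal(spec.sd_model[0], spec.sd_model[1], size=spec.n_genes))
    sds = np.maximum(sds, 0.05)
    cov = correlation * np.outer(sds, sds)
    draws = rng.multivariate_normal(
        means, cov, size=spec.n_rep, check_valid="ignore", method="eigh"
    )
    screen = ScreenMatrix(
        spec.genes,
        draws.T,
        [("sim", r + 1) for r in range(spec.n_rep)],
    )
    return screen, GoldStandard(spec.genes, g)


def make_prior(
    gold: GoldStandard,
    fpr: float,
    fnr: float,
    seed: int | np.random.Generator | None = None,
) -> PriorNetwork:
    """Corrupt the gold standard into a prior interaction list.

    Exactly round(fnr * |true|) true edges are removed (false negatives)
    and round(fpr * |non|) non-edges added (false positives), sampled
    uniformly without replacement.
    """
    if not (0.0 <= fpr <= 1.0 and 0.0 <= fnr <= 1.0):
        raise ValidationError("fpr and fnr must lie in [0, 1]")
    rng = _as_rng(seed)
    true_pairs = sorted(gold.true_pairs())
    non_pairs = sorted(gold.non_pairs())
    n_remove = int(round(fnr * len(true_pairs)))
    n_add = int(round(fpr * len(non_pairs)))
    keep_idx = rng.choice(len(true_pairs), size=len(true_pairs) - n_remove, replace=False)
    add_idx = rng.choice(len(non_pairs), size=n_add, replace=False)
    pairs = {true_pairs[i] for i in keep_idx} | {non_pairs[i] for i in add_idx}
    return PriorNetwork(pairs=pairs, source_label=f"simulated fpr={fpr:g} fnr={fnr:g}")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random true edge outranks random non-edge), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("gold standard needs both true edges and non-edges")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def simulate_auc(
    spec: SimulationSpec,
    seed: int | np.random.Generator | None = None,
    model: str = "global",
    fpr: float = 0.0,
    fnr: float = 0.0,
    gamma_scale: float = 0.0,
    n_perm: int = 5,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> float:
    """One simulation -> pipeline -> AUC against the planted gold standard.

    ``model='stratified'`` corrupts the gold standard into a prior with
    the given error rates and fits stratum-specific mixture coefficients.
    """
    rng = _as_rng(seed if seed is not None else spec.seed)
    screen, gold = sample_screen(spec, seed=rng)
    assoc = cosine_matrix(screen)
    if model == "stratified":
        prior = make_prior(gold, fpr, fnr, rng)
        assoc.set_strata_from_prior(prior)
    elif model != "global":
        raise ValidationError(f"unknown model {model!r}")
    perms = permute_screen(screen, n_perm, rng, mode="per_column")
    null = fit_null(perms)
    results = fit_map(assoc, null, gamma_scale=gamma_scale, tol=tol, max_iter=max_iter)
    return auc(results.snr(), gold.edge_labels())


def run_grid(
    rep_range=(2, 4, 8),
    noise_range=(0.25, 0.5, 0.75, 1.0),
    n_sims: int = 20,
    seed: int | None = None,
    model: str = "global",
    fpr: float = 0.0,
    fnr: float = 0.0,
    base_spec: SimulationSpec | None = None,
    n_perm: int = 5,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> pd.DataFrame:
    """Mean/sd AUC over a (replicates x noise) grid of simulated screens.

    Every cell averages ``n_sims`` independent seeded simulations through
    the full pipeline (simulate, cosine, permutation null, mixture fit,
    posterior odds, AUC).  Fit failures are counted, not fatal.
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    base = base_spec or SimulationSpec()
    master = np.random.SeedSequence(seed)
    rows = []
    for n_rep in rep_range:
        for eps in noise_range:
            spec = SimulationSpec(
                n_genes=base.n_genes,
                sizes=base.sizes,
                noise=eps,
                n_rep=int(n_rep),
                mean_model=base.mean_model,
                sd_model=base.sd_model,
            )
            aucs, n_fail = [], 0
            for child in master.spawn(n_sims):
                try:
                    aucs.append(
                        simulate_auc(
                            spec,
                            seed=np.random.default_rng(child),
                            model=model,
                            fpr=fpr,
                            fnr=fnr,
                            n_perm=n_perm,
                            tol=tol,
                            max_iter=max_iter,
                        )
                    )
                except (ValidationError, np.linalg.LinAlgError) as exc:
                    logger.warning("simulation failed (n_rep=%s, eps=%s): %s", n_rep, eps, exc)
                    n_fail += 1
            rows.append(
                {
                    "n_rep": int(n_rep),
                    "noise": float(eps),
                    "model": model,
                    "mean_auc": float(np.mean(aucs)) if aucs else float("nan"),
                    "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                    "n_sims": len(aucs),
                    "n_fail": n_fail,
                }
            )
    return pd.DataFrame(rows)


def calibrate_noise(
    target_auc: float = 0.65,
    noise_grid=(0.6, 0.7, 0.8, 0.85, 0.9, 0.95),
    n_rep: int = 8,
    n_sims: int = 10,
    seed: int | None = None,
    base_spec: SimulationSpec | None = None,
    **pipeline_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Noise proportion at which the global model attains a target mean AUC.

    Mean AUC is measured on a grid of noise values and the target is
    located by linear interpolation between the bracketing grid points
    (AUC decreases in noise); if the target lies outside the measured
    range, the nearest endpoint is returned.
    """
    table = run_grid(
        rep_range=(n_rep,),
        noise_range=noise_grid,
        n_sims=n_sims,
        seed=seed,
        model="global",
        base_spec=base_spec,
        **pipeline_kwargs,
    ).sort_values("noise", ignore_index=True)
    eps = table["noise"].to_numpy()
    mean_auc = table["mean_auc"].to_numpy()
    if target_auc >= mean_auc.max():
        return float(eps[int(np.argmax(mean_auc))]), table
    if target_auc <= mean_auc.min():
        return float(eps[int(np.argmin(mean_auc))]), table
    for i in range(len(eps) - 1):
        hi, lo = mean_auc[i], mean_auc[i + 1]
        if (hi - target_auc) * (lo - target_auc) <= 0 and hi != lo:
            frac = (hi - target_auc) / (hi - lo)
            return float(eps[i] + frac * (eps[i + 1] - eps[i])), table
    # non-monotone grid: fall back to the closest measured point
    return float(eps[int(np.argmin(np.abs(mean_auc - target_auc)))]), table
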