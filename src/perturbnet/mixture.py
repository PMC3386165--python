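"""Three-component beta-mixture model of association scores.

Transformed association scores a in (0, 1) are modelled as a mixture of
three beta densities representing negative association (x-), lack of
association (x0) and positive association (x+).  The x0 component is fixed
from a permutation null (see :mod:`perturbnet.association`); the other two
components and the mixture coefficients are estimated by an EM algorithm.

Pairs may be partitioned into strata (e.g. with / without prior evidence
of a protein-protein interaction); each stratum k carries its own mixture
coefficients pi_k while the three component densities are shared.  A
Dirichlet prior with hyperparameters gamma_km regularises the coefficients
(maximum a posteriori estimation); gamma identically 1 recovers plain
maximum likelihood.

The user-facing surface mirrors statsmodels: build a
:class:`BetaMixtureModel` from data, call :meth:`~BetaMixtureModel.fit`,
and read estimates off the returned :class:`BetaMixtureResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from ._betafit import beta_mom, fit_beta_suffstats
from .association import CLIP_DELTA, AssociationSet, NullBeta
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "COMPONENTS",
    "BetaMixtureModel",
    "BetaMixtureResults",
    "FitTrace",
    "MixtureParams",
    "fit_map",
    "snr",
]

#: Component order used everywhere: negative, none (null), positive.
COMPONENTS = ("neg", "null", "pos")
_NEG, _NULL, _POS = 0, 1, 2

SNR_CAP = 1e12  # posterior odds reported when the null responsibility is 0
_PI_FLOOR = 1e-8


@dataclass
class MixtureParams:
    """Current parameter state: 3 beta shape pairs and K x 3 coefficients."""

    shapes: np.ndarray  # (3, 2) rows (alpha_m, beta_m) in COMPONENTS order
    pi: np.ndarray  # (K, 3) rows on the simplex

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.shapes.shape != (3, 2) or np.any(self.shapes <= 0):
            raise ValidationError("shapes must be a positive (3, 2) array")
        if self.pi.ndim != 2 or self.pi.shape[1] != 3:
            raise ValidationError("pi must be (K, 3)")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("each pi row must sum to 1")

    def component_means(self) -> np.ndarray:
        return self.shapes[:, 0] / self.shapes.sum(axis=1)

    def copy(self) -> "MixtureParams":
        return MixtureParams(self.shapes.copy(), self.pi.copy())


@dataclass
class FitTrace:
    """Per-iteration log-posterior values of an EM run."""

    objective_path: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return max(len(self.objective_path) - 1, 0)


def make_gamma(
    gamma_scale: float,
    prior_weights: np.ndarray,
    decomposition: str = "shifted",
) -> np.ndarray:
    """Dirichlet hyperparameters from a scale and normalised prior weights.

    ``shifted`` (default): gamma_km = 1 + scale * (p_km - 1/3), so a zero
    scale or uniform weights give gamma = 1 everywhere and the MAP update
    degenerates to maximum likelihood.  The scale must lie in [0, 3) to
    keep every gamma positive.  ``scaled``: gamma = scale * p (requires
    scale * min(p) > 0).
    """
    p = np.asarray(prior_weights, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ConfigurationError("prior_weights must be a (K, 3) array")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ConfigurationError("each prior_weights row must be a distribution")
    if decomposition == "shifted":
        if not 0 <= gamma_scale < 3:
            raise ConfigurationError("gamma_scale must be in [0, 3) for 'shifted'")
        gamma = 1.0 + gamma_scale * (p - 1.0 / 3.0)
    elif decomposition == "scaled":
        if gamma_scale <= 0:
            raise ConfigurationError("gamma_scale must be > 0 for 'scaled'")
        gamma = gamma_scale * p
        if np.any(gamma <= 0):
            raise ConfigurationError("scaled decomposition needs strictly positive weights")
    else:
        raise ConfigurationError(f"unknown decomposition {decomposition!r}")
    return gamma


class BetaMixtureModel:
    """Beta-mixture model of one screen's transformed association scores.

    Parameters
    ----------
    assoc
        Association set; its ``stratum`` labels define the K strata.
    null
        Fixed shapes of the no-association component (permutation null).
        Pass ``null_fixed=False`` to let EM update this component too.
    gamma_scale, prior_weights, decomposition
        Dirichlet regularisation of the mixture coefficients.  Defaults
        (scale 0, uniform weights) give gamma = 1, i.e. plain ML.
    """

    def __init__(
        self,
        assoc: AssociationSet,
        null: NullBeta,
        gamma_scale: float = 0.0,
        prior_weights: np.ndarray | None = None,
        decomposition: str = "shifted",
        null_fixed: bool = True,
    ) -> None:
        self.assoc = assoc
        self.null = null
        self.scores = np.clip(assoc.a, CLIP_DELTA, 1 - CLIP_DELTA)
        self.strata = assoc.stratum
        self.K = assoc.n_strata
        self.null_fixed = bool(null_fixed)
        if prior_weights is None:
            prior_weights = np.full((self.K, 3), 1.0 / 3.0)
        prior_weights = np.asarray(prior_weights, dtype=float)
        if prior_weights.shape[0] != self.K:
            raise ConfigurationError(
                f"prior_weights has {prior_weights.shape[0]} rows for {self.K} strata"
            )
        self.prior_weights = prior_weights
        self.gamma_scale = float(gamma_scale)
        self.gamma = make_gamma(self.gamma_scale, prior_weights, decomposition)
        self.stratum_sizes = np.bincount(self.strata, minlength=self.K).astype(float)
        # sufficient-statistic ingredients reused by every M-step
        self._log_a = np.log(self.scores)
        self._log_1ma = np.log1p(-self.scores)

    # ------------------------------------------------------------------ EM

    def initial_params(self) -> MixtureParams:
        """Moment-based start: x-/x+ from the lower/upper score terciles."""
        lo, hi = np.quantile(self.scores, [1.0 / 3.0, 2.0 / 3.0])
        lower = self.scores[self.scores <= lo]
        upper = self.scores[self.scores >= hi]
        shapes = np.empty((3, 2))
        shapes[_NEG] = beta_mom(lower.mean(), lower.var())
        shapes[_NULL] = (self.null.alpha0, self.null.beta0)
        shapes[_POS] = beta_mom(upper.mean(), upper.var())
        # guarantee the required mean ordering mean(x-) < mean(x0) < mean(x+)
        if shapes[_NEG, 0] / shapes[_NEG].sum() >= 0.5:
            shapes[_NEG] = (1.0, 2.0)
        if shapes[_POS, 0] / shapes[_POS].sum() <= 0.5:
            shapes[_POS] = (2.0, 1.0)
        pi = np.full((self.K, 3), 1.0 / 3.0)
        return MixtureParams(shapes, pi)

    def _log_density(self, params: MixtureParams) -> np.ndarray:
        """(n, 3) matrix of component log densities at the scores."""
        return stats.beta.logpdf(
            self.scores[:, None], params.shapes[None, :, 0], params.shapes[None, :, 1]
        )

    def e_step(self, params: MixtureParams) -> np.ndarray:
        """Responsibilities z_ijm by Bayes' rule, computed in log space."""
        logw = self._log_density(params) + np.log(params.pi)[self.strata]
        logz = logw - logsumexp(logw, axis=1, keepdims=True)
        return np.exp(logz)

    def m_step(self, params: MixtureParams, resp: np.ndarray) -> MixtureParams:
        """MAP update of mixture coefficients and free component shapes."""
        zk = np.zeros((self.K, 3))
        np.add.at(zk, self.strata, resp)
        numer = zk + self.gamma - 1.0
        denom = self.stratum_sizes[:, None] + self.gamma.sum(axis=1, keepdims=True) - 3.0
        pi = numer / denom
        if np.any(pi <= 0):
            logger.warning(
                "a mixture-coefficient update was <= 0 before clamping "
                "(Dirichlet prior too weak for the stratum size)"
            )
            pi = np.clip(pi, _PI_FLOOR, 1.0)
        pi = np.clip(pi, _PI_FLOOR, 1.0)
        pi = pi / pi.sum(axis=1, keepdims=True)

        shapes = params.shapes.copy()
        free = (_NEG, _POS) if self.null_fixed else (_NEG, _NULL, _POS)
        for m in free:
            w = resp[:, m]
            wsum = w.sum()
            if wsum <= 1e-12:
                continue  # component currently empty; leave its shapes alone
            mlx = float(w @ self._log_a / wsum)
            ml1x = float(w @ self._log_1ma / wsum)
            a, b, _ = fit_beta_suffstats(mlx, ml1x, tuple(shapes[m]), max_iter=100)
            shapes[m] = (a, b)
        # identifiability: keep x- left of x+ (label swap prevents switching)
        if shapes[_NEG, 0] / shapes[_NEG].sum() > shapes[_POS, 0] / shapes[_POS].sum():
            shapes[[_NEG, _POS]] = shapes[[_POS, _NEG]]
            pi[:, [_NEG, _POS]] = pi[:, [_POS, _NEG]]
        return MixtureParams(shapes, pi)

    def log_posterior(self, params: MixtureParams) -> float:
        """Observed-data log-likelihood plus the Dirichlet log-prior term.

        The constant Dirichlet normaliser is omitted, so with gamma = 1
        this equals the log-likelihood exactly.
        """
        logw = self._log_density(params) + np.log(params.pi)[self.strata]
        loglik = float(logsumexp(logw, axis=1).sum())
        prior = float(((self.gamma - 1.0) * np.log(params.pi)).sum())
        return loglik + prior

    def fit(
        self,
        tol: float = 1e-6,
        max_iter: int = 1000,
        start: MixtureParams | None = None,
    ) -> "BetaMixtureResults":
        """Run MAP-EM until the objective changes by less than ``tol``."""
        if np.any(self.stratum_sizes < 10):
            raise ValidationError("every stratum needs >= 10 pairs to be fitted")
        if np.any(self.stratum_sizes < 100):
            logger.warning("a stratum has fewer than 100 pairs; estimates may be noisy")
        params = start.copy() if start is not None else self.initial_params()
        trace = FitTrace()
        obj = self.log_posterior(params)
        trace.objective_path.append(obj)
        for _ in range(max_iter):
            resp = self.e_step(params)
            params = self.m_step(params, resp)
            new_obj = self.log_posterior(params)
            trace.objective_path.append(new_obj)
            if abs(new_obj - obj) < tol:
                trace.converged = True
                obj = new_obj
                break
            obj = new_obj
        if not trace.converged:
            logger.warning("EM did not converge within %d iterations", max_iter)
        resp = self.e_step(params)  # responsibilities at the final parameters
        return BetaMixtureResults(self, params, resp, trace)


class BetaMixtureResults:
    """Fitted beta-mixture: estimates, responsibilities and diagnostics."""

    def __init__(
        self,
        model: BetaMixtureModel,
        params: MixtureParams,
        responsibilities: np.ndarray,
        trace: FitTrace,
    ) -> None:
        self.model = model
        self.params = params
        self.responsibilities = responsibilities
        self.trace = trace

    # ------------------------------------------------------------ estimates

    @property
    def shapes(self) -> np.ndarray:
        return self.params.shapes

    @property
    def pi(self) -> np.ndarray:
        return self.params.pi

    @property
    def converged(self) -> bool:
        return self.trace.converged

    def posterior_probs(self) -> np.ndarray:
        """Per-pair posterior probabilities (P(x-), P(x0), P(x+)).

        Identical to the E-step at the fitted parameters.
        """
        return self.responsibilities

    def snr(self, cap: float = SNR_CAP) -> np.ndarray:
        """Posterior odds of association vs no association per pair."""
        return snr(self.responsibilities, cap=cap)

    def posterior_frame(self) -> pd.DataFrame:
        """Pair table: gene1, gene2, p_neg, p_null, p_pos, snr."""
        frame = self.model.assoc.to_frame()[["gene1", "gene2"]].copy()
        resp = self.responsibilities
        frame["p_neg"] = resp[:, _NEG]
        frame["p_null"] = resp[:, _NULL]
        frame["p_pos"] = resp[:, _POS]
        frame["snr"] = self.snr()
        return frame

    def summary(self) -> str:
        lines = [
            "Beta-mixture model of association scores",
            "=" * 44,
            f"pairs: {self.model.scores.size}   strata: {self.model.K}   "
            f"gamma scale: {self.model.gamma_scale:g}",
            f"EM iterations: {self.trace.iterations}   converged: {self.converged}   "
            f"log-posterior: {self.trace.objective_path[-1]:.4f}",
            "",
            "component   alpha      beta       mean     fixed",
        ]
        means = self.params.component_means()
        for m, name in enumerate(COMPONENTS):
            fixed = self.model.null_fixed and m == _NULL
            lines.append(
                f"{name:<10}  {self.shapes[m, 0]:<9.4f}  {self.shapes[m, 1]:<9.4f}  "
                f"{means[m]:<7.4f}  {'yes' if fixed else 'no'}"
            )
        lines.append("")
        lines.append("stratum     n pairs    pi_neg    pi_null   pi_pos")
        for k in range(self.model.K):
            lines.append(
                f"{k:<10}  {int(self.model.stratum_sizes[k]):<9d}  "
                f"{self.pi[k, 0]:<8.4f}  {self.pi[k, 1]:<8.4f}  {self.pi[k, 2]:<8.4f}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------- plumbing

    def to_dict(self) -> dict:
        return {
            "components": list(COMPONENTS),
            "shapes": self.shapes.tolist(),
            "pi": self.pi.tolist(),
            "gamma": self.model.gamma.tolist(),
            "gamma_scale": self.model.gamma_scale,
            "null_fixed": self.model.null_fixed,
            "trace": {
                "iterations": self.trace.iterations,
                "converged": self.converged,
                "final_objective": self.trace.objective_path[-1],
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def infer_network(self, screen=None, cutoff: float = 10.0, **kwargs):
        """Threshold SNR scores into a signed posterior association network."""
        from .network import infer_pan

        return infer_pan(self.responsibilities, self.model.assoc, screen, cutoff, **kwargs)


def snr(resp: np.ndarray, cap: float = SNR_CAP) -> np.ndarray:
    """Posterior odds K = (P(x-) + P(x+)) / P(x0) per pair.

    A zero null responsibility yields the documented cap instead of inf.
    """
    resp = np.asarray(resp, dtype=float)
    if not np.allclose(resp.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("responsibility rows must sum to 1")
    signal = resp[:, _NEG] + resp[:, _POS]
    noise = resp[:, _NULL]
    if np.any(noise == 0):
        logger.warning("zero null responsibility; posterior odds capped at %g", cap)
    with np.errstate(divide="ignore"):
        out = np.where(noise > 0, signal / np.maximum(noise, np.finfo(float).tiny), cap)
    return np.minimum(out, cap)


def fit_map(
    assoc: AssociationSet,
    null: NullBeta,
    gamma_scale: float = 0.0,
    prior_weights: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    decomposition: str = "shifted",
) -> BetaMixtureResults:
    """One-call MAP-EM fit; see :class:`BetaMixtureModel`."""
    model = BetaMixtureModel(
        assoc,
        null,
        gamma_scale=gamma_scale,
        prior_weights=prior_weights,
        decomposition=decomposition,
    )
    return model.fit(tol=tol, max_iter=max_iter)
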