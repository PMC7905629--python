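"""Scikit-learn style front end for the posterior sampler.

``DirectionalArnasonSchwarz`` follows the estimator protocol (constructor
stores hyperparameters unchanged, ``fit`` learns and sets trailing-
underscore attributes, ``get_params``/``set_params`` support cloning and
grid search), in the spirit of hmmlearn's HMM estimators.  The heavy
lifting lives in :mod:`telemark.inference`; this class wires an
observation matrix, a prior specification and class labels into one
``fit`` call and exposes the posterior summaries as fitted attributes.
"""

from __future__ import annotations

import numpy as np

try:  # sklearn is optional; the estimator degrades to a plain class without it
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:
        def get_params(self, deep=True):
            import inspect

            keys = inspect.signature(self.__init__).parameters
            return {k: getattr(self, k) for k in keys}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self


from .discretize import ObservationMatrix
from .inference import MCMCConfig, dic, run_mcmc, summarize
from .priors import PriorSpec, build_prior_spec


class DirectionalArnasonSchwarz(BaseEstimator):
    """Bayesian multistate mark-recapture model with directional priors.

    Parameters
    ----------
    priors : PriorSpec or None
        Joint prior.  ``None`` builds the default weakly-informative
        prior (flat Dirichlet at the entrances) matching the season and
        class structure of the data at fit time.
    season_of : array-like or None
        0-based season index per occasion (length f+1, index 0 is a
        clamp).  ``None`` treats the whole study as one season.
    n_chains, n_iterations, burn_in, thin, seed
        Sampler settings (see :class:`telemark.inference.MCMCConfig`).

    Attributes
    ----------
    draws_ : PosteriorDraws
    summary_ : Summary
        Medians, equal-tailed 90% intervals, R-hat, class contrasts.
    rhat_max_ : float
    dic_ : dict with keys ``dic``, ``pd``, ``mean_deviance``
    """

    def __init__(
        self,
        priors: PriorSpec | None = None,
        season_of=None,
        n_chains: int = 4,
        n_iterations: int = 2000,
        burn_in: int = 500,
        thin: int = 5,
        seed: int = 0,
    ):
        self.priors = priors
        self.season_of = season_of
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed

    def _resolve(self, X: ObservationMatrix, y):
        if not isinstance(X, ObservationMatrix):
            raise TypeError("X must be an ObservationMatrix (see telemark.discretize)")
        classes = (
            np.zeros(X.n_fish, dtype=np.int64)
            if y is None
            else np.asarray(y, dtype=np.int64)
        )
        if classes.shape != (X.n_fish,):
            raise ValueError("y must provide one class label per fish")
        season_of = (
            np.zeros(X.f + 1, dtype=np.int64)
            if self.season_of is None
            else np.asarray(self.season_of, dtype=np.int64)
        )
        if season_of.shape != (X.f + 1,):
            raise ValueError("season_of must have length f + 1")
        n_classes = int(classes.max()) + 1 if X.n_fish else 1
        n_seasons = int(season_of.max()) + 1
        spec = self.priors or build_prior_spec(n_classes, n_seasons)
        if spec.n_classes != n_classes or spec.n_seasons != n_seasons:
            raise ValueError(
                f"prior is for {spec.n_classes} classes x {spec.n_seasons} seasons, "
                f"data implies {n_classes} x {n_seasons}"
            )
        return classes, season_of, spec

    def fit(self, X: ObservationMatrix, y=None):
        """Sample the posterior given observations ``X`` and class labels ``y``."""
        classes, season_of, spec = self._resolve(X, y)
        config = MCMCConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
        )
        self.draws_ = run_mcmc(X, spec, classes, season_of, config)
        self.summary_ = summarize(self.draws_)
        self.summary_.dic = dic(self.draws_, X, season_of, classes) if X.n_fish else None
        self.dic_ = self.summary_.dic
        self.rhat_max_ = float(self.summary_.table["rhat"].max())
        self._season_of = season_of
        return self

    def score(self, X: ObservationMatrix, y=None):
        """Log marginal likelihood of ``X`` at the posterior-mean parameters."""
        from .model import forward_loglik

        classes, season_of, _ = self._resolve(X, y)
        return float(
            forward_loglik(X, self.draws_.mean_params(), season_of, classes).sum()
        )
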