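"""Joint prior: empirical Dirichlet priors at entrances, flat elsewhere.

At each entrance array the assigned passage counts are treated as draws
from a Multinomial over (move to sound, stay, move to gulf), giving the
empirical-Bayes prior

    (psi^{r4}, psi^{rr}, psi^{r8}) ~ Dirichlet(d^{r4}+1, d^{rr}+1, d^{r8}+1)

per class y and season k.  The stay pseudo-count d^{rr} may be
fractional; the Dirichlet is well defined for any positive reals.  With
no passages in a cell the prior reduces to the flat Dirichlet(1,1,1).

Everywhere else weakly-informative defaults are used: Dirichlet(2,...,2)
on each remaining movement simplex and Beta(2,2) on the sound and gulf
survival probabilities, identical across classes and seasons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

from .direction import DirectionalCounts
from .states import ENTRANCE_STATES, MORTAL_STATES, MOVE_DESTS


@dataclass
class PriorSpec:
    """Dirichlet/Beta prior parameters for every model block.

    ``dirichlet[(origin, y, k)]`` is the concentration vector over
    ``MOVE_DESTS[origin]``; ``beta[(r, y, k)]`` the (a, b) pair of the
    survival prior for r in {4, 8}.
    """

    n_classes: int
    n_seasons: int
    dirichlet: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for (origin, y, k), alpha in self.dirichlet.items():
            alpha = np.asarray(alpha, dtype=float)
            if alpha.shape != (len(MOVE_DESTS[origin]),):
                raise ValueError(
                    f"prior block ({origin},{y},{k}): expected "
                    f"{len(MOVE_DESTS[origin])} concentrations, got {alpha.shape}"
                )
            if not np.all(alpha > 0):
                raise ValueError(f"prior block ({origin},{y},{k}): concentrations must be > 0")
        for (r, y, k), (a, b) in self.beta.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"survival prior ({r},{y},{k}): Beta parameters must be > 0")

    def to_json(self, path) -> None:
        payload = {
            "n_classes": self.n_classes,
            "n_seasons": self.n_seasons,
            "dirichlet": {
                f"{origin},{y},{k}": list(map(float, alpha))
                for (origin, y, k), alpha in self.dirichlet.items()
            },
            "beta": {f"{r},{y},{k}": [float(a), float(b)] for (r, y, k), (a, b) in self.beta.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PriorSpec":
        with open(path) as fh:
            payload = json.load(fh)
        spec = cls(n_classes=payload["n_classes"], n_seasons=payload["n_seasons"])
        for key, alpha in payload["dirichlet"].items():
            origin, y, k = map(int, key.split(","))
            spec.dirichlet[(origin, y, k)] = np.asarray(alpha, dtype=float)
        for key, ab in payload["beta"].items():
            r, y, k = map(int, key.split(","))
            spec.beta[(r, y, k)] = (float(ab[0]), float(ab[1]))
        return spec


def build_entrance_priors(counts: DirectionalCounts) -> dict:
    """Informative Dirichlet parameters at the entrances.

    For entrance state r with destination order (4, r, 8):
    alpha = (d^{r4} + 1, d^{rr} + 1, d^{r8} + 1).
    """
    blocks = {}
    for r in ENTRANCE_STATES:
        for y in range(counts.n_classes):
            for k in range(counts.n_seasons):
                d4 = counts.d4[(r, y, k)]
                d8 = counts.d8[(r, y, k)]
                if d4 < 0 or d8 < 0:
                    raise ValueError(f"negative directional count at ({r},{y},{k})")
                drr = counts.drr(r, y, k)
                blocks[(r, y, k)] = np.array([d4 + 1.0, drr + 1.0, d8 + 1.0])
    return blocks


def build_noninformative_priors(n_classes: int, n_seasons: int) -> tuple[dict, dict]:
    """Default Dirichlet/Beta parameters away from the entrances."""
    dirichlet, beta = {}, {}
    for y in range(n_classes):
        for k in range(n_seasons):
            for origin in (2, 3, 4, 8):
                dirichlet[(origin, y, k)] = np.full(len(MOVE_DESTS[origin]), 2.0)
            for r in MORTAL_STATES:
                beta[(r, y, k)] = (2.0, 2.0)
    return dirichlet, beta


def build_prior_spec(
    n_classes: int, n_seasons: int, counts: DirectionalCounts | None = None
) -> PriorSpec:
    """Assemble the joint prior; entrance blocks are flat without counts."""
    dirichlet, beta = build_noninformative_priors(n_classes, n_seasons)
    if counts is not None:
        dirichlet.update(build_entrance_priors(counts))
    else:
        for r in ENTRANCE_STATES:
            for y in range(n_classes):
                for k in range(n_seasons):
                    dirichlet[(r, y, k)] = np.ones(3)
    spec = PriorSpec(n_classes=n_classes, n_seasons=n_seasons, dirichlet=dirichlet, beta=beta)
    spec.validate()
    return spec


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-8:
        raise ValueError("movement block is off the probability simplex")
    with np.errstate(divide="ignore"):
        core = np.where(alpha == 1.0, 0.0, (alpha - 1.0) * np.log(np.clip(x, 1e-300, None)))
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum() + core.sum())


def _beta_logpdf(x: float, a: float, b: float) -> float:
    if not 0.0 < x < 1.0:
        raise ValueError("survival probability must lie in (0, 1)")
    return float((a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b))


def prior_log_density(params, spec: PriorSpec) -> float:
    """Log joint prior density of a full parameter set.

    The joint prior is the product of the per-block Dirichlet densities
    and the Beta survival densities.
    """
    total = 0.0
    for key, alpha in spec.dirichlet.items():
        total += _dirichlet_logpdf(params.psi[key], alpha)
    for key, (a, b) in spec.beta.items():
        total += _beta_logpdf(params.surv[key], a, b)
    return total
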