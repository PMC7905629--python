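"""Arnason-Schwarz hidden-Markov core: parameters, transitions, likelihood.

Parameters are held per fish class y and season k as movement simplexes
``psi^{r.}`` over the allowed destinations of each live origin state r,
plus survival probabilities ``S^4`` and ``S^8`` for the two states in
which death is possible.  Transition probabilities factor as
``phi^{rs} = S^r psi^{rs}`` with the remaining mass ``1 - S^r`` going to
the absorbing expired state; survival is fixed to 1 at the arrays, where
a live fish is always detected.

The marginal likelihood of an observation matrix is computed by the HMM
forward algorithm.  Emission is deterministic (each state emits exactly
one code), so the forward recursion simply restricts support to the
states feasible for each week's observation.  The recursion is carried
with per-step renormalization and log accumulation to avoid underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from .discretize import ObservationMatrix
from .states import (
    MORTAL_STATES,
    MOVE_DESTS,
    N_STATES,
    SPAWN,
    feasible_mask,
)

_FEASIBLE = feasible_mask()


class InfeasibleSequenceError(ValueError):
    pass


@dataclass
class ModelParams:
    """Movement simplexes and survival probabilities per class and season.

    ``psi[(origin, y, k)]`` is the simplex over ``MOVE_DESTS[origin]``;
    ``surv[(r, y, k)]`` the survival probability for r in {4, 8}.
    """

    n_classes: int
    n_seasons: int
    psi: dict = field(default_factory=dict)
    surv: dict = field(default_factory=dict)

    def validate(self, atol: float = 1e-8) -> None:
        for y in range(self.n_classes):
            for k in range(self.n_seasons):
                for origin, dests in MOVE_DESTS.items():
                    block = np.asarray(self.psi[(origin, y, k)], dtype=float)
                    if block.shape != (len(dests),) or np.any(block < 0):
                        raise ValueError(f"psi block ({origin},{y},{k}) malformed")
                    if abs(block.sum() - 1.0) > atol:
                        raise ValueError(
                            f"psi block ({origin},{y},{k}) does not sum to 1 "
                            f"(sum={block.sum()!r})"
                        )
                for r in MORTAL_STATES:
                    s = self.surv[(r, y, k)]
                    if not 0.0 < s <= 1.0:
                        raise ValueError(f"survival S^{r}_({y},{k}) outside (0, 1]")

    def transition_matrix(self, y: int, k: int) -> np.ndarray:
        """8x8 row-stochastic transition matrix for class y, season k."""
        T = np.zeros((N_STATES, N_STATES))
        T[0, 0] = 1.0  # expired state is absorbing
        for origin, dests in MOVE_DESTS.items():
            block = np.asarray(self.psi[(origin, y, k)], dtype=float)
            s = self.surv.get((origin, y, k), 1.0) if origin in MORTAL_STATES else 1.0
            for dest, p in zip(dests, block):
                T[origin - 1, dest - 1] = s * p
            if origin in MORTAL_STATES:
                T[origin - 1, 0] = 1.0 - s
        return T

    def transition_tensor(self) -> np.ndarray:
        """(n_classes, n_seasons, 8, 8) stack of transition matrices."""
        out = np.empty((self.n_classes, self.n_seasons, N_STATES, N_STATES))
        for y in range(self.n_classes):
            for k in range(self.n_seasons):
                out[y, k] = self.transition_matrix(y, k)
        return out


def build_transition(params: ModelParams, y: int, k: int) -> np.ndarray:
    """Transition matrix for one class/season (validates the psi blocks)."""
    params.validate()
    return params.transition_matrix(y, k)


def forward_loglik(
    obs: ObservationMatrix,
    params: ModelParams,
    season_of: np.ndarray,
    classes: np.ndarray,
    transition_tensor: np.ndarray | None = None,
) -> np.ndarray:
    """Per-fish log marginal likelihood by the forward algorithm.

    ``season_of[j]`` is the 0-based season of occasion j (index 0 is a
    clamp for releases before occasion 1); ``classes[i]`` the class of
    fish i.  Returns -inf for fish whose observation sequence has zero
    probability under the structural-zero graph.
    """
    n, f = obs.n_fish, obs.f
    logp = np.zeros(n)
    if n == 0:
        return logp
    Tm = params.transition_tensor() if transition_tensor is None else transition_tensor
    alpha = np.zeros((n, N_STATES))
    alpha[:, SPAWN - 1] = 1.0  # release on the spawning grounds
    c = obs.release_occasion
    last = obs.last_occasion
    for j in range(1, f + 1):
        active = (c < j) & (j <= last)
        if not active.any():
            continue
        k = int(season_of[j - 1])
        codes_j = obs.codes[active, j].astype(np.int64)
        prev = alpha[active]
        nxt = np.empty_like(prev)
        ys = classes[active]
        for y in np.unique(ys):
            sel = ys == y
            nxt[sel] = prev[sel] @ Tm[y, k]
        nxt *= _FEASIBLE[codes_j]
        norm = nxt.sum(axis=1)
        dead = norm <= 0.0
        idx = np.nonzero(active)[0]
        with np.errstate(divide="ignore"):
            logp[idx] += np.log(norm)
        norm[dead] = 1.0
        alpha[idx] = nxt / norm[:, None]
    return logp


def log_likelihood(
    obs: ObservationMatrix,
    params: ModelParams,
    season_of: np.ndarray,
    classes: np.ndarray,
    strict: bool = True,
) -> float:
    """Total log marginal likelihood over fish.

    An observation sequence with zero probability raises (strict, the
    default, surfacing upstream discretization conflicts) or yields
    -inf with the offending fish recorded.
    """
    per_fish = forward_loglik(obs, params, season_of, classes)
    bad = np.nonzero(~np.isfinite(per_fish))[0]
    if len(bad) and strict:
        tags = [obs.tag_ids[i] for i in bad[:10]]
        raise InfeasibleSequenceError(
            f"zero-probability observation sequence for fish {tags}"
        )
    return float(per_fish.sum())


def covariate_effect(draws_y0: np.ndarray, draws_y1: np.ndarray) -> dict:
    """Posterior of the logit-scale class contrast beta_1.

    Under the logit link logit(p_y) = beta_0 + beta_1 y, the slope is
    recovered draw-by-draw as logit(p_{y=1}) - logit(p_{y=0}).  Returns
    the per-draw contrasts, the equal-tailed 90% interval, and a
    significance flag (interval excludes 0).
    """
    draws_y0 = np.asarray(draws_y0, dtype=float)
    draws_y1 = np.asarray(draws_y1, dtype=float)
    if draws_y0.shape != draws_y1.shape:
        raise ValueError("class draws must have matching shapes")
    beta1 = logit(draws_y1) - logit(draws_y0)
    lo, med, hi = np.percentile(beta1, [5, 50, 95], method="linear")
    return {
        "draws": beta1,
        "median": float(med),
        "ci90": (float(lo), float(hi)),
        "significant": bool(lo > 0 or hi < 0),
    }
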