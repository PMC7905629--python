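"""Posterior computation: FFBS-within-Gibbs, diagnostics, DIC, summaries.

The Dirichlet/Beta priors are conjugate to the complete-data likelihood
(multinomial movement counts, binomial survival counts), so the sampler
alternates two exact steps:

1. *forward-filtering backward-sampling* (FFBS) draws every fish's
   latent weekly state path from its exact conditional distribution
   given the observations and current parameters;
2. a *conjugate update* draws new parameters from
   Dirichlet(alpha + movement counts) and Beta(a + survivors, b + deaths)
   given the complete paths.

Chains are independently seeded from one root seed via numpy
``SeedSequence`` spawning; identical configurations reproduce draws
bit-for-bit.  Convergence is monitored with the classic Gelman-Rubin
potential scale reduction factor and models are compared by DIC computed
from the marginal (latent-states-integrated-out) deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import ObservationMatrix
from .model import ModelParams, covariate_effect, forward_loglik
from .priors import PriorSpec
from .states import MORTAL_STATES, MOVE_DESTS, N_STATES, SPAWN, feasible_mask

_FEASIBLE = feasible_mask()


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults follow the study's production runs."""

    n_chains: int = 4
    n_iterations: int = 200_000
    burn_in: int = 10_000
    thin: int = 25
    seed: int = 0
    strict: bool = True

    def __post_init__(self):
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# parameter vector layout

def param_names(n_classes: int, n_seasons: int) -> list[str]:
    names = []
    for y in range(n_classes):
        for k in range(n_seasons):
            for origin in sorted(MOVE_DESTS):
                for dest in MOVE_DESTS[origin]:
                    names.append(f"psi[{origin}->{dest}|y{y},k{k}]")
            for r in MORTAL_STATES:
                names.append(f"S[{r}|y{y},k{k}]")
    return names


def params_to_vector(params: ModelParams) -> np.ndarray:
    out = []
    for y in range(params.n_classes):
        for k in range(params.n_seasons):
            for origin in sorted(MOVE_DESTS):
                out.extend(params.psi[(origin, y, k)])
            for r in MORTAL_STATES:
                out.append(params.surv[(r, y, k)])
    return np.asarray(out, dtype=float)


def vector_to_params(
    vec: np.ndarray, n_classes: int, n_seasons: int, renormalize: bool = False
) -> ModelParams:
    params = ModelParams(n_classes=n_classes, n_seasons=n_seasons)
    pos = 0
    for y in range(n_classes):
        for k in range(n_seasons):
            for origin in sorted(MOVE_DESTS):
                m = len(MOVE_DESTS[origin])
                block = np.asarray(vec[pos : pos + m], dtype=float)
                if renormalize:
                    block = block / block.sum()
                params.psi[(origin, y, k)] = block
                pos += m
            for r in MORTAL_STATES:
                params.surv[(r, y, k)] = float(np.clip(vec[pos], 1e-12, 1.0))
                pos += 1
    return params


# ---------------------------------------------------------------------------
# FFBS

class _Workspace:
    """Precomputed index structure for repeated FFBS sweeps.

    The active-fish sets, class splits and feasibility masks depend only
    on the data, so they are built once per sampler run; the alpha and
    path buffers are reused across iterations (inactive entries are
    never read).
    """

    def __init__(self, obs, classes, season_of, n_classes):
        n, f = obs.n_fish, obs.f
        self.n, self.f = n, f
        self.tag_ids = obs.tag_ids
        self.season_of = np.asarray(season_of, dtype=np.int64)
        c, last = obs.release_occasion, obs.last_occasion
        self.c, self.last = c, last
        feas_rows = _FEASIBLE[obs.codes.astype(np.int64)]  # (n, f+1, 8)
        self.fwd = []   # per occasion j: list of (y, idx, feas[idx])
        self.term = []  # per occasion j: idx with last == j
        self.mid = []   # per occasion j: list of (y, idx) with c < j < last
        for j in range(f + 1):
            if j == 0:
                self.fwd.append([])
                self.term.append(np.empty(0, dtype=np.int64))
                self.mid.append([])
                continue
            active = (c < j) & (j <= last)
            groups = []
            mids = []
            for y in range(n_classes):
                idx = np.nonzero(active & (classes == y))[0]
                if len(idx):
                    groups.append((y, idx, feas_rows[idx, j]))
                m = np.nonzero((c < j) & (j < last) & (classes == y))[0]
                if len(m):
                    mids.append((y, m))
            self.fwd.append(groups)
            self.term.append(np.nonzero((last == j) & (c < j))[0])
            self.mid.append(mids)
        self.alphas = np.zeros((n, f + 1, N_STATES))
        for i in range(n):
            self.alphas[i, min(c[i], f), SPAWN - 1] = 1.0
        self.Z = np.full((n, f + 1), -1, dtype=np.int8)
        for i in range(n):
            if c[i] <= f:
                self.Z[i, c[i]] = SPAWN - 1


def _forward_ws(ws: _Workspace, Tm):
    """Forward filtering on a workspace; returns per-fish log likelihood."""
    logp = np.zeros(ws.n)
    alphas = ws.alphas
    season_of = ws.season_of
    for j in range(1, ws.f + 1):
        groups = ws.fwd[j]
        if not groups:
            continue
        k = int(season_of[j - 1])
        for y, idx, feas in groups:
            nxt = alphas[idx, j - 1] @ Tm[y, k]
            nxt *= feas
            norm = nxt.sum(axis=1)
            if not np.all(norm > 0.0):
                bad = idx[norm <= 0.0]
                raise InfeasibleFFBSError([ws.tag_ids[int(i)] for i in bad[:10]])
            logp[idx] += np.log(norm)
            alphas[idx, j] = nxt / norm[:, None]
    return logp


def _backward_ws(ws: _Workspace, Tm, rng):
    """Backward sampling on a filtered workspace; fills and returns ws.Z."""
    Z = ws.Z
    alphas = ws.alphas
    season_of = ws.season_of
    for j in range(ws.f, 0, -1):
        idx_t = ws.term[j]
        if len(idx_t):
            Z[idx_t, j] = _categorical_rows(alphas[idx_t, j], rng)
        mids = ws.mid[j]
        if mids:
            k = int(season_of[j])
            for y, idx in mids:
                znext = Z[idx, j + 1].astype(np.int64)
                P = alphas[idx, j] * Tm[y, k][:, znext].T
                Z[idx, j] = _categorical_rows(P, rng)
    return Z


class InfeasibleFFBSError(ValueError):
    def __init__(self, tags):
        self.tags = tags
        super().__init__(f"observation sequence infeasible for fish {tags}")


def _categorical_rows(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row from unnormalized row distributions."""
    cs = np.cumsum(P, axis=1)
    u = rng.random(P.shape[0]) * cs[:, -1]
    return (cs < u[:, None]).sum(axis=1)


def ffbs_all(
    obs: ObservationMatrix,
    params: ModelParams,
    season_of: np.ndarray,
    classes: np.ndarray,
    rng: np.random.Generator,
    transition_tensor: np.ndarray | None = None,
):
    """Draw latent state paths for every fish from the exact conditional.

    Returns ``(Z, logp)`` where ``Z[i, j]`` is the 0-based state index of
    fish i at occasion j (-1 outside the window, release occasion fixed
    to the spawning-ground state) and ``logp`` the per-fish marginal log
    likelihood from the forward pass.
    """
    Tm = params.transition_tensor() if transition_tensor is None else transition_tensor
    classes = np.asarray(classes, dtype=np.int64)
    ws = _Workspace(obs, classes, season_of, params.n_classes)
    logp = _forward_ws(ws, Tm)
    Z = _backward_ws(ws, Tm, rng)
    return Z.copy(), logp


def ffbs_draw(
    obs: ObservationMatrix,
    params: ModelParams,
    season_of: np.ndarray,
    classes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent path draw for a (possibly single-fish) observation matrix,
    returned in 1-based state codes (-1 outside the active window)."""
    Z, _ = ffbs_all(obs, params, season_of, classes, rng)
    out = Z.astype(np.int64)
    out[out >= 0] += 1
    return out


# ---------------------------------------------------------------------------
# conjugate update

def count_transitions(
    Z: np.ndarray, classes: np.ndarray, season_of: np.ndarray, n_classes: int, n_seasons: int
) -> np.ndarray:
    """Complete-data transition counts, shape (n_classes, n_seasons, 8, 8).

    The transition from occasion j to j+1 is binned to the season of
    occasion j.
    """
    counts = np.zeros((n_classes, n_seasons, N_STATES, N_STATES), dtype=np.int64)
    n, fp1 = Z.shape
    if n == 0:
        return counts
    for j in range(1, fp1):
        prev = Z[:, j - 1]
        cur = Z[:, j]
        valid = (prev >= 0) & (cur >= 0)
        if not valid.any():
            continue
        k = int(season_of[j - 1])
        np.add.at(
            counts,
            (classes[valid], k, prev[valid].astype(np.int64), cur[valid].astype(np.int64)),
            1,
        )
    return counts


def _count_ws(ws: _Workspace, Z: np.ndarray, n_classes: int, n_seasons: int) -> np.ndarray:
    """Transition counts via the precomputed active sets (bincount based)."""
    counts = np.zeros((n_classes, n_seasons, N_STATES, N_STATES), dtype=np.int64)
    for j in range(1, ws.f + 1):
        groups = ws.fwd[j]
        if not groups:
            continue
        k = int(ws.season_of[j - 1])
        for y, idx, _ in groups:
            code = Z[idx, j - 1].astype(np.int64) * N_STATES + Z[idx, j]
            counts[y, k] += np.bincount(code, minlength=64).reshape(N_STATES, N_STATES)
    return counts


def gibbs_update(counts: np.ndarray, spec: PriorSpec, rng: np.random.Generator) -> ModelParams:
    """Draw new parameters from their conjugate full conditionals.

    For origins 4 and 8: S ~ Beta(a + survivors, b + deaths) and
    psi ~ Dirichlet(alpha + movement counts among survivors); for the
    other origins psi ~ Dirichlet(alpha + counts).  With zero counts the
    draw is from the prior.
    """
    params = ModelParams(n_classes=spec.n_classes, n_seasons=spec.n_seasons)
    for y in range(spec.n_classes):
        for k in range(spec.n_seasons):
            for origin, dests in MOVE_DESTS.items():
                alpha = np.asarray(spec.dirichlet[(origin, y, k)], dtype=float)
                moves = counts[y, k, origin - 1, [d - 1 for d in dests]]
                params.psi[(origin, y, k)] = rng.dirichlet(alpha + moves)
                if origin in MORTAL_STATES:
                    a, b = spec.beta[(origin, y, k)]
                    deaths = counts[y, k, origin - 1, 0]
                    survivors = moves.sum()
                    params.surv[(origin, y, k)] = rng.beta(a + survivors, b + deaths)
    return params


def gibbs_update_from_paths(
    Z: np.ndarray,
    classes: np.ndarray,
    season_of: np.ndarray,
    spec: PriorSpec,
    rng: np.random.Generator,
) -> ModelParams:
    """Conjugate parameter draw from complete latent paths.

    ``Z`` carries 1-based state codes (as returned by :func:`ffbs_draw`)
    with 0 or -1 marking occasions outside the active window.
    """
    Z0 = np.asarray(Z).astype(np.int64) - 1  # inactive codes become negative
    counts = count_transitions(Z0, classes, season_of, spec.n_classes, spec.n_seasons)
    return gibbs_update(counts, spec, rng)


# ---------------------------------------------------------------------------
# the sampler

@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws per chain, plus per-draw marginal deviance."""

    names: list[str]
    values: np.ndarray    # (n_chains, n_draws, n_params)
    deviance: np.ndarray  # (n_chains, n_draws)
    n_classes: int
    n_seasons: int
    config: MCMCConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def pooled(self) -> np.ndarray:
        return self.values.reshape(-1, self.values.shape[2])

    def column(self, name: str) -> np.ndarray:
        return self.pooled()[:, self.names.index(name)]

    def mean_params(self) -> ModelParams:
        """Posterior-mean plug-in parameters (simplexes mean-then-renormalized)."""
        return vector_to_params(
            self.pooled().mean(axis=0), self.n_classes, self.n_seasons, renormalize=True
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chain in range(self.n_chains):
            for d in range(self.n_draws):
                for p, name in enumerate(self.names):
                    rows.append((chain, d, name, self.values[chain, d, p]))
                rows.append((chain, d, "deviance", self.deviance[chain, d]))
        return pd.DataFrame(rows, columns=["chain", "draw", "parameter", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_classes: int | None = None, n_seasons: int | None = None):
        df = pd.read_csv(path)
        names = [n for n in df["parameter"].unique() if n != "deviance"]
        chains = sorted(df["chain"].unique())
        draws = sorted(df["draw"].unique())
        wide = df.pivot_table(index=["chain", "draw"], columns="parameter", values="value")
        values = np.stack(
            [wide.loc[chain][names].to_numpy() for chain in chains]
        )
        deviance = np.stack([wide.loc[chain]["deviance"].to_numpy() for chain in chains])
        if n_classes is None:
            n_classes = 1 + max(int(n.split("|y")[1].split(",")[0]) for n in names)
        if n_seasons is None:
            n_seasons = 1 + max(int(n.split(",k")[1].rstrip("]")) for n in names)
        return cls(
            names=list(names),
            values=values,
            deviance=deviance,
            n_classes=n_classes,
            n_seasons=n_seasons,
        )


def run_mcmc(
    obs: ObservationMatrix,
    spec: PriorSpec,
    classes: np.ndarray,
    season_of: np.ndarray,
    config: MCMCConfig,
) -> PosteriorDraws:
    """FFBS-within-Gibbs sampler over the full parameter set.

    With an empty fish set the draws are from the joint prior (the
    conjugate update sees zero counts), which is used to validate the
    empirical-prior plumbing.
    """
    spec.validate()
    classes = np.asarray(classes, dtype=np.int64)
    season_of = np.asarray(season_of, dtype=np.int64)
    names = param_names(spec.n_classes, spec.n_seasons)
    n_draws = config.n_draws
    values = np.empty((config.n_chains, n_draws, len(names)))
    deviance = np.empty((config.n_chains, n_draws))
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    zero_counts = np.zeros(
        (spec.n_classes, spec.n_seasons, N_STATES, N_STATES), dtype=np.int64
    )
    ws = _Workspace(obs, classes, season_of, spec.n_classes) if obs.n_fish else None
    for chain in range(config.n_chains):
        rng = np.random.default_rng(children[chain])
        params = gibbs_update(zero_counts, spec, rng)  # init from the prior
        d = 0
        for it in range(1, config.n_iterations + 1):
            if ws is not None:
                Tm = params.transition_tensor()
                _forward_ws(ws, Tm)
                Z = _backward_ws(ws, Tm, rng)
                counts = _count_ws(ws, Z, spec.n_classes, spec.n_seasons)
            else:
                counts = zero_counts
            params = gibbs_update(counts, spec, rng)
            if it > config.burn_in and (it - config.burn_in) % config.thin == 0 and d < n_draws:
                values[chain, d] = params_to_vector(params)
                if ws is not None:
                    deviance[chain, d] = -2.0 * _forward_ws(ws, params.transition_tensor()).sum()
                else:
                    deviance[chain, d] = 0.0
                d += 1
    return PosteriorDraws(
        names=names,
        values=values,
        deviance=deviance,
        n_classes=spec.n_classes,
        n_seasons=spec.n_seasons,
        config=config,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries

def gelman_rubin(values: np.ndarray) -> np.ndarray:
    """Classic (non-rank-normalized) potential scale reduction factor.

    For m chains of n draws each: W is the mean within-chain variance,
    B/n the variance of the chain means, and

        R-hat = sqrt( ((n-1)/n * W + (1 + 1/m) * B/n) / W ).

    Constant chains (W = 0) are reported as 1 by convention, with a
    warning.  ``values`` has shape (m, n) or (m, n, P).
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 2
    if squeeze:
        values = values[:, :, None]
    m, n, _ = values.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin requires at least 10 draws per chain")
    W = values.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = values.mean(axis=1).var(axis=0, ddof=1)
    degenerate = W <= 0.0
    if degenerate.any():
        warnings.warn("constant chains encountered; R-hat reported as 1", RuntimeWarning)
    W_safe = np.where(degenerate, 1.0, W)
    rhat = np.sqrt(((n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n) / W_safe)
    rhat = np.where(degenerate, 1.0, rhat)
    return float(rhat[0]) if squeeze else rhat


def dic(
    draws: PosteriorDraws,
    obs: ObservationMatrix,
    season_of: np.ndarray,
    classes: np.ndarray,
) -> dict:
    """Deviance Information Criterion from the marginal deviance.

    Dbar is the posterior mean deviance; D(theta-bar) the deviance at the
    posterior-mean parameters (simplexes mean-then-renormalized);
    pD = Dbar - D(theta-bar); DIC = Dbar + pD.
    """
    dev = draws.deviance.ravel()
    if not np.all(np.isfinite(dev)):
        raise ValueError("non-finite deviances; cannot compute DIC")
    dbar = float(dev.mean())
    at_mean = -2.0 * forward_loglik(
        obs, draws.mean_params(), np.asarray(season_of), np.asarray(classes)
    ).sum()
    pd_ = dbar - float(at_mean)
    return {"dic": dbar + pd_, "pd": pd_, "mean_deviance": dbar}


@dataclass
class Summary:
    """Posterior medians, equal-tailed 90% intervals and R-hat per parameter."""

    table: pd.DataFrame            # index: parameter; median, lo5, hi95, rhat
    contrasts: pd.DataFrame | None = None  # beta_1 class contrasts (2-class fits)
    dic: dict | None = None

    def to_json(self, path) -> None:
        import json

        payload = {
            "parameters": self.table.reset_index().to_dict(orient="records"),
            "contrasts": None
            if self.contrasts is None
            else self.contrasts.reset_index().to_dict(orient="records"),
            "dic": self.dic,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def summarize(draws: PosteriorDraws) -> Summary:
    """Pooled posterior summaries with per-parameter R-hat.

    When two classes were fitted, logit-scale class contrasts beta_1 are
    derived for every movement and survival parameter.
    """
    pooled = draws.pooled()
    lo, med, hi = np.percentile(pooled, [5, 50, 95], axis=0, method="linear")
    rhat = gelman_rubin(draws.values)
    table = pd.DataFrame(
        {"median": med, "lo5": lo, "hi95": hi, "rhat": rhat},
        index=pd.Index(draws.names, name="parameter"),
    )
    contrasts = None
    if draws.n_classes == 2:
        rows = []
        for name in draws.names:
            if "|y0," in name:
                partner = name.replace("|y0,", "|y1,")
                eff = covariate_effect(draws.column(name), draws.column(partner))
                rows.append(
                    (
                        name.replace("|y0,", "|"),
                        eff["median"],
                        eff["ci90"][0],
                        eff["ci90"][1],
                        eff["significant"],
                    )
                )
        contrasts = pd.DataFrame(
            rows, columns=["parameter", "beta1_median", "beta1_lo5", "beta1_hi95", "significant"]
        ).set_index("parameter")
    return Summary(table=table, contrasts=contrasts)
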