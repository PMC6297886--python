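"""Estimation: Bayesian MCMC with the published prior recipe, a deterministic
MAP/EM fallback, convergence diagnostics and LOO-based fit indices.

Both estimators work on the *pseudo* parameterization with sign-bounded
supports, so every visited state satisfies the ordering constraints by
construction.  Priors are N(0, 20) (sd 20) on each item parameter, truncated
to the constrained support, and a symmetric Dirichlet(2) on the profile
prevalence.

The MCMC sampler is a Metropolis-within-Gibbs scheme on the augmented model:
latent class memberships are drawn exactly, prevalence is drawn from its
conjugate Dirichlet full conditional, and item-parameter scalars are updated
by adaptive random-walk Metropolis against class-by-option sufficient counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .design import (
    ModelKind,
    ParameterIndex,
    ProfileSpace,
    QMatrix,
    WMatrix,
    attribute_subsets,
    build_parameter_index,
    derive_w_matrix,
    effect_vector,
    enumerate_profiles,
)
from .exceptions import ConfigError, DataError
from .models import NaturalItemParams, PseudoItemParams, pseudo_to_natural
from .simulate import ResponseDataset

__all__ = [
    "SamplerConfig",
    "PosteriorSummary",
    "MapResult",
    "FitIndices",
    "fit",
    "fit_map",
    "rhat",
    "multivariate_rhat",
    "elpd_loo",
]

PRIOR_SD = 20.0
DIRICHLET_CONCENTRATION = 2.0


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC recipe: 2 chains of 6,000 iterations each, first 2,000 discarded."""

    chains: int = 2
    iterations: int = 6000
    burnin: int = 2000
    prior_sd: float = PRIOR_SD
    dirichlet_concentration: float = DIRICHLET_CONCENTRATION
    rhat_threshold: float = 1.1
    seed: int = 0
    loglik_thin: int = 5
    max_order: int | None = None

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ConfigError("burnin must be smaller than the total number of iterations")
        if self.chains < 2:
            raise ConfigError("at least two chains are required for convergence diagnostics")
        if self.prior_sd <= 0 or self.dirichlet_concentration <= 0:
            raise ConfigError("prior scales must be positive")


# ---------------------------------------------------------------------------
# Design bundle: everything the estimators precompute once


_BOUNDS_BY_ROLE = {
    "intercept_base": (-np.inf, np.inf),
    "intercept_increment": (-np.inf, 0.0),
    "item_intercept": (-np.inf, np.inf),
    "shared_intercept_base": (-np.inf, np.inf),
    "shared_intercept_increment": (-np.inf, 0.0),
    "main_effect": (0.0, np.inf),
    "interaction": (0.0, np.inf),
    "main_effect_increment": (0.0, np.inf),
    "interaction_increment": (0.0, np.inf),
}

_INIT_BY_ROLE = {
    "intercept_base": 0.0,
    "intercept_increment": -0.5,
    "item_intercept": 0.0,
    "shared_intercept_base": -0.5,
    "shared_intercept_increment": -0.5,
    "main_effect": 1.0,
    "interaction": 0.5,
    "main_effect_increment": 1.0,
    "interaction_increment": 0.5,
}


class _Design:
    """Precomputed structures binding a model kind to a Q-matrix and data."""

    def __init__(
        self,
        kind: ModelKind,
        q: QMatrix,
        options: Sequence[int],
        max_order: int | None = None,
    ) -> None:
        self.kind = kind
        self.q = q
        self.options = tuple(int(m) for m in options)
        self.max_order = q.n_attributes if max_order is None else max_order
        self.terms = attribute_subsets(q.n_attributes, self.max_order)
        self.profile_space: ProfileSpace = enumerate_profiles(q.n_attributes)
        self.w: WMatrix | None = derive_w_matrix(q) if kind is ModelKind.MORDM else None
        self.v_of_item = self.w.item_set if self.w is not None else None
        self.index: ParameterIndex = build_parameter_index(kind, q, self.options, self.max_order, self.w)
        # per-item effect-vector matrix over classes: (C, E)
        self.h = [
            np.array(
                [
                    effect_vector(self.profile_space.profiles[c], q.entries[i], self.max_order)
                    for c in range(self.profile_space.n_classes)
                ]
            )
            for i in range(q.n_items)
        ]
        self.bounds = [_BOUNDS_BY_ROLE[e.role] for e in self.index.entries]
        self.n_params = len(self.index)

    # -- flat vector <-> working containers -------------------------------

    def new_work(self) -> SimpleNamespace:
        n_items, n_terms = self.q.n_items, len(self.terms)
        work = SimpleNamespace(intercepts=None, effects=None, item_intercepts=None, shared_intercepts=None)
        if self.kind in (ModelKind.NRDM, ModelKind.ORDM):
            work.intercepts = [np.zeros(m - 1) for m in self.options]
        if self.kind is ModelKind.NRDM:
            work.effects = [np.zeros((m - 1, n_terms)) for m in self.options]
        else:
            work.effects = [np.zeros(n_terms) for _ in range(n_items)]
        if self.kind is ModelKind.MORDM:
            work.item_intercepts = np.zeros(n_items)
            work.shared_intercepts = [
                np.zeros(self.options[int(self.w.items_in_set(v)[0])] - 1) for v in range(self.w.n_sets)
            ]
        return work

    def set_theta(self, work: SimpleNamespace, theta: np.ndarray) -> None:
        for value, entry in zip(theta, self.index.entries):
            container = getattr(work, entry.container)
            if entry.container == "item_intercepts":
                container[entry.index[0]] = value
            else:
                container[entry.index[0]][entry.index[1:]] = value

    def get_theta(self, work: SimpleNamespace) -> np.ndarray:
        out = np.empty(self.n_params)
        for j, entry in enumerate(self.index.entries):
            container = getattr(work, entry.container)
            if entry.container == "item_intercepts":
                out[j] = container[entry.index[0]]
            else:
                out[j] = container[entry.index[0]][entry.index[1:]]
        return out

    def initial_theta(self) -> np.ndarray:
        return np.array([_INIT_BY_ROLE[e.role] for e in self.index.entries])

    def pseudo_from_theta(self, theta: np.ndarray) -> PseudoItemParams:
        work = self.new_work()
        self.set_theta(work, theta)
        return PseudoItemParams(
            model_kind=self.kind,
            options=self.options,
            effect_terms=self.terms,
            intercepts=work.intercepts,
            effects=work.effects,
            item_intercepts=work.item_intercepts,
            shared_intercepts=work.shared_intercepts,
        )

    def theta_from_pseudo(self, pseudo: PseudoItemParams) -> np.ndarray:
        work = SimpleNamespace(
            intercepts=pseudo.intercepts,
            effects=pseudo.effects,
            item_intercepts=pseudo.item_intercepts,
            shared_intercepts=pseudo.shared_intercepts,
        )
        return self.get_theta(work)

    # -- kernels -----------------------------------------------------------

    def item_log_probs(self, work: SimpleNamespace, i: int) -> np.ndarray:
        """(C, M_i) log P(X_i = m | alpha_c) for one item from pseudo values."""
        m_i = self.options[i]
        n_classes = self.profile_space.n_classes
        eta = np.zeros((n_classes, m_i))
        if self.kind is ModelKind.NRDM:
            nat0 = np.cumsum(work.intercepts[i])
            nat_eff = np.cumsum(work.effects[i], axis=0)
            eta[:, 1:] = nat0[None, :] + self.h[i] @ nat_eff.T
        elif self.kind is ModelKind.ORDM:
            nat0 = np.cumsum(work.intercepts[i])
            drift = self.h[i] @ work.effects[i]
            eta[:, 1:] = np.cumsum(nat0[None, :] + drift[:, None], axis=1)
        else:
            v = int(self.v_of_item[i])
            shared_nat = np.cumsum(work.shared_intercepts[v])
            drift = self.h[i] @ work.effects[i]
            steps = work.item_intercepts[i] + shared_nat[None, :] + drift[:, None]
            eta[:, 1:] = np.cumsum(steps, axis=1)
        return eta - logsumexp(eta, axis=1, keepdims=True)

    def all_log_probs(self, work: SimpleNamespace) -> list[np.ndarray]:
        return [self.item_log_probs(work, i) for i in range(self.q.n_items)]

    def pattern_log_likelihood(self, log_probs: list[np.ndarray], x: np.ndarray) -> np.ndarray:
        """(N, C) class-conditional log-likelihood of each respondent."""
        n, n_classes = x.shape[0], self.profile_space.n_classes
        out = np.zeros((n, n_classes))
        for i in range(self.q.n_items):
            out += log_probs[i][:, x[:, i]].T
        return out


def _log_prior(theta: np.ndarray, sd: float) -> float:
    return float(-0.5 * np.sum((theta / sd) ** 2))


def _check_dataset(responses: ResponseDataset | np.ndarray, options=None) -> ResponseDataset:
    if isinstance(responses, ResponseDataset):
        return responses
    if options is None:
        raise DataError("raw response arrays require explicit per-item option counts")
    return ResponseDataset(responses=np.asarray(responses), options=tuple(options))


def _warn_on_unused_options(data: ResponseDataset) -> None:
    for i, m_i in enumerate(data.options):
        seen = np.unique(data.responses[:, i])
        missing = sorted(set(range(m_i)) - set(int(s) for s in seen))
        if missing:
            warnings.warn(
                f"item {i} ({data.item_ids[i]}): options {missing} never chosen; "
                "estimation proceeds but those parameters are prior-dominated",
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# Deterministic MAP fit via (generalized) EM


@dataclass
class MapResult:
    """Posterior-mode fit: point estimates plus the objective trace."""

    model_kind: ModelKind
    params: NaturalItemParams
    pseudo: PseudoItemParams
    prevalence: np.ndarray
    theta: np.ndarray
    param_names: tuple[str, ...]
    log_posterior: float
    log_likelihood: float
    pointwise_log_likelihood: np.ndarray
    n_iter: int
    converged: bool


def fit_map(
    model_kind: ModelKind | str,
    responses: ResponseDataset,
    q: QMatrix,
    max_order: int | None = None,
    prior_sd: float = PRIOR_SD,
    dirichlet_concentration: float = DIRICHLET_CONCENTRATION,
    tol: float = 1e-6,
    max_iter: int = 500,
    inner_maxiter: int = 30,
) -> MapResult:
    """Deterministic MAP estimation by EM with block-coordinate M-steps.

    The E-step computes posterior class responsibilities; the M-step updates
    the prevalence in closed form (Dirichlet-MAP) and each item-parameter
    block by bounded quasi-Newton ascent of its expected complete-data log
    posterior.  Same likelihood, same constraints and same priors as the MCMC
    path, so it serves as a fast surrogate in recovery studies.
    """
    kind = ModelKind.coerce(model_kind)
    data = _check_dataset(responses)
    _warn_on_unused_options(data)
    design = _Design(kind, q, data.options, max_order)
    x = data.responses
    n, n_classes = x.shape[0], design.profile_space.n_classes

    # parameter blocks: per item, except MORDM where shared intercepts couple
    # all items of an attribute set
    blocks: dict[int, list[int]] = {}
    for j, entry in enumerate(design.index.entries):
        if kind is ModelKind.MORDM:
            key = int(design.v_of_item[entry.items[0]])
        else:
            key = int(entry.items[0])
        blocks.setdefault(key, []).append(j)
    block_items = {
        key: sorted({i for j in idx for i in design.index.entries[j].items})
        for key, idx in blocks.items()
    }

    theta = design.initial_theta()
    work = design.new_work()
    design.set_theta(work, theta)
    log_pi = np.full(n_classes, -np.log(n_classes))
    alpha = dirichlet_concentration

    def objective() -> tuple[float, np.ndarray, np.ndarray]:
        log_probs = design.all_log_probs(work)
        ll_matrix = design.pattern_log_likelihood(log_probs, x)
        joint = ll_matrix + log_pi[None, :]
        pointwise = logsumexp(joint, axis=1)
        resp = np.exp(joint - pointwise[:, None])
        loglik = float(pointwise.sum())
        lp = loglik + _log_prior(theta, prior_sd) + float((alpha - 1) * log_pi.sum())
        return lp, resp, pointwise

    log_post, resp, pointwise = objective()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step: prevalence (closed-form Dirichlet MAP)
        counts = resp.sum(axis=0)
        pi = counts + (alpha - 1.0)
        pi = np.maximum(pi, 1e-12)
        log_pi = np.log(pi / pi.sum())

        # weighted class-by-option counts per item
        weighted = []
        for i in range(design.q.n_items):
            m_i = design.options[i]
            cnt = np.zeros((n_classes, m_i))
            for m in range(m_i):
                sel = x[:, i] == m
                if sel.any():
                    cnt[:, m] = resp[sel].sum(axis=0)
            weighted.append(cnt)

        # M-step: item-parameter blocks
        for key, idx in blocks.items():
            idx_arr = np.array(idx)
            items = block_items[key]

            def neg_q(vals: np.ndarray) -> float:
                theta[idx_arr] = vals
                design.set_theta(work, theta)
                total = 0.0
                for i in items:
                    total += float(np.sum(weighted[i] * design.item_log_probs(work, i)))
                total += _log_prior(vals, prior_sd)
                return -total

            x0 = theta[idx_arr].copy()
            bounds = [design.bounds[j] for j in idx]
            res = minimize(
                neg_q, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": inner_maxiter}
            )
            new_vals = res.x if res.fun <= neg_q(x0) else x0
            theta[idx_arr] = new_vals
            design.set_theta(work, theta)

        new_log_post, resp, pointwise = objective()
        if abs(new_log_post - log_post) < tol * (abs(log_post) + 1.0):
            log_post = new_log_post
            converged = True
            break
        log_post = new_log_post

    pseudo = design.pseudo_from_theta(theta)
    natural = pseudo_to_natural(pseudo, check=False)
    prevalence = np.exp(log_pi)
    prevalence = prevalence / prevalence.sum()
    loglik = float(
        logsumexp(
            design.pattern_log_likelihood(design.all_log_probs(work), x) + log_pi[None, :], axis=1
        ).sum()
    )
    return MapResult(
        model_kind=kind,
        params=natural,
        pseudo=pseudo,
        prevalence=prevalence,
        theta=theta.copy(),
        param_names=design.index.names,
        log_posterior=log_post,
        log_likelihood=loglik,
        pointwise_log_likelihood=pointwise,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class PosteriorSummary:
    """Posterior draws and per-parameter summaries from the MCMC fit."""

    model_kind: ModelKind
    param_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    rhat: np.ndarray
    prevalence_mean: np.ndarray
    prevalence_sd: np.ndarray
    prevalence_rhat: np.ndarray
    params: NaturalItemParams
    pseudo: PseudoItemParams
    theta_draws: np.ndarray = field(repr=False)  # (chains, draws, P)
    prevalence_draws: np.ndarray = field(repr=False)  # (chains, draws, C)
    pointwise_loglik: np.ndarray = field(repr=False)  # (chains, draws_ll, N)
    acceptance: np.ndarray = field(repr=False)
    config: SamplerConfig = field(default_factory=SamplerConfig)

    @property
    def prevalence(self) -> np.ndarray:
        return self.prevalence_mean

    @property
    def converged(self) -> bool:
        return bool(
            (self.rhat < self.config.rhat_threshold).all()
            and (self.prevalence_rhat < self.config.rhat_threshold).all()
        )

    def summary_table(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "parameter": list(self.param_names),
                "mean": self.mean,
                "sd": self.sd,
                "rhat": self.rhat,
            }
        )
        prev = pd.DataFrame(
            {
                "parameter": [f"pi[{c}]" for c in range(self.prevalence_mean.shape[0])],
                "mean": self.prevalence_mean,
                "sd": self.prevalence_sd,
                "rhat": self.prevalence_rhat,
            }
        )
        return pd.concat([rows, prev], ignore_index=True)


def _run_chain(
    design: _Design,
    x: np.ndarray,
    config: SamplerConfig,
    seed_seq: np.random.SeedSequence,
) -> dict:
    rng = np.random.default_rng(seed_seq)
    n, n_classes = x.shape[0], design.profile_space.n_classes
    n_items = design.q.n_items
    n_params = design.n_params
    alpha = config.dirichlet_concentration

    # parameter blocks for joint proposals: per item, with MORDM shared
    # intercepts grouped with the items of their attribute set
    block_map: dict[int, list[int]] = {}
    for j, entry in enumerate(design.index.entries):
        if design.kind is ModelKind.MORDM:
            key = int(design.v_of_item[entry.items[0]])
        else:
            key = int(entry.items[0])
        block_map.setdefault(key, []).append(j)
    blocks = [
        (np.array(idx), tuple(sorted({i for j in idx for i in design.index.entries[j].items})))
        for idx in block_map.values()
    ]

    theta = design.initial_theta() + 0.1 * rng.standard_normal(n_params)
    lo = np.array([b[0] for b in design.bounds])
    hi = np.array([b[1] for b in design.bounds])
    theta = np.clip(theta, np.where(np.isfinite(lo), lo + 0.05, theta), np.where(np.isfinite(hi), hi - 0.05, theta))
    work = design.new_work()
    design.set_theta(work, theta)
    pi = rng.dirichlet(np.full(n_classes, alpha))

    scales = np.full(n_params, 0.25)
    accept_window = np.zeros(n_params)
    window = 0
    accepted_total = np.zeros(n_params)

    log_probs = design.all_log_probs(work)

    # running covariance per block for adaptive joint proposals
    blk_count = 0
    blk_mean = [np.zeros(len(idx)) for idx, _ in blocks]
    blk_m2 = [np.zeros((len(idx), len(idx))) for idx, _ in blocks]
    blk_chol: list[np.ndarray | None] = [None for _ in blocks]
    adapt_start = max(150, config.burnin // 4)

    keep = config.iterations - config.burnin
    theta_draws = np.empty((keep, n_params))
    pi_draws = np.empty((keep, n_classes))
    n_ll = (keep + config.loglik_thin - 1) // config.loglik_thin
    ll_draws = np.empty((n_ll, n))
    ll_pos = 0

    prior_var = config.prior_sd**2

    for it in range(config.iterations):
        # 1) latent classes via Gumbel-max on the joint log weights
        ll_matrix = design.pattern_log_likelihood(log_probs, x)
        with np.errstate(divide="ignore"):
            joint = ll_matrix + np.log(pi)[None, :]
        if it >= config.burnin and (it - config.burnin) % config.loglik_thin == 0:
            ll_draws[ll_pos] = logsumexp(joint, axis=1)
            ll_pos += 1
        gumbel = -np.log(-np.log(rng.random((n, n_classes))))
        z = np.argmax(joint + gumbel, axis=1)

        # 2) prevalence from its conjugate full conditional
        class_counts = np.bincount(z, minlength=n_classes)
        pi = rng.dirichlet(class_counts + alpha)

        # 3) class-by-option sufficient counts
        counts = [
            np.bincount(z * design.options[i] + x[:, i], minlength=n_classes * design.options[i]).reshape(
                n_classes, design.options[i]
            )
            for i in range(n_items)
        ]
        item_ll = np.array([float(np.sum(counts[i] * log_probs[i])) for i in range(n_items)])

        # 4) scalar random-walk Metropolis updates
        noise = rng.standard_normal(n_params)
        log_u = np.log(rng.random(n_params))
        for j in range(n_params):
            proposal = theta[j] + scales[j] * noise[j]
            if proposal < lo[j] or proposal > hi[j]:
                continue
            items = design.index.entries[j].items
            old_val = theta[j]
            theta[j] = proposal
            design.set_theta(work, theta)
            new_probs = {i: design.item_log_probs(work, i) for i in items}
            new_ll = {i: float(np.sum(counts[i] * new_probs[i])) for i in items}
            delta = sum(new_ll[i] - item_ll[i] for i in items)
            delta += (old_val**2 - proposal**2) / (2.0 * prior_var)
            if log_u[j] < delta:
                for i in items:
                    log_probs[i] = new_probs[i]
                    item_ll[i] = new_ll[i]
                accept_window[j] += 1
                accepted_total[j] += 1
            else:
                theta[j] = old_val
                design.set_theta(work, theta)

        # 5) adaptive joint block proposals along the empirical covariance,
        #    which rescues mixing when parameters sit on correlated ridges
        blk_count += 1
        for b, (idx, _) in enumerate(blocks):
            vec = theta[idx]
            delta_mean = vec - blk_mean[b]
            blk_mean[b] += delta_mean / blk_count
            blk_m2[b] += np.outer(delta_mean, vec - blk_mean[b])
        if blk_count > adapt_start:
            if blk_chol[0] is None or it % 100 == 0:
                for b, (idx, _) in enumerate(blocks):
                    d = len(idx)
                    cov = blk_m2[b] / (blk_count - 1) + 1e-8 * np.eye(d)
                    try:
                        blk_chol[b] = np.linalg.cholesky(2.38**2 / d * cov)
                    except np.linalg.LinAlgError:  # pragma: no cover
                        blk_chol[b] = None
            for b, (idx, items) in enumerate(blocks):
                if blk_chol[b] is None:
                    continue
                proposal = theta[idx] + blk_chol[b] @ rng.standard_normal(len(idx))
                if (proposal < lo[idx]).any() or (proposal > hi[idx]).any():
                    continue
                old_vals = theta[idx].copy()
                theta[idx] = proposal
                design.set_theta(work, theta)
                new_probs = {i: design.item_log_probs(work, i) for i in items}
                new_ll = {i: float(np.sum(counts[i] * new_probs[i])) for i in items}
                delta = sum(new_ll[i] - item_ll[i] for i in items)
                delta += float(np.sum(old_vals**2 - proposal**2) / (2.0 * prior_var))
                if np.log(rng.random()) < delta:
                    for i in items:
                        log_probs[i] = new_probs[i]
                        item_ll[i] = new_ll[i]
                else:
                    theta[idx] = old_vals
                    design.set_theta(work, theta)

        window += 1
        if it < config.burnin and window == 50:
            # aggressive early adaptation, annealed over the burn-in so scales
            # can climb to the prior sd for data-starved parameters
            gamma = 1.0 if it < config.burnin // 2 else 0.25
            rate = accept_window / window
            scales *= np.exp(gamma * (rate - 0.44))
            scales = np.clip(scales, 1e-3, 60.0)
            accept_window[:] = 0.0
            window = 0
        elif window == 50:
            accept_window[:] = 0.0
            window = 0

        if it >= config.burnin:
            pos = it - config.burnin
            theta_draws[pos] = theta
            pi_draws[pos] = pi

    return {
        "theta": theta_draws,
        "pi": pi_draws,
        "loglik": ll_draws[:ll_pos],
        "acceptance": accepted_total / config.iterations,
    }


def fit(
    model_kind: ModelKind | str,
    responses: ResponseDataset,
    q: QMatrix,
    config: SamplerConfig | None = None,
) -> PosteriorSummary:
    """Bayesian fit of one model to a response dataset.

    Non-convergence (any split R-hat at or above the threshold) is flagged on
    the summary, never fatal.
    """
    kind = ModelKind.coerce(model_kind)
    config = config or SamplerConfig()
    data = _check_dataset(responses)
    _warn_on_unused_options(data)
    design = _Design(kind, q, data.options, config.max_order)
    x = data.responses

    seeds = np.random.SeedSequence([int(config.seed), 905]).spawn(config.chains)
    chains = [_run_chain(design, x, config, s) for s in seeds]

    theta_draws = np.stack([c["theta"] for c in chains])  # (chains, draws, P)
    pi_draws = np.stack([c["pi"] for c in chains])
    ll_draws = np.stack([c["loglik"] for c in chains])
    acceptance = np.stack([c["acceptance"] for c in chains])

    mean = theta_draws.mean(axis=(0, 1))
    sd = theta_draws.std(axis=(0, 1), ddof=1)
    rhats = np.array([rhat(theta_draws[:, :, j]) for j in range(design.n_params)])
    prev_mean = pi_draws.mean(axis=(0, 1))
    prev_mean = prev_mean / prev_mean.sum()
    prev_sd = pi_draws.std(axis=(0, 1), ddof=1)
    prev_rhat = np.array([rhat(pi_draws[:, :, c]) for c in range(pi_draws.shape[2])])

    pseudo = design.pseudo_from_theta(mean)
    natural = pseudo_to_natural(pseudo, check=False)

    summary = PosteriorSummary(
        model_kind=kind,
        param_names=design.index.names,
        mean=mean,
        sd=sd,
        rhat=rhats,
        prevalence_mean=prev_mean,
        prevalence_sd=prev_sd,
        prevalence_rhat=prev_rhat,
        params=natural,
        pseudo=pseudo,
        theta_draws=theta_draws,
        prevalence_draws=pi_draws,
        pointwise_loglik=ll_draws,
        acceptance=acceptance,
        config=config,
    )
    if not summary.converged:
        warnings.warn(
            "MCMC convergence flagged: some R-hat values exceed "
            f"{config.rhat_threshold}; inspect summary.rhat",
            stacklevel=2,
        )
    return summary


# ---------------------------------------------------------------------------
# Diagnostics


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction statistic for one parameter.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, so the
    statistic also detects within-chain drift.  Degenerate (zero-variance)
    input returns 1.0 by convention.
    """
    draws = np.asarray(chains, dtype=np.float64)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ConfigError("rhat needs a 2-D (n_chains, n_draws) array with >= 2 chains")
    if draws.shape[1] < 4:
        raise ConfigError("rhat needs at least 4 draws per chain")
    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    within = split.var(axis=1, ddof=1).mean()
    between = n * chain_means.var(ddof=1)
    if within <= 1e-300:
        return 1.0
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def multivariate_rhat(draws: np.ndarray) -> float:
    """Brooks-Gelman multivariate potential scale reduction factor.

    ``draws`` is (n_chains, n_draws, n_params).  Offered as an optional
    joint diagnostic; the per-parameter threshold remains operational.
    """
    draws = np.asarray(draws, dtype=np.float64)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ConfigError("multivariate_rhat needs a (n_chains, n_draws, n_params) array")
    m, n, p = draws.shape
    chain_means = draws.mean(axis=1)  # (m, p)
    within = np.zeros((p, p))
    for c in range(m):
        centered = draws[c] - chain_means[c]
        within += centered.T @ centered / (n - 1)
    within /= m
    grand = chain_means.mean(axis=0)
    dev = chain_means - grand
    between = n * (dev.T @ dev) / (m - 1)
    eigvals = np.linalg.eigvals(np.linalg.pinv(within) @ between / n)
    lam = float(np.max(eigvals.real))
    return float(np.sqrt((n - 1) / n + (m + 1) / m * lam))


# ---------------------------------------------------------------------------
# LOO


@dataclass(frozen=True)
class FitIndices:
    """PSIS-LOO expected log predictive density and its IC scale."""

    elpd: float
    elpd_se: float
    looic: float
    looic_se: float
    pointwise: np.ndarray = field(repr=False)
    pareto_k: np.ndarray = field(repr=False)
    warnings: tuple[str, ...] = ()


def elpd_loo(pointwise_loglik: np.ndarray) -> FitIndices:
    """PSIS-LOO from a matrix of pointwise log-likelihood draws.

    Accepts (draws, n_obs) or (chains, draws, n_obs).  LOOIC is exactly
    -2 * ELPD.  Respondents with unstable importance weights (Pareto k > 0.7)
    are reported as warnings.
    """
    ll = np.asarray(pointwise_loglik, dtype=np.float64)
    if ll.ndim == 2:
        ll = ll[None, :, :]
    if ll.ndim != 3:
        raise DataError("pointwise log-likelihood must be 2-D or 3-D")
    if not np.isfinite(ll).all():
        raise DataError("pointwise log-likelihood contains non-finite values")
    n_obs = ll.shape[2]

    spread = ll.max(axis=(0, 1)) - ll.min(axis=(0, 1))
    if np.all(spread < 1e-12):
        # no posterior uncertainty: LOO reduces to the pointwise values
        pointwise = ll[0, 0, :]
        se = float(np.sqrt(n_obs * pointwise.var(ddof=1))) if n_obs > 1 else 0.0
        elpd = float(pointwise.sum())
        return FitIndices(elpd, se, -2 * elpd, 2 * se, pointwise, np.zeros(n_obs))

    import arviz as az

    idata = az.from_dict(
        posterior={"_placeholder": np.zeros(ll.shape[:2])},
        log_likelihood={"obs": ll},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    elpd = float(res.elpd_loo)
    se = float(res.se)
    k = np.asarray(res.pareto_k)
    notes = tuple(
        f"observation {i}: Pareto k = {k[i]:.3f} > 0.7, importance weights unstable"
        for i in np.flatnonzero(k > 0.7)
    )
    return FitIndices(
        elpd=elpd,
        elpd_se=se,
        looic=-2.0 * elpd,
        looic_se=2.0 * se,
        pointwise=np.asarray(res.loo_i),
        pareto_k=k,
        warnings=notes,
    )
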