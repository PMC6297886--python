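"""Parameter-recovery simulation harness.

For each replicate: simulate a dataset from the generating truth, fit the
model (deterministic MAP by default, MCMC optionally), classify respondents,
and aggregate per-parameter bias/RMSE plus per-attribute classification
accuracy descriptives across replicates.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ModelKind, QMatrix, derive_w_matrix
from .estimate import SamplerConfig, _Design, fit, fit_map
from .exceptions import ConfigError
from .models import (
    NaturalItemParams,
    class_conditional_table,
    natural_to_pseudo,
    validate_constraints,
    validate_prevalence,
)
from .score import classify
from .simulate import draw_profiles, draw_responses

__all__ = ["StudyConfig", "RecoveryReport", "bias", "rmse", "accuracy_descriptives", "run_recovery_study"]


def bias(estimates: Sequence[float], truth: float) -> float:
    """Mean of (estimate - truth) across replicates."""
    est = np.asarray(estimates, dtype=np.float64)
    if est.size == 0:
        raise ConfigError("bias needs at least one replicate estimate")
    return float(np.mean(est - truth))


def rmse(estimates: Sequence[float], truth: float, divisor: str = "r_minus_1") -> float:
    """Root of the squared-error sum divided by R-1 (default) or R."""
    est = np.asarray(estimates, dtype=np.float64)
    if divisor not in ("r_minus_1", "r"):
        raise ConfigError("divisor must be 'r_minus_1' or 'r'")
    r = est.size
    if r < 2 and divisor == "r_minus_1":
        raise ConfigError("RMSE with the R-1 divisor needs at least two replicates")
    if r == 0:
        raise ConfigError("rmse needs at least one replicate estimate")
    denom = r - 1 if divisor == "r_minus_1" else r
    return float(np.sqrt(np.sum((est - truth) ** 2) / denom))


def accuracy_descriptives(accuracies: Sequence[float]) -> dict:
    """Min/mean/max/sd (R-1 denominator) of per-replicate accuracies."""
    acc = np.asarray(accuracies, dtype=np.float64)
    if acc.size == 0:
        raise ConfigError("accuracy_descriptives needs at least one replicate")
    sd = float(acc.std(ddof=1)) if acc.size > 1 else 0.0
    return {
        "min": float(acc.min()),
        "mean": float(acc.mean()),
        "max": float(acc.max()),
        "sd": sd,
    }


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one recovery-study arm."""

    model_kind: ModelKind | str
    truth_params: NaturalItemParams
    truth_prevalence: np.ndarray
    q: QMatrix
    n_respondents: int = 500
    replications: int = 100
    estimator: str = "map"  # "map" or "mcmc"
    sampler: SamplerConfig | None = None
    master_seed: int = 0
    rmse_divisor: str = "r_minus_1"
    exclude_nonconverged: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind.coerce(self.model_kind))
        if self.replications < 2:
            raise ConfigError("replications: at least 2 are required (RMSE divides by R-1)")
        if self.n_respondents < 1:
            raise ConfigError("n_respondents must be positive")
        if self.estimator not in ("map", "mcmc"):
            raise ConfigError("estimator must be 'map' or 'mcmc'")
        validate_prevalence(self.truth_prevalence)


@dataclass
class RecoveryReport:
    """Aggregated recovery results across replicates."""

    model_kind: ModelKind
    param_recovery: pd.DataFrame  # parameter, truth, bias, rmse
    prevalence_recovery: pd.DataFrame
    accuracy: pd.DataFrame  # attribute, min, mean, max, sd
    per_replicate: pd.DataFrame = field(repr=False)
    estimates: np.ndarray = field(repr=False)  # (R, P) pseudo-space estimates
    prevalence_estimates: np.ndarray = field(repr=False)  # (R, C)
    converged: np.ndarray = field(repr=False)
    config_summary: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "model": self.model_kind.value,
            "config": self.config_summary,
            "param_recovery": self.param_recovery.to_dict(orient="records"),
            "prevalence_recovery": self.prevalence_recovery.to_dict(orient="records"),
            "accuracy": self.accuracy.to_dict(orient="records"),
            "converged": self.converged.astype(bool).tolist(),
        }


def run_recovery_study(config: StudyConfig) -> RecoveryReport:
    """Simulate-fit-classify over R replicates and aggregate recovery metrics.

    Classification accuracy is the per-replicate agreement between attribute
    calls under the fitted parameters and calls under the generating
    parameters (the published descriptives are on this scale; the generating
    parameters' own Bayes rate against the latent truth is well below it).
    Agreement against the drawn latent profiles is reported alongside as
    ``accuracy_latent``.
    """
    kind = ModelKind.coerce(config.model_kind)
    report = validate_constraints(config.truth_params, q=config.q)
    report.raise_if_failed()
    q = config.q
    w = derive_w_matrix(q) if kind is ModelKind.MORDM else None
    table = class_conditional_table(kind, config.truth_params, q, w)
    pi_truth = validate_prevalence(config.truth_prevalence, table.profile_space.n_classes)
    space = table.profile_space
    n_attr = space.n_attributes

    truth_pseudo = natural_to_pseudo(config.truth_params, check=False)
    design = _Design(kind, q, config.truth_params.options, max_order=None)
    truth_theta = design.theta_from_pseudo(truth_pseudo)
    names = design.index.names

    estimates = np.empty((config.replications, len(names)))
    prevalence_estimates = np.empty((config.replications, space.n_classes))
    realized_prevalence = np.empty((config.replications, space.n_classes))
    accuracies = np.empty((config.replications, n_attr))
    latent_acc = np.empty((config.replications, n_attr))
    converged = np.zeros(config.replications, dtype=bool)
    rows = []

    for r in range(config.replications):
        profile_seed = np.random.SeedSequence([int(config.master_seed), r, 1])
        response_seed = np.random.SeedSequence([int(config.master_seed), r, 2])
        profiles = draw_profiles(pi_truth, config.n_respondents, profile_seed)
        dataset = draw_responses(table, profiles, response_seed, item_ids=q.item_ids)
        realized_prevalence[r] = np.bincount(profiles, minlength=space.n_classes) / profiles.size

        t0 = time.perf_counter()
        if config.estimator == "map":
            result = fit_map(kind, dataset, q)
            estimates[r] = result.theta
            prevalence_estimates[r] = result.prevalence
            fitted_params, fitted_pi = result.params, result.prevalence
            converged[r] = result.converged
        else:
            sampler = config.sampler or SamplerConfig()
            sampler = SamplerConfig(
                chains=sampler.chains,
                iterations=sampler.iterations,
                burnin=sampler.burnin,
                prior_sd=sampler.prior_sd,
                dirichlet_concentration=sampler.dirichlet_concentration,
                rhat_threshold=sampler.rhat_threshold,
                seed=int(np.random.SeedSequence([int(config.master_seed), r, 3]).generate_state(1)[0]),
                loglik_thin=sampler.loglik_thin,
                max_order=sampler.max_order,
            )
            summary = fit(kind, dataset, q, sampler)
            estimates[r] = summary.mean
            prevalence_estimates[r] = summary.prevalence_mean
            fitted_params, fitted_pi = summary.params, summary.prevalence_mean
            converged[r] = summary.converged
        elapsed = time.perf_counter() - t0

        result_cls = classify(dataset.responses, fitted_params, fitted_pi, q, w)
        truth_cls = classify(dataset.responses, config.truth_params, pi_truth, q, w)
        truth_profiles = space.profiles[profiles]
        accuracies[r] = (result_cls.binary_calls == truth_cls.binary_calls).mean(axis=0)
        latent_acc[r] = (result_cls.binary_calls == truth_profiles).mean(axis=0)
        rows.append(
            {
                "replicate": r,
                "converged": bool(converged[r]),
                "fit_seconds": elapsed,
                **{f"accuracy_A{k + 1}": accuracies[r, k] for k in range(n_attr)},
                **{f"accuracy_latent_A{k + 1}": latent_acc[r, k] for k in range(n_attr)},
            }
        )

    keep = converged if config.exclude_nonconverged else np.ones(config.replications, dtype=bool)
    if not keep.any():
        keep = np.ones(config.replications, dtype=bool)

    param_recovery = pd.DataFrame(
        {
            "parameter": list(names),
            "truth": truth_theta,
            "bias": [bias(estimates[keep, j], truth_theta[j]) for j in range(len(names))],
            "rmse": [
                rmse(estimates[keep, j], truth_theta[j], config.rmse_divisor)
                for j in range(len(names))
            ],
        }
    )
    labels = space.labels()
    prevalence_recovery = pd.DataFrame(
        {
            "profile": list(labels),
            "truth": pi_truth,
            "bias": [bias(prevalence_estimates[keep, c], pi_truth[c]) for c in range(space.n_classes)],
            "rmse": [
                rmse(prevalence_estimates[keep, c], pi_truth[c], config.rmse_divisor)
                for c in range(space.n_classes)
            ],
            # comparator against the realized per-replicate class composition
            "bias_vs_realized": [
                float(np.mean(prevalence_estimates[keep, c] - realized_prevalence[keep, c]))
                for c in range(space.n_classes)
            ],
            "rmse_vs_realized": [
                float(
                    np.sqrt(
                        np.sum((prevalence_estimates[keep, c] - realized_prevalence[keep, c]) ** 2)
                        / (max(int(keep.sum()) - 1, 1))
                    )
                )
                for c in range(space.n_classes)
            ],
        }
    )
    acc_rows = []
    for k in range(n_attr):
        row = {"attribute": f"A{k + 1}", **accuracy_descriptives(accuracies[keep, k])}
        row.update(
            {f"latent_{s}": v for s, v in accuracy_descriptives(latent_acc[keep, k]).items()}
        )
        acc_rows.append(row)

    return RecoveryReport(
        model_kind=kind,
        param_recovery=param_recovery,
        prevalence_recovery=prevalence_recovery,
        accuracy=pd.DataFrame(acc_rows),
        per_replicate=pd.DataFrame(rows),
        estimates=estimates,
        prevalence_estimates=prevalence_estimates,
        converged=converged,
        config_summary={
            "model": kind.value,
            "n_respondents": config.n_respondents,
            "replications": config.replications,
            "estimator": config.estimator,
            "master_seed": config.master_seed,
            "rmse_divisor": config.rmse_divisor,
        },
    )
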