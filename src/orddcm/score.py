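"""Respondent classification and between-model comparison.

Classification uses plug-in (point-estimate) parameters by default, producing
per-respondent posterior class probabilities, a MAP profile, marginal
attribute possession probabilities (continuous scores) and thresholded binary
calls.  Comparison utilities cover crosstabs, percent agreement, Cohen's
kappa, RMSD of continuous scores, and response-option curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .design import ModelKind, ProfileSpace, QMatrix, WMatrix, derive_w_matrix, enumerate_profiles
from .exceptions import DataError
from .models import (
    ClassConditionalTable,
    NaturalItemParams,
    class_conditional_table,
    log_likelihood_matrix,
    option_probabilities,
    validate_prevalence,
)

__all__ = [
    "ClassificationResult",
    "AgreementReport",
    "classify",
    "agreement",
    "cohen_kappa",
    "rmsd_scores",
    "response_option_curves",
    "dominant_option_summary",
]


@dataclass
class ClassificationResult:
    """Per-respondent posterior over profiles plus derived scores."""

    profile_space: ProfileSpace
    class_probabilities: np.ndarray  # (N, C)
    map_class: np.ndarray  # (N,)
    marginal_scores: np.ndarray  # (N, K): P(possess attribute k)
    binary_calls: np.ndarray  # (N, K)
    threshold: float = 0.5

    @property
    def map_profiles(self) -> np.ndarray:
        return self.profile_space.profiles[self.map_class]

    def to_frame(self) -> pd.DataFrame:
        labels = self.profile_space.labels()
        data = {f"P{labels[c]}": self.class_probabilities[:, c] for c in range(len(labels))}
        data["map_class"] = self.map_class
        data["map_profile"] = [labels[c] for c in self.map_class]
        for k in range(self.marginal_scores.shape[1]):
            data[f"score_A{k + 1}"] = self.marginal_scores[:, k]
            data[f"call_A{k + 1}"] = self.binary_calls[:, k]
        return pd.DataFrame(data)


def classify(
    responses: np.ndarray,
    params: NaturalItemParams,
    prevalence: Sequence[float],
    q: QMatrix,
    w: WMatrix | None = None,
    threshold: float = 0.5,
    table: ClassConditionalTable | None = None,
) -> ClassificationResult:
    """Posterior profile probabilities, MAP profiles and attribute scores.

    Posterior class probability is proportional to pi_c * prod_i P(x_ei|c);
    MAP ties break to the lowest class index in the canonical profile order.
    """
    if table is None:
        if params.model_kind is ModelKind.MORDM and w is None:
            w = derive_w_matrix(q)
        table = class_conditional_table(params.model_kind, params, q, w)
    space = table.profile_space
    pi = validate_prevalence(prevalence, space.n_classes)
    ll = log_likelihood_matrix(np.asarray(responses), table)
    with np.errstate(divide="ignore"):
        joint = ll + np.log(pi)[None, :]
    norm = logsumexp(joint, axis=1, keepdims=True)
    if not np.isfinite(norm).all():
        raise DataError("a respondent has zero posterior mass in every class")
    probs = np.exp(joint - norm)
    map_class = probs.argmax(axis=1)  # argmax takes the first maximum: lowest index
    marginals = probs @ space.profiles
    return ClassificationResult(
        profile_space=space,
        class_probabilities=probs,
        map_class=map_class,
        marginal_scores=marginals,
        binary_calls=(marginals >= threshold).astype(np.int64),
        threshold=threshold,
    )


@dataclass
class AgreementReport:
    """Crosstab of two classification vectors with agreement statistics."""

    crosstab: np.ndarray
    labels: tuple[str, ...]
    percent_agreement: float
    kappa: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.crosstab, index=list(self.labels), columns=list(self.labels))


def cohen_kappa(crosstab: np.ndarray) -> float:
    """Cohen's kappa from a square crosstab, with marginal-product chance agreement."""
    table = np.asarray(crosstab, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise DataError("crosstab must be square")
    n = table.sum()
    if n <= 0:
        raise DataError("crosstab must contain observations")
    p_obs = np.trace(table) / n
    p_exp = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_exp >= 1.0:
        return 1.0
    return float((p_obs - p_exp) / (1.0 - p_exp))


def agreement(
    calls_a: Sequence[int],
    calls_b: Sequence[int],
    labels: Sequence[str] | None = None,
) -> AgreementReport:
    """Crosstab, percent agreement and Cohen's kappa between two call vectors."""
    a = np.asarray(calls_a, dtype=np.int64)
    b = np.asarray(calls_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("classification vectors must be one-dimensional and of equal length")
    if a.size == 0:
        raise DataError("classification vectors must be nonempty")
    n_cat = int(max(a.max(), b.max())) + 1
    if labels is not None:
        n_cat = max(n_cat, len(labels))
    table = np.zeros((n_cat, n_cat), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    if labels is None:
        labels = tuple(str(c) for c in range(n_cat))
    return AgreementReport(
        crosstab=table,
        labels=tuple(labels),
        percent_agreement=float(np.trace(table) / a.size),
        kappa=cohen_kappa(table),
        n=int(a.size),
    )


def rmsd_scores(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Root-mean-square deviation between two equal-length score vectors."""
    a = np.asarray(scores_a, dtype=np.float64).ravel()
    b = np.asarray(scores_b, dtype=np.float64).ravel()
    if a.size == 0:
        raise DataError("score vectors must be nonempty")
    if a.shape != b.shape:
        raise DataError("score vectors must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def response_option_curves(
    params: NaturalItemParams,
    item: int,
    q: QMatrix,
    w: WMatrix | None = None,
    profile_space: ProfileSpace | None = None,
) -> pd.DataFrame:
    """Long-format table of P(option | profile) for one item.

    Columns: profile label, option, probability.  Suitable for plotting
    option curves; probabilities match :func:`models.option_probabilities`.
    """
    if profile_space is None:
        profile_space = enumerate_profiles(q.n_attributes)
    if params.model_kind is ModelKind.MORDM and w is None:
        w = derive_w_matrix(q)
    rows = []
    labels = profile_space.labels()
    for c in range(profile_space.n_classes):
        p = option_probabilities(params.model_kind, params, item, profile_space.profiles[c], q, w)
        for m, prob in enumerate(p):
            rows.append({"profile": labels[c], "option": m, "probability": float(prob)})
    return pd.DataFrame(rows)


def dominant_option_summary(
    params: NaturalItemParams,
    item: int,
    q: QMatrix,
    w: WMatrix | None = None,
) -> dict:
    """Where the curves cross: per option, whether full mastery of the item's
    attributes beats non-mastery, and the minimum option from which it does."""
    if params.model_kind is ModelKind.MORDM and w is None:
        w = derive_w_matrix(q)
    k = q.n_attributes
    master = q.entries[item].copy()
    none = np.zeros(k, dtype=np.int64)
    p_master = option_probabilities(params.model_kind, params, item, master, q, w)
    p_none = option_probabilities(params.model_kind, params, item, none, q, w)
    higher = p_master > p_none
    crossing = np.flatnonzero(higher)
    return {
        "item": item,
        "higher_for_masters": higher.tolist(),
        "min_dominant_option": int(crossing[0]) if crossing.size else None,
    }
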