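"""Probability kernels for the NRDM, ORDM and MORDM.

All three models are confirmatory latent class models.  Option 0 of every item
is the reference option with all parameters fixed to 0.  The ORDM gives each
item one effect vector entering cumulatively across ordered options
(adjacent-category form); the MORDM further decomposes option intercepts into
an item-general intercept plus option intercepts shared within an attribute
set; the NRDM frees every option's intercept and effects.

Ordering and sign constraints are enforced through the *pseudo*
parameterization: a natural parameter for option m is the option-1 base plus
sign-constrained increments, so monotonicity holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .design import (
    ModelKind,
    ProfileSpace,
    QMatrix,
    WMatrix,
    allowed_effect_mask,
    attribute_subsets,
    derive_w_matrix,
    effect_vector,
    enumerate_profiles,
)
from .exceptions import ConstraintError, DataError, DesignError

__all__ = [
    "NaturalItemParams",
    "PseudoItemParams",
    "ClassConditionalTable",
    "ConstraintCheck",
    "ConstraintReport",
    "pseudo_to_natural",
    "natural_to_pseudo",
    "option_probabilities",
    "class_conditional_table",
    "marginal_log_likelihood",
    "log_likelihood_matrix",
    "validate_constraints",
    "validate_prevalence",
    "ordm_to_nrdm",
    "mordm_to_ordm",
]


def _as_tuple_of_arrays(arrays: Sequence[np.ndarray] | None) -> tuple[np.ndarray, ...] | None:
    if arrays is None:
        return None
    return tuple(np.asarray(a, dtype=np.float64) for a in arrays)


@dataclass(frozen=True)
class _ItemParamsBase:
    model_kind: ModelKind
    options: tuple[int, ...]
    effect_terms: tuple[tuple[int, ...], ...]
    # NRDM/ORDM: per-item arrays of shape (M_i - 1,)
    intercepts: tuple[np.ndarray, ...] | None = None
    # NRDM: per-item (M_i - 1, E); ORDM/MORDM: per-item (E,)
    effects: tuple[np.ndarray, ...] = ()
    # MORDM only
    item_intercepts: np.ndarray | None = None
    shared_intercepts: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind.coerce(self.model_kind))
        object.__setattr__(self, "options", tuple(int(m) for m in self.options))
        object.__setattr__(self, "effect_terms", tuple(tuple(t) for t in self.effect_terms))
        object.__setattr__(self, "intercepts", _as_tuple_of_arrays(self.intercepts))
        object.__setattr__(self, "effects", _as_tuple_of_arrays(self.effects))
        object.__setattr__(self, "shared_intercepts", _as_tuple_of_arrays(self.shared_intercepts))
        if self.item_intercepts is not None:
            object.__setattr__(
                self, "item_intercepts", np.asarray(self.item_intercepts, dtype=np.float64)
            )
        self._check_shapes()

    def _check_shapes(self) -> None:
        kind, n_items = self.model_kind, len(self.options)
        n_terms = len(self.effect_terms)
        if len(self.effects) != n_items:
            raise DesignError("one effect array per item is required")
        if kind in (ModelKind.NRDM, ModelKind.ORDM):
            if self.intercepts is None or len(self.intercepts) != n_items:
                raise DesignError("one intercept array per item is required")
            for i, (arr, m) in enumerate(zip(self.intercepts, self.options)):
                if arr.shape != (m - 1,):
                    raise DesignError(f"item {i}: intercept array must have shape ({m - 1},)")
        if kind is ModelKind.NRDM:
            for i, (arr, m) in enumerate(zip(self.effects, self.options)):
                if arr.shape != (m - 1, n_terms):
                    raise DesignError(f"item {i}: effect array must have shape ({m - 1}, {n_terms})")
        else:
            for i, arr in enumerate(self.effects):
                if arr.shape != (n_terms,):
                    raise DesignError(f"item {i}: effect array must have shape ({n_terms},)")
        if kind is ModelKind.MORDM:
            if self.item_intercepts is None or self.item_intercepts.shape != (n_items,):
                raise DesignError("MORDM requires one item intercept per item")
            if not self.shared_intercepts:
                raise DesignError("MORDM requires shared option intercepts per attribute set")

    @property
    def n_items(self) -> int:
        return len(self.options)

    def to_json_dict(self) -> dict:
        out: dict = {
            "model": self.model_kind.value,
            "options": list(self.options),
            "effect_terms": [list(t) for t in self.effect_terms],
            "effects": [np.asarray(a).tolist() for a in self.effects],
        }
        if self.intercepts is not None:
            out["intercepts"] = [a.tolist() for a in self.intercepts]
        if self.item_intercepts is not None:
            out["item_intercepts"] = self.item_intercepts.tolist()
        if self.shared_intercepts is not None:
            out["shared_intercepts"] = [a.tolist() for a in self.shared_intercepts]
        return out

    @classmethod
    def from_json_dict(cls, data: dict) -> "_ItemParamsBase":
        return cls(
            model_kind=ModelKind.coerce(data["model"]),
            options=tuple(data["options"]),
            effect_terms=tuple(tuple(t) for t in data["effect_terms"]),
            intercepts=[np.asarray(a) for a in data["intercepts"]] if "intercepts" in data else None,
            effects=[np.asarray(a) for a in data["effects"]],
            item_intercepts=np.asarray(data["item_intercepts"]) if "item_intercepts" in data else None,
            shared_intercepts=[np.asarray(a) for a in data["shared_intercepts"]]
            if "shared_intercepts" in data
            else None,
        )


@dataclass(frozen=True)
class NaturalItemParams(_ItemParamsBase):
    """Item parameters in natural form (the values entering the kernels)."""


@dataclass(frozen=True)
class PseudoItemParams(_ItemParamsBase):
    """Item parameters in pseudo form: option-1 base plus per-option increments.

    Intercept increments must be <= 0 and effect increments >= 0, so the
    cumulative sums satisfy the natural-form ordering constraints by
    construction.  For ORDM/MORDM effects (no option index) pseudo and natural
    values coincide.
    """


def _cum_along_m(arr: np.ndarray) -> np.ndarray:
    return np.cumsum(arr, axis=0)


def _diff_along_m(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[1:] = np.diff(arr, axis=0)
    return out


def pseudo_to_natural(pseudo: PseudoItemParams, check: bool = True) -> NaturalItemParams:
    """Cumulate base + increments into natural parameters.

    With ``check`` the pseudo sign constraints are verified first, so the
    resulting natural parameters satisfy their ordering invariants by
    construction.
    """
    if check:
        report = validate_constraints(pseudo)
        report.raise_if_failed()
    kind = pseudo.model_kind
    intercepts = None
    if pseudo.intercepts is not None:
        intercepts = tuple(_cum_along_m(a) for a in pseudo.intercepts)
    if kind is ModelKind.NRDM:
        effects = tuple(_cum_along_m(a) for a in pseudo.effects)
    else:
        effects = tuple(a.copy() for a in pseudo.effects)
    shared = None
    if pseudo.shared_intercepts is not None:
        shared = tuple(_cum_along_m(a) for a in pseudo.shared_intercepts)
    return NaturalItemParams(
        model_kind=kind,
        options=pseudo.options,
        effect_terms=pseudo.effect_terms,
        intercepts=intercepts,
        effects=effects,
        item_intercepts=None if pseudo.item_intercepts is None else pseudo.item_intercepts.copy(),
        shared_intercepts=shared,
    )


def natural_to_pseudo(natural: NaturalItemParams, check: bool = True) -> PseudoItemParams:
    """Invert :func:`pseudo_to_natural` via successive differences along m."""
    if check:
        report = validate_constraints(natural)
        report.raise_if_failed()
    kind = natural.model_kind
    intercepts = None
    if natural.intercepts is not None:
        intercepts = tuple(_diff_along_m(a) for a in natural.intercepts)
    if kind is ModelKind.NRDM:
        effects = tuple(_diff_along_m(a) for a in natural.effects)
    else:
        effects = tuple(a.copy() for a in natural.effects)
    shared = None
    if natural.shared_intercepts is not None:
        shared = tuple(_diff_along_m(a) for a in natural.shared_intercepts)
    return PseudoItemParams(
        model_kind=kind,
        options=natural.options,
        effect_terms=natural.effect_terms,
        intercepts=intercepts,
        effects=effects,
        item_intercepts=None if natural.item_intercepts is None else natural.item_intercepts.copy(),
        shared_intercepts=shared,
    )


# ---------------------------------------------------------------------------
# Constraint validation


@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    passed: bool
    violations: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConstraintReport:
    checks: tuple[ConstraintCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def raise_if_failed(self) -> None:
        if not self.ok:
            detail = "; ".join(
                f"{c.name}: {', '.join(c.violations)}" for c in self.checks if not c.passed
            )
            raise ConstraintError(f"parameter constraints violated -- {detail}")

    def __iter__(self):
        return iter(self.checks)


def _term_masks(params: _ItemParamsBase, q: QMatrix | None) -> list[np.ndarray]:
    """Per-item boolean masks over effect terms: which coefficients are free.

    Without a Q-matrix every term is treated as free, which is the right
    default for the non-strict check (structural zeros pass a >= 0 test).
    """
    n_terms = len(params.effect_terms)
    if q is None:
        return [np.ones(n_terms, dtype=bool)] * params.n_items
    masks = []
    for i in range(params.n_items):
        row = q.entries[i]
        masks.append(np.array([all(row[list(t)] == 1) for t in params.effect_terms], dtype=bool))
    return masks


def _effect_sign_violations(
    params: _ItemParamsBase, strict: bool, tol: float, masks: list[np.ndarray]
) -> list[str]:
    bad = []
    lo = tol if strict else -tol
    for i, arr in enumerate(params.effects):
        flat = np.atleast_2d(arr)
        ok = (flat >= lo) | ~masks[i][None, :]
        for idx in zip(*np.nonzero(~ok)):
            bad.append(f"item {i}, effect index {tuple(int(j) for j in idx)} = {flat[idx]:.6g}")
    return bad


def validate_constraints(
    params: _ItemParamsBase,
    strict: bool = False,
    tol: float = 1e-12,
    q: QMatrix | None = None,
) -> ConstraintReport:
    """Check the ordering/sign constraint families of a parameter set.

    Works on both natural and pseudo forms: for pseudo parameters the
    intercept constraint is "increments <= 0" and for natural parameters
    "nonincreasing in m" (the same condition after cumulation).  ``strict``
    demands strictly positive effects instead of nonnegative.
    """
    checks: list[ConstraintCheck] = []
    is_pseudo = isinstance(params, PseudoItemParams)
    kind = params.model_kind
    masks = _term_masks(params, q)

    if params.intercepts is not None:
        bad = []
        for i, arr in enumerate(params.intercepts):
            inc = arr[1:] if is_pseudo else np.diff(arr)
            for j in np.flatnonzero(~(inc <= tol)):
                bad.append(f"item {i}, option {j + 2}: increment {inc[j]:.6g} > 0")
        checks.append(
            ConstraintCheck("intercepts nonincreasing in option", not bad, tuple(bad))
        )

    if params.shared_intercepts is not None:
        bad = []
        for v, arr in enumerate(params.shared_intercepts):
            inc = arr[1:] if is_pseudo else np.diff(arr)
            for j in np.flatnonzero(~(inc <= tol)):
                bad.append(f"set {v}, option {j + 2}: increment {inc[j]:.6g} > 0")
        checks.append(
            ConstraintCheck("shared intercepts nonincreasing in option", not bad, tuple(bad))
        )

    if kind is ModelKind.NRDM:
        # ordered-NRDM estimation constraints: per-term effects nonnegative and
        # nondecreasing in the option index
        bad = []
        lo = tol if strict else -tol
        for i, arr in enumerate(params.effects):
            base = arr[0]
            inc = arr[1:] if is_pseudo else np.diff(arr, axis=0)
            for j in np.flatnonzero(~((base >= lo) | ~masks[i])):
                bad.append(f"item {i}, term {j}, option 1: {base[j]:.6g} < 0")
            for idx in zip(*np.nonzero(~((inc >= -tol) | ~masks[i][None, :]))):
                bad.append(f"item {i}, increment index {tuple(int(x) for x in idx)}: {inc[idx]:.6g} < 0")
        checks.append(ConstraintCheck("effects nonnegative and nondecreasing", not bad, tuple(bad)))
    else:
        bad = _effect_sign_violations(params, strict, tol, masks)
        label = "strictly positive" if strict else "nonnegative"
        checks.append(ConstraintCheck(f"effects {label}", not bad, tuple(bad)))

    return ConstraintReport(tuple(checks))


def validate_prevalence(prevalence: Sequence[float], n_classes: int | None = None) -> np.ndarray:
    pi = np.asarray(prevalence, dtype=np.float64)
    if pi.ndim != 1:
        raise DataError("prevalence must be a one-dimensional probability vector")
    if n_classes is not None and pi.shape[0] != n_classes:
        raise DataError(f"prevalence has {pi.shape[0]} entries, expected {n_classes}")
    if (pi < 0).any():
        raise DataError("prevalence entries must be nonnegative")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise DataError(f"prevalence must sum to 1 (got {pi.sum():.10f})")
    return pi


# ---------------------------------------------------------------------------
# Kernels


def _linear_predictors(
    params: NaturalItemParams,
    item: int,
    h: np.ndarray,
    w: WMatrix | None,
) -> np.ndarray:
    """Per-option linear predictors eta_m, m = 0..M_i-1, with eta_0 = 0."""
    kind = params.model_kind
    m_i = params.options[item]
    eta = np.zeros(m_i)
    if kind is ModelKind.NRDM:
        eta[1:] = params.intercepts[item] + params.effects[item] @ h
    elif kind is ModelKind.ORDM:
        steps = params.intercepts[item] + float(params.effects[item] @ h)
        eta[1:] = np.cumsum(steps)
    else:  # MORDM
        if w is None:
            raise DesignError("MORDM probabilities require the W-matrix")
        v = int(w.item_set[item])
        steps = (
            params.item_intercepts[item]
            + params.shared_intercepts[v]
            + float(params.effects[item] @ h)
        )
        eta[1:] = np.cumsum(steps)
    return eta


def _softmax(eta: np.ndarray) -> np.ndarray:
    # max-subtraction keeps exponentials finite for predictors of order +-20
    z = np.exp(eta - eta.max())
    return z / z.sum()


def option_probabilities(
    model_kind: ModelKind | str,
    params: NaturalItemParams,
    item: int,
    profile: Sequence[int],
    q: QMatrix,
    w: WMatrix | None = None,
) -> np.ndarray:
    """P(X_i = m | profile) for all options m of one item."""
    kind = ModelKind.coerce(model_kind)
    if kind is not params.model_kind:
        raise DesignError(f"params are for {params.model_kind.value}, requested {kind.value}")
    profile = np.asarray(profile, dtype=np.int64)
    if profile.shape[0] != q.n_attributes:
        raise DesignError(
            f"profile length {profile.shape[0]} does not match {q.n_attributes} attributes"
        )
    if not 0 <= item < q.n_items:
        raise DesignError(f"item index {item} outside design with {q.n_items} items")
    if kind is ModelKind.MORDM and w is None:
        w = derive_w_matrix(q)
    max_order = max((len(t) for t in params.effect_terms), default=1)
    h = effect_vector(profile, q.entries[item], max_order)
    return _softmax(_linear_predictors(params, item, h, w))


@dataclass(frozen=True)
class ClassConditionalTable:
    """items x classes x options array of P(X_i = m | alpha_c).

    ``probs`` is padded with zeros beyond each item's option count.
    """

    probs: np.ndarray
    options: tuple[int, ...]
    profile_space: ProfileSpace

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", probs)
        n_items, n_classes = len(self.options), self.profile_space.n_classes
        if probs.shape[:2] != (n_items, n_classes):
            raise DesignError("table shape inconsistent with design")

    @property
    def n_items(self) -> int:
        return len(self.options)

    def slice(self, item: int, class_index: int) -> np.ndarray:
        return self.probs[item, class_index, : self.options[item]]


def class_conditional_table(
    model_kind: ModelKind | str,
    params: NaturalItemParams,
    q: QMatrix,
    w: WMatrix | None = None,
    profile_space: ProfileSpace | None = None,
) -> ClassConditionalTable:
    """Evaluate :func:`option_probabilities` over every (item, class) pair."""
    kind = ModelKind.coerce(model_kind)
    if profile_space is None:
        profile_space = enumerate_profiles(q.n_attributes)
    if kind is ModelKind.MORDM and w is None:
        w = derive_w_matrix(q)
    m_max = max(params.options)
    probs = np.zeros((q.n_items, profile_space.n_classes, m_max))
    for i in range(q.n_items):
        for c in range(profile_space.n_classes):
            p = option_probabilities(kind, params, i, profile_space.profiles[c], q, w)
            probs[i, c, : params.options[i]] = p
    return ClassConditionalTable(probs=probs, options=params.options, profile_space=profile_space)


def log_likelihood_matrix(responses: np.ndarray, table: ClassConditionalTable) -> np.ndarray:
    """(N, C) matrix of log P(x_e | alpha_c), the class-conditional pattern log-likelihoods."""
    x = np.asarray(responses)
    if x.ndim != 2 or x.shape[1] != table.n_items:
        raise DataError(f"responses must be (N, {table.n_items})")
    for i, m_i in enumerate(table.options):
        bad = np.flatnonzero((x[:, i] < 0) | (x[:, i] >= m_i))
        if bad.size:
            raise DataError(
                f"respondent {int(bad[0])}, item {i}: code {int(x[bad[0], i])} outside 0..{m_i - 1}"
            )
    n, n_classes = x.shape[0], table.profile_space.n_classes
    out = np.zeros((n, n_classes))
    with np.errstate(divide="ignore"):
        log_probs = np.log(table.probs)
    for i in range(table.n_items):
        out += log_probs[i, :, x[:, i]]  # (N, C) via fancy indexing on the option axis
    return out


def marginal_log_likelihood(
    responses: np.ndarray,
    table: ClassConditionalTable,
    prevalence: Sequence[float],
) -> tuple[float, np.ndarray]:
    """Latent-class marginal log-likelihood.

    Returns the total and the per-respondent pointwise vector
    log sum_c pi_c prod_i P(x_ei | alpha_c), the quantity LOO needs.
    """
    pi = validate_prevalence(prevalence, table.profile_space.n_classes)
    ll = log_likelihood_matrix(responses, table)
    with np.errstate(divide="ignore"):
        pointwise = logsumexp(ll + np.log(pi), axis=1)
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# Nesting maps (used by tests and by model comparison utilities)


def ordm_to_nrdm(params: NaturalItemParams) -> NaturalItemParams:
    """Express ORDM parameters in NRDM form (identical probabilities).

    lambda0^N_{i,m} = sum_{j<=m} lambda0^O_{i,j};  lambda^N_{i,m} = m * lambda^O_i.
    """
    if params.model_kind is not ModelKind.ORDM:
        raise DesignError("expected ORDM parameters")
    intercepts = tuple(np.cumsum(a) for a in params.intercepts)
    effects = []
    for i, m_i in enumerate(params.options):
        mults = np.arange(1, m_i)[:, None]
        effects.append(mults * params.effects[i][None, :])
    return NaturalItemParams(
        model_kind=ModelKind.NRDM,
        options=params.options,
        effect_terms=params.effect_terms,
        intercepts=intercepts,
        effects=tuple(effects),
    )


def mordm_to_ordm(params: NaturalItemParams, w: WMatrix) -> NaturalItemParams:
    """Express MORDM parameters in ORDM form (identical probabilities).

    lambda0^O_{i,m} = lambda0_i + lambda0^{v(i)}_m.
    """
    if params.model_kind is not ModelKind.MORDM:
        raise DesignError("expected MORDM parameters")
    intercepts = []
    for i in range(params.n_items):
        v = int(w.item_set[i])
        intercepts.append(params.item_intercepts[i] + params.shared_intercepts[v])
    return NaturalItemParams(
        model_kind=ModelKind.ORDM,
        options=params.options,
        effect_terms=params.effect_terms,
        intercepts=tuple(intercepts),
        effects=tuple(a.copy() for a in params.effects),
    )
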