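"""Measurement design: attributes, profiles, Q-matrix, W-matrix and parameter structure.

The design layer is purely combinatorial.  It knows which latent attribute
profiles exist, which attributes each item measures (Q-matrix), which distinct
attribute *sets* occur among the items (W-matrix), and how many free item
parameters each model kind implies for a given design.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DesignError

__all__ = [
    "ModelKind",
    "QMatrix",
    "WMatrix",
    "ProfileSpace",
    "ParamEntry",
    "ParameterIndex",
    "enumerate_profiles",
    "derive_w_matrix",
    "attribute_subsets",
    "effect_vector",
    "allowed_effect_mask",
    "count_item_parameters",
    "build_parameter_index",
]


class ModelKind(str, enum.Enum):
    """The three model kinds handled by this package."""

    NRDM = "nrdm"
    ORDM = "ordm"
    MORDM = "mordm"

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise DesignError(f"unknown model kind: {value!r}") from None


@dataclass(frozen=True)
class QMatrix:
    """Item-by-attribute binary incidence matrix.

    ``entries[i, k] == 1`` means item ``i`` measures attribute ``k``.  Every
    item must measure at least one attribute and every attribute must be
    measured by at least one item.
    """

    entries: np.ndarray
    item_ids: tuple[str, ...] = ()
    attribute_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int64)
        if entries.ndim != 2:
            raise DesignError("Q-matrix must be two-dimensional (items x attributes)")
        if entries.size == 0:
            raise DesignError("Q-matrix must have at least one item and one attribute")
        if not np.isin(entries, (0, 1)).all():
            raise DesignError("Q-matrix entries must be 0 or 1")
        if (entries.sum(axis=1) == 0).any():
            bad = int(np.flatnonzero(entries.sum(axis=1) == 0)[0])
            raise DesignError(f"Q-matrix row {bad} is all zero: every item must measure an attribute")
        if (entries.sum(axis=0) == 0).any():
            bad = int(np.flatnonzero(entries.sum(axis=0) == 0)[0])
            raise DesignError(f"Q-matrix column {bad} is all zero: every attribute must be measured")
        object.__setattr__(self, "entries", entries)
        item_ids = tuple(self.item_ids) or tuple(f"item{i + 1}" for i in range(entries.shape[0]))
        attr_ids = tuple(self.attribute_ids) or tuple(f"A{k + 1}" for k in range(entries.shape[1]))
        if len(item_ids) != entries.shape[0]:
            raise DesignError("item_ids length does not match number of Q-matrix rows")
        if len(attr_ids) != entries.shape[1]:
            raise DesignError("attribute_ids length does not match number of Q-matrix columns")
        object.__setattr__(self, "item_ids", item_ids)
        object.__setattr__(self, "attribute_ids", attr_ids)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class WMatrix:
    """Item-by-attribute-set binary incidence matrix.

    Column ``v`` stands for one distinct attribute subset occurring among the
    Q-matrix rows; ``entries[i, v] == 1`` iff item ``i`` measures exactly that
    subset.  Each row therefore has a single 1.
    """

    entries: np.ndarray
    set_definitions: tuple[tuple[int, ...], ...]
    item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int64)
        if entries.ndim != 2:
            raise DesignError("W-matrix must be two-dimensional")
        if not np.isin(entries, (0, 1)).all():
            raise DesignError("W-matrix entries must be 0 or 1")
        if not (entries.sum(axis=1) == 1).all():
            raise DesignError("every W-matrix row must contain exactly one 1")
        if len(self.set_definitions) != entries.shape[1]:
            raise DesignError("set_definitions length must match number of W-matrix columns")
        if len(set(self.set_definitions)) != len(self.set_definitions):
            raise DesignError("W-matrix attribute sets must be distinct")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "set_definitions", tuple(tuple(s) for s in self.set_definitions))
        item_ids = tuple(self.item_ids) or tuple(f"item{i + 1}" for i in range(entries.shape[0]))
        object.__setattr__(self, "item_ids", item_ids)

    @property
    def n_sets(self) -> int:
        return self.entries.shape[1]

    @property
    def item_set(self) -> np.ndarray:
        """Index of the attribute set measured by each item."""
        return self.entries.argmax(axis=1)

    def items_in_set(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.entries[:, v] == 1)


@dataclass(frozen=True)
class ProfileSpace:
    """All 2^K binary attribute profiles in a fixed enumeration order.

    Profiles are ordered by the number of possessed attributes, ties broken by
    attribute index, so for K=2 the order is (0,0), (1,0), (0,1), (1,1).
    """

    n_attributes: int
    profiles: np.ndarray

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=np.int64)
        if profiles.shape != (2 ** self.n_attributes, self.n_attributes):
            raise DesignError("profile array shape inconsistent with attribute count")
        object.__setattr__(self, "profiles", profiles)

    @property
    def n_classes(self) -> int:
        return self.profiles.shape[0]

    def index_of(self, profile: Sequence[int]) -> int:
        matches = np.flatnonzero((self.profiles == np.asarray(profile)).all(axis=1))
        if matches.size == 0:
            raise DesignError(f"profile {tuple(profile)} not in profile space")
        return int(matches[0])

    def labels(self) -> tuple[str, ...]:
        return tuple("(" + ",".join(str(a) for a in row) + ")" for row in self.profiles)


def enumerate_profiles(n_attributes: int) -> ProfileSpace:
    """Enumerate all 2^K attribute profiles in the canonical order.

    The order groups profiles by the number of possessed attributes and breaks
    ties by the (lexicographic) attribute subset, so mastery of attribute 1
    precedes mastery of attribute 2.
    """
    if n_attributes < 1:
        raise DesignError("need at least one attribute")
    profiles = []
    for size in range(n_attributes + 1):
        for subset in itertools.combinations(range(n_attributes), size):
            row = np.zeros(n_attributes, dtype=np.int64)
            row[list(subset)] = 1
            profiles.append(row)
    return ProfileSpace(n_attributes=n_attributes, profiles=np.array(profiles))


def derive_w_matrix(q: QMatrix) -> WMatrix:
    """Group items by the attribute set they measure.

    Columns are ordered by first occurrence among the items, so the mapping is
    deterministic for a given item order.
    """
    seen: dict[tuple[int, ...], int] = {}
    assignment = np.zeros(q.n_items, dtype=np.int64)
    for i in range(q.n_items):
        pattern = tuple(int(x) for x in q.entries[i])
        if pattern not in seen:
            seen[pattern] = len(seen)
        assignment[i] = seen[pattern]
    n_sets = len(seen)
    entries = np.zeros((q.n_items, n_sets), dtype=np.int64)
    entries[np.arange(q.n_items), assignment] = 1
    set_definitions = []
    for pattern in seen:  # insertion order
        set_definitions.append(tuple(k for k, bit in enumerate(pattern) if bit == 1))
    return WMatrix(entries=entries, set_definitions=tuple(set_definitions), item_ids=q.item_ids)


def attribute_subsets(n_attributes: int, max_order: int) -> tuple[tuple[int, ...], ...]:
    """Effect-term subsets: mains by attribute index, then interactions by
    order and lexicographic attribute indices."""
    if not 1 <= max_order <= n_attributes:
        raise DesignError(f"max_order must be in [1, {n_attributes}], got {max_order}")
    terms: list[tuple[int, ...]] = []
    for size in range(1, max_order + 1):
        terms.extend(itertools.combinations(range(n_attributes), size))
    return tuple(terms)


def effect_vector(
    profile: Sequence[int],
    q_row: Sequence[int],
    max_order: int | None = None,
) -> np.ndarray:
    """The coefficient-multiplier vector h(alpha, q_i) of the linear predictor.

    Entry for subset S is prod_{k in S} alpha_k * q_ik: mains first, then
    interactions.  Attributes the item does not measure are gated to zero.
    """
    profile = np.asarray(profile, dtype=np.int64)
    q_row = np.asarray(q_row, dtype=np.int64)
    if profile.shape != q_row.shape or profile.ndim != 1:
        raise DesignError("profile and q_row must be one-dimensional and of equal length")
    k = profile.shape[0]
    if max_order is None:
        max_order = k
    gated = profile * q_row
    terms = attribute_subsets(k, max_order)
    return np.array([np.prod(gated[list(s)]) for s in terms], dtype=np.float64)


def allowed_effect_mask(q_row: Sequence[int], max_order: int | None = None) -> np.ndarray:
    """Boolean mask over effect terms: True where every attribute of the term
    is measured by the item (the term's coefficient is a free parameter)."""
    q_row = np.asarray(q_row, dtype=np.int64)
    k = q_row.shape[0]
    if max_order is None:
        max_order = k
    terms = attribute_subsets(k, max_order)
    return np.array([all(q_row[list(s)] == 1) for s in terms], dtype=bool)


def _per_item_options(options: int | Sequence[int], n_items: int) -> tuple[int, ...]:
    if np.isscalar(options):
        out = (int(options),) * n_items
    else:
        out = tuple(int(m) for m in options)
        if len(out) != n_items:
            raise DesignError("per-item option counts must match the number of items")
    for i, m in enumerate(out):
        if m < 2:
            raise DesignError(f"item {i} has {m} response options; at least 2 are required")
    return out


def count_item_parameters(
    model_kind: ModelKind | str,
    q: QMatrix,
    options: int | Sequence[int],
    max_order: int | None = None,
) -> int:
    """Number of free item parameters implied by the design.

    NRDM:  sum_i (M_i - 1) * (1 + E_i)
    ORDM:  sum_i (M_i - 1) + E_i
    MORDM: sum_i (1 + E_i) + sum_v (M_v - 1)

    where E_i is the number of main-effect and interaction terms allowed by the
    item's Q-matrix row (up to ``max_order``) and M_v the option count shared
    by all items measuring attribute set v.
    """
    kind = ModelKind.coerce(model_kind)
    m_per_item = _per_item_options(options, q.n_items)
    if max_order is None:
        max_order = q.n_attributes
    n_effects = [int(allowed_effect_mask(q.entries[i], max_order).sum()) for i in range(q.n_items)]
    if kind is ModelKind.NRDM:
        return sum((m - 1) * (1 + e) for m, e in zip(m_per_item, n_effects))
    if kind is ModelKind.ORDM:
        return sum((m - 1) + e for m, e in zip(m_per_item, n_effects))
    # MORDM: shared option intercepts per attribute set
    w = derive_w_matrix(q)
    total = sum(1 + e for e in n_effects)
    for v in range(w.n_sets):
        ms = {m_per_item[i] for i in w.items_in_set(v)}
        if len(ms) != 1:
            raise DesignError(
                f"items measuring attribute set {v} have differing option counts {sorted(ms)}; "
                "shared option intercepts require a common count"
            )
        total += ms.pop() - 1
    return total


# ---------------------------------------------------------------------------
# Parameter bookkeeping


@dataclass(frozen=True)
class ParamEntry:
    """One named free parameter in the pseudo parameterization.

    ``container``/``index`` locate the value inside a parameter container
    (see models.PseudoItemParams); ``items`` lists the items whose response
    probabilities the parameter touches.
    """

    name: str
    role: str
    container: str
    index: tuple[int, ...]
    items: tuple[int, ...]


@dataclass(frozen=True)
class ParameterIndex:
    """Flat directory of the free item parameters of a model/design pair."""

    model_kind: ModelKind
    options: tuple[int, ...]
    max_order: int
    entries: tuple[ParamEntry, ...] = field(repr=False)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _term_label(term: tuple[int, ...], attribute_ids: tuple[str, ...]) -> str:
    return "*".join(attribute_ids[k] for k in term)


def build_parameter_index(
    model_kind: ModelKind | str,
    q: QMatrix,
    options: int | Sequence[int],
    max_order: int | None = None,
    w: WMatrix | None = None,
) -> ParameterIndex:
    """Enumerate the free parameters (pseudo form) for a model/design pair.

    The entry count always equals :func:`count_item_parameters` for the same
    arguments.
    """
    kind = ModelKind.coerce(model_kind)
    m_per_item = _per_item_options(options, q.n_items)
    if max_order is None:
        max_order = q.n_attributes
    terms = attribute_subsets(q.n_attributes, max_order)
    entries: list[ParamEntry] = []

    def item_terms(i: int) -> list[tuple[int, tuple[int, ...]]]:
        mask = allowed_effect_mask(q.entries[i], max_order)
        return [(e, t) for e, (t, ok) in enumerate(zip(terms, mask)) if ok]

    if kind in (ModelKind.NRDM, ModelKind.ORDM):
        for i in range(q.n_items):
            iid = q.item_ids[i]
            for m in range(1, m_per_item[i]):
                role = "intercept_base" if m == 1 else "intercept_increment"
                prefix = "lambda0" if m == 1 else "dlambda0"
                entries.append(
                    ParamEntry(f"{prefix}[{iid},m={m}]", role, "intercepts", (i, m - 1), (i,))
                )
            for e, t in item_terms(i):
                label = _term_label(t, q.attribute_ids)
                role = "main_effect" if len(t) == 1 else "interaction"
                if kind is ModelKind.ORDM:
                    entries.append(
                        ParamEntry(f"lambda[{iid},{label}]", role, "effects", (i, e), (i,))
                    )
                else:
                    for m in range(1, m_per_item[i]):
                        r = role if m == 1 else role + "_increment"
                        prefix = "lambda" if m == 1 else "dlambda"
                        entries.append(
                            ParamEntry(
                                f"{prefix}[{iid},{label},m={m}]", r, "effects", (i, m - 1, e), (i,)
                            )
                        )
    else:  # MORDM
        if w is None:
            w = derive_w_matrix(q)
        for i in range(q.n_items):
            iid = q.item_ids[i]
            entries.append(ParamEntry(f"lambda0[{iid}]", "item_intercept", "item_intercepts", (i,), (i,)))
            for e, t in item_terms(i):
                label = _term_label(t, q.attribute_ids)
                role = "main_effect" if len(t) == 1 else "interaction"
                entries.append(ParamEntry(f"lambda[{iid},{label}]", role, "effects", (i, e), (i,)))
        for v in range(w.n_sets):
            items = tuple(int(j) for j in w.items_in_set(v))
            m_set = m_per_item[items[0]]
            set_label = "{" + ",".join(q.attribute_ids[k] for k in w.set_definitions[v]) + "}"
            for m in range(1, m_set):
                role = "shared_intercept_base" if m == 1 else "shared_intercept_increment"
                prefix = "lambda0" if m == 1 else "dlambda0"
                entries.append(
                    ParamEntry(
                        f"{prefix}[set{set_label},m={m}]", role, "shared_intercepts", (v, m - 1), items
                    )
                )

    names = [e.name for e in entries]
    if len(set(names)) != len(names):  # pragma: no cover - defensive
        raise DesignError("duplicate parameter names in parameter index")
    expected = count_item_parameters(kind, q, options, max_order)
    if len(entries) != expected:  # pragma: no cover - defensive
        raise DesignError(f"parameter index size {len(entries)} != structural count {expected}")
    return ParameterIndex(model_kind=kind, options=m_per_item, max_order=max_order, entries=tuple(entries))
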