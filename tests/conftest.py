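import numpy as np
import pytest

from orddcm import reference
from orddcm.design import (
    ModelKind,
    QMatrix,
    allowed_effect_mask,
    attribute_subsets,
    derive_w_matrix,
)
from orddcm.models import NaturalItemParams, PseudoItemParams, pseudo_to_natural


@pytest.fixture
def survey_q() -> QMatrix:
    return reference.survey_q_matrix()


@pytest.fixture
def survey_w(survey_q):
    return derive_w_matrix(survey_q)


@pytest.fixture
def ordm_truth() -> NaturalItemParams:
    return reference.ordm_generating_params()


@pytest.fixture
def mordm_truth() -> NaturalItemParams:
    return reference.mordm_generating_params()


@pytest.fixture
def truth_prevalence() -> np.ndarray:
    return reference.generating_prevalence()


def random_pseudo(kind, q, options, rng, max_order=None) -> PseudoItemParams:
    """Random parameter set satisfying all pseudo-form sign constraints."""
    kind = ModelKind.coerce(kind)
    if max_order is None:
        max_order = q.n_attributes
    terms = attribute_subsets(q.n_attributes, max_order)
    n_items = q.n_items
    options = tuple(options) if not np.isscalar(options) else (int(options),) * n_items
    masks = [allowed_effect_mask(q.entries[i], max_order) for i in range(n_items)]

    intercepts = None
    item_intercepts = None
    shared = None
    if kind in (ModelKind.NRDM, ModelKind.ORDM):
        intercepts = []
        for m in options:
            arr = np.empty(m - 1)
            arr[0] = rng.normal(0, 1.5)
            arr[1:] = -np.abs(rng.normal(1.0, 0.8, m - 2))
            intercepts.append(arr)
    effects = []
    for i, m in enumerate(options):
        if kind is ModelKind.NRDM:
            arr = np.abs(rng.normal(1.0, 0.8, (m - 1, len(terms)))) + 0.05
            arr[:, ~masks[i]] = 0.0
        else:
            arr = np.abs(rng.normal(1.5, 0.8, len(terms))) + 0.05
            arr[~masks[i]] = 0.0
        effects.append(arr)
    if kind is ModelKind.MORDM:
        w = derive_w_matrix(q)
        item_intercepts = rng.normal(0, 2.0, n_items)
        shared = []
        for v in range(w.n_sets):
            m = options[int(w.items_in_set(v)[0])]
            arr = np.empty(m - 1)
            arr[0] = rng.normal(-1.0, 1.0)
            arr[1:] = -np.abs(rng.normal(1.0, 0.8, m - 2))
            shared.append(arr)
    return PseudoItemParams(
        model_kind=kind,
        options=options,
        effect_terms=terms,
        intercepts=intercepts,
        effects=effects,
        item_intercepts=item_intercepts,
        shared_intercepts=shared,
    )


def random_natural(kind, q, options, rng, max_order=None) -> NaturalItemParams:
    return pseudo_to_natural(random_pseudo(kind, q, options, rng, max_order))


@pytest.fixture
def small_q() -> QMatrix:
    return QMatrix(entries=np.array([[1, 0], [1, 1], [0, 1]]))
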