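"""Built-in example design and generating parameter sets.

An eight-item, two-attribute survey design with four ordered response options
per item: items 1-4 measure the first attribute, items 5-8 the second.  The
parameter sets below are published point estimates for this design and serve
as the default generating truth for the bundled recovery study.
"""

from __future__ import annotations

import numpy as np

from .design import ModelKind, QMatrix, WMatrix, derive_w_matrix
from .models import NaturalItemParams, PseudoItemParams, pseudo_to_natural

__all__ = [
    "survey_q_matrix",
    "survey_w_matrix",
    "generating_prevalence",
    "ordm_generating_pseudo",
    "ordm_generating_params",
    "mordm_generating_pseudo",
    "mordm_generating_params",
]

_EFFECT_TERMS = ((0,), (1,), (0, 1))


def survey_q_matrix() -> QMatrix:
    """8 items x 2 attributes: items 1-4 load on A1, items 5-8 on A2."""
    entries = np.array([[1, 0]] * 4 + [[0, 1]] * 4)
    return QMatrix(entries=entries, attribute_ids=("A1", "A2"))


def survey_w_matrix() -> WMatrix:
    return derive_w_matrix(survey_q_matrix())


def generating_prevalence() -> np.ndarray:
    """Profile prevalence over (0,0), (1,0), (0,1), (1,1)."""
    return np.array([0.351, 0.074, 0.156, 0.419])


# Per item: option-1 intercept, option-2/3 intercept increments, main effect.
_ORDM_PSEUDO = [
    (-0.390, -4.088, -5.321, 3.735),
    (-0.834, -2.181, -3.127, 1.971),
    (-1.533, -3.377, -3.194, 2.841),
    (0.289, -2.180, -3.784, 2.902),
    (1.991, -0.029, -1.352, 2.290),
    (1.352, -0.670, -2.586, 2.626),
    (0.071, -1.370, -2.297, 2.039),
    (0.646, -10.395, -12.733, 12.427),
]

# MORDM: per-item general intercepts and main effects; per attribute set the
# shared option-1 intercept and option-2/3 increments.
_MORDM_ITEM_INTERCEPTS = [5.834, 5.141, 4.491, 6.424, 10.313, 9.339, 7.948, 8.285]
_MORDM_EFFECTS = [2.472, 2.512, 2.732, 3.200, 3.262, 2.348, 1.622, 2.033]
_MORDM_SHARED = [
    (-6.204, -2.871, -3.781),
    (-7.893, -0.527, -2.111),
]


def _effect_row(item: int, value: float) -> np.ndarray:
    row = np.zeros(len(_EFFECT_TERMS))
    row[0 if item < 4 else 1] = value
    return row


def ordm_generating_pseudo() -> PseudoItemParams:
    intercepts = [np.array(row[:3]) for row in _ORDM_PSEUDO]
    effects = [_effect_row(i, row[3]) for i, row in enumerate(_ORDM_PSEUDO)]
    return PseudoItemParams(
        model_kind=ModelKind.ORDM,
        options=(4,) * 8,
        effect_terms=_EFFECT_TERMS,
        intercepts=intercepts,
        effects=effects,
    )


def ordm_generating_params() -> NaturalItemParams:
    return pseudo_to_natural(ordm_generating_pseudo())


def mordm_generating_pseudo() -> PseudoItemParams:
    effects = [_effect_row(i, v) for i, v in enumerate(_MORDM_EFFECTS)]
    return PseudoItemParams(
        model_kind=ModelKind.MORDM,
        options=(4,) * 8,
        effect_terms=_EFFECT_TERMS,
        effects=effects,
        item_intercepts=np.array(_MORDM_ITEM_INTERCEPTS),
        shared_intercepts=[np.array(s) for s in _MORDM_SHARED],
    )


def mordm_generating_params() -> NaturalItemParams:
    return pseudo_to_natural(mordm_generating_pseudo())
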