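"""Synthetic respondent generation from any of the three models.

One master seed drives the whole generation; profile draws and response draws
use independent seed-derived streams, so changing the item set never perturbs
profile assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import ModelKind, QMatrix, derive_w_matrix
from .exceptions import ConfigError, DataError
from .models import (
    ClassConditionalTable,
    NaturalItemParams,
    class_conditional_table,
    validate_prevalence,
)

__all__ = ["ResponseDataset", "draw_profiles", "draw_responses", "generate_dataset"]

# fixed sub-stream labels so each generation stage is independent of the others
_PROFILE_STREAM = 11
_RESPONSE_STREAM = 23


@dataclass
class ResponseDataset:
    """Respondent-by-item ordinal codes, plus option counts and optional truth."""

    responses: np.ndarray
    options: tuple[int, ...]
    item_ids: tuple[str, ...] = ()
    true_classes: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 2:
            raise DataError("responses must be a 2-D respondents x items array")
        self.options = tuple(int(m) for m in self.options)
        if len(self.options) != self.responses.shape[1]:
            raise DataError("one option count per item is required")
        for i, m_i in enumerate(self.options):
            col = self.responses[:, i]
            bad = np.flatnonzero((col < 0) | (col >= m_i))
            if bad.size:
                raise DataError(
                    f"respondent {int(bad[0])}, item {i}: code {int(col[bad[0]])} outside 0..{m_i - 1}"
                )
        if not self.item_ids:
            self.item_ids = tuple(f"item{i + 1}" for i in range(self.responses.shape[1]))
        if self.true_classes is not None:
            self.true_classes = np.asarray(self.true_classes, dtype=np.int64)
            if self.true_classes.shape != (self.responses.shape[0],):
                raise DataError("true_classes must have one entry per respondent")

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]


def draw_profiles(prevalence: Sequence[float], n: int, seed) -> np.ndarray:
    """I.i.d. latent-class draws from the profile prevalence vector."""
    pi = validate_prevalence(prevalence)
    if n < 1:
        raise ConfigError("need at least one respondent")
    rng = np.random.default_rng(seed)
    return rng.choice(pi.shape[0], size=n, p=pi)


def draw_responses(
    table: ClassConditionalTable,
    profiles: np.ndarray,
    seed,
    item_ids: Sequence[str] = (),
) -> ResponseDataset:
    """Draw each response from the categorical row of its (item, class)."""
    profiles = np.asarray(profiles, dtype=np.int64)
    n_classes = table.profile_space.n_classes
    if profiles.ndim != 1 or ((profiles < 0) | (profiles >= n_classes)).any():
        raise DataError("profile class indices outside the profile space")
    rng = np.random.default_rng(seed)
    n = profiles.shape[0]
    responses = np.zeros((n, table.n_items), dtype=np.int64)
    for i in range(table.n_items):
        cum = np.cumsum(table.probs[i, profiles, : table.options[i]], axis=1)
        u = rng.random(n)
        responses[:, i] = (u[:, None] > cum).sum(axis=1)
    return ResponseDataset(
        responses=responses,
        options=table.options,
        item_ids=tuple(item_ids),
        true_classes=profiles,
        metadata={"seed": seed},
    )


def generate_dataset(
    model_kind: ModelKind | str,
    params: NaturalItemParams,
    prevalence: Sequence[float],
    n: int,
    seed: int,
    q: QMatrix,
    out_dir: str | Path | None = None,
) -> ResponseDataset:
    """Simulate a full dataset and optionally write it to disk.

    Writes ``responses.csv``, a ``truth.csv`` sidecar (class index + binary
    profile) and the exact ``params.json`` used, all derived from one master
    seed.
    """
    kind = ModelKind.coerce(model_kind)
    if n < 1:
        raise ConfigError("n: need at least one respondent")
    if int(seed) != seed:
        raise ConfigError("seed must be an integer")
    w = derive_w_matrix(q) if kind is ModelKind.MORDM else None
    table = class_conditional_table(kind, params, q, w)
    pi = validate_prevalence(prevalence, table.profile_space.n_classes)
    profiles = draw_profiles(pi, n, np.random.SeedSequence([int(seed), _PROFILE_STREAM]))
    dataset = draw_responses(
        table, profiles, np.random.SeedSequence([int(seed), _RESPONSE_STREAM]), item_ids=q.item_ids
    )
    dataset.metadata = {
        "model": kind.value,
        "seed": int(seed),
        "n": int(n),
        "prevalence": pi.tolist(),
    }
    if out_dir is not None:
        from . import cli_io  # local import: cli_io depends on this module

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cli_io.write_responses(dataset, out / "responses.csv")
        cli_io.write_truth(dataset, table.profile_space, out / "truth.csv")
        (out / "params.json").write_text(json.dumps(params.to_json_dict(), indent=2) + "\n")
        (out / "config.json").write_text(json.dumps(dataset.metadata, indent=2, sort_keys=True) + "\n")
    return dataset
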