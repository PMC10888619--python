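"""Exhaustive candidate-model enumeration.

The candidate set M consists of every subset of at most ``k_max`` predictors
drawn from a predictor pool, including the null (empty) model.  For the full
18-predictor pool with ``k_max = 4`` this yields
sum(C(18, k) for k in 0..4) = 4048 candidate logistic models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .errors import ValidationError

__all__ = ["CandidateModel", "CandidateModelSpace", "enumerate_models"]


@dataclass(frozen=True)
class CandidateModel:
    """An ordered subset of predictor names; empty = intercept-only model."""

    predictors: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.predictors)

    def label(self) -> str:
        return "+".join(self.predictors) if self.predictors else "<null>"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label()


@dataclass
class CandidateModelSpace:
    models: list[CandidateModel]
    k_max: int
    predictor_pool: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def to_text(self) -> str:
        """One model per line, for audit logs."""
        return "\n".join(m.label() for m in self.models)


def enumerate_models(predictor_pool: Sequence[str], k_max: int) -> CandidateModelSpace:
    """Enumerate all subsets of at most ``k_max`` predictors.

    Ordering is deterministic: by subset size, then lexicographically by
    predictor name; the null model comes first.
    """
    pool = tuple(predictor_pool)
    if len(pool) == 0:
        raise ValidationError("predictor pool must be non-empty")
    if len(set(pool)) != len(pool):
        raise ValidationError("predictor pool contains duplicate names")
    if k_max < 0:
        raise ValidationError("k_max must be >= 0")
    if k_max > len(pool):
        raise ValidationError(
            f"k_max={k_max} exceeds the pool size {len(pool)}"
        )
    ordered = tuple(sorted(pool))
    models = [
        CandidateModel(combo)
        for k in range(k_max + 1)
        for combo in combinations(ordered, k)
    ]
    return CandidateModelSpace(models=models, k_max=k_max, predictor_pool=pool)
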