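"""Repeated stratified resampling for best-subset model selection.

Selection (flat): the cohort is split J times into stratified 80/20
training/test pairs; every candidate model is fitted on every training part
and its AUC measured on the matching test part; the model maximizing the
mean test AUC wins.

Nested validation: an outer loop draws K stratified 80% derivation cohorts
and re-runs the entire selection inside each; the selected model's mean
inner-test AUC per outer cohort, summarised as mean [min, max], measures the
selection procedure itself (without selection optimism).

Complete-case filtering is per model and per split by default: both parts of
a split are restricted to records complete on the model's own predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, complete_case_mask, complete_cases
from .errors import SelectionError, ValidationError
from .logistic import DEFAULT_DESIGN, DesignSpec, auc, encode_design, fit_logistic
from .model_space import CandidateModel, CandidateModelSpace
from .errors import FitError

__all__ = [
    "SplitPlan",
    "make_split_plan",
    "AUCMatrix",
    "evaluate_models",
    "SelectionResult",
    "select_best",
    "NestedValidationResult",
    "nested_validate",
    "run_selection",
    "FLAG_REASONS",
]

#: closed set of reasons an (split, model) AUC entry can be invalid
FLAG_REASONS = (
    "empty_train",
    "empty_test",
    "single_class_train",
    "single_class_test",
    "fit_error",
)


@dataclass
class SplitPlan:
    """J stratified train/test partitions of one cohort's row indices."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    train_fraction: float
    seed: int
    n: int
    n_events: int

    @property
    def J(self) -> int:
        return len(self.splits)


def _round_half_even(x: float) -> int:
    return int(round(x))


def make_split_plan(cohort: Cohort, J: int, train_fraction: float,
                    seed: int) -> SplitPlan:
    """Draw J independent stratified train/test splits.

    Per class the training part receives round(train_fraction * n_class)
    records (round-half-to-even), so every training cohort carries the same
    event/non-event counts; index arrays are sorted for determinism.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    if J < 1:
        raise ValidationError("J must be >= 1")
    cohort.require_both_classes()
    y = cohort.y
    classes = [np.flatnonzero(y == 1), np.flatnonzero(y == 0)]
    n_train = [_round_half_even(train_fraction * c.size) for c in classes]
    for cls, k in zip(classes, n_train):
        if k < 1 or k >= cls.size:
            raise SelectionError(
                f"a class with {cls.size} members cannot appear in both "
                f"partitions at train_fraction={train_fraction}"
            )
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(J):
        tr_parts, te_parts = [], []
        for cls, k in zip(classes, n_train):
            perm = rng.permutation(cls)
            tr_parts.append(perm[:k])
            te_parts.append(perm[k:])
        splits.append(
            (np.sort(np.concatenate(tr_parts)), np.sort(np.concatenate(te_parts)))
        )
    return SplitPlan(splits=splits, train_fraction=train_fraction, seed=seed,
                     n=cohort.n, n_events=cohort.n_events)


@dataclass
class AUCMatrix:
    """Test AUC per (split j, model m); invalid entries are NaN with a
    reason from :data:`FLAG_REASONS`."""

    values: np.ndarray  # shape (J, M), NaN = flagged
    reasons: dict[tuple[int, int], str]
    model_labels: tuple[str, ...]

    @property
    def J(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.model_labels))


def evaluate_models(cohort: Cohort, space: CandidateModelSpace, plan: SplitPlan,
                    spec: DesignSpec = DEFAULT_DESIGN,
                    fit_options: dict | None = None) -> AUCMatrix:
    """Fit every candidate model on every training part and score the test
    part.

    For each model the cohort is first restricted to records complete on
    that model's predictors; each split's train/test index sets are
    intersected with that complete-case subset.  Entries that cannot be
    computed are flagged with an explicit reason, never silently zeroed.
    """
    if plan.n != cohort.n:
        raise ValidationError("split plan was built for a different cohort size")
    fit_options = fit_options or {}
    J, M = plan.J, len(space)
    values = np.full((J, M), np.nan)
    reasons: dict[tuple[int, int], str] = {}
    for m_idx, model in enumerate(space):
        mask = complete_case_mask(cohort, model.predictors)
        if not mask.any():
            for j in range(J):
                reasons[(j, m_idx)] = "empty_train"
            continue
        rows = np.flatnonzero(mask)
        pos = np.full(cohort.n, -1, dtype=np.intp)
        pos[rows] = np.arange(rows.size)
        sub = cohort.subset(rows)
        design = encode_design(sub, model, spec)
        Xall, yall = design.X, design.y
        for j, (tr, te) in enumerate(plan.splits):
            trp = pos[tr]
            trp = trp[trp >= 0]
            tep = pos[te]
            tep = tep[tep >= 0]
            if trp.size == 0:
                reasons[(j, m_idx)] = "empty_train"
                continue
            if tep.size == 0:
                reasons[(j, m_idx)] = "empty_test"
                continue
            ytr, yte = yall[trp], yall[tep]
            if ytr.min() == ytr.max():
                reasons[(j, m_idx)] = "single_class_train"
                continue
            if yte.min() == yte.max():
                reasons[(j, m_idx)] = "single_class_test"
                continue
            Xtr = Xall[trp]
            # drop columns constant in this training part (absent category)
            if Xtr.shape[1]:
                keep = Xtr.min(axis=0) != Xtr.max(axis=0)
            else:
                keep = np.zeros(0, dtype=bool)
            try:
                fit = fit_logistic(Xtr[:, keep], ytr, **fit_options)
            except FitError:
                reasons[(j, m_idx)] = "fit_error"
                continue
            beta = np.fromiter(fit.coefficients.values(), dtype=float,
                               count=int(keep.sum()))
            eta = fit.intercept + Xall[tep][:, keep] @ beta
            values[j, m_idx] = auc(eta, yte)
    return AUCMatrix(values=values, reasons=reasons,
                     model_labels=tuple(m.label() for m in space))


@dataclass
class SelectionResult:
    best_model: CandidateModel
    best_index: int
    mean_auc: float
    min_auc: float
    max_auc: float
    per_split_auc: np.ndarray  # the winner's J AUCs (NaN where flagged)
    ties: list[int] = field(default_factory=list)  # indices sharing the top mean
    disqualified: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_model": list(self.best_model.predictors),
            "mean_auc": self.mean_auc,
            "min_auc": self.min_auc,
            "max_auc": self.max_auc,
            "per_split_auc": [None if np.isnan(v) else float(v)
                              for v in self.per_split_auc],
            "ties": self.ties,
            "disqualified": self.disqualified,
        }


def select_best(matrix: AUCMatrix, space: CandidateModelSpace,
                max_flagged_fraction: float = 0.5) -> SelectionResult:
    """Pick the model with the highest mean AUC over its valid entries.

    Models with more than ``max_flagged_fraction`` flagged splits are
    disqualified (and reported).  Ties on the mean are broken by fewer
    predictors, then enumeration order; all tied indices are recorded.
    """
    vals = matrix.values
    valid = ~np.isnan(vals)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n_valid > 0, np.nansum(vals, axis=0) / np.maximum(n_valid, 1),
                         -np.inf)
    disqualified = [
        int(m) for m in range(len(space))
        if n_valid[m] == 0 or (matrix.J - n_valid[m]) / matrix.J > max_flagged_fraction
    ]
    eligible = [m for m in range(len(space)) if m not in set(disqualified)]
    if not eligible:
        raise SelectionError("no candidate model has enough valid AUC entries")
    order = sorted(eligible, key=lambda m: (-means[m], space.models[m].size, m))
    best = order[0]
    ties = [m for m in eligible if means[m] == means[best]]
    col = vals[:, best]
    return SelectionResult(
        best_model=space.models[best],
        best_index=int(best),
        mean_auc=float(means[best]),
        min_auc=float(np.nanmin(col)),
        max_auc=float(np.nanmax(col)),
        per_split_auc=col.copy(),
        ties=[int(m) for m in ties],
        disqualified=disqualified,
    )


def run_selection(cohort: Cohort, space: CandidateModelSpace, J: int = 100,
                  train_fraction: float = 0.8, seed: int = 0,
                  spec: DesignSpec = DEFAULT_DESIGN,
                  complete_case_mode: str = "per_split"
                  ) -> tuple[SelectionResult, AUCMatrix]:
    """One full selection pass (split plan + AUC matrix + argmax).

    ``complete_case_mode``: "per_split" (default) filters each model within
    each split on its own predictors; "pre_split" filters the cohort once on
    the union of the pool's predictors before any splitting.
    """
    if complete_case_mode == "pre_split":
        cohort = complete_cases(cohort, space.predictor_pool)
    elif complete_case_mode != "per_split":
        raise ValidationError(f"unknown complete_case_mode {complete_case_mode!r}")
    plan = make_split_plan(cohort, J, train_fraction, seed)
    matrix = evaluate_models(cohort, space, plan, spec)
    return select_best(matrix, space), matrix


def _inner_seed(master_seed: int, k: int) -> int:
    """Deterministic per-outer-cohort seed derived from (master seed, k)."""
    return int(np.random.SeedSequence([master_seed, k]).generate_state(1)[0])


@dataclass
class NestedValidationResult:
    auc_values: np.ndarray  # AUC(k) on the outer validation cohorts, k = 1..K
    inner_mean_auc: np.ndarray  # the winner's mean inner-test AUC per k
    selected_models: list[CandidateModel]
    mean_auc: float
    min_auc: float
    max_auc: float

    def to_dict(self) -> dict:
        return {
            "auc_values": [float(v) for v in self.auc_values],
            "inner_mean_auc": [float(v) for v in self.inner_mean_auc],
            "selected_models": [list(m.predictors) for m in self.selected_models],
            "mean_auc": self.mean_auc,
            "min_auc": self.min_auc,
            "max_auc": self.max_auc,
        }


def _holdout_auc(cohort: Cohort, derive_idx: np.ndarray, valid_idx: np.ndarray,
                 model: CandidateModel, spec: DesignSpec) -> float:
    """Refit ``model`` on the derivation rows and score the validation rows
    (complete-case filtered on the model's own predictors)."""
    mask = complete_case_mask(cohort, model.predictors)
    derive_idx = derive_idx[mask[derive_idx]]
    valid_idx = valid_idx[mask[valid_idx]]
    if derive_idx.size == 0 or valid_idx.size == 0:
        raise SelectionError("hold-out evaluation has an empty partition")
    dsub = cohort.subset(derive_idx)
    vsub = cohort.subset(valid_idx)
    design = encode_design(dsub, model, spec)
    if design.X.shape[1]:
        keep = design.X.min(axis=0) != design.X.max(axis=0)
    else:
        keep = np.zeros(0, dtype=bool)
    fit = fit_logistic(design.X[:, keep], design.y)
    vdesign = encode_design(vsub, model, spec)
    beta = np.fromiter(fit.coefficients.values(), dtype=float, count=int(keep.sum()))
    eta = fit.intercept + vdesign.X[:, keep] @ beta
    return auc(eta, vsub.y)


def nested_validate(cohort: Cohort, space: CandidateModelSpace, K: int = 100,
                    J: int = 100, train_fraction: float = 0.8, seed: int = 0,
                    spec: DesignSpec = DEFAULT_DESIGN,
                    complete_case_mode: str = "per_split"
                    ) -> NestedValidationResult:
    """Outer-loop internal validation of the selection procedure.

    Each of K outer iterations draws a stratified derivation cohort D(k)
    (80%) and holds out the complementary validation cohort Dk* (20%).  The
    full selection (J inner splits) runs inside D(k); the winning model is
    then refitted on all of D(k) and AUC(k) is its AUC on the held-out Dk*,
    so AUC(k) is free of the optimism of the inner selection.  Summarised as
    mean [min, max].
    """
    outer = make_split_plan(cohort, K, train_fraction, seed)
    aucs = np.empty(K)
    inner_means = np.empty(K)
    models: list[CandidateModel] = []
    for k, (derive_idx, valid_idx) in enumerate(outer.splits):
        sub = cohort.subset(derive_idx, name=f"{cohort.name}/derivation{k}")
        try:
            sel, _ = run_selection(
                sub, space, J=J, train_fraction=train_fraction,
                seed=_inner_seed(seed, k), spec=spec,
                complete_case_mode=complete_case_mode,
            )
            aucs[k] = _holdout_auc(cohort, derive_idx, valid_idx,
                                   sel.best_model, spec)
        except (SelectionError, ValidationError, FitError) as exc:
            raise SelectionError(f"outer derivation cohort {k}: {exc}") from exc
        inner_means[k] = sel.mean_auc
        models.append(sel.best_model)
    return NestedValidationResult(
        auc_values=aucs,
        inner_mean_auc=inner_means,
        selected_models=models,
        mean_auc=float(aucs.mean()),
        min_auc=float(aucs.min()),
        max_auc=float(aucs.max()),
    )
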