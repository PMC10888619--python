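"""Design encoding, maximum-likelihood logistic regression and ROC AUC.

Categorical predictors are dummy-coded against fixed reference levels; the
fitter is iteratively reweighted least squares (Newton with step-halving, so
the deviance path is non-increasing).  When a fit does not converge or runs
away — the signature of complete or quasi-complete separation on a small
training split — the model is refitted with a small L2 penalty and flagged
``stabilized`` instead of being discarded, so every (model, split) pair can
still yield an AUC.

AUC uses the Mann–Whitney estimator: the fraction of (event, non-event)
pairs in which the event scores higher, tied pairs counted 1/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .cohort import OUTCOME, SCHEMA, Cohort
from .errors import FitError, ValidationError
from .model_space import CandidateModel

__all__ = [
    "DesignSpec",
    "DEFAULT_DESIGN",
    "Design",
    "encode_design",
    "FitResult",
    "fit_logistic",
    "fit_model",
    "predict_prob",
    "auc",
]


@dataclass(frozen=True)
class DesignSpec:
    """Reference level per categorical predictor (continuous predictors enter
    untransformed as identity columns)."""

    references: dict[str, str]

    def reference(self, var: str) -> str:
        try:
            return self.references[var]
        except KeyError:
            raise ValidationError(f"no reference level recorded for {var!r}") from None

    def with_reference(self, var: str, level: str) -> "DesignSpec":
        refs = dict(self.references)
        refs[var] = level
        return DesignSpec(refs)


#: Default reference levels (the published model's reference categories).
DEFAULT_DESIGN = DesignSpec(
    references={
        "sex": "male",
        "asa": "1",
        "anticoagulant": "no",
        "prior_surgeries": "0",
        "fracture": "no",
        "tumor": "no",
        "surgery_type": "cervical",
        "incision": "dorsal",
        "vbr": "no",
        "stages": "0",
    }
)


def column_name(var: str, level: str | None = None) -> str:
    return var if level is None else f"{var}[{level}]"


@dataclass
class Design:
    """Encoded design: predictor columns only (no intercept column)."""

    X: np.ndarray
    columns: tuple[str, ...]
    y: np.ndarray
    degenerate: tuple[str, ...] = ()  # constant columns noted at encoding


def encode_design(cohort: Cohort, model: CandidateModel,
                  spec: DesignSpec = DEFAULT_DESIGN) -> Design:
    """Encode a complete-case cohort for one candidate model.

    Column order is deterministic: model predictor order, and within a
    categorical predictor the schema level order with the reference level
    skipped.  Dummy columns are 0/1; the outcome is 0/1.
    """
    n = cohort.n
    cols: list[np.ndarray] = []
    names: list[str] = []
    for var in model.predictors:
        cspec = SCHEMA[var]
        series = cohort.data[var]
        if series.isna().any():
            raise ValidationError(
                f"{var!r} has missing values; complete-case filter the cohort first"
            )
        if cspec.kind == "continuous":
            cols.append(series.to_numpy(dtype=float))
            names.append(column_name(var))
        else:
            ref = spec.reference(var)
            if ref not in cspec.levels:
                raise ValidationError(f"{var!r}: reference {ref!r} not a schema level")
            codes = series.cat.codes.to_numpy()
            for j, level in enumerate(cspec.levels):
                if level == ref:
                    continue
                cols.append((codes == j).astype(float))
                names.append(column_name(var, level))
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    degenerate = tuple(
        names[j] for j in range(X.shape[1]) if X[:, j].min() == X[:, j].max()
    )
    return Design(X=X, columns=tuple(names), y=cohort.y, degenerate=degenerate)


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit."""

    intercept: float
    coefficients: dict[str, float]
    converged: bool
    n_used: int
    stabilized: bool = False
    deviance: float = float("nan")
    deviance_path: tuple[float, ...] = ()
    standard_errors: dict[str, float] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()  # degenerate columns excluded from this fit

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "converged": self.converged,
                "n_used": self.n_used,
                "stabilized": self.stabilized,
                "deviance": self.deviance,
                "dropped": list(self.dropped),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            converged=d["converged"],
            n_used=d["n_used"],
            stabilized=d.get("stabilized", False),
            deviance=d.get("deviance", float("nan")),
            dropped=tuple(d.get("dropped", ())),
        )


def _deviance(Xi: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = Xi @ beta
    # -2 log L, numerically stable form
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def _irls(Xi: np.ndarray, y: np.ndarray, ridge: float, tol: float,
          dev_tol: float, max_iter: int):
    """Newton/IRLS with step-halving on the (penalized) deviance.

    The penalty excludes the intercept (first column).  Returns
    (beta, converged, deviance path of the unpenalized deviance).
    """
    n, p = Xi.shape
    pen = np.ones(p)
    pen[0] = 0.0
    beta = np.zeros(p)
    ybar = y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar))

    def objective(b):
        return _deviance(Xi, y, b) + ridge * float(np.sum(pen * b * b))

    obj = objective(beta)
    path = [_deviance(Xi, y, beta)]
    converged = False
    for _ in range(max_iter):
        eta = Xi @ beta
        mu = expit(eta)
        score = Xi.T @ (y - mu) - ridge * pen * beta
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (Xi * w[:, None]).T @ Xi + ridge * np.diag(pen)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            raise FitError("singular information matrix") from None
        # step-halving guarantees a non-increasing deviance path
        new_beta, new_obj = beta, obj
        scale = 1.0
        for _h in range(25):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if cand_obj <= obj + 1e-12:
                new_beta, new_obj = cand, cand_obj
                break
            scale *= 0.5
        if new_obj >= obj:  # no descent possible
            converged = np.max(np.abs(score)) < 1e-4
            break
        rel = abs(obj - new_obj) / (abs(obj) + 1.0)
        beta, obj = new_beta, new_obj
        path.append(_deviance(Xi, y, beta))
        if rel < dev_tol:
            converged = True
            break
    return beta, converged, path


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    column_names: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    dev_tol: float = 1e-10,
    max_iter: int = 50,
    stabilize_ridge: float = 1e-3,
    runaway: float = 30.0,
) -> FitResult:
    """Maximum-likelihood logistic regression of 0/1 ``y`` on ``X``.

    ``X`` holds predictor columns only; the intercept is added internally.
    Convergence: max |score| < ``tol`` or relative deviance change <
    ``dev_tol``.  On non-convergence or runaway coefficients (separation) the
    model is refitted with ridge ``stabilize_ridge`` and flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise FitError("X and y have incompatible shapes")
    n, p = X.shape
    if n < p + 1:
        raise FitError(f"need at least {p + 1} rows for {p} predictors, got {n}")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise FitError("y must be 0/1")
    if uniq.size < 2:
        raise FitError("y contains a single class; logistic fit undefined")
    names = tuple(column_names) if column_names is not None else tuple(
        f"x{j}" for j in range(p)
    )
    if p > 0:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
        if rank < p + 1:
            raise FitError(
                f"rank-deficient design (rank {rank} < {p + 1}); columns: {names}"
            )
    Xi = np.column_stack([np.ones(n), X])
    beta, converged, path = _irls(Xi, y, 0.0, tol, dev_tol, max_iter)
    stabilized = False
    if not converged or np.max(np.abs(beta)) > runaway:
        beta, converged, path = _irls(Xi, y, stabilize_ridge, tol, dev_tol, max_iter)
        stabilized = True
    if not np.all(np.isfinite(beta)):
        raise FitError("non-finite estimates after stabilization")
    # observed-information standard errors (used by parameter-recovery checks)
    mu = expit(Xi @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (Xi * w[:, None]).T @ Xi
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - guarded by rank check
        se = np.full(p + 1, np.nan)
    return FitResult(
        intercept=float(beta[0]),
        coefficients={names[j]: float(beta[j + 1]) for j in range(p)},
        converged=bool(converged),
        n_used=int(n),
        stabilized=stabilized,
        deviance=float(path[-1]),
        deviance_path=tuple(path),
        standard_errors={
            "intercept": float(se[0]),
            **{names[j]: float(se[j + 1]) for j in range(p)},
        },
    )


def fit_model(cohort: Cohort, model: CandidateModel,
              spec: DesignSpec = DEFAULT_DESIGN, **options) -> FitResult:
    """Encode and fit one candidate model on a complete-case cohort.

    Degenerate (constant) dummy columns — a category absent from the cohort —
    are dropped for the fit and recorded; they predict with coefficient 0.
    """
    design = encode_design(cohort, model, spec)
    keep = [j for j, c in enumerate(design.columns) if c not in design.degenerate]
    X = design.X[:, keep]
    names = tuple(design.columns[j] for j in keep)
    fit = fit_logistic(X, design.y, column_names=names, **options)
    fit.dropped = design.degenerate
    return fit


def predict_prob(fit: FitResult, design: Design) -> np.ndarray:
    """Predicted event probabilities for an encoded design.

    Every fitted coefficient must have a matching design column; design
    columns without a fitted coefficient (dropped as degenerate during
    training) contribute 0.
    """
    missing = [c for c in fit.coefficients if c not in design.columns]
    if missing:
        raise ValidationError(f"design lacks fitted column(s): {missing}")
    beta = np.array([fit.coefficients.get(c, 0.0) for c in design.columns])
    eta = fit.intercept + design.X @ beta  # X @ beta is zeros(n) for the null model
    return expit(eta)


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score_event > score_non-event) + 1/2 P(tie)."""
    s = np.asarray(scores, dtype=float).ravel()
    lab = np.asarray(labels).ravel().astype(int)
    if s.size != lab.size:
        raise ValidationError("scores and labels differ in length")
    n1 = int((lab == 1).sum())
    n0 = int((lab == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC undefined: both classes must be present")
    r = rankdata(s)  # average ranks implement the 1/2-per-tie convention
    u = r[lab == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
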