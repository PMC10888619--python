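"""Synthetic patient-cohort generator.

Emulates the published marginal structure of a 252-patient invasive spine
surgery cohort: categorical frequencies and truncated-normal continuous
distributions matching the study's descriptive tables, missing-completely-
at-random missingness at the observed per-variable rates, and a binary
transfusion outcome drawn from a known ground-truth logistic model over
{surgery_type, vbr, stages, hb} with the published coefficient magnitudes.
The ground-truth intercept is calibrated by root finding so the expected
event rate equals the observed 61/252 ≈ 24.2%.

Covariates are drawn independently (only marginals are published); this is a
stated simplification, not an inference about the real data.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import OUTCOME, PREDICTORS, SCHEMA, Cohort
from .errors import ValidationError

__all__ = [
    "CategoricalSpec",
    "ContinuousSpec",
    "TrueModel",
    "SyntheticConfig",
    "default_config",
    "generate",
    "calibrate_intercept",
    "linear_predictor",
    "STUDY_EVENT_RATE",
]

#: observed transfusion rate 61/252
STUDY_EVENT_RATE = 61.0 / 252.0

# Published overall-column counts (n = 252; asa observed 226, vbr observed 251)
_CAT_COUNTS: dict[str, dict[str, int]] = {
    "sex": {"male": 129, "female": 123},
    "asa": {"1": 23, "2": 131, "ge3": 72},
    "anticoagulant": {"no": 176, "yes": 76},
    "prior_surgeries": {"0": 214, "1": 34, "2": 4},
    "fracture": {"no": 179, "yes": 73},
    "tumor": {"no": 210, "yes": 42},
    "surgery_type": {"cervical": 71, "thoracic": 32, "lumbar": 105, "combination": 44},
    "incision": {"dorsal": 199, "ventral": 53},
    "vbr": {"no": 222, "yes": 29},
    "stages": {"0": 104, "1": 32, "2": 57, "3": 24, "gt3": 35},
}

# mean, SD, observed [min, max] used as truncation bounds
_CONT_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "age": (62.6, 17.3, 14.0, 89.0),
    "height": (172.0, 10.1, 140.0, 198.0),
    "weight": (79.9, 18.3, 38.0, 150.0),
    "hb": (12.7, 2.32, 7.0, 19.1),
    "quick": (101.0, 14.7, 21.0, 130.0),
    "inr": (1.00, 0.146, 0.80, 2.80),
    "ptt": (25.1, 4.62, 18.0, 65.0),
    "thrombocytes": (281.0, 104.0, 84.0, 792.0),
}

# missing counts out of 252
_MISSING_COUNTS: dict[str, int] = {
    "height": 7, "weight": 2, "asa": 26, "quick": 1,
    "inr": 1, "ptt": 3, "thrombocytes": 4, "vbr": 1,
}

#: published log-odds of the four-covariate transfusion model
TRUE_COEFFICIENTS: dict[str, object] = {
    "surgery_type": {"thoracic": 0.267, "lumbar": 1.099, "combination": 1.783},
    "vbr": {"yes": 0.841},
    "stages": {"1": 0.593, "2": 1.805, "3": 2.260, "gt3": 2.122},
    "hb": -0.665,
}


@dataclass(frozen=True)
class CategoricalSpec:
    """Category probabilities (summing to one over the levels)."""
    probs: dict[str, float]

    def validate(self, name: str) -> None:
        levels = SCHEMA[name].levels
        if set(self.probs) != set(levels):
            raise ValidationError(f"{name}: probabilities must cover levels {levels}")
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"{name}: category probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in self.probs.values()):
            raise ValidationError(f"{name}: negative category probability")


@dataclass(frozen=True)
class ContinuousSpec:
    """Truncated normal: location/scale with hard clip range [low, high]."""
    mean: float
    sd: float
    low: float
    high: float

    def validate(self, name: str) -> None:
        if not (self.low < self.high):
            raise ValidationError(f"{name}: clip range requires low < high")
        if self.sd <= 0:
            raise ValidationError(f"{name}: sd must be positive")


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth logistic outcome model.

    ``coefficients`` maps a categorical variable to ``{level: log-odds}``
    (absent levels are reference, log-odds 0) and a continuous variable to a
    per-unit log-odds slope.
    """
    intercept: float
    coefficients: dict[str, object] = field(default_factory=dict)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


@dataclass
class SyntheticConfig:
    n: int
    seed: int
    marginals: dict[str, object]
    missingness: dict[str, float]
    true_model: TrueModel

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be a positive integer")
        for name in PREDICTORS:
            if name not in self.marginals:
                raise ValidationError(f"marginal spec missing for {name!r}")
            self.marginals[name].validate(name)
        for name, p in self.missingness.items():
            if name == OUTCOME:
                raise ValidationError("the outcome can never be missing")
            if name not in PREDICTORS:
                raise ValidationError(f"missingness refers to unknown field {name!r}")
            if not (0.0 <= p < 1.0):
                raise ValidationError(f"{name}: missing probability {p!r} not in [0, 1)")
            if p > 0.0 and not SCHEMA[name].missing_allowed:
                raise ValidationError(f"{name}: schema does not allow missing values")
        for var in self.true_model.variables:
            if var not in PREDICTORS:
                raise ValidationError(f"true model refers to unknown predictor {var!r}")
            if self.missingness.get(var, 0.0) >= 1.0:
                raise ValidationError(f"outcome-determining covariate {var!r} is entirely missing")

    # -- round-trip serialisation ---------------------------------------
    def to_dict(self) -> dict:
        marg = {}
        for k, v in self.marginals.items():
            if isinstance(v, CategoricalSpec):
                marg[k] = {"probs": dict(v.probs)}
            else:
                marg[k] = {"mean": v.mean, "sd": v.sd, "low": v.low, "high": v.high}
        return {
            "n": self.n,
            "seed": self.seed,
            "marginals": marg,
            "missingness": dict(self.missingness),
            "true_model": {
                "intercept": self.true_model.intercept,
                "coefficients": self.true_model.coefficients,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        marg = {}
        for k, v in d["marginals"].items():
            if "probs" in v:
                marg[k] = CategoricalSpec(dict(v["probs"]))
            else:
                marg[k] = ContinuousSpec(v["mean"], v["sd"], v["low"], v["high"])
        tm = TrueModel(d["true_model"]["intercept"], d["true_model"]["coefficients"])
        return cls(int(d["n"]), int(d["seed"]), marg, dict(d["missingness"]), tm)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _default_marginals() -> dict[str, object]:
    marg: dict[str, object] = {}
    for name in PREDICTORS:
        if SCHEMA[name].kind == "categorical":
            counts = _CAT_COUNTS[name]
            total = sum(counts.values())
            marg[name] = CategoricalSpec({k: v / total for k, v in counts.items()})
        else:
            marg[name] = ContinuousSpec(*_CONT_PARAMS[name])
    return marg


def linear_predictor(df: pd.DataFrame, model: TrueModel) -> np.ndarray:
    """Ground-truth linear predictor (including intercept) per record.

    Requires the model's covariates to be non-missing.
    """
    lp = np.full(len(df), model.intercept, dtype=float)
    for var, coef in model.coefficients.items():
        col = df[var]
        if col.isna().any():
            raise ValidationError(f"linear predictor needs non-missing {var!r}")
        if isinstance(coef, dict):
            lp += col.map(lambda lev: coef.get(lev, 0.0)).to_numpy(dtype=float)
        else:
            lp += float(coef) * col.to_numpy(dtype=float)
    return lp


def calibrate_intercept(
    marginals: dict[str, object],
    coefficients: dict[str, object],
    target_rate: float = STUDY_EVENT_RATE,
    n_mc: int = 400_000,
) -> float:
    """Solve (brentq) for the intercept making the mean simulated event
    probability equal ``target_rate`` under the given covariate marginals.

    The expectation is taken over a large covariate sample drawn with a fixed
    internal seed, so the result is deterministic.
    """
    rng = np.random.default_rng(np.random.SeedSequence(20240207))
    lp0 = np.zeros(n_mc)
    for var, coef in coefficients.items():
        spec = marginals[var]
        if isinstance(spec, CategoricalSpec):
            levels = list(spec.probs)
            draws = rng.choice(len(levels), size=n_mc, p=[spec.probs[l] for l in levels])
            per_level = np.array([coef.get(l, 0.0) for l in levels])
            lp0 += per_level[draws]
        else:
            a = (spec.low - spec.mean) / spec.sd
            b = (spec.high - spec.mean) / spec.sd
            x = truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, size=n_mc, random_state=rng)
            lp0 += float(coef) * x

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + lp0))) - target_rate

    return float(brentq(gap, -30.0, 30.0, xtol=1e-10))


@functools.lru_cache(maxsize=None)
def _calibrated_default_intercept() -> float:
    return calibrate_intercept(_default_marginals(), TRUE_COEFFICIENTS)


def default_config(n: int = 252, seed: int = 0) -> SyntheticConfig:
    """Study-condition configuration: published marginals, missingness and
    ground-truth coefficients, intercept calibrated to the 24.2% event rate."""
    marginals = _default_marginals()
    missingness = {k: v / 252.0 for k, v in _MISSING_COUNTS.items()}
    tm = TrueModel(_calibrated_default_intercept(), TRUE_COEFFICIENTS)
    cfg = SyntheticConfig(n=n, seed=seed, marginals=marginals,
                          missingness=missingness, true_model=tm)
    cfg.validate()
    return cfg


def null_config(n: int = 400, seed: int = 0,
                event_rate: float = STUDY_EVENT_RATE) -> SyntheticConfig:
    """No-signal variant: outcomes independent of every covariate, constant
    event probability ``event_rate``; no missingness."""
    cfg = default_config(n=n, seed=seed)
    cfg.missingness = {}
    cfg.true_model = TrueModel(float(np.log(event_rate / (1 - event_rate))), {})
    cfg.validate()
    return cfg


def generate(config: SyntheticConfig) -> Cohort:
    """Draw a synthetic cohort of exactly ``config.n`` records.

    Covariates are drawn independently per the marginals in schema order; the
    outcome is Bernoulli(expit(true linear predictor)) computed *before*
    missingness; missingness is then applied completely at random per field.
    Deterministic for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    cols: dict[str, object] = {}
    for name in PREDICTORS:
        spec = config.marginals[name]
        if isinstance(spec, CategoricalSpec):
            levels = list(SCHEMA[name].levels)
            p = np.array([spec.probs[l] for l in levels], dtype=float)
            p = p / p.sum()
            idx = rng.choice(len(levels), size=n, p=p)
            cols[name] = pd.Categorical.from_codes(idx, categories=levels)
        else:
            a = (spec.low - spec.mean) / spec.sd
            b = (spec.high - spec.mean) / spec.sd
            cols[name] = truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd,
                                       size=n, random_state=rng)
    df = pd.DataFrame(cols)
    prob = expit(linear_predictor(df, config.true_model))
    y = rng.random(n) < prob
    df[OUTCOME] = pd.Categorical(np.where(y, "yes", "no"), categories=("no", "yes"))
    # MCAR missingness, applied after the outcome draw
    for name in PREDICTORS:
        p_miss = config.missingness.get(name, 0.0)
        if p_miss > 0.0:
            mask = rng.random(n) < p_miss
            if mask.any():
                col = df[name]
                if isinstance(col.dtype, pd.CategoricalDtype):
                    codes = col.cat.codes.to_numpy().copy()
                    codes[mask] = -1
                    df[name] = pd.Categorical.from_codes(codes, categories=col.cat.categories)
                else:
                    vals = col.to_numpy(dtype=float).copy()
                    vals[mask] = np.nan
                    df[name] = vals
    return Cohort(df, name=f"synthetic(n={n},seed={config.seed})")
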