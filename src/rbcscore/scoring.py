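"""Sullivan-style integer point system built from a fitted logistic model.

The fitted log-odds are converted to integer risk points by dividing by a
constant B — the log-odds corresponding to one point, here taken as the
vertebral-body-replacement coefficient — and rounding to the nearest integer
(half away from zero).  Continuous predictors are banded; each band is
represented by a value W and contributes round(beta * (W - W_ref) / B)
points, with the lowest-risk band as the zero-point reference.  A look-up
table then maps every attainable total score to the model's estimated
transfusion probability expit(b0 + base + B * P), where ``base`` collects
the contribution of all zero-point reference values.

The published point system and its score→probability table are also shipped
verbatim as a fixture, since the underlying patient data (and hence the
fitted intercept behind the published table) are not public.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import OUTCOME, SCHEMA, Cohort
from .errors import ScoringError, ValidationError
from .logistic import DEFAULT_DESIGN, DesignSpec, FitResult, column_name

__all__ = [
    "Band",
    "BandSpec",
    "default_hb_bands",
    "ScoreSystem",
    "LookupTable",
    "reorient_to_lowest_risk",
    "derive_points",
    "build_lookup",
    "score_patient",
    "score_cohort",
    "published_coefficients",
    "published_score_fixture",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (the rule that reproduces the
    published points from the published coefficients)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class Band:
    label: str
    lower: float  # -inf allowed
    upper: float  # +inf allowed
    lower_closed: bool
    upper_closed: bool
    rep_value: float  # Sullivan's W

    def contains(self, x: float) -> bool:
        lo = x >= self.lower if self.lower_closed else x > self.lower
        hi = x <= self.upper if self.upper_closed else x < self.upper
        return lo and hi


@dataclass(frozen=True)
class BandSpec:
    """Ordered, contiguous banding of one continuous variable."""

    variable: str
    bands: tuple[Band, ...]
    reference_label: str

    def __post_init__(self):
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ScoringError(f"{self.variable}: duplicate band labels")
        if self.reference_label not in labels:
            raise ScoringError(f"{self.variable}: reference band {self.reference_label!r} unknown")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper != b.lower or a.upper_closed == b.lower_closed:
                raise ScoringError(f"{self.variable}: bands {a.label!r}/{b.label!r} do not tile")
        if any(not np.isfinite(b.rep_value) for b in self.bands):
            raise ScoringError(f"{self.variable}: non-finite representative value")

    @property
    def reference(self) -> Band:
        return next(b for b in self.bands if b.label == self.reference_label)

    @property
    def w_ref(self) -> float:
        return self.reference.rep_value

    def assign(self, x: float) -> Band:
        for b in self.bands:
            if b.contains(x):
                return b
        raise ScoringError(f"{self.variable}: value {x!r} falls in no band")


def default_hb_bands() -> BandSpec:
    """Hemoglobin banding <8, [8;12), [12;16], >16 g/dL.

    Representative values: band midpoints 10 and 14 for the bounded bands,
    7.5 for "<8" (midpoint of the observed minimum 7.0 and the band edge),
    and the boundary value 16 for the lowest-risk reference band ">16" —
    the convention that reproduces the published points 7/5/2/0.
    """
    inf = float("inf")
    return BandSpec(
        variable="hb",
        bands=(
            Band("<8", -inf, 8.0, False, False, 7.5),
            Band("[8,12)", 8.0, 12.0, True, False, 10.0),
            Band("[12,16]", 12.0, 16.0, True, True, 14.0),
            Band(">16", 16.0, inf, False, False, 16.0),
        ),
        reference_label=">16",
    )


@dataclass
class ScoreSystem:
    """Integer risk points per category/band plus the constant B."""

    b: float  # log-odds per point
    categorical_points: dict[str, dict[str, int]]  # var -> level -> points
    banded_points: dict[str, dict[str, int]]  # var -> band label -> points
    band_specs: dict[str, BandSpec]
    provenance: str = "derived"

    def __post_init__(self):
        if self.b <= 0:
            raise ScoringError("B must be positive")
        for var, pts in {**self.categorical_points, **self.banded_points}.items():
            if any(p < 0 for p in pts.values()):
                raise ScoringError(f"{var}: negative risk points")
            if min(pts.values()) != 0:
                raise ScoringError(f"{var}: some category must carry 0 points")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.categorical_points) + tuple(self.banded_points)

    @property
    def max_score(self) -> int:
        return sum(max(p.values()) for p in self.categorical_points.values()) + \
            sum(max(p.values()) for p in self.banded_points.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "b": self.b,
                "categorical_points": self.categorical_points,
                "banded_points": self.banded_points,
                "bands": {
                    v: [
                        [b.label, b.lower, b.upper, b.lower_closed, b.upper_closed, b.rep_value]
                        for b in s.bands
                    ]
                    for v, s in self.band_specs.items()
                },
                "reference_bands": {v: s.reference_label for v, s in self.band_specs.items()},
                "max_score": self.max_score,
                "provenance": self.provenance,
            },
            sort_keys=True,
        )

    def to_text(self) -> str:
        """Human-readable table in the published layout."""
        lines = [f"Risk factor points (B = {self.b} log-odds per point)"]
        for var, pts in self.categorical_points.items():
            lines.append(var)
            for lev, p in pts.items():
                lines.append(f"  {lev}: {p}")
        for var, pts in self.banded_points.items():
            lines.append(var)
            for lab, p in pts.items():
                lines.append(f"  {lab}: {p}")
        lines.append(f"maximum total score: {self.max_score}")
        return "\n".join(lines)


@dataclass
class LookupTable:
    """Total score -> estimated transfusion probability (fraction in (0,1))."""

    probabilities: dict[int, float]

    def __post_init__(self):
        scores = sorted(self.probabilities)
        if scores != list(range(scores[0], scores[-1] + 1)) or scores[0] != 0:
            raise ScoringError("lookup domain must be exactly 0..max_score")
        probs = [self.probabilities[s] for s in scores]
        if any(not (0.0 < p < 1.0) for p in probs):
            raise ScoringError("lookup probabilities must lie in (0, 1)")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ScoringError("lookup probabilities must be strictly increasing")

    def __getitem__(self, score: int) -> float:
        try:
            return self.probabilities[int(score)]
        except KeyError:
            raise ScoringError(f"score {score} outside lookup domain") from None

    @property
    def max_score(self) -> int:
        return max(self.probabilities)

    def to_json(self) -> str:
        return json.dumps({str(k): v for k, v in sorted(self.probabilities.items())})

    def to_text(self) -> str:
        return "\n".join(f"{s}\t{100 * p:.2f}%" for s, p in sorted(self.probabilities.items()))


# ---------------------------------------------------------------------------
# Construction from a fitted model
# ---------------------------------------------------------------------------

def _grouped_terms(fit: FitResult) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Split fit coefficients into categorical {var: {level: beta}} and
    continuous {var: beta} groups based on the ``var[level]`` naming."""
    cat: dict[str, dict[str, float]] = {}
    cont: dict[str, float] = {}
    for name, beta in fit.coefficients.items():
        if "[" in name:
            var, level = name[:-1].split("[", 1)
            cat.setdefault(var, {})[level] = beta
        else:
            cont[name] = beta
    return cat, cont


def reorient_to_lowest_risk(fit: FitResult, spec: DesignSpec = DEFAULT_DESIGN
                            ) -> tuple[FitResult, DesignSpec]:
    """Re-express every categorical factor against its lowest-risk category.

    Each factor's minimum coefficient (the implicit 0 of the current
    reference included) is shifted to zero and absorbed into the intercept,
    so predicted probabilities are unchanged and all categorical
    coefficients become non-negative.  A fit already referenced at the
    lowest-risk categories is returned unchanged.
    """
    cat, _cont = _grouped_terms(fit)
    coefficients = dict(fit.coefficients)
    intercept = fit.intercept
    new_spec = spec
    for var, levels in cat.items():
        ref = spec.reference(var)
        full = dict(levels)
        full[ref] = 0.0
        min_level = min(full, key=lambda l: (full[l], l))
        shift = full[min_level]
        if shift >= 0.0 and min_level == ref:
            continue
        intercept += shift
        for level in full:
            coefficients.pop(column_name(var, level), None)
        for level, beta in full.items():
            if level != min_level:
                coefficients[column_name(var, level)] = beta - shift
        new_spec = new_spec.with_reference(var, min_level)
    out = replace(fit, intercept=intercept, coefficients=coefficients,
                  standard_errors={})
    return out, new_spec


def derive_points(fit: FitResult, b_source: str,
                  bands: Iterable[BandSpec] = (),
                  spec: DesignSpec = DEFAULT_DESIGN) -> ScoreSystem:
    """Convert fitted log-odds into integer risk points.

    ``b_source`` names a binary (single-dummy) factor whose coefficient
    defines B, the log-odds worth one point.  Categorical points are
    round(beta / B); banded continuous points are
    round(beta * (W_band - W_ref) / B).  All points must come out
    non-negative — reorient to the lowest-risk references first.
    """
    cat, cont = _grouped_terms(fit)
    band_specs = {bs.variable: bs for bs in bands}

    if b_source in cat:
        dummies = cat[b_source]
        if len(dummies) != 1:
            raise ScoringError(
                f"B-source {b_source!r} must be a binary factor with one dummy, "
                f"found levels {sorted(dummies)}"
            )
        B = next(iter(dummies.values()))
    elif b_source in fit.coefficients:
        B = fit.coefficients[b_source]
    else:
        raise ScoringError(f"B-source term {b_source!r} not in the fitted model")
    if not B > 0:
        raise ScoringError(f"B must be positive after reorientation, got {B!r}")

    categorical_points: dict[str, dict[str, int]] = {}
    for var, levels in cat.items():
        ref = spec.reference(var)
        pts = {ref: 0}
        for level, beta in levels.items():
            if beta < 0:
                raise ScoringError(
                    f"{var}[{level}] has negative log-odds {beta}; "
                    "apply reorient_to_lowest_risk first"
                )
            pts[level] = round_half_away(beta / B)
        # keep schema level order where known
        order = SCHEMA[var].levels if var in SCHEMA else tuple(pts)
        categorical_points[var] = {l: pts[l] for l in order if l in pts}

    banded_points: dict[str, dict[str, int]] = {}
    for var, beta in cont.items():
        if var not in band_specs:
            raise ScoringError(f"continuous term {var!r} needs a band specification")
        bs = band_specs[var]
        pts = {}
        for band in bs.bands:
            raw = beta * (band.rep_value - bs.w_ref) / B
            if raw < -0.5:
                raise ScoringError(
                    f"{var} band {band.label!r} scores negative points ({raw:.2f}); "
                    "the reference band must be the lowest-risk band"
                )
            pts[band.label] = round_half_away(max(raw, 0.0))
        banded_points[var] = pts

    return ScoreSystem(
        b=float(B),
        categorical_points=categorical_points,
        banded_points=banded_points,
        band_specs=band_specs,
        provenance="derived",
    )


def build_lookup(fit: FitResult, system: ScoreSystem) -> LookupTable:
    """Score -> probability table: expit(b0 + base + B*P) for P = 0..max.

    ``base`` is the summed linear-predictor contribution of all zero-point
    reference values: 0 for categorical references, beta * W_ref for each
    banded continuous term.  Strictly increasing since B > 0.
    """
    if fit.intercept is None or not np.isfinite(fit.intercept):
        raise ScoringError("a finite fitted intercept is required for the lookup table")
    _cat, cont = _grouped_terms(fit)
    base = 0.0
    for var in system.banded_points:
        if var not in cont:
            raise ScoringError(f"banded term {var!r} missing from the fit")
        base += cont[var] * system.band_specs[var].w_ref
    probs = {
        P: float(expit(fit.intercept + base + system.b * P))
        for P in range(system.max_score + 1)
    }
    return LookupTable(probs)


# ---------------------------------------------------------------------------
# Patient / cohort scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreResult:
    total: int
    probability: float
    per_term: dict[str, int]


def score_patient(record: Mapping, system: ScoreSystem,
                  lookup: LookupTable | None = None) -> ScoreResult:
    """Total risk points (and lookup probability) for one patient record.

    ``record`` maps variable names to values (categorical level strings,
    numbers for banded terms).  All score terms must be present and
    non-missing.
    """
    missing = [
        t for t in system.terms
        if t not in record or record[t] is None or
        (isinstance(record[t], float) and math.isnan(record[t]))
        or pd.isna(record[t])
    ]
    if missing:
        raise ScoringError(f"record is missing score term(s): {', '.join(missing)}")
    per_term: dict[str, int] = {}
    for var, pts in system.categorical_points.items():
        level = str(record[var])
        if level not in pts:
            raise ScoringError(f"{var}: level {level!r} has no point entry")
        per_term[var] = pts[level]
    for var, pts in system.banded_points.items():
        band = system.band_specs[var].assign(float(record[var]))
        per_term[var] = pts[band.label]
    total = int(sum(per_term.values()))
    prob = lookup[total] if lookup is not None else float("nan")
    return ScoreResult(total=total, probability=prob, per_term=per_term)


def score_cohort(cohort: Cohort, system: ScoreSystem) -> tuple[pd.Series, int]:
    """Vectorised total scores for a cohort.

    Returns (scores, n_dropped): records missing any score term get NaN and
    are counted as dropped.
    """
    df = cohort.data
    ok = df[list(system.terms)].notna().all(axis=1).to_numpy()
    total = np.zeros(cohort.n, dtype=float)
    for var, pts in system.categorical_points.items():
        total += df[var].map(lambda l: pts.get(l, np.nan)).to_numpy(dtype=float)
    for var, pts in system.banded_points.items():
        bs = system.band_specs[var]
        vals = df[var].to_numpy(dtype=float)
        banded = np.full(cohort.n, np.nan)
        for band in bs.bands:
            lo = vals >= band.lower if band.lower_closed else vals > band.lower
            hi = vals <= band.upper if band.upper_closed else vals < band.upper
            banded[lo & hi] = pts[band.label]
        total += banded
    total[~ok] = np.nan
    return pd.Series(total, name="score"), int((~ok).sum())


# ---------------------------------------------------------------------------
# Published artifact (point system and look-up table)
# ---------------------------------------------------------------------------

#: published per-term log-odds of the final four-covariate model
_PUBLISHED_COEFFS = {
    "surgery_type[thoracic]": 0.267,
    "surgery_type[lumbar]": 1.099,
    "surgery_type[combination]": 1.783,
    "vbr[yes]": 0.841,
    "stages[1]": 0.593,
    "stages[2]": 1.805,
    "stages[3]": 2.260,
    "stages[gt3]": 2.122,
    "hb": -0.665,
}

#: published score -> probability table (percent)
_PUBLISHED_LOOKUP_PERCENT = {
    0: 0.13, 1: 0.29, 2: 0.67, 3: 1.54, 4: 3.5, 5: 7.76, 6: 16.32,
    7: 31.13, 8: 51.16, 9: 70.82, 10: 84.91, 11: 92.88, 12: 96.8, 13: 98.59,
}


def published_coefficients() -> FitResult:
    """The published final-model coefficients as a FitResult.

    The intercept behind the published look-up table is not public, so it is
    NaN here; use :func:`published_score_fixture` for probabilities.
    """
    return FitResult(
        intercept=float("nan"),
        coefficients=dict(_PUBLISHED_COEFFS),
        converged=True,
        n_used=251,
    )


def published_score_fixture() -> tuple[ScoreSystem, LookupTable]:
    """The published point system and look-up table, verbatim."""
    bands = default_hb_bands()
    system = ScoreSystem(
        b=0.841,
        categorical_points={
            "surgery_type": {"cervical": 0, "thoracic": 0, "lumbar": 1, "combination": 2},
            "vbr": {"no": 0, "yes": 1},
            "stages": {"0": 0, "1": 1, "2": 2, "3": 3, "gt3": 3},
        },
        banded_points={"hb": {"<8": 7, "[8,12)": 5, "[12,16]": 2, ">16": 0}},
        band_specs={"hb": bands},
        provenance="published",
    )
    lookup = LookupTable({k: v / 100.0 for k, v in _PUBLISHED_LOOKUP_PERCENT.items()})
    return system, lookup
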