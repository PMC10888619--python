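"""Cohort data model and CSV input/output.

A cohort is one surgery episode per row: 18 pre-operative predictors plus a
binary red-blood-cell transfusion outcome.  Categorical variables (including
yes/no flags) are stored as pandas ``Categorical`` columns with fixed level
sets; continuous variables are float64 with ``NaN`` marking a missing value.

The on-disk format is plain UTF-8 CSV with a mandatory header; an empty cell
or the token ``NA`` denotes a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ColumnSpec",
    "SCHEMA",
    "PREDICTORS",
    "OUTCOME",
    "COLUMNS",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "summarize",
    "complete_cases",
    "complete_case_mask",
]


@dataclass(frozen=True)
class ColumnSpec:
    """Schema entry for one cohort column."""

    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] | None = None
    missing_allowed: bool = False
    lower: float | None = None  # open lower bound unless lower_closed
    lower_closed: bool = False

    def check_value(self, x: float) -> bool:
        """Range check for a non-missing continuous value."""
        if not np.isfinite(x):
            return False
        if self.lower is not None:
            return x >= self.lower if self.lower_closed else x > self.lower
        return True


_YESNO = ("no", "yes")

#: Column order of the on-disk CSV and of every encoded design matrix.
SCHEMA: dict[str, ColumnSpec] = {
    s.name: s
    for s in [
        ColumnSpec("sex", "categorical", ("male", "female")),
        ColumnSpec("age", "continuous", lower=0.0, lower_closed=True),
        ColumnSpec("height", "continuous", missing_allowed=True, lower=0.0),
        ColumnSpec("weight", "continuous", missing_allowed=True, lower=0.0),
        ColumnSpec("asa", "categorical", ("1", "2", "ge3"), missing_allowed=True),
        ColumnSpec("anticoagulant", "categorical", _YESNO),
        ColumnSpec("prior_surgeries", "categorical", ("0", "1", "2")),
        ColumnSpec("hb", "continuous", lower=0.0),
        ColumnSpec("quick", "continuous", missing_allowed=True, lower=0.0),
        ColumnSpec("inr", "continuous", missing_allowed=True, lower=0.0),
        ColumnSpec("ptt", "continuous", missing_allowed=True, lower=0.0),
        ColumnSpec("thrombocytes", "continuous", missing_allowed=True, lower=0.0),
        ColumnSpec("fracture", "categorical", _YESNO),
        ColumnSpec("tumor", "categorical", _YESNO),
        ColumnSpec(
            "surgery_type",
            "categorical",
            ("cervical", "thoracic", "lumbar", "combination"),
        ),
        ColumnSpec("incision", "categorical", ("dorsal", "ventral")),
        ColumnSpec("vbr", "categorical", _YESNO, missing_allowed=True),
        ColumnSpec("stages", "categorical", ("0", "1", "2", "3", "gt3")),
        ColumnSpec("transfused", "categorical", _YESNO),
    ]
}

OUTCOME = "transfused"
PREDICTORS: tuple[str, ...] = tuple(c for c in SCHEMA if c != OUTCOME)
COLUMNS: tuple[str, ...] = tuple(SCHEMA)

_MISSING_TOKENS = ("", "NA")


@dataclass
class Cohort:
    """An ordered collection of surgery episodes.

    ``data`` holds one row per episode with the schema columns in canonical
    order; the index is always ``0..n-1``.
    """

    data: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.data = _coerce_frame(self.data)
        if len(self.data) < 1:
            raise ValidationError("a cohort must contain at least one record")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def y(self) -> np.ndarray:
        """Outcome as a 0/1 integer vector."""
        return (self.data[OUTCOME] == "yes").to_numpy(dtype=np.int64)

    @property
    def n_events(self) -> int:
        return int(self.y.sum())

    def require_both_classes(self) -> None:
        """Raise unless at least one event and one non-event are present
        (needed by stratified splitting and grouped summaries)."""
        ne = self.n_events
        if ne == 0 or ne == self.n:
            raise ValidationError(
                f"cohort {self.name!r} needs at least one event and one "
                f"non-event ({ne}/{self.n} events found)"
            )

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Cohort":
        """Row subset by positional indices; order of ``indices`` preserved."""
        df = self.data.iloc[np.asarray(indices, dtype=np.intp)].reset_index(drop=True)
        return Cohort(df, name or self.name)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n

    def equals(self, other: "Cohort") -> bool:
        return self.data.equals(other.data)


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a raw DataFrame into schema dtypes."""
    missing_cols = [c for c in SCHEMA if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    out = {}
    problems: list[tuple[int, str, str]] = []
    for name, spec in SCHEMA.items():
        col = df[name]
        if spec.kind == "continuous":
            vals = pd.to_numeric(col, errors="coerce").astype(np.float64)
            orig_na = col.isna()
            bad = vals.isna() & ~orig_na
            for i in np.flatnonzero(bad.to_numpy()):
                problems.append((int(i), name, f"unparseable number {col.iloc[i]!r}"))
            if not spec.missing_allowed:
                for i in np.flatnonzero(orig_na.to_numpy()):
                    problems.append((int(i), name, "missing value not allowed"))
            ok = vals.notna()
            rng_bad = ok & ~vals.map(spec.check_value).astype(bool)
            for i in np.flatnonzero(rng_bad.to_numpy()):
                problems.append((int(i), name, f"out-of-range value {vals.iloc[i]!r}"))
            out[name] = vals
        else:
            s = col.astype("object").where(col.notna(), None)
            s = s.map(lambda v: v if v is None else str(v))
            cat = pd.Categorical(s, categories=spec.levels)
            invalid = pd.isna(cat) & pd.notna(np.asarray(s, dtype=object))
            for i in np.flatnonzero(invalid):
                problems.append((int(i), name, f"level {s.iloc[i]!r} not in {spec.levels}"))
            if not spec.missing_allowed:
                base_na = pd.isna(np.asarray(s, dtype=object))
                for i in np.flatnonzero(base_na):
                    problems.append((int(i), name, "missing value not allowed"))
            out[name] = pd.Series(cat)
    if problems:
        msgs = "; ".join(f"row {r}: {f}: {m}" for r, f, m in problems[:10])
        raise ValidationError(
            f"{len(problems)} invalid field(s): {msgs}", details=problems
        )
    frame = pd.DataFrame(out, columns=list(SCHEMA))
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def read_cohort(path, column_map: Mapping[str, str] | None = None,
                name: str | None = None) -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    path
        File path or readable buffer.
    column_map
        Optional mapping from alternate header names to schema names.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    raw = raw.mask(raw.isin(_MISSING_TOKENS))
    label = name if name is not None else (str(path) if isinstance(path, str) else "cohort")
    try:
        return Cohort(raw, name=label)
    except ValidationError as exc:
        # shift reported rows to CSV line numbers (header is line 1)
        details = [(r + 2, f, m) for r, f, m in exc.details]
        msgs = "; ".join(f"line {r}: {f}: {m}" for r, f, m in details[:10])
        raise ValidationError(f"invalid CSV cohort: {msgs}", details=details) from None


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; ``read_cohort`` round-trips it field-for-field.

    Output is byte-stable for a given cohort: fixed column order, ``\\n`` line
    terminator, missing values as empty cells.
    """
    df = cohort.data.copy()
    for name, spec in SCHEMA.items():
        if spec.kind == "continuous":
            df[name] = df[name].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        else:
            df[name] = df[name].astype(object).where(df[name].notna(), "")
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Descriptive summaries (layout of the cohort-description tables)
# ---------------------------------------------------------------------------

def _summary_block(df: pd.DataFrame, group: str) -> list[dict]:
    rows = []
    n_grp = len(df)
    for name, spec in SCHEMA.items():
        if name == OUTCOME:
            continue
        col = df[name]
        miss = int(col.isna().sum())
        if spec.kind == "continuous":
            v = col.dropna().to_numpy(dtype=float)
            stats = {
                "mean": float(np.mean(v)) if v.size else np.nan,
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else (0.0 if v.size else np.nan),
                "median": float(np.median(v)) if v.size else np.nan,
                "min": float(np.min(v)) if v.size else np.nan,
                "max": float(np.max(v)) if v.size else np.nan,
            }
            for item, val in stats.items():
                rows.append(dict(variable=name, item=item, group=group, value=val))
            rows.append(dict(variable=name, item="missing", group=group, value=float(miss)))
        else:
            counts = col.value_counts(dropna=True)
            for lev in spec.levels:
                c = int(counts.get(lev, 0))
                rows.append(dict(variable=name, item=f"{lev}:count", group=group, value=float(c)))
                rows.append(dict(variable=name, item=f"{lev}:percent", group=group,
                                 value=100.0 * c / n_grp if n_grp else np.nan))
            rows.append(dict(variable=name, item="missing", group=group, value=float(miss)))
    return rows


def summarize(cohort: Cohort, group_by_outcome: bool = False) -> pd.DataFrame:
    """Descriptive summary: mean (SD), median [min, max] for continuous
    variables; count (percent) plus missing counts for categorical variables.

    Returns a long-format frame with columns ``variable, item, group, value``.
    With ``group_by_outcome`` the non-transfused / transfused groups are
    summarised alongside the overall column (both classes must be present).
    """
    if group_by_outcome:
        cohort.require_both_classes()
    rows = _summary_block(cohort.data, "overall")
    if group_by_outcome:
        for label, lev in (("no_transfusion", "no"), ("transfusion", "yes")):
            sub = cohort.data[cohort.data[OUTCOME] == lev]
            rows.extend(_summary_block(sub, label))
    return pd.DataFrame(rows, columns=["variable", "item", "group", "value"])


def format_summary(summary: pd.DataFrame) -> str:
    """Pretty text rendering of a :func:`summarize` frame."""
    wide = summary.pivot_table(index=["variable", "item"], columns="group",
                               values="value", sort=False, aggfunc="first")
    return wide.to_string(float_format=lambda v: f"{v:.3g}")


# ---------------------------------------------------------------------------
# Complete-case filtering
# ---------------------------------------------------------------------------

def complete_case_mask(cohort: Cohort, variables: Iterable[str]) -> np.ndarray:
    """Boolean row mask: True where none of ``variables`` (nor the outcome)
    is missing."""
    variables = list(variables)
    unknown = [v for v in variables if v not in PREDICTORS]
    if unknown:
        raise SchemaError(f"unknown predictor(s): {', '.join(unknown)}")
    cols = variables + [OUTCOME]
    return cohort.data[cols].notna().all(axis=1).to_numpy()


def complete_cases(cohort: Cohort, variables: Iterable[str]) -> Cohort:
    """Sub-cohort with no missing values among ``variables`` and the outcome.

    Row order is preserved.  The analysis convention is complete-case
    filtering per considered model, so the variable set is typically one
    candidate model's predictors.
    """
    mask = complete_case_mask(cohort, variables)
    if not mask.any():
        raise ValidationError(
            f"complete-case filtering on {sorted(set(variables))} removes every "
            f"record of cohort {cohort.name!r}"
        )
    return cohort.subset(np.flatnonzero(mask))
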