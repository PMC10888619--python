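"""Run artifacts: score-distribution report and reproducibility manifest.

The score-distribution report is the tabular analogue of the published
score-frequency figure: per observed total score, its relative frequency in
the cohort, the observed transfusion frequency in that stratum, and the
look-up table's estimated probability.  Records not scoreable (missing a
score term) are dropped and counted, mirroring the complete-case logic that
put n = 251 behind the published figure.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OUTCOME, Cohort
from .errors import ValidationError
from .scoring import LookupTable, ScoreSystem, score_cohort

__all__ = ["ScoreDistributionReport", "score_distribution", "run_manifest"]


@dataclass
class ScoreDistributionReport:
    """Per-score row: n, relative frequency, observed event rate, estimated
    probability.  ``dropped`` counts unscoreable records."""

    table: pd.DataFrame
    dropped: int
    n_scoreable: int

    def __post_init__(self):
        freq = self.table["rel_freq"].to_numpy()
        if abs(freq.sum() - 1.0) > 1e-9:
            raise ValidationError("relative frequencies must sum to 1")
        obs = self.table["observed_rate"].to_numpy()
        if ((obs < 0) | (obs > 1)).any():
            raise ValidationError("observed frequencies must lie in [0, 1]")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")


def score_distribution(cohort: Cohort, system: ScoreSystem,
                       lookup: LookupTable) -> ScoreDistributionReport:
    """Tabulate the cohort's total-score distribution against the lookup."""
    scores, dropped = score_cohort(cohort, system)
    ok = scores.notna().to_numpy()
    if not ok.any():
        raise ValidationError("no scoreable records in the cohort")
    s = scores[ok].astype(int).to_numpy()
    y = cohort.y[ok]
    n_ok = int(ok.sum())
    rows = []
    for val in np.unique(s):
        in_stratum = s == val
        n_s = int(in_stratum.sum())
        rows.append(
            {
                "score": int(val),
                "n": n_s,
                "rel_freq": n_s / n_ok,
                "observed_rate": float(y[in_stratum].mean()),
                "estimated_prob": lookup[int(val)],
            }
        )
    table = pd.DataFrame(rows, columns=["score", "n", "rel_freq",
                                        "observed_rate", "estimated_prob"])
    report = ScoreDistributionReport(table=table, dropped=dropped, n_scoreable=n_ok)
    assert report.n_scoreable + report.dropped == cohort.n
    return report


def run_manifest(path, config: dict, seeds: dict, versions: dict | None = None) -> dict:
    """Write a JSON manifest sufficient to reproduce a run bit-for-bit.

    ``config`` echoes every pipeline setting (J, K, train fraction,
    complete-case mode, ...); ``seeds`` every random seed in play.
    """
    if versions is None:
        import scipy

        from . import __version__

        versions = {
            "rbcscore": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        }
    manifest = {"config": config, "seeds": seeds, "versions": versions}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
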