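"""Batch validation by parameter recovery: per-subset Pearson correlation
between pipeline-estimated and reference subset percentages across cases.

The reference is either simulator ground truth or a manual-gating table
(CSV: case id, tube, subset, percent).  An r above the threshold (0.9 by
default) counts as strong concordance for that subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedCorrelationError(ValueError):
    """Zero variance on one side makes Pearson r undefined."""


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise UndefinedCorrelationError("zero variance in an argument")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ConcordanceReport:
    table: pd.DataFrame        # subset, tube, n, r, mean_bias, passed
    threshold: float
    scatter_data: dict[tuple[str, str], pd.DataFrame]

    def passed(self, tube: str, subset: str) -> bool:
        row = self.table[(self.table["tube"] == tube)
                         & (self.table["subset"] == subset)]
        return bool(row["passed"].iloc[0]) if not row.empty else False

    def r_of(self, tube: str, subset: str) -> float:
        row = self.table[(self.table["tube"] == tube)
                         & (self.table["subset"] == subset)]
        if row.empty:
            raise KeyError(f"no concordance row for {tube}/{subset}")
        return float(row["r"].iloc[0])

    def to_dict(self) -> dict:
        return {"threshold": self.threshold,
                "subsets": self.table.to_dict(orient="records")}


def estimates_from_report(report) -> dict[tuple[str, str], float]:
    """(tube, subset) -> percent of lymphocytes, from a case Report."""
    out = {}
    for tube, table in report.tables.items():
        for _, row in table.rows.iterrows():
            out[(tube, row["subset"])] = float(row["pct_of_lymphocytes"])
    return out


def reference_from_truth(truth, tubes=("ALPS-T", "ACT-T", "ALPS-B"),
                         ) -> dict[tuple[str, str], float]:
    """(tube, subset) -> true percent of lymphocytes, from a TruthTable."""
    out = {}
    for tube in tubes:
        for subset, pct in truth.subset_percentages(tube).items():
            out[(tube, subset)] = pct
    return out


def evaluate_batch(cases: list[tuple[dict, dict]], threshold: float = 0.9,
                   ) -> ConcordanceReport:
    """Correlate estimated vs reference percentages subset by subset.

    ``cases`` is a list of (estimates, reference) dicts keyed by
    (tube, subset).  Subsets present in fewer than half the cases are
    excluded (with a warning row carrying n only); zero-variance references
    surface as r = NaN rather than a silent pass.
    """
    keys: dict[tuple[str, str], int] = {}
    for est, ref in cases:
        for k in est:
            if k in ref:
                keys[k] = keys.get(k, 0) + 1
    n_cases = len(cases)
    rows = []
    scatter: dict[tuple[str, str], pd.DataFrame] = {}
    for key, cnt in sorted(keys.items()):
        tube, subset = key
        if subset == "lymphocytes":
            continue
        if cnt <= n_cases / 2:
            rows.append({"tube": tube, "subset": subset, "n": cnt,
                         "r": np.nan, "mean_bias": np.nan, "passed": False,
                         "note": "present in <= 50% of cases; excluded"})
            continue
        est_v, ref_v = [], []
        for est, ref in cases:
            if key in est and key in ref:
                est_v.append(est[key])
                ref_v.append(ref[key])
        est_v = np.array(est_v)
        ref_v = np.array(ref_v)
        try:
            r = pearson_r(est_v, ref_v)
            note = ""
        except UndefinedCorrelationError:
            r = np.nan
            note = "undefined correlation (zero variance)"
        rows.append({"tube": tube, "subset": subset, "n": len(est_v),
                     "r": r, "mean_bias": float(np.mean(est_v - ref_v)),
                     "passed": bool(r >= threshold) if np.isfinite(r)
                     else False,
                     "note": note})
        scatter[key] = pd.DataFrame({"estimate": est_v, "reference": ref_v})
    return ConcordanceReport(table=pd.DataFrame(rows), threshold=threshold,
                             scatter_data=scatter)
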