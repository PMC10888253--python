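"""Case report assembly: subset enumeration, diagnostic-criteria evaluation,
reference-range flags, pattern interpretation, machine-readable output.

Percentages are always recomputed from counts.  Each subset's percent of
lymphocytes uses its own tube's lymphocyte denominator.  The pattern layer
emits interpretation codes with the triggering values spelled out — never a
clinical diagnosis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apc import NON_LYMPHOCYTE_LABELS, LabeledEvents
from .panel import ALPSCriteria, PanelConfig, ReferenceRanges, SubsetDef


class EnumerationError(ValueError):
    pass


@dataclass
class SubsetTable:
    rows: pd.DataFrame            # subset, tube, count, pct_of_parent, pct_of_lymphs
    lymphocyte_count: int
    tube_name: str

    def pct_of_lymphs(self, subset: str) -> float:
        r = self.rows[self.rows["subset"] == subset]
        if r.empty:
            raise KeyError(f"subset {subset!r} not in table")
        return float(r["pct_of_lymphocytes"].iloc[0])

    def count(self, subset: str) -> int:
        r = self.rows[self.rows["subset"] == subset]
        if r.empty:
            raise KeyError(f"subset {subset!r} not in table")
        return int(r["count"].iloc[0])


def _subtree_names(name: str, subsets: list[SubsetDef]) -> set[str]:
    out = {name}
    changed = True
    while changed:
        changed = False
        for s in subsets:
            if s.parent in out and s.name not in out and s.axis == "primary":
                out.add(s.name)
                changed = True
    return out


def enumerate_subsets(labeled: LabeledEvents,
                      subsets: list[SubsetDef]) -> SubsetTable:
    """Counts and percentages per taxonomy subset.  A subset's count is the
    number of events whose deepest label lies in its subtree; light-chain
    subsets count from the secondary axis.  Errors when the tube has zero
    lymphocytes (nothing to report against)."""
    labels = labeled.labels
    lineages = labeled.lineages
    is_lymph = ~np.isin(lineages.astype(str), NON_LYMPHOCYTE_LABELS)
    n_lymph = int(is_lymph.sum())
    if n_lymph == 0:
        raise EnumerationError(
            f"tube {labeled.tube_name}: zero lymphocytes after gating")

    counts: dict[str, int] = {"lymphocytes": n_lymph}
    primary = [s for s in subsets if s.axis == "primary"]
    for s in primary:
        names = _subtree_names(s.name, primary)
        counts[s.name] = int(np.isin(labels.astype(str), list(names)).sum())
    for s in subsets:
        if s.axis == "light_chain":
            counts[s.name] = int((labeled.light_chain == s.name).sum())

    parent_of = {s.name: s.parent for s in subsets}
    parent_of["lymphocytes"] = None
    rows = []
    for s in [SubsetDef("lymphocytes", "", labeled.tube_name)] + list(subsets):
        cnt = counts.get(s.name, 0)
        parent = parent_of.get(s.name)
        denom = counts.get(parent, 0) if parent else None
        rows.append({
            "subset": s.name,
            "tube": labeled.tube_name,
            "parent": parent or "",
            "count": cnt,
            "pct_of_parent": (100.0 * cnt / denom) if denom else
            (100.0 if parent is None else 0.0),
            "pct_of_lymphocytes": 100.0 * cnt / n_lymph,
        })
    df = pd.DataFrame(rows)
    # drop children whose count exceeding parent would signal a logic bug
    return SubsetTable(rows=df, lymphocyte_count=n_lymph,
                       tube_name=labeled.tube_name)


@dataclass
class ALPSResult:
    dnt_pct_of_lymphs: float
    dnt_pct_of_cd3: float
    flag: bool
    criteria: ALPSCriteria

    def to_dict(self) -> dict:
        return {"dnt_pct_of_lymphs": self.dnt_pct_of_lymphs,
                "dnt_pct_of_cd3": self.dnt_pct_of_cd3,
                "flag": bool(self.flag),
                "thresholds": {
                    "pct_of_lymphs": self.criteria.dnt_pct_of_lymphs,
                    "pct_of_cd3": self.criteria.dnt_pct_of_cd3}}


DNT_SUBSET = "TCRab+ DNT cells"
T_SUBSET = "T cells"


def evaluate_alps(table: SubsetTable, criteria: ALPSCriteria) -> ALPSResult:
    """TCRab+ DNT as % of lymphocytes and % of CD3+ T; the flag is the OR of
    the two threshold exceedances."""
    try:
        dnt = table.count(DNT_SUBSET)
        t = table.count(T_SUBSET)
    except KeyError as exc:
        raise EnumerationError(f"missing row for ALPS evaluation: {exc}")
    pct_lymphs = 100.0 * dnt / table.lymphocyte_count
    pct_cd3 = 100.0 * dnt / t if t else 0.0
    flag = (pct_lymphs > criteria.dnt_pct_of_lymphs) or \
           (pct_cd3 > criteria.dnt_pct_of_cd3)
    return ALPSResult(dnt_pct_of_lymphs=pct_lymphs, dnt_pct_of_cd3=pct_cd3,
                      flag=flag, criteria=criteria)


def apply_reference_ranges(tables: dict[str, SubsetTable],
                           ranges: ReferenceRanges) -> list[dict]:
    """One flag per subset whose percent-of-denominator falls outside its
    [low, high] range; direction recorded."""
    flags = []
    for subset, (low, high, denom) in ranges.ranges.items():
        found = False
        for table in tables.values():
            try:
                cnt = table.count(subset)
                dcount = (table.lymphocyte_count if denom == "lymphocytes"
                          else table.count(denom))
            except KeyError:
                continue
            found = True
            value = 100.0 * cnt / dcount if dcount else 0.0
            if low is not None and value < low:
                flags.append({"subset": subset, "value": value,
                              "bound": low, "direction": "low",
                              "denominator": denom})
            elif high is not None and value > high:
                flags.append({"subset": subset, "value": value,
                              "bound": high, "direction": "high",
                              "denominator": denom})
        if not found:
            raise EnumerationError(
                f"reference range for unknown subset {subset!r}")
    return flags


XLA_B_THRESHOLD = 0.1   # % of lymphocytes


def evaluate_patterns(tables: dict[str, SubsetTable], flags: list[dict],
                      alps: ALPSResult) -> list[dict]:
    """Interpretation codes with human-readable rationale.

    ALPS_PATTERN  — the DNT diagnostic screen flagged.
    DIGEORGE_PATTERN — CD45RA+ T low AND CD45RO+ T high AND switched memory
    B low (the reciprocal naive/memory shift with poor class switching).
    XLA_PATTERN   — B cells essentially absent (<= 0.1% of lymphocytes).
    NORMAL        — nothing above fired.
    """
    out = []
    if alps.flag:
        out.append({
            "code": "ALPS_PATTERN",
            "rationale": (
                f"TCRab+ DNT = {alps.dnt_pct_of_lymphs:.2f}% of lymphocytes "
                f"and {alps.dnt_pct_of_cd3:.2f}% of CD3+ T cells "
                f"(thresholds {alps.criteria.dnt_pct_of_lymphs}% / "
                f"{alps.criteria.dnt_pct_of_cd3}%, OR logic)")})

    def flagged(subset, direction):
        return next((f for f in flags if f["subset"] == subset
                     and f["direction"] == direction), None)

    ra_low = flagged("CD45RA+ T cells", "low")
    ro_high = flagged("CD45RO+ T cells", "high")
    sw_low = flagged("switched memory B cells", "low")
    if ra_low and ro_high and sw_low:
        out.append({
            "code": "DIGEORGE_PATTERN",
            "rationale": (
                f"CD45RA+ T = {ra_low['value']:.1f}% of T (low), CD45RO+ T = "
                f"{ro_high['value']:.1f}% of T (high), switched memory B = "
                f"{sw_low['value']:.1f}% of B (low)")})

    b_pct = None
    for table in tables.values():
        try:
            b_pct = table.pct_of_lymphs("B cells")
            break
        except KeyError:
            continue
    if b_pct is not None and b_pct <= XLA_B_THRESHOLD:
        out.append({
            "code": "XLA_PATTERN",
            "rationale": f"B cells = {b_pct:.3f}% of lymphocytes "
                         f"(<= {XLA_B_THRESHOLD}%)"})
    if not out:
        out.append({"code": "NORMAL",
                    "rationale": "no diagnostic pattern triggered"})
    return out


@dataclass
class Report:
    case_id: str
    tables: dict[str, SubsetTable]
    qc: dict[str, dict]
    viability_proxy: dict[str, float]
    range_flags: list[dict]
    alps: ALPSResult
    interpretations: list[dict]
    provenance: dict = field(default_factory=dict)
    low_confidence: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": "1.0",
            "case_id": self.case_id,
            "subset_tables": {
                tube: t.rows.to_dict(orient="records")
                for tube, t in self.tables.items()},
            "qc": self.qc,
            "viability_proxy": self.viability_proxy,
            "range_flags": self.range_flags,
            "alps": self.alps.to_dict(),
            "interpretations": self.interpretations,
            "provenance": self.provenance,
            "low_confidence_clusters": self.low_confidence,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2,
                          default=_json_default) + "\n"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def build_report(case_id: str, panel: PanelConfig,
                 labeled: dict[str, LabeledEvents],
                 qc_summaries: dict[str, dict],
                 viability: dict[str, float],
                 provenance: dict | None = None,
                 low_confidence: dict[str, list[int]] | None = None,
                 out_dir: str | None = None,
                 plots: bool = False,
                 clean_samples: dict | None = None) -> Report:
    """Assemble and (optionally) write the case report.

    Writes ``<case_id>.report.json`` plus a subset-table CSV into
    ``out_dir`` when given; ``plots=True`` additionally renders per-stage
    2D scatter PNGs from ``clean_samples``."""
    tables = {}
    for tube_name, lab in labeled.items():
        tables[tube_name] = enumerate_subsets(
            lab, panel.subsets_for(tube_name))
    alps = evaluate_alps(tables["ALPS-T"], panel.alps_criteria) \
        if "ALPS-T" in tables else ALPSResult(0.0, 0.0, False,
                                              panel.alps_criteria)
    flags = apply_reference_ranges(tables, panel.reference_ranges)
    interp = evaluate_patterns(tables, flags, alps)
    report = Report(case_id=case_id, tables=tables, qc=qc_summaries,
                    viability_proxy=viability, range_flags=flags, alps=alps,
                    interpretations=interp, provenance=provenance or {},
                    low_confidence=low_confidence or {})
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, f"{case_id}.report.json"), "w") as fh:
            fh.write(report.to_json())
        pd.concat([t.rows for t in tables.values()]).to_csv(
            os.path.join(out_dir, f"{case_id}.subsets.csv"), index=False)
        if plots and clean_samples:
            _render_plots(case_id, out_dir, clean_samples)
    return report


def _render_plots(case_id: str, out_dir: str, clean_samples: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    for tube_name, clean in clean_samples.items():
        s = clean.sample
        fig, ax = plt.subplots(figsize=(4, 4))
        fsc = s.column("FSC-A")
        fsc_h = s.column("FSC-H")
        ax.scatter(fsc[::10], fsc_h[::10], s=1, alpha=0.3)
        slope = float(s.keywords.get("_doublet_slope", "nan"))
        icept = float(s.keywords.get("_doublet_intercept", "nan"))
        if np.isfinite(slope):
            xs = np.linspace(0, np.percentile(fsc, 99.9), 10)
            ax.plot(xs, slope * xs + icept, "r-", lw=1,
                    label="singlet ridge")
            ax.legend(fontsize=7)
        ax.set_xlabel("FSC-A")
        ax.set_ylabel("FSC-H")
        ax.set_title(f"{tube_name} singlet gate")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir,
                                 f"{case_id}.{tube_name}.fsc.png"), dpi=90)
        plt.close(fig)


def load_report_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
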