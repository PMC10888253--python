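"""Cluster classification and subset refinement.

Clusters (not events) are classified: a bagged random forest maps
marker-keyed cluster features to lineage labels (T / B / NK / ...); events
inherit their cluster's label.  Features are keyed by normalized marker
name and laid out in lexicographic marker order, so a model trained on one
reagent/color scheme applies to any tube carrying the same antibodies.

Fine diagnostic subsets (CD4/CD8/DNT, memory B, light chains, ...) are then
assigned by auditable marker-level predicates on the cluster phenotype
codes — the taxonomy's rules, not the forest — so every diagnostic call can
be traced to expression levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .mdpc import ClusterSet
from .panel import PanelConfig, SubsetDef, TubeSpec

LOW_CONFIDENCE = 0.7        # review threshold for the interactive loop
NON_LYMPHOCYTE_LABELS = ("Monocytes", "Granulocytes", "other")


class FeatureError(ValueError):
    pass


class VocabularyError(ValueError):
    pass


class TrainingError(ValueError):
    pass


def featurize(clusters: ClusterSet, tube: TubeSpec) -> pd.DataFrame:
    """One feature row per cluster: per-marker median and ordinal level,
    fraction of cleaned events, scatter medians normalized by the sample
    95th percentile.  Columns ordered by sorted marker name; a marker
    required by the tube but absent from the clustering is an error."""
    markers = sorted(tube.markers)
    missing = set(markers) - set(clusters.markers)
    if missing:
        raise FeatureError(f"cluster set lacks marker(s) {sorted(missing)}")
    order = [clusters.markers.index(m) for m in markers]
    total = sum(c.size for c in clusters.clusters)

    fsc_all = np.array([c.scatter_medians.get(tube.fsc_a, np.nan)
                        for c in clusters.clusters])
    ssc_all = np.array([c.scatter_medians.get(tube.ssc_a, np.nan)
                        for c in clusters.clusters])
    fsc_norm = np.nanpercentile(fsc_all, 95) if len(fsc_all) else 1.0
    ssc_norm = np.nanpercentile(ssc_all, 95) if len(ssc_all) else 1.0

    rows = []
    for c in clusters.clusters:
        row: dict[str, float] = {}
        for m, oi in zip(markers, order):
            row[f"med_{m}"] = c.marker_medians[m]
            row[f"lvl_{m}"] = float(c.code[oi])
        row["frac"] = c.size / total if total else 0.0
        row["fsc_a_n"] = float(fsc_all[c.cluster_id] / max(fsc_norm, 1e-9))
        row["ssc_a_n"] = float(ssc_all[c.cluster_id] / max(ssc_norm, 1e-9))
        rows.append(row)
    cols = [f"{p}_{m}" for m in markers for p in ("med", "lvl")]
    cols += ["frac", "fsc_a_n", "ssc_a_n"]
    df = pd.DataFrame(rows, columns=cols)
    df.index = [c.cluster_id for c in clusters.clusters]
    return df


@dataclass
class TrainingStore:
    """Append-only collection of labeled cluster features, per tube."""

    tube_name: str
    marker_key: tuple[str, ...]               # sorted markers = feature layout
    features: list[dict] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    case_ids: list[str] = field(default_factory=list)
    vocabulary: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.labels)

    def append_case(self, feats: pd.DataFrame, labels: dict[int, str],
                    case_id: str) -> "TrainingStore":
        for cid, lab in labels.items():
            if self.vocabulary and lab not in self.vocabulary:
                raise VocabularyError(
                    f"label {lab!r} not in tube {self.tube_name} vocabulary")
            self.features.append(feats.loc[cid].to_dict())
            self.labels.append(lab)
            self.case_ids.append(case_id)
        return self

    def to_json(self) -> str:
        return json.dumps({
            "tube": self.tube_name, "markers": list(self.marker_key),
            "vocabulary": list(self.vocabulary),
            "entries": [{"f": f, "label": l, "case": c}
                        for f, l, c in zip(self.features, self.labels,
                                           self.case_ids)]}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainingStore":
        doc = json.loads(text)
        store = cls(tube_name=doc["tube"], marker_key=tuple(doc["markers"]),
                    vocabulary=tuple(doc["vocabulary"]))
        for e in doc["entries"]:
            store.features.append(e["f"])
            store.labels.append(e["label"])
            store.case_ids.append(e["case"])
        return store


def store_for_tube(panel: PanelConfig, tube_name: str) -> TrainingStore:
    tube = panel.tube(tube_name)
    vocab = tuple(panel.lineages_for(tube_name)) + NON_LYMPHOCYTE_LABELS
    return TrainingStore(tube_name=tube_name,
                         marker_key=tuple(sorted(tube.markers)),
                         vocabulary=vocab)


def update_store(store: TrainingStore, feats: pd.DataFrame,
                 labels: dict[int, str], case_id: str) -> TrainingStore:
    """Append one labeled case (e.g. from manual gating review); prior
    entries are never mutated."""
    return store.append_case(feats, labels, case_id)


@dataclass
class ForestModel:
    forest: RandomForestClassifier
    feature_columns: list[str]
    label_set: list[str]
    tube_name: str
    oob_accuracy: float
    n_training: int
    seed: int

    def to_params(self) -> dict:
        return {"tube": self.tube_name, "labels": self.label_set,
                "oob_accuracy": self.oob_accuracy,
                "n_training": self.n_training, "seed": self.seed,
                "n_trees": self.forest.n_estimators}


def train(store: TrainingStore, n_trees: int = 200, seed: int = 0,
          min_per_label: int = 5) -> ForestModel:
    """Fit a bagged random forest on the store.  Requires at least two
    labels, each with >= ``min_per_label`` examples.  Deterministic given
    (store, seed)."""
    if len(store) == 0:
        raise TrainingError("empty training store")
    labels = pd.Series(store.labels)
    counts = labels.value_counts()
    deficient = sorted(counts[counts < min_per_label].index)
    if len(counts) < 2:
        raise TrainingError(
            f"need >= 2 labels, got {sorted(counts.index)}")
    if deficient:
        raise TrainingError(
            f"label(s) with < {min_per_label} examples: {deficient}")
    X = pd.DataFrame(store.features)
    cols = sorted(X.columns)
    X = X[cols]
    forest = RandomForestClassifier(
        n_estimators=n_trees, bootstrap=True, oob_score=True,
        random_state=seed % (2 ** 31), n_jobs=1)
    forest.fit(X.to_numpy(), labels.to_numpy())
    return ForestModel(
        forest=forest, feature_columns=cols,
        label_set=list(forest.classes_), tube_name=store.tube_name,
        oob_accuracy=float(forest.oob_score_), n_training=len(store),
        seed=seed)


def predict(model: ForestModel, feats: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster (label, probability, low_confidence) by majority vote of
    the forest; clusters below the confidence threshold are flagged for
    review."""
    if feats.empty:
        return pd.DataFrame(columns=["label", "probability",
                                     "low_confidence"])
    if sorted(feats.columns) != model.feature_columns:
        raise FeatureError(
            "feature layout mismatch between model and input")
    X = feats[model.feature_columns].to_numpy()
    proba = model.forest.predict_proba(X)
    top = np.argmax(proba, axis=1)
    out = pd.DataFrame({
        "label": [model.label_set[i] for i in top],
        "probability": proba[np.arange(len(top)), top],
        "low_confidence": proba[np.arange(len(top)), top] < LOW_CONFIDENCE,
    }, index=feats.index)
    return out


def label_clusters_by_truth(clusters: ClusterSet,
                            truth_lineages: np.ndarray) -> dict[int, str]:
    """Majority ground-truth lineage per cluster — the synthetic stand-in for
    a manually gated training case.  Doublet/debris-dominated clusters get
    'other'."""
    out: dict[int, str] = {}
    for c in clusters.clusters:
        members = truth_lineages[clusters.assignment == c.cluster_id]
        vals, counts = np.unique(members.astype(str), return_counts=True)
        top = str(vals[np.argmax(counts)])
        if top in ("doublet", "debris"):
            top = "other"
        out[c.cluster_id] = top
    return out


# ---------------------------------------------------------------------------
# Rule-based refinement

@dataclass
class LabeledEvents:
    """Per-event deepest subset label (primary axis), lineage, and the
    optional light-chain axis label for B-lineage events."""

    labels: np.ndarray                 # deepest primary label per event
    lineages: np.ndarray
    light_chain: np.ndarray            # "" where not applicable
    cluster_labels: dict[int, str]     # cluster id -> deepest label
    cluster_lineages: dict[int, str]
    tube_name: str


def refine_subsets(clusters: ClusterSet, lineage_labels: dict[int, str],
                   tube: TubeSpec, subsets: list[SubsetDef]) -> LabeledEvents:
    """Assign within-lineage subsets by the taxonomy's ordered marker-level
    predicates on cluster phenotype codes (first match wins per depth;
    children are tested under their matched parent).  Events inherit their
    cluster's deepest label."""
    marker_index = {m: i for i, m in enumerate(clusters.markers)}
    for s in subsets:
        if s.predicate is not None:
            missing = s.predicate.markers - set(marker_index)
            if missing:
                raise FeatureError(
                    f"subset {s.name!r} references marker(s) "
                    f"{sorted(missing)} absent from tube {tube.name}")

    primary = [s for s in subsets if s.axis == "primary"]
    light = [s for s in subsets if s.axis == "light_chain"]

    def children_of(parent: str) -> list[SubsetDef]:
        return [s for s in primary if s.parent == parent
                and s.predicate is not None]

    cluster_deepest: dict[int, str] = {}
    cluster_light: dict[int, str] = {}
    for c in clusters.clusters:
        lineage = lineage_labels.get(c.cluster_id, "other")
        code = {m: c.code[marker_index[m]] for m in clusters.markers}
        label = lineage
        if lineage not in NON_LYMPHOCYTE_LABELS:
            # descend: at each level take the first matching child predicate
            while True:
                nxt = None
                for s in children_of(label):
                    if s.predicate.evaluate(code):
                        nxt = s.name
                        break
                if nxt is None:
                    break
                label = nxt
        cluster_deepest[c.cluster_id] = label
        lc = ""
        for s in light:
            if _under(label, s.parent, primary) or label == s.parent:
                if s.predicate.evaluate(code):
                    lc = s.name
                    break
        cluster_light[c.cluster_id] = lc

    n = clusters.assignment.size
    labels = np.empty(n, dtype=object)
    lineages = np.empty(n, dtype=object)
    lchain = np.empty(n, dtype=object)
    for c in clusters.clusters:
        sel = clusters.assignment == c.cluster_id
        labels[sel] = cluster_deepest[c.cluster_id]
        lineages[sel] = lineage_labels.get(c.cluster_id, "other")
        lchain[sel] = cluster_light[c.cluster_id]
    return LabeledEvents(labels=labels, lineages=lineages, light_chain=lchain,
                         cluster_labels=cluster_deepest,
                         cluster_lineages=dict(lineage_labels),
                         tube_name=tube.name)


def _under(name: str, ancestor: str, subsets: list[SubsetDef]) -> bool:
    by_name = {s.name: s for s in subsets}
    cur = name
    while cur in by_name:
        parent = by_name[cur].parent
        if parent == ancestor:
            return True
        cur = parent
    return False
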