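import numpy as np
import pandas as pd
import pytest

import immunogate as ig
from immunogate import apc, mdpc, pipeline
from immunogate.apc import (FeatureError, TrainingError, VocabularyError,
                            featurize, label_clusters_by_truth, predict,
                            refine_subsets, store_for_tube, train,
                            update_store)
from immunogate.mdpc import ChannelLevels, ClusterInfo, ClusterSet


def _toy_clusterset(markers, codes, sizes, medians=None):
    """Hand-built ClusterSet for feature/refinement tests."""
    levels = {m: ChannelLevels(boundaries=(0.8, 1.85, 2.9, 3.95),
                               neg_mode=0.4, neg_spread=0.2)
              for m in markers}
    n = sum(sizes)
    assignment = np.repeat(np.arange(len(sizes)), sizes)
    infos = []
    for cid, (code, size) in enumerate(zip(codes, sizes)):
        med = medians[cid] if medians else [
            (0.4, 1.4, 2.5, 3.6, 4.7)[l] for l in code]
        infos.append(ClusterInfo(
            cluster_id=cid, size=size,
            marker_medians=dict(zip(markers, med)),
            code=tuple(code), peak_density=1.0,
            scatter_medians={"FSC-A": 2e5, "FSC-H": 1.9e5, "SSC-A": 1e5}))
    return ClusterSet(assignment=assignment, clusters=infos,
                      markers=list(markers), levels=levels)


def test_featurize_layout_and_ordinals(panel):
    tube = panel.tube("ALPS-T")
    markers = tube.markers
    code = [0] * len(markers)
    code[markers.index("CD3")] = 4
    cs = _toy_clusterset(markers, [code], [100])
    feats = featurize(cs, tube)
    assert feats.loc[0, "lvl_CD3"] == 4.0
    # layout: lexicographic marker order
    med_cols = [c for c in feats.columns if c.startswith("med_")]
    assert med_cols == sorted(med_cols)
    assert list(feats.columns[-3:]) == ["frac", "fsc_a_n", "ssc_a_n"]


def test_featurize_transfer_across_fluorochromes(panel):
    """Two tubes with the same antibodies on different color schemes must
    produce the identical feature layout."""
    from immunogate.panel import TubeSpec
    t1 = panel.tube("ALPS-T")
    recolored = TubeSpec(name="ALPS-T-v2", channels=[
        (f"FL{i+1}", f"DYE{i}", marker)
        for i, (_, _, marker) in enumerate(t1.channels)])
    cs = _toy_clusterset(t1.markers, [[3] * 9], [50])
    f1 = featurize(cs, t1)
    f2 = featurize(cs, recolored)
    assert list(f1.columns) == list(f2.columns)
    pd.testing.assert_frame_equal(f1, f2)


def test_featurize_missing_marker_errors(panel):
    tube = panel.tube("ALPS-T")
    short = _toy_clusterset([m for m in tube.markers if m != "CD4"],
                            [[3] * 8], [50])
    with pytest.raises(FeatureError, match="CD4"):
        featurize(short, tube)


def _toy_store(panel, n_per_label=8, seed=0):
    tube = panel.tube("ALPS-T")
    store = store_for_tube(panel, "ALPS-T")
    rng = np.random.RandomState(seed)
    lineage_codes = {
        "T cells": {"CD3": 3, "CD45": 4, "TCRAB": 3},
        "B cells": {"CD19": 3, "CD45": 4},
        "NK cells": {"CD45": 4},
        "Monocytes": {"CD45": 3, "CD4": 1},
    }
    for label, on in lineage_codes.items():
        for i in range(n_per_label):
            code = [on.get(m, 0) for m in tube.markers]
            # jitter medians within the band
            meds = [[(0.4, 1.4, 2.5, 3.6, 4.7)[l] + rng.normal(0, 0.1)
                     for l in code]]
            cs = _toy_clusterset(tube.markers, [code], [100],
                                 medians=meds)
            update_store(store, featurize(cs, tube), {0: label},
                         case_id=f"c{label}{i}")
    return store


def test_train_and_predict_lineages(panel):
    store = _toy_store(panel)
    model = train(store, seed=1)
    assert model.oob_accuracy >= 0.9
    tube = panel.tube("ALPS-T")
    t_code = [0] * 9
    t_code[tube.markers.index("CD3")] = 3
    t_code[tube.markers.index("CD45")] = 4
    t_code[tube.markers.index("TCRAB")] = 3
    cs = _toy_clusterset(tube.markers, [t_code], [100])
    out = predict(model, featurize(cs, tube))
    assert out.loc[0, "label"] == "T cells"
    assert not out.loc[0, "low_confidence"]


def test_train_determinism(panel):
    store = _toy_store(panel)
    tube = panel.tube("ALPS-T")
    cs = _toy_clusterset(tube.markers, [[3, 0, 0, 0, 2, 3, 0, 3, 4]], [70])
    feats = featurize(cs, tube)
    p1 = predict(train(store, seed=7), feats)
    p2 = predict(train(store, seed=7), feats)
    pd.testing.assert_frame_equal(p1, p2)


def test_train_single_label_rejected(panel):
    store = store_for_tube(panel, "ALPS-T")
    tube = panel.tube("ALPS-T")
    cs = _toy_clusterset(tube.markers, [[3] * 9], [50])
    feats = featurize(cs, tube)
    for i in range(6):
        update_store(store, feats, {0: "T cells"}, case_id=f"c{i}")
    with pytest.raises(TrainingError, match=">= 2 labels"):
        train(store)


def test_train_deficient_label_rejected(panel):
    store = _toy_store(panel, n_per_label=8)
    tube = panel.tube("ALPS-T")
    cs = _toy_clusterset(tube.markers, [[1] * 9], [50])
    update_store(store, featurize(cs, tube), {0: "other"}, case_id="x")
    with pytest.raises(TrainingError, match="other"):
        train(store)


def test_predict_empty_features(panel):
    store = _toy_store(panel)
    model = train(store)
    out = predict(model, pd.DataFrame(columns=model.feature_columns))
    assert out.empty


def test_low_confidence_between_templates(panel):
    """A cluster with conflicting lineage evidence (CD3 positive like a T
    cell, TCRab negative like an NK cell) splits the forest vote and must
    carry the review flag."""
    store = _toy_store(panel, n_per_label=12)
    model = train(store, seed=3)
    tube = panel.tube("ALPS-T")
    mid_code = [0] * 9
    mid_code[tube.markers.index("CD3")] = 3      # T-like
    mid_code[tube.markers.index("CD45")] = 4
    # TCRAB stays negative: NK-like
    meds = [[(0.4, 1.4, 2.5, 3.6, 4.7)[l] for l in mid_code]]
    cs = _toy_clusterset(tube.markers, [mid_code], [80], medians=meds)
    out = predict(model, featurize(cs, tube))
    assert out.loc[0, "probability"] < 0.999
    assert bool(out.loc[0, "low_confidence"]) == (
        out.loc[0, "probability"] < apc.LOW_CONFIDENCE)
    assert out.loc[0, "low_confidence"]


def test_update_store_appends_only(panel):
    store = _toy_store(panel, n_per_label=5)
    n0 = len(store)
    first = (dict(store.features[0]), store.labels[0])
    tube = panel.tube("ALPS-T")
    cs = _toy_clusterset(tube.markers, [[3] * 9, [0] * 9], [50, 60])
    update_store(store, featurize(cs, tube),
                 {0: "T cells", 1: "NK cells"}, case_id="new")
    assert len(store) == n0 + 2
    assert (store.features[0], store.labels[0]) == first


def test_update_store_unknown_label(panel):
    store = store_for_tube(panel, "ALPS-T")
    tube = panel.tube("ALPS-T")
    cs = _toy_clusterset(tube.markers, [[3] * 9], [50])
    with pytest.raises(VocabularyError, match="plasma"):
        update_store(store, featurize(cs, tube), {0: "plasma cells"},
                     case_id="x")


def test_store_json_round_trip(panel):
    store = _toy_store(panel, n_per_label=5)
    store2 = apc.TrainingStore.from_json(store.to_json())
    assert store2.labels == store.labels
    assert store2.features == store.features
    assert store2.to_json() == store.to_json()


def test_incremental_training_keeps_oob(panel):
    """Appending labeled cases and retraining must not degrade out-of-bag
    accuracy by more than 2 points."""
    store = _toy_store(panel, n_per_label=8, seed=1)
    oob0 = train(store, seed=5).oob_accuracy
    extra = _toy_store(panel, n_per_label=4, seed=2)
    for f, l, c in zip(extra.features, extra.labels, extra.case_ids):
        store.features.append(f)
        store.labels.append(l)
        store.case_ids.append("extra-" + c)
    oob1 = train(store, seed=5).oob_accuracy
    assert oob1 >= oob0 - 0.02


# ---------------------------------------------------------------------------
# refinement

def _alps_t_code(panel, **levels):
    tube = panel.tube("ALPS-T")
    code = [0] * len(tube.markers)
    for m, l in levels.items():
        code[tube.markers.index(m)] = l
    return code


def test_refine_dnt(panel):
    tube = panel.tube("ALPS-T")
    code = _alps_t_code(panel, CD3=3, TCRAB=3, CD45=4)
    cs = _toy_clusterset(tube.markers, [code], [100])
    lab = refine_subsets(cs, {0: "T cells"}, tube,
                         panel.subsets_for("ALPS-T"))
    assert lab.cluster_labels[0] == "TCRab+ DNT cells"
    assert set(lab.labels) == {"TCRab+ DNT cells"}


def test_refine_cd4_cd8_treg(panel):
    tube = panel.tube("ALPS-T")
    cd4 = _alps_t_code(panel, CD3=3, CD4=3, CD127=3, TCRAB=3, CD45=4)
    cd8 = _alps_t_code(panel, CD3=3, CD8=4, TCRAB=3, CD45=4)
    treg = _alps_t_code(panel, CD3=3, CD4=3, CD25=3, TCRAB=3, CD45=4)
    gd = _alps_t_code(panel, CD3=3, TCRGD=3, CD45=4)
    cs = _toy_clusterset(tube.markers, [cd4, cd8, treg, gd],
                         [100, 80, 30, 20])
    lab = refine_subsets(cs, {i: "T cells" for i in range(4)}, tube,
                         panel.subsets_for("ALPS-T"))
    assert lab.cluster_labels[0] == "CD4 T cells"
    assert lab.cluster_labels[1] == "CD8 T cells"
    assert lab.cluster_labels[2] == "Treg-like cells"    # nested under CD4
    assert lab.cluster_labels[3] == "gd T cells"         # takes priority


def test_refine_switched_memory_b(panel):
    tube = panel.tube("ALPS-B")
    markers = tube.markers
    code = [0] * len(markers)
    code[markers.index("CD19")] = 3
    code[markers.index("CD27")] = 3
    code[markers.index("KAPPA")] = 3
    code[markers.index("CD45")] = 4
    cs = _toy_clusterset(markers, [code], [60])
    lab = refine_subsets(cs, {0: "B cells"}, tube,
                         panel.subsets_for("ALPS-B"))
    assert lab.cluster_labels[0] == "switched memory B cells"
    assert set(lab.light_chain) == {"kappa+ B cells"}


def test_refine_no_predicate_match_keeps_lineage(panel):
    tube = panel.tube("ALPS-T")
    # CD4 and CD8 both partial: no subset predicate fires
    code = _alps_t_code(panel, CD3=3, CD4=2, CD8=2, CD45=4)
    cs = _toy_clusterset(tube.markers, [code], [40])
    lab = refine_subsets(cs, {0: "T cells"}, tube,
                         panel.subsets_for("ALPS-T"))
    assert lab.cluster_labels[0] == "T cells"


def test_label_clusters_by_truth_majority():
    markers = ["CD3"]
    cs = _toy_clusterset(markers, [[3], [0]], [10, 10])
    lineages = np.array(["T cells"] * 9 + ["B cells"] +
                        ["doublet"] * 6 + ["NK cells"] * 4, dtype=object)
    labels = label_clusters_by_truth(cs, lineages)
    assert labels == {0: "T cells", 1: "other"}


def test_pipeline_transfer_property(panel, small_models):
    """Permuting channel order (new color scheme, same antibodies) must not
    change any prediction."""
    scenario = ig.make_scenario("NORMAL", seed=31, n_events=6000)
    samples, _ = ig.make_case(scenario, panel)
    sample = samples["ALPS-T"]
    rep1 = pipeline.analyze_tube(sample, panel, small_models["ALPS-T"],
                                 downsample_cap=10_000)
    rng = np.random.RandomState(1)
    perm = rng.permutation(len(sample.channel_meta))
    shuffled = ig.Sample(events=sample.events[:, perm],
                         channel_meta=[sample.channel_meta[i] for i in perm],
                         keywords=dict(sample.keywords))
    rep2 = pipeline.analyze_tube(shuffled, panel, small_models["ALPS-T"],
                                 downsample_cap=10_000)
    assert rep1[4].cluster_labels == rep2[4].cluster_labels
    np.testing.assert_array_equal(rep1[4].labels, rep2[4].labels)
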