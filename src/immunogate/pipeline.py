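"""End-to-end case analysis: pregate -> transform -> cluster -> classify ->
refine -> report, plus the training-batch builder used by the CLI and the
validation harness."""

from __future__ import annotations

import numpy as np

from . import apc, mdpc, qc_pregate, synth
from .apc import ForestModel, TrainingStore
from .fcs_io import Sample, apply_transform
from .panel import PanelConfig, default_panel, match_tube
from .report import Report, build_report


def analyze_tube(sample: Sample, panel: PanelConfig, model: ForestModel | None,
                 rho_merge: float = 0.5, downsample_cap: int | None = None):
    """One tube through the full pipeline.  Returns
    (tube, CleanSample, ClusterSet, predictions, LabeledEvents)."""
    tube = match_tube(sample, panel)
    clean = qc_pregate.pregate(sample)
    clean.sample = apply_transform(clean.sample)
    cap = downsample_cap or mdpc.DOWNSAMPLE_CAP
    clusters = mdpc.cluster(clean, tube, rho_merge=rho_merge,
                            downsample_cap=cap)
    feats = apc.featurize(clusters, tube)
    if model is None:
        raise ValueError(f"no model for tube {tube.name}")
    preds = apc.predict(model, feats)
    lineage = {int(cid): str(preds.loc[cid, "label"]) for cid in preds.index}
    labeled = apc.refine_subsets(clusters, lineage, tube,
                                 panel.subsets_for(tube.name))
    return tube, clean, clusters, preds, labeled


def analyze_case(samples: dict[str, Sample], panel: PanelConfig,
                 models: dict[str, ForestModel], case_id: str,
                 out_dir: str | None = None, plots: bool = False,
                 provenance: dict | None = None,
                 downsample_cap: int | None = None) -> Report:
    """All tubes of one case -> assembled Report."""
    labeled, qc_sum, viability, lowconf, cleans = {}, {}, {}, {}, {}
    for tube_name, sample in samples.items():
        tube, clean, clusters, preds, lab = analyze_tube(
            sample, panel, models.get(tube_name),
            downsample_cap=downsample_cap)
        labeled[tube.name] = lab
        qc_sum[tube.name] = clean.qc.summary()
        viability[tube.name] = clean.viability_proxy
        lowconf[tube.name] = [int(c) for c in
                              preds.index[preds["low_confidence"]]]
        cleans[tube.name] = clean
    prov = dict(provenance or {})
    prov.setdefault("models", {
        t: m.to_params() for t, m in models.items() if m is not None})
    return build_report(case_id, panel, labeled, qc_sum, viability,
                        provenance=prov, low_confidence=lowconf,
                        out_dir=out_dir, plots=plots, clean_samples=cleans)


# ---------------------------------------------------------------------------
# Training on labeled (synthetic or manually gated) cases

def build_training_stores(n_cases: int, base_seed: int,
                          panel: PanelConfig | None = None,
                          n_events: int = 20_000,
                          scenario_cycle: tuple[str, ...] = (
                              "NORMAL", "NORMAL", "NORMAL", "ALPS",
                              "NORMAL", "DIGEORGE", "NORMAL", "XLA"),
                          downsample_cap: int | None = None,
                          ) -> dict[str, TrainingStore]:
    """Simulate ``n_cases`` labeled cases and fill one TrainingStore per
    tube.  Cluster labels are the majority ground-truth lineage per cluster —
    the synthetic stand-in for manually gated files."""
    panel = panel or default_panel()
    stores = {t.name: apc.store_for_tube(panel, t.name) for t in panel.tubes}
    for i in range(n_cases):
        scen_name = scenario_cycle[i % len(scenario_cycle)]
        seed = (base_seed + 1000 + i) % (2 ** 31)
        scenario = synth.make_scenario(scen_name, seed=seed,
                                       n_events=n_events)
        samples, truth = synth.make_case(scenario, panel)
        for tube_name, sample in samples.items():
            tube = match_tube(sample, panel)
            clean = qc_pregate.pregate(sample)
            clean.sample = apply_transform(clean.sample)
            clusters = mdpc.cluster(
                clean, tube, downsample_cap=downsample_cap or
                mdpc.DOWNSAMPLE_CAP)
            feats = apc.featurize(clusters, tube)
            kept = clean.qc.event_mask
            lineages_kept = truth.lineages[tube_name][kept]
            labels = apc.label_clusters_by_truth(clusters, lineages_kept)
            apc.update_store(stores[tube_name], feats, labels,
                             case_id=f"train-{i}")
    return stores


def train_models(stores: dict[str, TrainingStore], seed: int = 0,
                 n_trees: int = 200) -> dict[str, ForestModel]:
    return {tube: apc.train(store, n_trees=n_trees, seed=seed)
            for tube, store in stores.items()}


# ---------------------------------------------------------------------------
# Parameter-recovery validation batch

# 12-case scenario rotation: 2/3 normal, the rest the panel's target
# diseases, emulating the composition of a clinical ALPS-panel cohort
VALIDATION_CYCLE = ("NORMAL", "ALPS", "NORMAL", "NORMAL", "DIGEORGE",
                    "NORMAL", "NORMAL", "ALPS", "NORMAL", "NORMAL",
                    "XLA", "NORMAL")
DIRICHLET_CONCENTRATION = 5.0


def run_concordance_batch(models, n_cases: int = 60, base_seed: int = 0,
                          panel: PanelConfig | None = None,
                          n_events: int = 20_000,
                          downsample_cap: int | None = None,
                          concentration: float = DIRICHLET_CONCENTRATION):
    """Simulate ``n_cases`` cases (scenario rotation, Dirichlet-jittered
    abundances, seeds base_seed+1 .. base_seed+n_cases), run each through the
    full pipeline, and return (list of (estimates, reference) dicts keyed by
    (tube, subset), list of Reports)."""
    from . import concordance as conc
    panel = panel or default_panel()
    cases, reports = [], []
    for i in range(1, n_cases + 1):
        case_seed = (base_seed + i) % (2 ** 31)
        scen_name = VALIDATION_CYCLE[(i - 1) % len(VALIDATION_CYCLE)]
        scenario = synth.make_scenario(scen_name, seed=case_seed,
                                       n_events=n_events)
        rng = np.random.RandomState((base_seed * 1009 + i) % (2 ** 31))
        scenario = synth.jitter_scenario(scenario, concentration, rng)
        samples, truth = synth.make_case(scenario, panel)
        report = analyze_case(samples, panel, models, f"case-{case_seed}",
                              downsample_cap=downsample_cap)
        est = conc.estimates_from_report(report)
        ref = conc.reference_from_truth(truth)
        cases.append((est, ref))
        reports.append(report)
    return cases, reports
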