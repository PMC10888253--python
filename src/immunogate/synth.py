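"""Synthetic 3-tube panel cases with per-event ground truth.

The generator states the world the pipeline assumes: each population is a
template of per-marker expression levels on the analysis (asinh) scale, with
the level -> mean geometry matching the discretizer's five bands
(negative ~0.4, dim ~1.4, partial ~2.5, positive ~3.6, bright ~4.7
transformed units).  Scatter comes from mode-specific bivariate Gaussians
with FSC-H proportional to FSC-A.  Artifacts — doublets (summed events),
debris (exponential low scatter, unstained), acquisition drift (a gain step
over a time window) — are injected with per-event truth tags so every
cleanup stage can be scored against ground truth.

Scenarios (NORMAL / ALPS / DIGEORGE / XLA) fix per-tube population
abundances to the qualitative disease patterns the panel screens for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fcs_io import (DEFAULT_COFACTOR, RAW_MAX, ChannelMeta, Sample,
                     TransformSpec)
from .panel import PanelConfig, default_panel

# transformed-scale means for levels 0..4; the sits-above-zero negative mean
# reflects autofluorescence (raw ~50 on a 2^20 axis)
LEVEL_MEANS = (0.4, 1.4, 2.5, 3.6, 4.7)
LEVEL_SPREADS = (0.20, 0.28, 0.28, 0.28, 0.28)

SCATTER_MODES = {
    #              FSC-A mean/sd     SSC-A mean/sd
    "lymphocyte": ((200_000, 18_000), (100_000, 16_000)),
    "monocyte": ((320_000, 25_000), (185_000, 25_000)),
    "granulocyte": ((300_000, 25_000), (400_000, 40_000)),
}
FSC_H_SLOPE = 0.95
FSC_H_NOISE = 6_000.0
DEBRIS_FSC_SCALE = 25_000.0
DEBRIS_SSC_SCALE = 18_000.0
TIME_SPAN = 1024.0      # instrument ticks per acquisition


@dataclass(frozen=True)
class PopulationTemplate:
    name: str
    lineage: str                        # classifier-level label
    levels: dict[str, int]              # marker -> 0..4 (absent -> 0)
    subsets: tuple[str, ...]            # taxonomy subsets the population is in
    scatter_mode: str = "lymphocyte"
    spread_mult: float = 1.0

    def level_of(self, marker: str) -> int:
        return self.levels.get(marker, 0)


def _t(name, lineage, levels, subsets, scatter="lymphocyte"):
    return PopulationTemplate(name, lineage, levels, tuple(subsets), scatter)


TEMPLATES: dict[str, list[PopulationTemplate]] = {
    "ALPS-T": [
        _t("CD4 T", "T cells",
           {"CD3": 3, "CD4": 3, "CD127": 3, "TCRAB": 3, "CD45": 4, "CD25": 1},
           ["T cells", "CD4 T cells"]),
        _t("CD8 T", "T cells",
           {"CD3": 3, "CD8": 3, "TCRAB": 3, "CD45": 4, "CD127": 2},
           ["T cells", "CD8 T cells"]),
        _t("TCRab+ DNT", "T cells",
           {"CD3": 3, "TCRAB": 3, "CD45": 4, "CD127": 1},
           ["T cells", "DNT cells", "TCRab+ DNT cells"]),
        _t("gd T", "T cells",
           {"CD3": 3, "TCRGD": 3, "CD45": 4},
           ["T cells", "gd T cells"]),
        _t("Treg", "T cells",
           {"CD3": 3, "CD4": 3, "CD25": 3, "TCRAB": 3, "CD45": 4},
           ["T cells", "CD4 T cells", "Treg-like cells"]),
        _t("B", "B cells", {"CD19": 3, "CD45": 4}, ["B cells"]),
        _t("NK", "NK cells", {"CD45": 4}, ["NK cells"]),
        _t("Monocyte", "Monocytes", {"CD45": 3, "CD4": 1}, [],
           scatter="monocyte"),
    ],
    "ACT-T": [
        _t("naive CD4 T", "T cells",
           {"CD3": 3, "CD4": 3, "CD45RA": 3, "CD45": 4},
           ["T cells", "CD45RA+ T cells"]),
        _t("naive CD8 T", "T cells",
           {"CD3": 3, "CD8": 3, "CD45RA": 3, "CD45": 4},
           ["T cells", "CD45RA+ T cells"]),
        _t("memory CD4 T", "T cells",
           {"CD3": 3, "CD4": 3, "CD45RO": 3, "CD45": 4, "PD1": 1},
           ["T cells", "CD45RO+ T cells"]),
        _t("memory CD8 T", "T cells",
           {"CD3": 3, "CD8": 3, "CD45RO": 3, "CD45": 4},
           ["T cells", "CD45RO+ T cells"]),
        _t("activated T", "T cells",
           {"CD3": 3, "CD4": 3, "CD45RO": 3, "CD69": 3, "HLADR": 3,
            "CD45": 4}, ["T cells", "CD45RO+ T cells"]),
        _t("non-T lymph", "non-T lymphocytes",
           {"HLADR": 3, "CD45": 4}, ["non-T lymphocytes"]),
        _t("Monocyte", "Monocytes", {"CD45": 3, "HLADR": 3, "CD4": 1}, [],
           scatter="monocyte"),
    ],
    "ALPS-B": [
        _t("naive B kappa", "B cells",
           {"CD19": 3, "IGD": 3, "KAPPA": 3, "CD45": 4},
           ["B cells", "naive B cells", "kappa+ B cells"]),
        _t("naive B lambda", "B cells",
           {"CD19": 3, "IGD": 3, "LAMBDA": 3, "CD45": 4},
           ["B cells", "naive B cells", "lambda+ B cells"]),
        _t("switched memory B kappa", "B cells",
           {"CD19": 3, "CD27": 3, "KAPPA": 3, "CD45": 4},
           ["B cells", "switched memory B cells", "kappa+ B cells"]),
        _t("switched memory B lambda", "B cells",
           {"CD19": 3, "CD27": 3, "LAMBDA": 3, "CD45": 4},
           ["B cells", "switched memory B cells", "lambda+ B cells"]),
        _t("non-switched memory B kappa", "B cells",
           {"CD19": 3, "CD27": 3, "IGD": 3, "KAPPA": 3, "CD45": 4},
           ["B cells", "non-switched memory B cells", "kappa+ B cells"]),
        _t("non-switched memory B lambda", "B cells",
           {"CD19": 3, "CD27": 3, "IGD": 3, "LAMBDA": 3, "CD45": 4},
           ["B cells", "non-switched memory B cells", "lambda+ B cells"]),
        _t("T", "T cells", {"CD3": 3, "CD5": 3, "CD45": 4}, ["T cells"]),
        _t("NK", "NK cells", {"CD56": 3, "CD45": 4}, ["NK cells"]),
        _t("Monocyte", "Monocytes", {"CD45": 3}, [], scatter="monocyte"),
    ],
}

# scenario -> tube -> population -> abundance (fraction of tube events)
SCENARIO_ABUNDANCES: dict[str, dict[str, dict[str, float]]] = {
    "NORMAL": {
        "ALPS-T": {"CD4 T": 0.30, "CD8 T": 0.17, "TCRab+ DNT": 0.008,
                   "gd T": 0.025, "Treg": 0.035, "B": 0.10, "NK": 0.095,
                   "Monocyte": 0.267},
        "ACT-T": {"naive CD4 T": 0.17, "naive CD8 T": 0.10,
                  "memory CD4 T": 0.16, "memory CD8 T": 0.09,
                  "activated T": 0.02, "non-T lymph": 0.20,
                  "Monocyte": 0.26},
        "ALPS-B": {"naive B kappa": 0.0456, "naive B lambda": 0.0304,
                   "switched memory B kappa": 0.0144,
                   "switched memory B lambda": 0.0096,
                   "non-switched memory B kappa": 0.0120,
                   "non-switched memory B lambda": 0.0080,
                   "T": 0.50, "NK": 0.11, "Monocyte": 0.27},
    },
    "ALPS": {
        "ALPS-T": {"CD4 T": 0.25, "CD8 T": 0.14, "TCRab+ DNT": 0.09,
                   "gd T": 0.02, "Treg": 0.03, "B": 0.09, "NK": 0.09,
                   "Monocyte": 0.29},
        "ACT-T": {"naive CD4 T": 0.15, "naive CD8 T": 0.09,
                  "memory CD4 T": 0.17, "memory CD8 T": 0.10,
                  "activated T": 0.04, "non-T lymph": 0.19,
                  "Monocyte": 0.26},
        "ALPS-B": {"naive B kappa": 0.042, "naive B lambda": 0.028,
                   "switched memory B kappa": 0.0144,
                   "switched memory B lambda": 0.0096,
                   "non-switched memory B kappa": 0.0120,
                   "non-switched memory B lambda": 0.0080,
                   "T": 0.52, "NK": 0.098, "Monocyte": 0.268},
    },
    "DIGEORGE": {
        "ALPS-T": {"CD4 T": 0.24, "CD8 T": 0.14, "TCRab+ DNT": 0.007,
                   "gd T": 0.02, "Treg": 0.03, "B": 0.11, "NK": 0.11,
                   "Monocyte": 0.343},
        "ACT-T": {"naive CD4 T": 0.030, "naive CD8 T": 0.015,
                  "memory CD4 T": 0.25, "memory CD8 T": 0.15,
                  "activated T": 0.035, "non-T lymph": 0.20,
                  "Monocyte": 0.32},
        "ALPS-B": {"naive B kappa": 0.054, "naive B lambda": 0.036,
                   "switched memory B kappa": 0.0011,
                   "switched memory B lambda": 0.0007,
                   "non-switched memory B kappa": 0.0108,
                   "non-switched memory B lambda": 0.0074,
                   "T": 0.51, "NK": 0.11, "Monocyte": 0.27},
    },
    "XLA": {
        "ALPS-T": {"CD4 T": 0.33, "CD8 T": 0.19, "TCRab+ DNT": 0.008,
                   "gd T": 0.027, "Treg": 0.035, "B": 0.0002, "NK": 0.11,
                   "Monocyte": 0.2998},
        "ACT-T": {"naive CD4 T": 0.19, "naive CD8 T": 0.11,
                  "memory CD4 T": 0.17, "memory CD8 T": 0.10,
                  "activated T": 0.02, "non-T lymph": 0.13,
                  "Monocyte": 0.28},
        "ALPS-B": {"naive B kappa": 0.0002, "T": 0.58, "NK": 0.13,
                   "Monocyte": 0.2898},
    },
}

TUBE_ORDER = ("ALPS-T", "ACT-T", "ALPS-B")


class ScenarioError(ValueError):
    pass


@dataclass
class Scenario:
    name: str
    abundances: dict[str, dict[str, float]]    # tube -> pop -> fraction
    n_events: int = 20_000
    doublet_rate: float = 0.02
    debris_rate: float = 0.02
    drift: dict | None = None      # {"window":f, "gain":g, "channel":marker}
    seed: int = 0
    jittered: bool = False

    def validate(self) -> None:
        for tube, ab in self.abundances.items():
            s = sum(ab.values())
            if abs(s - 1.0) > 1e-6:
                raise ScenarioError(
                    f"{self.name}/{tube}: abundances sum to {s:.6f}, not 1")
        if self.jittered:
            return
        if self.name == "ALPS":
            ab = self.abundances["ALPS-T"]
            t_total = sum(v for p, v in ab.items()
                          if _pop(("ALPS-T"), p).lineage == "T cells")
            if ab.get("TCRab+ DNT", 0) / t_total < 0.10:
                raise ScenarioError("ALPS scenario needs DNT >= 10% of T")
        if self.name == "XLA":
            ab = self.abundances["ALPS-B"]
            lymph = sum(v for p, v in ab.items()
                        if _pop("ALPS-B", p).lineage != "Monocytes")
            b = sum(v for p, v in ab.items()
                    if _pop("ALPS-B", p).lineage == "B cells")
            if b / lymph > 0.0005:
                raise ScenarioError("XLA scenario needs B <= 0.05% of lymphocytes")
        if self.name == "DIGEORGE":
            ab = self.abundances["ACT-T"]
            t = sum(v for p, v in ab.items()
                    if _pop("ACT-T", p).lineage == "T cells")
            ra = sum(v for p, v in ab.items()
                     if "CD45RA+ T cells" in _pop("ACT-T", p).subsets)
            if ra / t > 0.10:
                raise ScenarioError("DIGEORGE needs CD45RA+ <= 10% of T")
            abb = self.abundances["ALPS-B"]
            btot = sum(v for p, v in abb.items()
                       if _pop("ALPS-B", p).lineage == "B cells")
            sw = sum(v for p, v in abb.items()
                     if "switched memory B cells" in _pop("ALPS-B", p).subsets)
            if sw / btot > 0.02:
                raise ScenarioError("DIGEORGE needs switched memory B <= 2% of B")


def _pop(tube: str, name: str) -> PopulationTemplate:
    for t in TEMPLATES[tube]:
        if t.name == name:
            return t
    raise KeyError(f"no template {name!r} in tube {tube}")


def make_scenario(name: str, seed: int = 0, n_events: int = 20_000,
                  doublet_rate: float = 0.02, debris_rate: float = 0.02,
                  drift: dict | None = None,
                  overrides: dict | None = None) -> Scenario:
    """A named scenario preset; ``overrides`` replaces per-tube abundance
    maps (used e.g. for the 30%-DNT worked case)."""
    if name not in SCENARIO_ABUNDANCES:
        raise ScenarioError(f"unknown scenario {name!r}")
    ab = {tube: dict(pops) for tube, pops in SCENARIO_ABUNDANCES[name].items()}
    if overrides:
        for tube, pops in overrides.items():
            ab[tube] = dict(pops)
    sc = Scenario(name=name, abundances=ab, seed=seed, n_events=n_events,
                  doublet_rate=doublet_rate, debris_rate=debris_rate,
                  drift=drift, jittered=overrides is not None)
    sc.validate()
    return sc


def jitter_scenario(scenario: Scenario, concentration: float,
                    rng: np.random.RandomState) -> Scenario:
    """Per-case abundance variation: Dirichlet draw with
    alpha_i = concentration * n_pops * mean_i (so total concentration scales
    with the number of populations and the mean composition is preserved)."""
    ab = {}
    for tube, pops in scenario.abundances.items():
        names = list(pops)
        means = np.array([pops[p] for p in names])
        alpha = np.maximum(concentration * len(names) * means, 1e-3)
        draw = rng.dirichlet(alpha)
        ab[tube] = {p: float(v) for p, v in zip(names, draw)}
    return replace(scenario, abundances=ab, jittered=True)


@dataclass
class TruthTable:
    """Per-event ground truth per tube plus exact subset percentages."""

    labels: dict[str, np.ndarray] = field(default_factory=dict)      # population
    artifacts: dict[str, np.ndarray] = field(default_factory=dict)   # tag
    lineages: dict[str, np.ndarray] = field(default_factory=dict)

    def clean_mask(self, tube: str) -> np.ndarray:
        tag = self.artifacts[tube]
        return (tag == "singlet") | (tag == "drift-affected")

    def subset_percentages(self, tube: str) -> dict[str, float]:
        """True percent-of-lymphocytes per subset (and lineage), computed
        from event labels of biological singlets."""
        mask = self.clean_mask(tube)
        labels = self.labels[tube][mask]
        counts: dict[str, int] = {}
        lymph = 0
        for pop_name in np.unique(labels):
            tmpl = _pop(tube, str(pop_name))
            n = int((labels == pop_name).sum())
            if tmpl.lineage != "Monocytes":
                lymph += n
            for s in tmpl.subsets:
                counts[s] = counts.get(s, 0) + n
        if lymph == 0:
            return {}
        return {s: 100.0 * c / lymph for s, c in counts.items()}


# ---------------------------------------------------------------------------

def _tube_channel_meta(panel: PanelConfig, tube_name: str) -> list[ChannelMeta]:
    tube = panel.tube(tube_name)
    meta = [ChannelMeta("FSC-A", ""), ChannelMeta("FSC-H", ""),
            ChannelMeta("SSC-A", "")]
    for det, fluor, marker in tube.channels:
        meta.append(ChannelMeta(det, f"{marker} {fluor}"))
    meta.append(ChannelMeta("TIME", "", 65536))
    return meta


def simulate_tube(panel: PanelConfig, tube_name: str,
                  abundances: dict[str, float], n: int, seed: int,
                  ) -> tuple[Sample, np.ndarray]:
    """Draw ``n`` raw-scale events for one tube.  Populations are drawn
    categorically by abundance; marker intensities are Gaussian on the
    transformed scale then mapped back through sinh; scatter is Gaussian per
    scatter mode with FSC-H = 0.95 FSC-A + noise.

    Returns (Sample, per-event population label array)."""
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-6:
        raise ScenarioError(f"abundances sum to {total:.6f}, not 1")
    rng = np.random.RandomState(seed % (2 ** 31))
    tube = panel.tube(tube_name)
    markers = tube.markers
    names = list(abundances)
    probs = np.array([abundances[p] for p in names])
    pop_idx = rng.choice(len(names), size=n, p=probs / probs.sum())
    labels = np.array(names, dtype=object)[pop_idx]

    spec = TransformSpec()
    n_ch = 3 + len(markers) + 1
    events = np.zeros((n, n_ch))
    for j, pname in enumerate(names):
        tmpl = _pop(tube_name, pname)
        sel = pop_idx == j
        m = int(sel.sum())
        if m == 0:
            continue
        (fm, fs), (sm, ss) = SCATTER_MODES[tmpl.scatter_mode]
        fsc = rng.normal(fm, fs, m)
        ssc = rng.normal(sm, ss, m)
        events[sel, 0] = fsc
        events[sel, 1] = FSC_H_SLOPE * fsc + rng.normal(0, FSC_H_NOISE, m)
        events[sel, 2] = ssc
        for mi, marker in enumerate(markers):
            lvl = tmpl.level_of(marker)
            mu = LEVEL_MEANS[lvl]
            sd = LEVEL_SPREADS[lvl] * tmpl.spread_mult
            y = rng.normal(mu, sd, m)
            events[sel, 3 + mi] = np.sinh(y) * DEFAULT_COFACTOR
        events[sel, -1] = 0.0
    events[:, -1] = np.sort(rng.uniform(0, TIME_SPAN, n))  # acquisition time
    np.clip(events[:, :-1], 0, RAW_MAX, out=events[:, :-1])

    meta = _tube_channel_meta(panel, tube_name)
    kw = {"$TIMESTEP": "0.01", "TUBE": tube_name}
    return Sample(events=events, channel_meta=meta, keywords=kw), labels


def inject_doublets(sample: Sample, labels: np.ndarray, tags: np.ndarray,
                    rate: float, seed: int):
    """Append round(rate*n) doublet events: scatter areas and fluorescence of
    two random singlets summed, FSC-H = max of the pair + 5% noise."""
    n = sample.n_events
    n_new = int(round(rate * n))
    if n_new == 0:
        return sample, labels, tags
    rng = np.random.RandomState((seed + 7) % (2 ** 31))
    i = rng.randint(0, n, n_new)
    j = rng.randint(0, n, n_new)
    ev = sample.events
    new = ev[i] + ev[j]
    h_col = 1
    new[:, h_col] = np.maximum(ev[i, h_col], ev[j, h_col]) * \
        (1.0 + rng.normal(0, 0.05, n_new))
    t_col = ev.shape[1] - 1
    new[:, t_col] = ev[i, t_col]
    np.clip(new[:, :-1], 0, RAW_MAX, out=new[:, :-1])
    out = replace(sample, events=np.vstack([ev, new]),
                  marker_map=dict(sample.marker_map))
    labels2 = np.concatenate([labels, np.array(["doublet"] * n_new,
                                               dtype=object)])
    tags2 = np.concatenate([tags, np.array(["doublet"] * n_new, dtype=object)])
    return out, labels2, tags2


def inject_debris(sample: Sample, labels: np.ndarray, tags: np.ndarray,
                  rate: float, seed: int):
    """Append round(rate*n) debris events: exponential low scatter,
    autofluorescence-only marker signal."""
    n = sample.n_events
    n_new = int(round(rate * n))
    if n_new == 0:
        return sample, labels, tags
    rng = np.random.RandomState((seed + 13) % (2 ** 31))
    n_ch = sample.events.shape[1]
    new = np.zeros((n_new, n_ch))
    fsc = rng.exponential(DEBRIS_FSC_SCALE, n_new)
    new[:, 0] = fsc
    new[:, 1] = FSC_H_SLOPE * fsc + rng.normal(0, FSC_H_NOISE / 2, n_new)
    new[:, 2] = rng.exponential(DEBRIS_SSC_SCALE, n_new)
    for c in range(3, n_ch - 1):
        new[:, c] = np.sinh(rng.normal(0.2, 0.2, n_new)) * DEFAULT_COFACTOR
    new[:, -1] = rng.uniform(0, TIME_SPAN, n_new)
    np.clip(new[:, :-1], 0, RAW_MAX, out=new[:, :-1])
    out = replace(sample, events=np.vstack([sample.events, new]),
                  marker_map=dict(sample.marker_map))
    labels2 = np.concatenate([labels, np.array(["debris"] * n_new,
                                               dtype=object)])
    tags2 = np.concatenate([tags, np.array(["debris"] * n_new, dtype=object)])
    return out, labels2, tags2


def inject_drift(sample: Sample, tags: np.ndarray, window: float, gain: float,
                 channel: str, seed: int):
    """Multiply one channel's raw intensity by ``gain`` inside a contiguous
    time window covering ``window`` of the acquisition; tag affected events."""
    if gain == 1.0 or window <= 0:
        return sample, tags
    rng = np.random.RandomState((seed + 29) % (2 ** 31))
    t = sample.time
    t0 = rng.uniform(0, (1 - window)) * TIME_SPAN
    t1 = t0 + window * TIME_SPAN
    affected = (t >= t0) & (t < t1)
    col = None
    for i, m in enumerate(sample.channel_meta):
        if m.detector == channel or m.stain.split(" ")[0] == channel:
            col = i
            break
    if col is None:
        raise KeyError(f"channel {channel!r} not in sample")
    ev = sample.events.copy()
    ev[affected, col] = np.clip(ev[affected, col] * gain, 0, RAW_MAX)
    tags2 = tags.copy()
    tags2[affected & (tags == "singlet")] = "drift-affected"
    out = replace(sample, events=ev, marker_map=dict(sample.marker_map))
    return out, tags2


def make_case(scenario: Scenario, panel: PanelConfig | None = None,
              ) -> tuple[dict[str, Sample], TruthTable]:
    """Build all three tubes for one case, artifacts included."""
    panel = panel or default_panel()
    scenario.validate()
    samples: dict[str, Sample] = {}
    truth = TruthTable()
    for ti, tube_name in enumerate(TUBE_ORDER):
        seed = (scenario.seed * 31 + ti * 101 + 17) % (2 ** 31)
        sample, labels = simulate_tube(
            panel, tube_name, scenario.abundances[tube_name],
            scenario.n_events, seed)
        tags = np.array(["singlet"] * sample.n_events, dtype=object)
        sample, labels, tags = inject_doublets(
            sample, labels, tags, scenario.doublet_rate, seed)
        sample, labels, tags = inject_debris(
            sample, labels, tags, scenario.debris_rate, seed)
        if scenario.drift:
            d = scenario.drift
            sample, tags = inject_drift(sample, tags, d["window"], d["gain"],
                                        d["channel"], seed)
        lineages = np.array([
            _pop(tube_name, str(l)).lineage if t in ("singlet", "drift-affected")
            else str(t)
            for l, t in zip(labels, tags)], dtype=object)
        samples[tube_name] = sample
        truth.labels[tube_name] = labels
        truth.artifacts[tube_name] = tags
        truth.lineages[tube_name] = lineages
    return samples, truth
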