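"""Panel description: tubes, markers, subset taxonomy, reference ranges.

A panel config declares what each tube measures and how subsets nest.  Tube
identity is keyed by *marker* names (normalized), not detectors or
fluorochromes, so a model trained on one reagent/color scheme transfers to
another carrying the same antibodies.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import yaml

LEVEL_NAMES = ("negative", "dim", "partial", "positive", "bright")
LEVEL_INDEX = {n: i for i, n in enumerate(LEVEL_NAMES)}

# Aliases collapse reagent-catalog spellings onto one marker identity.
_MARKER_ALIASES = {
    "CD279": "PD1", "TCRALPHABETA": "TCRAB", "TCRAB": "TCRAB",
    "TCRGAMMADELTA": "TCRGD", "TCRGD": "TCRGD", "HLADR": "HLADR",
    "IGD": "IGD", "ANTIKAPPA": "KAPPA", "ANTILAMBDA": "LAMBDA",
}


class PanelConfigError(ValueError):
    """Config file violates the panel schema; message names the key."""


class TubeMatchError(ValueError):
    """Sample stains match no tube, or more than one."""


def normalize_marker(name: str) -> str:
    """Canonical marker key: strip spaces/dashes/punctuation, uppercase,
    resolve Greek letters and catalog aliases."""
    s = name.strip()
    for greek, latin in (("α", "ALPHA"), ("β", "BETA"), ("γ", "GAMMA"),
                         ("δ", "DELTA"), ("κ", "KAPPA"), ("λ", "LAMBDA")):
        s = s.replace(greek, latin).replace(greek.upper(), latin)
    s = s.upper()
    s = re.sub(r"[\s\-_/()\.]+", "", s)
    return _MARKER_ALIASES.get(s, s)


@dataclass(frozen=True)
class Predicate:
    """Conjunction of marker-level atoms, e.g. CD4>=positive & CD8<=dim."""

    atoms: tuple[tuple[str, str, int], ...]  # (marker, op, level index)

    @classmethod
    def parse(cls, text: str) -> "Predicate":
        atoms = []
        for part in text.split("&"):
            m = re.match(r"\s*([\w+]+)\s*(>=|<=)\s*(\w+)\s*$", part)
            if not m:
                raise PanelConfigError(f"cannot parse predicate atom {part!r}")
            marker, op, level = m.groups()
            if level not in LEVEL_INDEX:
                raise PanelConfigError(f"unknown level {level!r} in predicate")
            atoms.append((normalize_marker(marker), op, LEVEL_INDEX[level]))
        return cls(tuple(atoms))

    @property
    def markers(self) -> set[str]:
        return {a[0] for a in self.atoms}

    def evaluate(self, code: dict[str, int]) -> bool:
        for marker, op, lvl in self.atoms:
            v = code[marker]
            if op == ">=" and not v >= lvl:
                return False
            if op == "<=" and not v <= lvl:
                return False
        return True


@dataclass(frozen=True)
class SubsetDef:
    name: str
    parent: str
    tube: str
    predicate: Predicate | None = None   # None for classifier-assigned lineages
    axis: str = "primary"


@dataclass
class TubeSpec:
    name: str
    channels: list[tuple[str, str, str]]  # (detector, fluorochrome, marker)
    fsc_a: str = "FSC-A"
    fsc_h: str = "FSC-H"
    ssc_a: str = "SSC-A"
    time_channel: str = "TIME"

    @property
    def markers(self) -> list[str]:
        return [normalize_marker(m) for (_, _, m) in self.channels]

    @property
    def scatter_channels(self) -> list[str]:
        return [self.fsc_a, self.fsc_h, self.ssc_a]

    def validate(self) -> None:
        mk = self.markers
        if len(set(mk)) != len(mk):
            dup = sorted({m for m in mk if mk.count(m) > 1})
            raise PanelConfigError(
                f"tube {self.name!r}: duplicate marker(s) {dup}")
        for ch in (self.fsc_a, self.fsc_h, self.ssc_a):
            if not ch:
                raise PanelConfigError(
                    f"tube {self.name!r}: scatter channel missing")


@dataclass
class ReferenceRanges:
    ranges: dict[str, tuple[float | None, float | None, str]] = field(
        default_factory=dict)  # subset -> (low, high, denominator)

    def validate(self) -> None:
        for name, (low, high, denom) in self.ranges.items():
            for b in (low, high):
                if b is not None and not (0 <= b <= 100):
                    raise PanelConfigError(
                        f"reference_ranges[{name!r}]: bound {b} outside [0,100]")
            if low is not None and high is not None and not low < high:
                raise PanelConfigError(
                    f"reference_ranges[{name!r}]: low must be < high")


@dataclass
class ALPSCriteria:
    """OR-logic diagnostic screen: TCRab+ DNT above either threshold flags
    the case (>1.5% of lymphocytes or >2.5% of CD3+ T cells by default)."""

    dnt_pct_of_lymphs: float = 1.5
    dnt_pct_of_cd3: float = 2.5

    def validate(self) -> None:
        if self.dnt_pct_of_lymphs <= 0 or self.dnt_pct_of_cd3 <= 0:
            raise PanelConfigError("alps_criteria thresholds must be > 0")


@dataclass
class PanelConfig:
    tubes: list[TubeSpec]
    taxonomy: dict[str, list[SubsetDef]]   # tube name -> subset definitions
    reference_ranges: ReferenceRanges
    alps_criteria: ALPSCriteria
    version: str = "0"

    def tube(self, name: str) -> TubeSpec:
        for t in self.tubes:
            if t.name == name:
                return t
        raise KeyError(f"no tube named {name!r}")

    def subsets_for(self, tube_name: str) -> list[SubsetDef]:
        return self.taxonomy.get(tube_name, [])

    def lineages_for(self, tube_name: str) -> list[str]:
        return [s.name for s in self.subsets_for(tube_name)
                if s.predicate is None]

    def validate(self) -> None:
        for t in self.tubes:
            t.validate()
        for tube_name, subsets in self.taxonomy.items():
            tube = self.tube(tube_name)
            markers = set(tube.markers)
            names = {"lymphocytes"} | {s.name for s in subsets}
            for s in subsets:
                if s.parent not in names:
                    raise PanelConfigError(
                        f"taxonomy[{tube_name}][{s.name!r}]: unknown parent "
                        f"{s.parent!r}")
                if s.predicate is not None:
                    missing = s.predicate.markers - markers
                    if missing:
                        raise PanelConfigError(
                            f"taxonomy[{tube_name}][{s.name!r}]: predicate "
                            f"references marker(s) {sorted(missing)} absent "
                            f"from tube")
            # tree check: walking parents must terminate at the root
            by_name = {s.name: s for s in subsets}
            for s in subsets:
                seen, cur = set(), s.name
                while cur != "lymphocytes":
                    if cur in seen:
                        raise PanelConfigError(
                            f"taxonomy[{tube_name}]: cycle at {cur!r}")
                    seen.add(cur)
                    cur = by_name[cur].parent if cur in by_name else "lymphocytes"
        self.reference_ranges.validate()
        self.alps_criteria.validate()


# ---------------------------------------------------------------------------

def _build_panel(doc: dict) -> PanelConfig:
    try:
        tubes = []
        for td in doc["tubes"]:
            sc = td.get("scatter_channels", {})
            tubes.append(TubeSpec(
                name=td["name"],
                channels=[tuple(c) for c in td["channels"]],
                fsc_a=sc.get("fsc_a", "FSC-A"),
                fsc_h=sc.get("fsc_h", "FSC-H"),
                ssc_a=sc.get("ssc_a", "SSC-A"),
                time_channel=td.get("time_channel", "TIME"),
            ))
        taxonomy: dict[str, list[SubsetDef]] = {}
        for tube_name, entries in doc.get("taxonomy", {}).items():
            subs = []
            for e in entries:
                pred = Predicate.parse(e["predicate"]) if "predicate" in e else None
                subs.append(SubsetDef(
                    name=e["name"], parent=e["parent"], tube=tube_name,
                    predicate=pred, axis=e.get("axis", "primary")))
            taxonomy[tube_name] = subs
        rr = ReferenceRanges({
            name: (spec.get("low"), spec.get("high"), spec["denominator"])
            for name, spec in (doc.get("reference_ranges") or {}).items()})
        ac_doc = doc.get("alps_criteria") or {}
        ac = ALPSCriteria(
            dnt_pct_of_lymphs=float(ac_doc.get("dnt_pct_of_lymphs", 1.5)),
            dnt_pct_of_cd3=float(ac_doc.get("dnt_pct_of_cd3", 2.5)))
    except (KeyError, TypeError) as exc:
        raise PanelConfigError(f"panel config missing/invalid key: {exc}") from exc
    panel = PanelConfig(tubes=tubes, taxonomy=taxonomy, reference_ranges=rr,
                        alps_criteria=ac, version=str(doc.get("version", "0")))
    panel.validate()
    return panel


def load_panel(source: str) -> PanelConfig:
    """Load and validate a panel config from YAML text or a file path."""
    if "\n" not in source and source.endswith((".yaml", ".yml")):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict):
        raise PanelConfigError("panel config must be a mapping")
    return _build_panel(doc)


def default_panel() -> PanelConfig:
    """The bundled 3-tube ALPS panel."""
    text = (importlib.resources.files("immunogate.data") / "alps_panel.yaml"
            ).read_text()
    return load_panel(text)


def serialize_panel(panel: PanelConfig) -> str:
    """Inverse of load_panel (round-trips field-for-field)."""
    doc: dict = {"version": panel.version, "tubes": [], "taxonomy": {},
                 "reference_ranges": {}, "alps_criteria": {
                     "dnt_pct_of_lymphs": panel.alps_criteria.dnt_pct_of_lymphs,
                     "dnt_pct_of_cd3": panel.alps_criteria.dnt_pct_of_cd3}}
    for t in panel.tubes:
        doc["tubes"].append({
            "name": t.name,
            "scatter_channels": {"fsc_a": t.fsc_a, "fsc_h": t.fsc_h,
                                 "ssc_a": t.ssc_a},
            "time_channel": t.time_channel,
            "channels": [list(c) for c in t.channels]})
    for tube_name, subs in panel.taxonomy.items():
        entries = []
        for s in subs:
            e: dict = {"name": s.name, "parent": s.parent}
            if s.predicate is None:
                e["level"] = "lineage"
            else:
                e["predicate"] = " & ".join(
                    f"{m}{op}{LEVEL_NAMES[lvl]}" for m, op, lvl in
                    s.predicate.atoms)
            if s.axis != "primary":
                e["axis"] = s.axis
            entries.append(e)
        doc["taxonomy"][tube_name] = entries
    for name, (low, high, denom) in panel.reference_ranges.ranges.items():
        doc["reference_ranges"][name] = {"low": low, "high": high,
                                         "denominator": denom}
    return yaml.safe_dump(doc, sort_keys=False)


def match_tube(sample, panel: PanelConfig) -> TubeSpec:
    """Identify which tube a sample is, by its stain (marker) names; attaches
    the marker -> column map to the sample.  Channel order does not matter."""
    stains = {}
    for i, m in enumerate(sample.channel_meta):
        if not m.stain:
            continue
        # $PnS is often "MARKER FLUOROCHROME"; index both spellings
        stains.setdefault(normalize_marker(m.stain), i)
        head = m.stain.split()[0]
        stains.setdefault(normalize_marker(head), i)
    matches = [t for t in panel.tubes if set(t.markers) <= set(stains)]
    if not matches:
        raise TubeMatchError(
            f"stains {sorted(stains)} match no tube in panel")
    if len(matches) > 1:
        raise TubeMatchError(
            f"stains match multiple tubes: {[t.name for t in matches]}")
    tube = matches[0]
    sample.marker_map = {mk: stains[mk] for mk in tube.markers}
    return tube
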