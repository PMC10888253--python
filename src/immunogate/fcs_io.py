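"""Reading and writing FCS 3.0/3.1 list-mode event files.

Flow cytometers emit FCS files: an ASCII header with segment offsets, a
delimited TEXT segment of ``$KEY/value`` metadata, and a binary DATA segment
holding the event-by-channel intensity matrix.  Beckman Coulter LMD
containers concatenate an FCS 2.0 and an FCS 3.0 dataset; only the FCS 3.0
segment (higher dynamic range) is read here.

Reading applies the stored spillover (compensation) matrix to fluorescence
channels when present.  Analysis happens on a transformed scale: asinh with
a per-channel cofactor for fluorescence, linear for scatter and time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Cofactor conventional for PMT-based clinical analyzers of this class;
# the raw intensity axis spans roughly [0, 2^20].
DEFAULT_COFACTOR = 150.0
RAW_MAX = float(2 ** 20)

SCATTER_NAMES = ("FSC-A", "FSC-H", "SSC-A", "SSC-H", "FSC-W", "SSC-W")
TIME_NAMES = ("TIME",)


class FcsIntegrityError(ValueError):
    """The file failed the stage-1 integrity check (truncated DATA, $TOT
    mismatch, unsupported datatype, bad header)."""


class FcsStateError(RuntimeError):
    """Operation applied in the wrong sample state (e.g. double transform)."""


def is_scatter(name: str) -> bool:
    return name.upper().replace(" ", "") in {s.replace("-", "-") for s in SCATTER_NAMES} or \
        name.upper() in SCATTER_NAMES


def is_time(name: str) -> bool:
    return name.upper() in TIME_NAMES


@dataclass
class TransformSpec:
    """Per-channel intensity transform: asinh(x / cofactor) for fluorescence,
    identity for scatter and time channels."""

    cofactor: float = DEFAULT_COFACTOR
    per_channel: dict[str, str] = field(default_factory=dict)  # name -> "asinh"|"linear"

    def rule_for(self, channel_name: str) -> str:
        if channel_name in self.per_channel:
            return self.per_channel[channel_name]
        if is_scatter(channel_name) or is_time(channel_name):
            return "linear"
        return "asinh"

    def forward(self, x: np.ndarray, channel_name: str) -> np.ndarray:
        if self.rule_for(channel_name) == "asinh":
            return np.arcsinh(x / self.cofactor)
        return x

    def inverse(self, y: np.ndarray, channel_name: str) -> np.ndarray:
        if self.rule_for(channel_name) == "asinh":
            return np.sinh(y) * self.cofactor
        return y


@dataclass
class ChannelMeta:
    detector: str          # $PnN
    stain: str             # $PnS (marker / fluorochrome label), may be ""
    range: float = RAW_MAX


@dataclass
class Sample:
    """One tube's events: an (n_events, n_channels) float matrix plus FCS
    metadata.  ``marker_map`` (marker -> column index) is attached by
    ``panel.match_tube``."""

    events: np.ndarray
    channel_meta: list[ChannelMeta]
    keywords: dict[str, str] = field(default_factory=dict)
    transformed: bool = False
    transform: TransformSpec | None = None
    compensated: bool = False
    marker_map: dict[str, int] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])

    @property
    def channel_names(self) -> list[str]:
        return [m.detector for m in self.channel_meta]

    @property
    def stain_names(self) -> list[str]:
        return [m.stain for m in self.channel_meta]

    def column(self, name: str) -> np.ndarray:
        """Column by detector name, stain name, or (if set) marker name."""
        if name in self.marker_map:
            return self.events[:, self.marker_map[name]]
        for i, m in enumerate(self.channel_meta):
            if m.detector == name or m.stain == name:
                return self.events[:, i]
        raise KeyError(f"channel {name!r} not found")

    @property
    def time(self) -> np.ndarray | None:
        for i, m in enumerate(self.channel_meta):
            if is_time(m.detector):
                return self.events[:, i]
        return None

    def subset(self, mask: np.ndarray) -> "Sample":
        return replace(self, events=self.events[mask],
                       marker_map=dict(self.marker_map))


# ---------------------------------------------------------------------------
# FCS parsing

_HEADER_LEN = 58


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsIntegrityError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # Fields are delimiter-separated; a doubled delimiter escapes a literal one.
    parts = body.strip(delim).split(delim)
    kv: dict[str, str] = {}
    for i in range(0, len(parts) - 1, 2):
        kv[parts[i].strip().upper()] = parts[i + 1]
    return kv


def _find_fcs3_offset(buf: bytes) -> int:
    """Offset of the FCS3.x dataset; LMD containers embed it after an FCS2.0
    segment, so scan for the version signature."""
    if buf[:6] in (b"FCS3.0", b"FCS3.1"):
        return 0
    for sig in (b"FCS3.1", b"FCS3.0"):
        pos = buf.find(sig)
        if pos > 0:
            return pos
    raise FcsIntegrityError("no FCS3.0/FCS3.1 header found (unsupported file)")


def _parse_spillover(value: str) -> tuple[list[str], np.ndarray]:
    toks = [t.strip() for t in value.split(",")]
    n = int(float(toks[0]))
    names = toks[1:1 + n]
    vals = np.array([float(t) for t in toks[1 + n:1 + n + n * n]], dtype=float)
    if vals.size != n * n:
        raise FcsIntegrityError("$SPILLOVER matrix size mismatch")
    return names, vals.reshape(n, n)


def read_fcs(path: str, compensate: bool = True) -> Sample:
    """Read an FCS 3.0/3.1 file (or the FCS3 segment of an LMD container).

    Performs the stage-1 integrity check: header offsets must be coherent,
    ``$TOT`` must match the DATA segment length, and ``$DATATYPE`` must be
    F, D or I.  Applies ``$SPILLOVER`` compensation to fluorescence channels
    when present.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    base = _find_fcs3_offset(buf)
    header = buf[base:base + _HEADER_LEN]
    if len(header) < _HEADER_LEN:
        raise FcsIntegrityError("truncated FCS header")
    try:
        text_start = int(header[10:18])
        text_end = int(header[18:26])
        data_start = int(header[26:34])
        data_end = int(header[34:42])
    except ValueError as exc:
        raise FcsIntegrityError(f"malformed header offsets: {exc}") from exc

    text = _parse_text_segment(buf[base + text_start: base + text_end + 1])
    if data_start == 0 and data_end == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")

    if dtype_code == "F":
        itemsize, fmt = 4, "f"
    elif dtype_code == "D":
        itemsize, fmt = 8, "d"
    elif dtype_code == "I":
        bits = int(text.get("$P1B", "32"))
        if bits not in (16, 32):
            raise FcsIntegrityError(f"unsupported integer width {bits}")
        itemsize, fmt = bits // 8, ("H" if bits == 16 else "I")
    else:
        raise FcsIntegrityError(f"unsupported $DATATYPE {dtype_code!r}")

    expected = n_tot * n_par * itemsize
    data_raw = buf[base + data_start: base + data_end + 1]
    if len(data_raw) < expected:
        raise FcsIntegrityError(
            f"DATA segment holds {len(data_raw)} bytes; "
            f"$TOT={n_tot} x $PAR={n_par} needs {expected}")
    order = "<" if little else ">"
    arr = np.frombuffer(data_raw[:expected], dtype=f"{order}{fmt}")
    events = arr.reshape(n_tot, n_par).astype(np.float64)
    if not np.all(np.isfinite(events)):
        raise FcsIntegrityError("non-finite values in DATA segment")

    meta = []
    for p in range(1, n_par + 1):
        det = text.get(f"$P{p}N", f"P{p}")
        stain = text.get(f"$P{p}S", "")
        rng = float(text.get(f"$P{p}R", RAW_MAX))
        meta.append(ChannelMeta(det, stain, rng))

    sample = Sample(events=events, channel_meta=meta, keywords=dict(text))
    if compensate and "$SPILLOVER" in text:
        sample = _apply_spillover(sample, text["$SPILLOVER"])
    return sample


def _apply_spillover(sample: Sample, spill_kw: str) -> Sample:
    names, spill = _parse_spillover(spill_kw)
    idx = []
    for nm in names:
        cols = [i for i, m in enumerate(sample.channel_meta)
                if m.detector == nm or m.stain == nm]
        if not cols:
            raise FcsIntegrityError(f"$SPILLOVER channel {nm!r} not in file")
        idx.append(cols[0])
    if np.allclose(spill, np.eye(len(names))):
        sample.compensated = True
        return sample
    comp = np.linalg.inv(spill)
    ev = sample.events.copy()
    ev[:, idx] = ev[:, idx] @ comp
    return replace(sample, events=ev, compensated=True,
                   marker_map=dict(sample.marker_map))


# ---------------------------------------------------------------------------
# FCS writing

def write_fcs(sample: Sample, path: str) -> str:
    """Write a standards-conformant FCS 3.1 file ($DATATYPE F, list mode,
    little-endian).  Refuses to write a sample with zero events."""
    if sample.n_events == 0:
        raise ValueError("refusing to write an FCS file with zero events")
    if sample.transformed:
        raise FcsStateError("write_fcs expects raw-scale (untransformed) data")
    n, p = sample.events.shape
    kv: dict[str, str] = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$TOT": str(n), "$PAR": str(p), "$NEXTDATA": "0",
    }
    for j, m in enumerate(sample.channel_meta, start=1):
        kv[f"$P{j}N"] = m.detector
        if m.stain:
            kv[f"$P{j}S"] = m.stain
        kv[f"$P{j}B"] = "32"
        kv[f"$P{j}E"] = "0,0"
        kv[f"$P{j}R"] = str(int(max(m.range, 1)))
    for extra in ("$TIMESTEP", "$SPILLOVER", "$CYT"):
        if extra in sample.keywords:
            kv[extra] = sample.keywords[extra]

    data = sample.events.astype("<f4").tobytes()
    delim = "/"

    def render_text(begin_data: int, end_data: int) -> bytes:
        kv2 = dict(kv)
        kv2["$BEGINDATA"] = str(begin_data)
        kv2["$ENDDATA"] = str(end_data)
        kv2["$BEGINANALYSIS"] = "0"
        kv2["$ENDANALYSIS"] = "0"
        kv2["$BEGINSTEXT"] = "0"
        kv2["$ENDSTEXT"] = "0"
        out = delim
        for k, v in kv2.items():
            out += f"{k}{delim}{v}{delim}"
        return out.encode("latin-1")

    # Two-pass: TEXT length depends on the data offsets it declares.
    text_start = _HEADER_LEN
    text_bytes = render_text(0, 0)
    for _ in range(4):
        text_end = text_start + len(text_bytes) - 1
        data_start = text_end + 1
        data_end = data_start + len(data) - 1
        new_text = render_text(data_start, data_end)
        if len(new_text) == len(text_bytes):
            text_bytes = new_text
            break
        text_bytes = new_text
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1

    header = (b"FCS3.1    "
              + f"{text_start:>8d}".encode()
              + f"{text_end:>8d}".encode()
              + (f"{data_start:>8d}".encode() if data_start <= 99999999 else b"       0")
              + (f"{data_end:>8d}".encode() if data_end <= 99999999 else b"       0"))
    assert len(header) == 42
    header = header + b" " * (_HEADER_LEN - len(header))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# Transform

def apply_transform(sample: Sample, spec: TransformSpec | None = None) -> Sample:
    """Map fluorescence channels to asinh(x / cofactor); scatter and time stay
    linear.  Errors if the sample was already transformed."""
    if sample.transformed:
        raise FcsStateError("sample already transformed")
    spec = spec or TransformSpec()
    ev = sample.events.copy()
    for i, m in enumerate(sample.channel_meta):
        ev[:, i] = spec.forward(ev[:, i], m.detector)
    return replace(sample, events=ev, transformed=True, transform=spec,
                   marker_map=dict(sample.marker_map))
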