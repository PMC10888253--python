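"""Event cleanup before clustering: time-segment QC, doublet exclusion,
debris removal.

Stage order is fixed: signal/flow stability check over acquisition time,
then doublets (events whose FSC-A exceeds the singlet FSC-A/FSC-H ridge
prediction), then debris (the joint low-FSC-A/low-SSC-A cloud).  Each event
is attributed to the first stage that drops it, so the per-stage removal
fractions are disjoint and sum to the total loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gaussian_kde

from .fcs_io import Sample

MIN_EVENTS_REQUIRED = 100_000   # acquisition floor for a reportable case
MIN_SURVIVING_EVENTS = 500


class SampleRejectedError(ValueError):
    """Too few usable events to analyze."""


class FitError(ValueError):
    pass


@dataclass
class QCResult:
    event_mask: np.ndarray                       # True = keep
    bins_dropped: list[tuple[tuple[float, float], str]] = field(
        default_factory=list)                    # ((t0, t1), "rate"|"level")
    min_events_required: int = MIN_EVENTS_REQUIRED
    pass_min_events: bool = True
    fractions_removed: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_events": int(self.event_mask.size),
            "n_kept": int(self.event_mask.sum()),
            "bins_dropped": [
                {"window": [float(a), float(b)], "reason": r}
                for (a, b), r in self.bins_dropped],
            "min_events_required": self.min_events_required,
            "pass_min_events": bool(self.pass_min_events),
            "fractions_removed": {k: float(v)
                                  for k, v in self.fractions_removed.items()},
        }


@dataclass
class DoubletModel:
    """Robust singlet ridge FSC-H = slope * FSC-A + intercept.  An event is a
    doublet when its FSC-A exceeds the ridge's FSC-A prediction from FSC-H
    by more than ratio_threshold (relative)."""

    slope: float
    intercept: float
    ratio_threshold: float = 0.25


@dataclass
class CleanSample:
    sample: Sample            # surviving events only (raw scale)
    qc: QCResult
    viability_proxy: float    # scatter-based survival fraction, NOT a dye


# ---------------------------------------------------------------------------
# Stage 1: time-segment QC

def time_qc(sample: Sample, n_bins: int = 50, mad_k: float = 5.0,
            min_events_required: int = MIN_EVENTS_REQUIRED) -> QCResult:
    """Drop time bins whose event rate or any channel median jumps.

    Events are split into ``n_bins`` equal-count bins by acquisition time; a
    bin is dropped when its event rate or any channel's median deviates from
    the cross-bin median by more than ``mad_k`` robust standard deviations
    (1.4826 * MAD, floored to avoid zero-MAD blowups).
    """
    n = sample.n_events
    mask = np.ones(n, dtype=bool)
    res = QCResult(event_mask=mask,
                   min_events_required=min_events_required,
                   pass_min_events=n >= min_events_required)
    t = sample.time
    if t is None or n < n_bins * 20:
        res.fractions_removed["time_qc"] = 0.0
        return res

    order = np.argsort(t, kind="stable")
    edges_idx = np.linspace(0, n, n_bins + 1).astype(int)
    drop_bins: list[tuple[int, str]] = []

    t_sorted = t[order]
    spans = np.array([
        max(t_sorted[min(edges_idx[b + 1], n - 1)] - t_sorted[edges_idx[b]], 1e-12)
        for b in range(n_bins)])
    counts = np.diff(edges_idx)
    rates = counts / spans

    def robust_dev(vals: np.ndarray, scale_floor: float) -> np.ndarray:
        med = np.median(vals)
        sigma = 1.4826 * np.median(np.abs(vals - med))
        sigma = max(sigma, scale_floor, 1e-12)
        return np.abs(vals - med) / sigma

    rate_dev = robust_dev(rates, 0.01 * max(np.median(rates), 1e-12))

    fluor_cols = [i for i, m in enumerate(sample.channel_meta)
                  if not _is_time_col(sample, i)]
    ev_sorted = sample.events[order]
    bin_n = max(int(n / n_bins), 1)
    level_dev = np.zeros(n_bins)
    for col in fluor_cols:
        # Deviations are measured in rank space (pooled ECDF of the channel):
        # on a multimodal channel a bin quantile can hop between modes on the
        # intensity axis while moving smoothly in rank, so rank space is the
        # only scale where "abrupt" is distribution-free.  The bin median
        # alone can be blind to a gain step (a shifted mode may land at the
        # same pooled rank), so all three quartiles are checked.  Floor at
        # the binomial sampling noise of a bin quantile.
        pooled = np.sort(sample.events[:, col])
        for q in (0.25, 0.5, 0.75):
            binvals = np.array([
                np.quantile(ev_sorted[edges_idx[b]:edges_idx[b + 1], col], q)
                for b in range(n_bins)])
            binq = np.searchsorted(pooled, binvals, side="left") / n
            floor = np.sqrt(max(q * (1 - q), 0.1) / bin_n)
            level_dev = np.maximum(level_dev, robust_dev(binq, floor))

    # hysteresis: a bin neighboring a dropped bin falls at half threshold,
    # so a shift window straddling bin edges is excised whole
    def hysteresis(dev: np.ndarray) -> np.ndarray:
        hard = dev > mad_k
        soft = dev > 0.5 * mad_k
        grown = hard.copy()
        while True:
            neigh = np.r_[grown[1:], False] | np.r_[False, grown[:-1]]
            add = soft & neigh & ~grown
            if not add.any():
                break
            grown |= add
        return grown

    for b in np.nonzero(hysteresis(rate_dev))[0]:
        drop_bins.append((int(b), "rate"))
    for b in np.nonzero(hysteresis(level_dev))[0]:
        if not any(d[0] == b for d in drop_bins):
            drop_bins.append((int(b), "level"))

    for b, reason in sorted(drop_bins):
        idx = order[edges_idx[b]:edges_idx[b + 1]]
        mask[idx] = False
        res.bins_dropped.append(
            ((float(t_sorted[edges_idx[b]]),
              float(t_sorted[min(edges_idx[b + 1], n - 1)])), reason))
    if not mask.any():
        raise SampleRejectedError("time QC dropped every bin")
    res.fractions_removed["time_qc"] = 1.0 - mask.mean()
    return res


def _is_time_col(sample: Sample, i: int) -> bool:
    return sample.channel_meta[i].detector.upper() == "TIME"


# ---------------------------------------------------------------------------
# Stage 2: doublets

def fit_doublet_model(fsc_a: np.ndarray, fsc_h: np.ndarray,
                      ratio_threshold: float = 0.25,
                      n_iter: int = 20) -> DoubletModel:
    """Robust line through the singlet ridge in (FSC-A, FSC-H).

    Iteratively reweighted least squares with Tukey bisquare weights, so the
    doublet minority (high FSC-A for their FSC-H) gets zero weight.
    """
    fsc_a = np.asarray(fsc_a, float)
    fsc_h = np.asarray(fsc_h, float)
    if fsc_a.size < 100:
        raise FitError("need >= 100 events to fit the doublet model")
    if np.std(fsc_a) < 1e-12 or np.std(fsc_h) < 1e-12:
        raise FitError("degenerate scatter: zero variance in FSC-A or FSC-H")

    X = np.column_stack([fsc_a, np.ones_like(fsc_a)])
    beta, *_ = np.linalg.lstsq(X, fsc_h, rcond=None)
    for _ in range(n_iter):
        resid = fsc_h - X @ beta
        s = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        s = max(s, 1e-9 * max(np.median(np.abs(fsc_h)), 1.0))
        u = resid / (4.685 * s)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        if w.sum() < 10:
            break
        W = w[:, None] * X
        beta_new = np.linalg.solve(X.T @ W, (w * fsc_h) @ X)
        if np.allclose(beta_new, beta, rtol=1e-12, atol=1e-12):
            beta = beta_new
            break
        beta = beta_new
    slope, intercept = float(beta[0]), float(beta[1])
    if slope <= 0:
        raise FitError(f"non-positive singlet ridge slope ({slope:.3g})")
    return DoubletModel(slope=slope, intercept=intercept,
                        ratio_threshold=ratio_threshold)


def remove_doublets(sample: Sample, model: DoubletModel) -> np.ndarray:
    """Keep-mask: drop events whose FSC-A exceeds the ridge prediction
    (FSC-H - intercept)/slope by more than the relative threshold."""
    fsc_a = sample.column("FSC-A")
    fsc_h = sample.column("FSC-H")
    pred_a = (fsc_h - model.intercept) / model.slope
    return ~(fsc_a > pred_a * (1.0 + model.ratio_threshold))


# ---------------------------------------------------------------------------
# Stage 3: debris

def _valley_cut(values: np.ndarray, fallback_q: float) -> float:
    """1-D KDE valley between the low-intensity (debris) mode and the main
    leukocyte modes; falls back to the ``fallback_q`` quantile when no
    bimodal structure exists."""
    v = np.asarray(values, float)
    fallback = float(np.quantile(v, fallback_q))
    lo, hi = np.quantile(v, [0.001, 0.999])
    if hi - lo < 1e-9:
        return fallback
    sub = v if v.size <= 20000 else v[:: v.size // 20000 + 1]
    try:
        kde = gaussian_kde(sub)   # Silverman-style bandwidth (scott default ~)
        kde.set_bandwidth("silverman")
    except np.linalg.LinAlgError:
        return fallback
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    # local maxima (tiny-height peaks are noise, not modes)
    rising = np.r_[True, dens[1:] > dens[:-1]]
    falling = np.r_[dens[:-1] > dens[1:], True]
    peaks = np.nonzero(rising & falling & (dens > 0.01 * dens.max()))[0]
    if len(peaks) < 2:
        return fallback
    main = peaks[np.argmax(dens[peaks])]
    # the debris mode must sit well below the main leukocyte mode; otherwise
    # there is no low-scatter cloud and the quantile floor applies
    low_peaks = peaks[grid[peaks] < 0.5 * grid[main]]
    if len(low_peaks) == 0:
        return fallback
    first = low_peaks[0]
    nxt = peaks[peaks > first][0]          # nearest mode above the debris mode
    valley = first + int(np.argmin(dens[first:nxt + 1]))
    return float(grid[valley])


def remove_debris(sample: Sample, fsc_quantile: float = 0.02,
                  ssc_quantile: float = 0.02) -> np.ndarray:
    """Keep-mask: drop events in the joint low-scatter corner
    (FSC-A < cut_f AND SSC-A < cut_s), cuts found at the density valley
    between the debris and leukocyte modes on each axis."""
    fsc = sample.column("FSC-A")
    ssc = sample.column("SSC-A")
    cut_f = _valley_cut(fsc, fsc_quantile)
    cut_s = _valley_cut(ssc, ssc_quantile)
    return ~((fsc < cut_f) & (ssc < cut_s))


# ---------------------------------------------------------------------------
# Composition

def pregate(sample: Sample, n_bins: int = 50, mad_k: float = 5.0,
            ratio_threshold: float = 0.25,
            fsc_quantile: float = 0.02, ssc_quantile: float = 0.02,
            min_events_required: int = MIN_EVENTS_REQUIRED) -> CleanSample:
    """time_qc -> doublets -> debris; cumulative keep-mask with per-stage
    attribution.  Rejects the sample when < 500 events survive."""
    n = sample.n_events
    if n == 0:
        raise SampleRejectedError("empty sample")
    qc = time_qc(sample, n_bins=n_bins, mad_k=mad_k,
                 min_events_required=min_events_required)
    mask = qc.event_mask.copy()

    survivors = sample.subset(mask)
    if survivors.n_events < max(100, MIN_SURVIVING_EVENTS):
        raise SampleRejectedError("too few events after time QC")
    model = fit_doublet_model(survivors.column("FSC-A"),
                              survivors.column("FSC-H"),
                              ratio_threshold=ratio_threshold)
    keep_singlet = remove_doublets(survivors, model)
    idx_alive = np.nonzero(mask)[0]
    mask[idx_alive[~keep_singlet]] = False
    qc.fractions_removed["doublets"] = float((~keep_singlet).sum()) / n

    survivors2 = sample.subset(mask)
    keep_clean = remove_debris(survivors2, fsc_quantile, ssc_quantile)
    idx_alive2 = np.nonzero(mask)[0]
    mask[idx_alive2[~keep_clean]] = False
    qc.fractions_removed["debris"] = float((~keep_clean).sum()) / n

    if mask.sum() < MIN_SURVIVING_EVENTS:
        raise SampleRejectedError(
            f"only {int(mask.sum())} events survive pre-gating")

    post_qc = int(qc.event_mask.sum())
    viability = float(mask.sum()) / post_qc if post_qc else 0.0
    qc.event_mask = mask
    clean = replace(sample, events=sample.events[mask],
                    marker_map=dict(sample.marker_map))
    # doublet model retained for report scatterplots
    clean.keywords = dict(sample.keywords)
    clean.keywords["_doublet_slope"] = repr(model.slope)
    clean.keywords["_doublet_intercept"] = repr(model.intercept)
    return CleanSample(sample=clean, qc=qc, viability_proxy=viability)
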