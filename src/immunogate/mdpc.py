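"""Density-phenotype coupled clustering (the automatic gating engine).

Works in all marker and scatter dimensions at once.  Two ingredients:

* a per-channel five-level discretizer (negative / dim / partial / positive /
  bright) anchored on the negative (lowest-intensity) density mode;
* bottom-up density clustering: kNN density estimation, each event linked to
  its nearest higher-density neighbor (density-peak seeding), followed by
  iterative merging of adjacent seed clusters that agree on BOTH criteria —
  identical per-marker phenotype code AND density continuity across the
  shared boundary (saddle-to-peak density ratio above ``rho_merge``).

Everything is deterministic given the input event order; no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.neighbors import NearestNeighbors

from .panel import LEVEL_NAMES, TubeSpec
from .qc_pregate import CleanSample

DOWNSAMPLE_CAP = 50_000
DOWNSAMPLE_SEED = 12345     # fixed: clustering is deterministic by contract


@dataclass
class ChannelLevels:
    """Five-level partition of one channel's transformed intensity axis.

    b1 sits 2 robust SDs above the negative mode; the span from b1 to the
    99.9th percentile is split into four equal-width bands (dim, partial,
    positive, bright).
    """

    boundaries: tuple[float, float, float, float]   # b1 < b2 < b3 < b4
    neg_mode: float
    neg_spread: float
    degenerate: bool = False

    def discretize(self, values) -> np.ndarray:
        """Level index 0..4; bands are left-closed: [b1,b2) -> dim etc."""
        return np.searchsorted(np.asarray(self.boundaries),
                               np.asarray(values, float), side="right")


def fit_discretizer(values: np.ndarray) -> ChannelLevels:
    """Fit five-level boundaries to one channel (transformed scale).

    The negative mode is the lowest-intensity major density mode (peak with
    >= 5% of the maximum density); its spread is a reflected MAD of the
    values at or below it.  Channels with no usable structure collapse to a
    degenerate all-negative rule with boundaries just above the 2nd
    percentile.
    """
    v = np.asarray(values, float)
    if v.size < 1000:
        raise ValueError("need >= 1000 values to fit a discretizer")
    lo, hi = np.quantile(v, [0.0, 1.0])
    span = hi - lo
    if span < 1e-12:
        return _degenerate_levels(v)

    sub = v if v.size <= 20000 else v[:: v.size // 20000 + 1]
    try:
        kde = gaussian_kde(sub)
        kde.set_bandwidth("silverman")
        grid = np.linspace(lo - 0.02 * span, hi + 0.02 * span, 512)
        dens = kde(grid)
    except np.linalg.LinAlgError:
        return _degenerate_levels(v)
    rising = np.r_[True, dens[1:] > dens[:-1]]
    falling = np.r_[dens[:-1] > dens[1:], True]
    peaks = np.nonzero(rising & falling & (dens >= 0.05 * dens.max()))[0]
    if len(peaks) == 0:
        return _degenerate_levels(v)
    mu0 = float(grid[peaks[0]])

    below = v[v <= mu0]
    if below.size < 5:
        sigma0 = 1.4826 * np.median(np.abs(v - mu0)) / 2
    else:
        sigma0 = 1.4826 * float(np.median(mu0 - below))
    sigma0 = max(sigma0, 1e-6 * max(span, 1.0))
    b1 = mu0 + 2.0 * sigma0
    q999 = float(np.quantile(v, 0.999))
    if q999 <= b1 + 1e-9:
        # no expression above the negative band: unimodal channel
        return _degenerate_levels(v, mu0=mu0, sigma0=sigma0)
    step = (q999 - b1) / 4.0
    bounds = (b1, b1 + step, b1 + 2 * step, b1 + 3 * step)
    return ChannelLevels(boundaries=bounds, neg_mode=mu0, neg_spread=sigma0)


def _degenerate_levels(v: np.ndarray, mu0: float | None = None,
                       sigma0: float | None = None) -> ChannelLevels:
    q02 = float(np.quantile(v, 0.02))
    eps = max(1e-6, 1e-6 * abs(q02))
    hi = float(np.quantile(v, 1.0))
    b1 = max(q02, hi) + eps
    bounds = (b1, b1 + eps, b1 + 2 * eps, b1 + 3 * eps)
    return ChannelLevels(boundaries=bounds,
                         neg_mode=mu0 if mu0 is not None else q02,
                         neg_spread=sigma0 if sigma0 is not None else eps,
                         degenerate=True)


def discretize(value, levels: ChannelLevels):
    """Five-level code of a single value (or array)."""
    out = levels.discretize(value)
    return out if isinstance(value, np.ndarray) else int(out)


# ---------------------------------------------------------------------------

@dataclass
class ClusterInfo:
    cluster_id: int
    size: int
    marker_medians: dict[str, float]
    code: tuple[int, ...]                  # per-marker level, tube order
    peak_density: float
    scatter_medians: dict[str, float]

    def code_string(self, markers: list[str]) -> str:
        return "|".join(f"{m}:{LEVEL_NAMES[l][:3]}"
                        for m, l in zip(markers, self.code))


@dataclass
class ClusterSet:
    assignment: np.ndarray                 # per-event cluster id (0..K-1)
    clusters: list[ClusterInfo]
    markers: list[str]
    levels: dict[str, ChannelLevels]
    saddles: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def summary_table(self):
        import pandas as pd
        rows = []
        for c in self.clusters:
            row = {"cluster_id": c.cluster_id, "size": c.size,
                   "code": c.code_string(self.markers)}
            row.update({f"median_{m}": c.marker_medians[m]
                        for m in self.markers})
            rows.append(row)
        return pd.DataFrame(rows)


def _standardize(X: np.ndarray) -> np.ndarray:
    med = np.median(X, axis=0)
    mad = 1.4826 * np.median(np.abs(X - med), axis=0)
    scale = np.where(mad > 1e-9, mad, np.maximum(X.std(axis=0), 1e-9))
    return (X - med) / scale


def knn_density(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density = 1 / mean distance to the k nearest neighbors.
    Returns (density, neighbor index matrix, neighbor distance matrix)."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, X.shape[0]))
    nn.fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]          # drop self
    mean_d = np.maximum(dist.mean(axis=1), 1e-12)
    return 1.0 / mean_d, idx, dist


def seed_clusters(X: np.ndarray, k: int | None = None,
                  min_cluster_size: int | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Density-peak seeding on standardized data.

    Each event links to its nearest strictly-higher-density neighbor within
    its k-neighborhood (ties broken by index for a strict total order);
    events with none are density modes and root a seed cluster.  Seeds below
    ``min_cluster_size`` are dissolved into the nearest retained cluster by
    centroid distance.

    Returns (assignment, density, knn index matrix, knn distance matrix).
    """
    n = X.shape[0]
    if k is None:
        k = min(100, int(np.ceil(np.sqrt(n))))
    if min_cluster_size is None:
        min_cluster_size = max(25, int(0.001 * n))
    if n < 2 * k or n < 50:
        return (np.zeros(n, dtype=int), np.ones(n),
                np.zeros((n, 0), dtype=int), np.zeros((n, 0)))

    Z = _standardize(X)
    rho, nb_idx, nb_dist = knn_density(Z, k)

    # total order on (density, index): j above i iff rho_j > rho_i, tie -> j > i
    parent = np.arange(n)
    rho_nb = rho[nb_idx]
    higher = (rho_nb > rho[:, None]) | ((rho_nb == rho[:, None])
                                        & (nb_idx > np.arange(n)[:, None]))
    masked = np.where(higher, nb_dist, np.inf)
    best = np.argmin(masked, axis=1)
    has = np.isfinite(masked[np.arange(n), best])
    parent[has] = nb_idx[has, best[has]]

    # kNN density is noisy, so a mild local maximum inside one population can
    # root a spurious fragment.  A root stays a mode only if no higher-density
    # event exists within twice its neighborhood radius; otherwise it links
    # to the nearest such event (bottom-up, still deterministic).
    roots = np.nonzero(parent == np.arange(n))[0]
    if roots.size > 1:
        nn = NearestNeighbors(n_neighbors=min(4 * k + 1, n)).fit(Z)
        dist_r, idx_r = nn.kneighbors(Z[roots])
        for ri, root in enumerate(roots):
            radius = 2.0 / rho[root]        # 2 x mean kNN distance
            for d, j in zip(dist_r[ri], idx_r[ri]):
                if d > radius:
                    break
                if j == root:               # self (not always column 0)
                    continue
                if (rho[j] > rho[root]) or (rho[j] == rho[root]
                                            and j > root):
                    parent[root] = j
                    break

    # resolve forest roots (path halving)
    assign = parent.copy()
    while True:
        nxt = assign[assign]
        if np.array_equal(nxt, assign):
            break
        assign = nxt
    roots, assignment = np.unique(assign, return_inverse=True)

    # dissolve small seeds into nearest retained centroid
    sizes = np.bincount(assignment)
    keep = np.nonzero(sizes >= min_cluster_size)[0]
    if keep.size == 0:
        keep = np.array([int(np.argmax(sizes))])
    if keep.size < sizes.size:
        centroids = np.vstack([Z[assignment == c].mean(axis=0) for c in keep])
        relabel = -np.ones(sizes.size, dtype=int)
        relabel[keep] = np.arange(keep.size)
        small = np.nonzero(relabel < 0)[0]
        for c in small:
            cen = Z[assignment == c].mean(axis=0)
            relabel[c] = int(np.argmin(((centroids - cen) ** 2).sum(axis=1)))
        assignment = relabel[assignment]
    else:
        assignment = np.arange(keep.size)[assignment]
    return assignment, rho, nb_idx, nb_dist


# ---------------------------------------------------------------------------

def phenotype_of(member_values: np.ndarray, markers: list[str],
                 levels: dict[str, ChannelLevels]) -> tuple[int, ...]:
    """Per-marker five-level code of a cluster: discretized member medians.
    ``member_values`` has one column per marker, tube order."""
    med = np.median(np.atleast_2d(member_values), axis=0)
    return tuple(int(levels[m].discretize(v)) for m, v in zip(markers, med))


def _saddle_map(assignment: np.ndarray, rho: np.ndarray,
                nb_idx: np.ndarray) -> dict[tuple[int, int], float]:
    """saddle(a,b) = max over kNN edges crossing a|b of min(rho_i, rho_j)."""
    n = assignment.size
    src = np.repeat(np.arange(n), nb_idx.shape[1])
    dst = nb_idx.ravel()
    ca, cb = assignment[src], assignment[dst]
    cross = ca != cb
    ca, cb, src, dst = ca[cross], cb[cross], src[cross], dst[cross]
    edge_rho = np.minimum(rho[src], rho[dst])
    lo = np.minimum(ca, cb)
    hi = np.maximum(ca, cb)
    saddles: dict[tuple[int, int], float] = {}
    for a, b, r in zip(lo, hi, edge_rho):
        key = (int(a), int(b))
        if r > saddles.get(key, -np.inf):
            saddles[key] = float(r)
    return saddles


def merge_clusters(marker_values: np.ndarray, assignment: np.ndarray,
                   rho: np.ndarray, nb_idx: np.ndarray,
                   markers: list[str], levels: dict[str, ChannelLevels],
                   rho_merge: float = 0.5) -> tuple[np.ndarray, dict]:
    """Iteratively merge adjacent seed clusters that (a) carry the identical
    phenotype code on every marker and (b) are density-continuous:
    saddle / min(peak densities) > rho_merge.  The qualifying pair with the
    highest saddle-to-peak ratio merges first; codes are recomputed after
    every merge.

    Returns (merged assignment, final saddle map)."""
    assignment = assignment.copy()
    saddles = _saddle_map(assignment, rho, nb_idx)

    def cluster_ids():
        return np.unique(assignment)

    codes = {int(c): phenotype_of(marker_values[assignment == c], markers,
                                  levels) for c in cluster_ids()}
    peaks = {int(c): float(rho[assignment == c].max()) for c in cluster_ids()}

    while True:
        best_pair, best_ratio = None, rho_merge
        for (a, b), s in saddles.items():
            if a == b or codes.get(a) is None or codes.get(b) is None:
                continue
            if codes[a] != codes[b]:
                continue
            ratio = s / min(peaks[a], peaks[b])
            if ratio > best_ratio:
                best_ratio, best_pair = ratio, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        assignment[assignment == b] = a
        peaks[a] = max(peaks[a], peaks.pop(b))
        codes.pop(b)
        codes[a] = phenotype_of(marker_values[assignment == a], markers, levels)
        new_saddles: dict[tuple[int, int], float] = {}
        for (x, y), s in saddles.items():
            x2 = a if x == b else x
            y2 = a if y == b else y
            if x2 == y2:
                continue
            key = (min(x2, y2), max(x2, y2))
            new_saddles[key] = max(new_saddles.get(key, -np.inf), s)
        saddles = new_saddles
    return assignment, saddles


def cluster(clean: CleanSample, tube: TubeSpec, rho_merge: float = 0.5,
            k: int | None = None, min_cluster_size: int | None = None,
            downsample_cap: int = DOWNSAMPLE_CAP) -> ClusterSet:
    """Full gating: per-channel discretizers -> density-peak seeds ->
    phenotype/density coupled merging.  Deterministic given the input.

    ``clean.sample`` must already be transformed (asinh fluorescence).
    Clustering runs on at most ``downsample_cap`` events (uniform subsample,
    fixed seed); the rest join their nearest cluster centroid.
    """
    sample = clean.sample
    if not sample.transformed:
        raise ValueError("cluster() expects a transformed sample")
    markers = tube.markers
    mk_cols = [sample.marker_map[m] for m in markers]
    sc_names = [tube.fsc_a, tube.fsc_h, tube.ssc_a]
    sc_cols = []
    for nm in sc_names:
        for i, m in enumerate(sample.channel_meta):
            if m.detector == nm:
                sc_cols.append(i)
                break
    X_all = sample.events[:, mk_cols + sc_cols]
    n = X_all.shape[0]

    levels = {m: fit_discretizer(sample.events[:, c])
              for m, c in zip(markers, mk_cols)}

    if n > downsample_cap:
        rng = np.random.RandomState(DOWNSAMPLE_SEED)
        sub_idx = np.sort(rng.choice(n, downsample_cap, replace=False))
    else:
        sub_idx = np.arange(n)
    X = X_all[sub_idx]

    seed_assign, rho, nb_idx, _ = seed_clusters(
        X, k=k, min_cluster_size=min_cluster_size)
    merged, saddles = merge_clusters(
        X[:, :len(markers)], seed_assign, rho, nb_idx, markers, levels,
        rho_merge=rho_merge)

    ids = np.unique(merged)
    relabel = {int(c): i for i, c in enumerate(ids)}
    assignment_sub = np.array([relabel[int(c)] for c in merged])

    if sub_idx.size < n:
        Z_all = _standardize(X_all)
        cents = np.vstack([Z_all[sub_idx][assignment_sub == i].mean(axis=0)
                           for i in range(len(ids))])
        assignment = np.empty(n, dtype=int)
        assignment[sub_idx] = assignment_sub
        rest = np.setdiff1d(np.arange(n), sub_idx, assume_unique=True)
        if rest.size:
            d = ((Z_all[rest][:, None, :] - cents[None, :, :]) ** 2).sum(axis=2) \
                if rest.size * len(ids) < 5_000_000 else None
            if d is not None:
                assignment[rest] = np.argmin(d, axis=1)
            else:
                for i0 in range(0, rest.size, 20000):
                    blk = rest[i0:i0 + 20000]
                    dd = ((Z_all[blk][:, None, :] - cents[None, :, :]) ** 2
                          ).sum(axis=2)
                    assignment[blk] = np.argmin(dd, axis=1)
    else:
        assignment = assignment_sub

    rho_full = np.zeros(n)
    rho_full[sub_idx] = rho
    infos = []
    for i in range(len(ids)):
        members = assignment == i
        mvals = sample.events[np.ix_(members, mk_cols)]
        code = phenotype_of(mvals, markers, levels)
        med = np.median(mvals, axis=0)
        sc_med = {nm: float(np.median(sample.events[members, c]))
                  for nm, c in zip(sc_names, sc_cols)}
        infos.append(ClusterInfo(
            cluster_id=i, size=int(members.sum()),
            marker_medians={m: float(v) for m, v in zip(markers, med)},
            code=code, peak_density=float(rho_full[members].max()),
            scatter_medians=sc_med))
    saddle_out = {(relabel[a], relabel[b]): s for (a, b), s in saddles.items()
                  if a in relabel and b in relabel}
    return ClusterSet(assignment=assignment, clusters=infos, markers=markers,
                      levels=levels, saddles=saddle_out)
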