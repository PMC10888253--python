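import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from merge_oracle import brute_force_merge, same_partition

from immunogate import mdpc
from immunogate.panel import LEVEL_NAMES


# ---------------------------------------------------------------------------
# discretizer

def _bimodal(seed=0, n=10_000):
    rng = np.random.RandomState(seed)
    return np.r_[rng.normal(0, 0.1, n // 2), rng.normal(4, 0.3, n // 2)]


def test_discretizer_two_gaussians():
    """Negative mode at 0 with spread 0.1 puts the first boundary near
    0.2; a value at the upper mode lands in the top two bands."""
    v = _bimodal()
    levels = mdpc.fit_discretizer(v)
    b1, b2, b3, b4 = levels.boundaries
    assert b1 == pytest.approx(0.2, abs=0.1)
    assert b1 < b2 < b3 < b4
    assert len(levels.boundaries) + 1 == 5
    assert mdpc.discretize(4.0, levels) >= 3


def test_discretizer_degenerate_constant():
    levels = mdpc.fit_discretizer(np.zeros(2000))
    assert levels.degenerate
    b = levels.boundaries
    assert b[0] < b[1] < b[2] < b[3]
    assert mdpc.discretize(0.0, levels) == 0    # everything negative


def test_discretizer_translation_equivariance():
    v = _bimodal(seed=1)
    l0 = mdpc.fit_discretizer(v)
    l1 = mdpc.fit_discretizer(v + 2.5)
    np.testing.assert_allclose(np.array(l1.boundaries),
                               np.array(l0.boundaries) + 2.5, atol=0.02)


def test_discretize_boundary_conventions():
    levels = mdpc.ChannelLevels(boundaries=(1.0, 2.0, 3.0, 4.0),
                                neg_mode=0.0, neg_spread=0.5)
    assert mdpc.discretize(1.0, levels) == 1          # b1 itself -> dim
    assert mdpc.discretize(0.999, levels) == 0        # below b1 -> negative
    assert mdpc.discretize(4.0, levels) == 4          # b4 -> bright
    assert [LEVEL_NAMES[mdpc.discretize(x, levels)]
            for x in (0.5, 1.5, 2.5, 3.5, 9.0)] == list(LEVEL_NAMES)


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2 ** 31 - 1))
def test_discretize_monotone_in_intensity(seed):
    levels = mdpc.ChannelLevels(boundaries=(0.5, 1.5, 2.5, 3.5),
                                neg_mode=0.0, neg_spread=0.2)
    x = np.sort(np.random.RandomState(seed).uniform(-1, 6, 1000))
    lv = levels.discretize(x)
    assert (np.diff(lv) >= 0).all()


# ---------------------------------------------------------------------------
# seeding

def _two_blobs(seed=0, n_each=5000, sep=8.0, dim=5):
    rng = np.random.RandomState(seed)
    a = rng.normal(0, 1, (n_each, dim))
    b = rng.normal(0, 1, (n_each, dim))
    b[:, 0] += sep
    X = np.vstack([a, b])
    y = np.r_[np.zeros(n_each, int), np.ones(n_each, int)]
    return X, y


def test_seed_clusters_two_gaussians():
    X, y = _two_blobs()
    assign, rho, _, _ = mdpc.seed_clusters(X)
    assert len(np.unique(assign)) == 2
    # majority-map accuracy
    acc = max((assign == y).mean(), (assign == 1 - y).mean())
    assert acc >= 0.99


def test_seed_clusters_partition_uniform_cube():
    rng = np.random.RandomState(4)
    X = rng.uniform(0, 1, (1000, 3))
    assign, _, _, _ = mdpc.seed_clusters(X)
    assert assign.min() >= 0
    assert len(assign) == 1000
    sizes = np.bincount(assign)
    assert sizes.sum() == 1000 and (sizes > 0).all()


def test_seed_clusters_duplicate_dataset_same_count():
    X, _ = _two_blobs(seed=2, n_each=1000)
    a1, *_ = mdpc.seed_clusters(X)
    a2, *_ = mdpc.seed_clusters(np.vstack([X, X]))
    assert len(np.unique(a1)) == len(np.unique(a2))


# ---------------------------------------------------------------------------
# phenotype codes

def _levels_for(markers):
    return {m: mdpc.ChannelLevels(boundaries=(0.8, 1.85, 2.9, 3.95),
                                  neg_mode=0.4, neg_spread=0.2)
            for m in markers}


def test_phenotype_of_median_based():
    markers = ["CD3", "CD4"]
    levels = _levels_for(markers)
    vals = np.array([[4.5, 0.3], [4.7, 0.5], [4.6, 0.4]])
    code = mdpc.phenotype_of(vals, markers, levels)
    assert code == (4, 0)
    # single event
    assert mdpc.phenotype_of(vals[:1], markers, levels) == (4, 0)
    # duplication invariance
    assert mdpc.phenotype_of(np.vstack([vals, vals]), markers,
                             levels) == code


# ---------------------------------------------------------------------------
# merging

def _merge_instance(seed, n_blobs, n_each=150, dim=3):
    """Gaussian blobs with only two distinct phenotype codes, so some pairs
    are code-identical and merge candidates while others never merge."""
    rng = np.random.RandomState(seed)
    centers = rng.uniform(0, 6, (n_blobs, dim))
    X = np.vstack([rng.normal(c, 1.1, (n_each, dim)) for c in centers])
    markers = [f"M{i}" for i in range(dim)]
    levels = {m: mdpc.ChannelLevels(boundaries=(3.0, 6.0, 9.0, 12.0),
                                    neg_mode=0.0, neg_spread=1.0)
              for m in markers}
    assign, rho, nb_idx, _ = mdpc.seed_clusters(X, k=20,
                                                min_cluster_size=10)
    return X, assign, rho, nb_idx, markers, levels


@pytest.mark.parametrize("seed,n_blobs", [(0, 3), (1, 4), (2, 5), (3, 6),
                                          (4, 8), (6, 8)])
def test_merge_agrees_with_brute_force(seed, n_blobs):
    X, assign, rho, nb_idx, markers, levels = _merge_instance(seed, n_blobs)
    if len(np.unique(assign)) > 8:
        pytest.skip("seeding produced >8 clusters for this instance")
    merged, _ = mdpc.merge_clusters(X, assign, rho, nb_idx, markers,
                                    levels, rho_merge=0.5)
    oracle = brute_force_merge(X, assign, rho, nb_idx, markers, levels,
                               rho_merge=0.5)
    assert same_partition(merged, oracle)


def test_overseeded_gaussian_merges_to_one():
    """Splitting one Gaussian by over-seeding yields same-code fragments
    with a shallow valley; merging must reunite them."""
    rng = np.random.RandomState(7)
    X = rng.normal(0, 1, (4000, 4))
    markers = [f"M{i}" for i in range(4)]
    levels = {m: mdpc.ChannelLevels(boundaries=(5.0, 6.0, 7.0, 8.0),
                                    neg_mode=0.0, neg_spread=1.0)
              for m in markers}
    # tiny k forces over-seeding
    assign, rho, nb_idx, _ = mdpc.seed_clusters(X, k=10, min_cluster_size=10)
    assert len(np.unique(assign)) >= 1
    merged, _ = mdpc.merge_clusters(X, assign, rho, nb_idx, markers, levels,
                                    rho_merge=0.3)
    assert len(np.unique(merged)) == 1


def test_different_codes_never_merge():
    rng = np.random.RandomState(8)
    # two overlapping blobs whose codes differ on marker 0
    a = rng.normal([2.0, 0.0], 0.8, (2000, 2))
    b = rng.normal([6.0, 0.0], 0.8, (2000, 2))
    X = np.vstack([a, b])
    markers = ["CD4", "CD8"]
    levels = {m: mdpc.ChannelLevels(boundaries=(4.0, 10.0, 11.0, 12.0),
                                    neg_mode=0.0, neg_spread=1.0)
              for m in markers}
    assign, rho, nb_idx, _ = mdpc.seed_clusters(X, k=30, min_cluster_size=20)
    merged, _ = mdpc.merge_clusters(X, assign, rho, nb_idx, markers, levels,
                                    rho_merge=0.0)
    codes = {c: mdpc.phenotype_of(X[merged == c], markers, levels)
             for c in np.unique(merged)}
    assert len({codes[c] for c in codes}) >= 2


def test_merge_monotone_in_rho():
    X, assign, rho, nb_idx, markers, levels = _merge_instance(10, 6)
    counts = []
    for rho_merge in (0.1, 0.5, 0.9):
        merged, _ = mdpc.merge_clusters(X, assign, rho, nb_idx, markers,
                                        levels, rho_merge=rho_merge)
        counts.append(len(np.unique(merged)))
    assert counts[0] <= counts[1] <= counts[2]


# ---------------------------------------------------------------------------
# full clustering

def test_cluster_alps_t_populations(panel, clean_alps_t):
    tube, clean, truth = clean_alps_t
    cs = mdpc.cluster(clean, tube, downsample_cap=10_000)
    assert 6 <= cs.n_clusters <= 14
    assert sum(c.size for c in cs.clusters) == clean.sample.n_events
    kept = clean.qc.event_mask
    tl = truth.labels["ALPS-T"][kept].astype(str)
    pops, counts = np.unique(tl, return_counts=True)
    for pop, cnt in zip(pops, counts):
        if cnt / len(tl) < 0.02 or pop in ("doublet", "debris"):
            continue
        best_purity = 0.0
        for c in cs.clusters:
            members = tl[cs.assignment == c.cluster_id]
            if len(members):
                best_purity = max(best_purity, (members == pop).mean())
        assert best_purity >= 0.80, pop


def test_cluster_deterministic(panel, clean_alps_t):
    tube, clean, _ = clean_alps_t
    c1 = mdpc.cluster(clean, tube, downsample_cap=10_000)
    c2 = mdpc.cluster(clean, tube, downsample_cap=10_000)
    np.testing.assert_array_equal(c1.assignment, c2.assignment)
    assert [c.code for c in c1.clusters] == [c.code for c in c2.clusters]


def test_cluster_shuffle_invariant_partition(panel, clean_alps_t):
    from dataclasses import replace
    tube, clean, _ = clean_alps_t
    c1 = mdpc.cluster(clean, tube, downsample_cap=10_000)
    rng = np.random.RandomState(0)
    perm = rng.permutation(clean.sample.n_events)
    shuffled = replace(clean, sample=clean.sample.subset(perm))
    c2 = mdpc.cluster(shuffled, tube, downsample_cap=10_000)
    # same partition up to relabeling: co-membership must agree
    a1 = c1.assignment[perm]
    a2 = c2.assignment
    mapping = {}
    ok = 0
    for x, y in zip(a1, a2):
        mapping.setdefault(x, y)
        ok += mapping[x] == y
    assert ok / len(a1) >= 0.995
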