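"""Brute-force reference implementation of phenotype/density coupled
merging, independent of the package's incremental bookkeeping: every round
recomputes all codes, peaks and pairwise saddles from scratch."""

import numpy as np

from immunogate import mdpc


def brute_force_merge(marker_values, assignment, rho, nb_idx, markers,
                      levels, rho_merge):
    assignment = assignment.copy()
    while True:
        ids = np.unique(assignment)
        codes = {c: mdpc.phenotype_of(marker_values[assignment == c],
                                      markers, levels) for c in ids}
        peaks = {c: rho[assignment == c].max() for c in ids}
        best, best_ratio = None, rho_merge
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                if codes[a] != codes[b]:
                    continue
                in_a = assignment == a
                in_b = assignment == b
                saddle = -np.inf
                for i in np.nonzero(in_a | in_b)[0]:
                    for j in nb_idx[i]:
                        if (in_a[i] and in_b[j]) or (in_b[i] and in_a[j]):
                            saddle = max(saddle, min(rho[i], rho[j]))
                if not np.isfinite(saddle):
                    continue
                ratio = saddle / min(peaks[a], peaks[b])
                if ratio > best_ratio:
                    best_ratio, best = ratio, (a, b)
        if best is None:
            return assignment
        a, b = best
        assignment[assignment == b] = a


def same_partition(a1, a2):
    """True iff two labelings describe the same partition."""
    _, inv1 = np.unique(a1, return_inverse=True)
    _, inv2 = np.unique(a2, return_inverse=True)
    fwd = {}
    for x, y in zip(inv1, inv2):
        if fwd.setdefault(x, y) != y:
            return False
    return len(set(fwd.values())) == len(fwd)
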