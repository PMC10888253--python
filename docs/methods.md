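# Methods

## Problem and scope

A clinical primary-immunodeficiency (ALPS) flow-cytometry panel measures
three tubes of ten channels each (forward/side scatter plus nine antibodies
per tube) on at least 100,000 leukocytes.  `immunogate` automates the
analysis path a technologist would otherwise gate by hand: event-file
integrity and acquisition-stability checks, doublet and debris exclusion,
unsupervised identification of cell populations in all dimensions at once,
classification of those populations into lineages, enumeration of the
diagnostic lymphocyte subsets, and rule-based flagging of
immunodeficiency-compatible patterns (ALPS, DiGeorge-like, XLA-like).  It
also ships a ground-truthed simulator of the same panel, because the
validation strategy is parameter recovery: the pipeline is correct to the
extent that it recovers known subset percentages from synthetic cases.

The output is a machine-readable report (JSON + CSV) with pattern codes and
rationale text, never a diagnosis: the intended user is a laboratory that
wants a reproducible first-pass analysis with every diagnostic call
traceable to expression levels.

## Intensity scale

Fluorescence is analyzed as `asinh(x / c)` with cofactor `c = 150`,
conventional for PMT-based clinical analyzers whose raw axis spans about
[0, 2^20]; scatter and time stay linear.  The cofactor is configurable per
channel.  Spillover compensation uses the matrix stored in the file
(`$SPILLOVER`) when present and is applied at most once.

## Pre-gating

Stage order is fixed: time QC, doublets, debris.  Each event is attributed
to the first stage that drops it, so per-stage removal fractions are
disjoint.

**Time QC.**  Events are split into 50 equal-count bins by acquisition
time.  A bin is dropped when its event rate, or any channel's bin quartile,
is an outlier across bins: deviation > `mad_k = 5` robust standard
deviations (1.4826·MAD).  Two numerical choices matter and were made after
the obvious version failed on realistic mixtures:

* Channel levels are compared in *rank space* (the pooled ECDF of the
  channel), not on the intensity axis.  The median of a bimodal channel
  whose components are near 50/50 hops discontinuously between modes from
  bin to bin; in rank space it moves smoothly, so the outlier scale is
  distribution-free.  The MAD is floored at the binomial sampling noise of
  a bin quantile, `sqrt(q(1-q)/n_bin)`.
* All three quartiles (q25, q50, q75) are checked per channel.  A gain step
  can move a mode to a position with the same pooled rank as the original
  median (observed on CD3 when a bin happens to be slightly
  negative-majority); some quartile always moves.
* Hysteresis: bins adjacent to a dropped bin are dropped at half the
  threshold, so a shift window straddling bin boundaries is excised whole.

`pass_min_events` records whether the acquisition met the 100,000-event
floor; it is a report flag, not a rejection.

**Doublets.**  A robust line (IRLS, Tukey bisquare, 4.685 tuning constant)
through the singlet ridge in (FSC-A, FSC-H); an event is dropped when its
FSC-A exceeds the ridge's FSC-A prediction from FSC-H by more than 25%
(relative).  The rule is scale-invariant and the bisquare weights zero out
the doublet minority during fitting.

**Debris.**  Joint low-scatter cut: FSC-A and SSC-A both below their axis
cuts.  Each cut is the KDE valley (Silverman bandwidth) between the
low-scatter mode and the nearest leukocyte mode; a low mode is only
accepted below half the main mode's position, and with no such mode the cut
falls back to the 2nd-percentile floor.  Samples with fewer than 500
surviving events are rejected.

**Viability proxy.**  The panel contains no viability dye, so the reported
"viability" is the scatter-based survival fraction of post-time-QC events
and is labeled a proxy everywhere it appears.

## Clustering (density-phenotype coupling)

Populations must satisfy two criteria at once: they are density modes, and
they are phenotypically homogeneous on a five-level expression code.

**Five-level discretizer.**  Per channel, on the transformed scale: the
negative mode `mu0` is the lowest-intensity KDE peak with at least 5% of
the maximum density; `sigma0` is a reflected MAD of values at or below it;
the first boundary is `b1 = mu0 + 2*sigma0`, and the span from `b1` to the
99.9th percentile is split into four equal-width bands (dim, partial,
positive, bright).  Bands are left-closed.  Degenerate channels (no
expression above the negative band) collapse to an all-negative rule with
an epsilon boundary ladder just above the 2nd percentile, preserving the
strict boundary ordering.  Known limitation: on a channel with no negative
population (CD45 in this panel) the "negative" mode is the dimmest positive
mode and the code is not biologically meaningful; no taxonomy predicate
uses CD45 for this reason.

**Seeding.**  All marker and scatter dimensions, standardized by
median/MAD.  Density is `1 / (mean distance to the k nearest neighbors)`
with `k = ceil(sqrt(n))` capped at 100.  Each event links to its nearest
neighbor that is higher in the strict (density, index) order within its
k-neighborhood; link-forest roots are density modes.  Because kNN density
is noisy, a root survives only if no higher-density event exists within
twice its mean neighbor distance — otherwise it links to the nearest such
event.  Without this rescue a single 5,000-event Gaussian fragments into
2–4 basins; with it, well-separated modes are untouched (their nearest
higher-density event is many radii away).  Seeds below
`min_cluster_size = max(25, 0.1% of events)` dissolve into the nearest
retained centroid.

**Merging.**  Adjacency comes from kNN edges crossing cluster boundaries;
the saddle of a pair is the highest `min(rho_i, rho_j)` over its crossing
edges.  The pair with the highest saddle-to-peak ratio merges only if it
satisfies BOTH criteria: identical five-level code on every marker, and
`saddle / min(peak densities) > rho_merge = 0.5`.  Codes are recomputed
after every merge.  Raising `rho_merge` can only increase the final
cluster count.  A brute-force merger that recomputes everything each round
is kept in the test suite as the oracle.

Scatter channels participate in density but not in phenotype codes.
Clustering is deterministic: no randomness anywhere, and when an input
exceeds the subsample cap (50,000 by default) the subsample uses a fixed
constant seed, with remaining events assigned to the nearest cluster
centroid.  The validation harness and acceptance script run with the cap at
10,000 events per tube to keep a 120-case batch inside a desk-scale
runtime; estimates are unchanged in kind because every event is still
gated, assigned and counted — only the density estimation is subsampled.

## Classification and refinement

The classifier operates on clusters, not events.  Features per cluster:
per-marker median (transformed) and ordinal level, fraction of cleaned
events, and scatter medians normalized by the sample's 95th percentile —
keyed by normalized marker name and laid out in lexicographic marker order,
so models transfer across reagent/color schemes carrying the same
antibodies.  The model is a bagged random forest (scikit-learn, 200 trees,
out-of-bag accuracy recorded, fixed seed); training requires at least two
labels with five examples each.  Incremental training is append-and-retrain
on an append-only store — reproducible, and sufficient for reusing manually
gated cases.  Predictions below 0.7 probability carry a review flag.

Diagnostic subsets are *not* forest outputs: within each predicted lineage,
ordered marker-level predicates on the cluster code assign the deepest
subset (first match wins, children tested under their matched parent), so
every diagnostic call is auditable.  γδ T cells are tested before DNT so
that CD4−CD8− γδ T cells are not counted in the ALPS numerator; the DNT
subset then requires TCRαβ positivity for the flagged
`TCRab+ DNT cells` child.  Kappa/lambda light chains cross-cut the memory
status partition inside B cells, so they live on a secondary axis: the
primary taxonomy stays a tree (one deepest label per event, exact roll-up)
and B-lineage events carry an additional light-chain label.

## Report

Counts are the source of truth; every percentage is recomputed from counts
(verified to 1e-9 in tests).  Percent-of-lymphocytes uses the event's own
tube's lymphocyte denominator.  The ALPS screen is
`DNT% of lymphocytes > 1.5 OR DNT% of CD3 > 2.5` (strict inequalities,
configurable).  Reference ranges: CD45RA+ T cells 30–60% of T and switched
memory B cells > 5% of B are clinically sourced defaults; the CD45RO upper
bound of 60% (used by the DiGeorge rule for "reciprocally increased") is an
illustrative default, as is anything else a deployment would have to
calibrate locally.  Pattern codes: `ALPS_PATTERN` (screen flagged),
`DIGEORGE_PATTERN` (CD45RA+ low AND CD45RO+ high AND switched memory B
low), `XLA_PATTERN` (B cells ≤ 0.1% of lymphocytes), `NORMAL` otherwise —
each with the triggering values in the rationale.  Report JSON is canonical
(sorted keys) and byte-stable across runs with the same inputs and seeds.

## Simulator

The simulator states the world the pipeline assumes, and its defaults are
the stated conditions, not tuning knobs:

* Populations are templates of per-marker levels; level L maps to a
  transformed-scale Gaussian with means (0.4, 1.4, 2.5, 3.6, 4.7) and
  spreads (0.20, 0.28, ...).  The negative mean sits above zero because
  real negatives have autofluorescence; raw values are clipped to
  [0, 2^20].  The geometry matches the discretizer's band construction
  (verified: ≥90% of a population's events discretize to within one band of
  the template level).
* Scatter: bivariate Gaussians per mode (lymphocyte FSC-A ≈ 200k,
  monocyte ≈ 320k), FSC-H = 0.95·FSC-A + noise; debris is exponential
  low-scatter with autofluorescence-only marker signal.
* Artifacts with per-event truth tags: doublets sum two singlets
  (FSC-H = max of the pair + 5% noise), debris as above, drift multiplies
  one channel by a gain inside a contiguous time window.  Injectors are
  invertible via their tags.
* Scenarios: NORMAL, ALPS (TCRαβ+ DNT ≥ 10% of T), DIGEORGE (CD45RA+ ≤ 10%
  of T, switched memory B ≤ 2% of B), XLA (B ≤ 0.05% of lymphocytes).
  Default 20,000 events/tube, 2% doublets, 2% debris.

What the simulator does **not** emulate: instrument-specific detector
noise, spectral spillover (beyond what compensation tests inject),
autofluorescence spectra, day-to-day staining variation, or continuous
biological gradients between populations (every population is a discrete
template).  A green concordance result therefore establishes that the
pipeline recovers composition under the stated noise model — not clinical
performance on patient samples.

## Validation design

Concordance is Pearson r between estimated and true percent-of-lymphocytes
per subset across a 60-case batch; r ≥ 0.9 counts as strong.  Per-case
abundances are jittered around scenario means with a Dirichlet
(`alpha_i = 5 * n_pops * mean_i`, so the mean composition is preserved and
the total concentration scales with the number of populations) — without
spread the correlation would be undefined.  The batch rotates scenarios
(2/3 NORMAL, the rest ALPS/DIGEORGE/XLA) because a correlation over an
all-normal batch would not exercise the diagnostic subsets' dynamic range;
this mirrors the composition of a referral cohort for this panel.  The
percent-of-lymphocytes basis (rather than percent-of-parent) is the
default, configurable.

## Known limitations

* Sub-populations below the minimum cluster size (25 events after
  subsampling) can be absorbed by a neighbor; at 20,000 events/tube this
  bounds sensitivity at roughly 0.3% of events.
* Populations differing in a single marker and together smaller than the
  kNN neighborhood (k = 100) may form one density mode and merge if the
  shared code agrees (observed for the two smallest memory-B
  sub-populations at default abundances).
* The FCS writer emits FCS 3.1 float list-mode only; FCS 2.0 is read only
  as the skipped leading segment of an LMD container.
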