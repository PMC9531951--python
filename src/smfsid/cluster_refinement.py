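"""Block 5: area-of-similarity refinement, cluster merging, and observables.

The density-peak step finds the *centers* of recurrent unfolding patterns but
not their borders.  For each center an "area of similarity" (AoS) is built by
superimposing the center with its two nearest neighbours and rasterising
every point above 30 pN and before the center's last force peak onto a
5 nm x 5 pN grid.  Every candidate curve whose final peak falls within
0.7-1.3 times the center length is then scored by how many of its points
land inside the AoS; the sorted score curve shows two slopes, and the knee
between them (fitted as a two-segment piecewise line) sets the membership
threshold.  Clusters sharing more than 40% of their above-threshold traces
are merged, largest first, with the sweep stopping once four consecutive
clusters merged away and every remaining one holds fewer than 3 traces.

Each final cluster is summarised by the observables fed to the Bayesian
identification: the contour length of its last meaningful pooled-histogram
peak (Lc_max), the mean rupture-peak force, and the unit-area pooled Lc
profile of points in the 40-100 pN band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import TRACE_FORCE_FLOOR_PN
from .quality_score import (
    DEFAULT_BIN_WIDTH_NM,
    LcHistogram,
    ScoredTrace,
    build_lc_histogram,
    detect_histogram_peaks,
    force_peaks,
    last_force_peak_x,
)
from .trace_distance import DistanceMatrix
from .wlc_transform import LcProfile

AOS_CELL_NM = 5.0
AOS_CELL_PN = 5.0
LENGTH_BAND = (0.7, 1.3)
OVERLAP_MIN = 0.40
PROFILE_FORCE_BAND = (40.0, 100.0)
STOP_CONSECUTIVE_MERGES = 4
STOP_MIN_SIZE = 3


@dataclass
class AreaOfSimilarity:
    """Rasterised envelope of a center and its two nearest neighbours."""

    occupied: set[tuple[int, int]]
    source_ids: list[str]
    L: float  # center length: separation of the center's last force peak (nm)
    flagged_single: bool = False  # built from the center alone


@dataclass
class ClusterObservables:
    """Per-cluster evidence for the Bayesian identification."""

    lc_max: float  # nm
    mean_force: float  # pN
    peak_profile: np.ndarray  # unit-area density over profile_edges bins
    profile_edges: np.ndarray  # nm
    n_members: int
    lc_max_fallback: bool = False


@dataclass
class RefinedClusters:
    """Final clusters with their members, merge history and observables."""

    clusters: dict[int, list[str]]
    merge_log: list[dict] = field(default_factory=list)
    observables: dict[int, ClusterObservables] = field(default_factory=dict)
    dropped: list[int] = field(default_factory=list)


def _cells(trace: ScoredTrace, x_limit: float, floor: float = TRACE_FORCE_FLOOR_PN):
    """5 nm x 5 pN cell indices of points with force > floor and x < x_limit."""
    x, f = trace.trace.x, trace.trace.force
    sel = (f > floor) & (x < x_limit)
    cx = np.floor(x[sel] / AOS_CELL_NM).astype(int)
    cf = np.floor(f[sel] / AOS_CELL_PN).astype(int)
    return set(zip(cx.tolist(), cf.tolist()))


def build_aos(center: ScoredTrace, neighbors: list[ScoredTrace]) -> AreaOfSimilarity:
    """Union of the rasterised cells of the center and its two nearest
    neighbours, limited to points before the center's last force peak."""
    L = last_force_peak_x(center.trace)
    if L <= 0:
        L = float(center.trace.x[-1])
    occupied = _cells(center, L)
    for nb in neighbors[:2]:
        occupied |= _cells(nb, L)
    return AreaOfSimilarity(
        occupied=occupied,
        source_ids=[center.curve_id] + [nb.curve_id for nb in neighbors[:2]],
        L=L,
        flagged_single=len(neighbors) == 0,
    )


def aos_score(trace: ScoredTrace, aos: AreaOfSimilarity, floor: float = TRACE_FORCE_FLOOR_PN) -> int:
    """Number of the trace's own points (above floor, before its last peak)
    that fall inside the AoS cells."""
    own_limit = last_force_peak_x(trace.trace)
    if own_limit <= 0:
        own_limit = float(trace.trace.x[-1])
    x, f = trace.trace.x, trace.trace.force
    sel = (f > floor) & (x < own_limit)
    cx = np.floor(x[sel] / AOS_CELL_NM).astype(int)
    cf = np.floor(f[sel] / AOS_CELL_PN).astype(int)
    return int(sum((a, b) in aos.occupied for a, b in zip(cx.tolist(), cf.tolist())))


KNEE_GAIN_MIN = 0.5  # two-segment fit must at least halve the single-line SSE
KNEE_CLIFF_MIN = 0.15  # breakpoint drop as a fraction of the top score
# No-knee fallback threshold, as a fraction of the top score.  The top scorer
# is the center itself (its points all lie inside its own AoS); genuine
# members retain roughly half to two thirds of their points, off-pattern
# curves an order of magnitude less, so one third of the self-score separates
# the two regimes without a knee.
FALLBACK_SCORE_FRACTION = 0.3


def knee_threshold(sorted_scores: np.ndarray) -> float:
    """Similarity threshold from the two-slope structure of the descending
    score curve.

    The curve is fitted with the best two-segment piecewise line and the
    score at the breakpoint is the threshold — provided the breakpoint is a
    genuine slope change: the fit must at least halve the single-line
    residual and the scores must drop by a sizable fraction of their range
    at the break.  A homogeneous candidate pool (every eligible curve
    matches the pattern, so there is no second slope to read) fails that
    test; the threshold then falls back to half the top score, which keeps
    a uniformly high-scoring pool and rejects a uniformly poor one.
    """
    y = np.asarray(sorted_scores, dtype=float)
    n = len(y)
    if n < 4:
        return 0.0
    x = np.arange(n, dtype=float)

    def sse(xs, ys):
        A = np.vstack([xs, np.ones_like(xs)]).T
        coef, _, _, _ = np.linalg.lstsq(A, ys, rcond=None)
        resid = ys - A @ coef
        return float(resid @ resid)

    single = sse(x, y)
    best_b, best_cost = None, np.inf
    for b in range(2, n - 1):
        cost = sse(x[:b], y[:b]) + sse(x[b:], y[b:])
        if cost < best_cost:
            best_cost, best_b = cost, b
    cliff = 0.0
    if best_b is not None and y[0] > 0:
        lo, hi = max(best_b - 2, 1), min(best_b + 3, n)
        cliff = float(np.max(y[lo - 1 : hi - 1] - y[lo:hi])) / y[0]
    knee_ok = (
        single > 0 and best_cost <= KNEE_GAIN_MIN * single and cliff >= KNEE_CLIFF_MIN
    )
    if knee_ok:
        return float(y[best_b])
    return FALLBACK_SCORE_FRACTION * float(y[0])


def similarity_threshold(
    aos: AreaOfSimilarity,
    candidates: list[ScoredTrace],
    length_band: tuple[float, float] = LENGTH_BAND,
) -> tuple[dict[str, int], float, list[str], bool]:
    """Score all candidates against the AoS and threshold at the knee.

    Candidates whose final force peak lies outside ``length_band`` times the
    center length are excluded.  Returns (scores, threshold, above_ids,
    flagged): flagged is True when fewer than 3 candidates were eligible, in
    which case all of them pass with threshold 0.
    """
    lo, hi = length_band[0] * aos.L, length_band[1] * aos.L
    eligible = []
    for tr in candidates:
        fp = last_force_peak_x(tr.trace)
        if lo <= fp <= hi:
            eligible.append(tr)
    scores = {tr.curve_id: aos_score(tr, aos) for tr in eligible}
    if len(eligible) < 3:
        return scores, 0.0, [tr.curve_id for tr in eligible], True
    # The AoS source curves score near 100% by construction; keep them out of
    # the knee fit so their step above the bulk is not mistaken for the knee.
    sources = set(aos.source_ids)
    pool = [s for cid, s in scores.items() if cid not in sources]
    if len(pool) < 4:
        pool = list(scores.values())
    thr = knee_threshold(np.array(sorted(pool, reverse=True)))
    above = [cid for cid, s in scores.items() if s > thr]
    return scores, thr, above, False


def merge_clusters(
    above_sets: dict[int, list[str]],
    overlap_min: float = OVERLAP_MIN,
) -> RefinedClusters:
    """Merge clusters sharing more than ``overlap_min`` of their
    above-threshold traces, sweeping in decreasing size order.

    The overlap fraction is shared / |smaller set|, so a small cluster
    engulfed by a large one merges.  Stop rule: once four consecutive
    clusters have merged away and every remaining unprocessed cluster holds
    fewer than 3 traces, the sweep stops and those clusters are dropped.
    """
    order = sorted(above_sets, key=lambda c: (-len(above_sets[c]), c))
    retained: dict[int, set[str]] = {}
    log: list[dict] = []
    dropped: list[int] = []
    consecutive = 0
    for pos, cid in enumerate(order):
        members = set(above_sets[cid])
        target = None
        best_overlap = 0.0
        for rid in retained:
            shared = len(members & retained[rid])
            denom = min(len(members), len(retained[rid]))
            if denom == 0:
                continue
            frac = shared / denom
            if frac > overlap_min and target is None:
                target, best_overlap = rid, frac
        if not members:
            dropped.append(cid)
            continue
        if target is not None:
            retained[target] |= members
            log.append({"merged": cid, "into": target, "overlap": best_overlap})
            consecutive += 1
            if consecutive >= STOP_CONSECUTIVE_MERGES:
                rest = order[pos + 1 :]
                if rest and all(len(above_sets[c]) < STOP_MIN_SIZE for c in rest):
                    dropped.extend(rest)
                    log.append({"stopped_after": cid, "dropped": list(rest)})
                    break
        else:
            retained[cid] = members
            consecutive = 0
    return RefinedClusters(
        clusters={cid: sorted(m) for cid, m in retained.items()},
        merge_log=log,
        dropped=dropped,
    )


def _pooled_histogram(members: list[ScoredTrace], bin_width: float) -> LcHistogram:
    lcs = [m.lc_profile.valid_lc for m in members]
    all_lc = np.concatenate(lcs) if lcs else np.array([])
    profile = LcProfile(lc_values=all_lc, valid_mask=np.ones(len(all_lc), dtype=bool))
    return build_lc_histogram(profile, bin_width)


def cluster_observables(
    members: list[ScoredTrace],
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    force_band: tuple[float, float] = PROFILE_FORCE_BAND,
) -> ClusterObservables:
    """Summarise a cluster: Lc_max, mean rupture force, and the unit-area
    pooled Lc profile of points in the 40-100 pN normalisation band."""
    if not members:
        raise ValueError("cluster has no members")
    hist = _pooled_histogram(members, bin_width)
    peaks = detect_histogram_peaks(hist)
    fallback = False
    if peaks:
        # position of the rightmost meaningful peak, refined below bin
        # resolution as the mean Lc of the points in its member bins
        last = peaks[-1]
        pooled = np.concatenate([m.lc_profile.valid_lc for m in members])
        lo, hi = last.lc_range
        in_peak = pooled[(pooled >= lo) & (pooled < hi)]
        lc_max = float(in_peak.mean()) if len(in_peak) else (last.peak_bin + 0.5) * bin_width
    else:
        finals = [float(m.lc_profile.valid_lc.max()) for m in members if len(m.lc_profile.valid_lc)]
        lc_max = float(np.percentile(finals, 95)) if finals else 0.0
        fallback = True

    peak_forces = []
    for m in members:
        _, pf = force_peaks(m.trace)
        peak_forces.extend(pf.tolist())
    mean_force = float(np.mean(peak_forces)) if peak_forces else 0.0

    # pooled Lc profile restricted to the force band, as a unit-area density
    band_lc = []
    for m in members:
        f = m.trace.force
        sel = m.lc_profile.valid_mask & (f >= force_band[0]) & (f <= force_band[1])
        band_lc.append(m.lc_profile.lc_values[sel])
    band_lc = np.concatenate(band_lc) if band_lc else np.array([])
    edges = hist.bin_edges
    if len(band_lc):
        counts, _ = np.histogram(band_lc, bins=edges)
        area = counts.sum() * bin_width
        profile = counts / area if area > 0 else counts.astype(float)
    else:
        profile = np.zeros(len(edges) - 1)
    return ClusterObservables(
        lc_max=float(lc_max),
        mean_force=mean_force,
        peak_profile=profile,
        profile_edges=edges,
        n_members=len(members),
        lc_max_fallback=fallback,
    )


def refine_clusters(
    clustering,
    scored: list[ScoredTrace],
    D: DistanceMatrix,
    overlap_min: float = OVERLAP_MIN,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
) -> RefinedClusters:
    """Full Block-5 pass: AoS + knee threshold per center, then merging and
    observables.  ``clustering`` is the Block-4 result; every scored trace is
    a refinement candidate regardless of its Block-4 label."""
    by_id = {t.curve_id: t for t in scored}
    above_sets: dict[int, list[str]] = {}
    thresholds: dict[int, float] = {}
    for lbl, center_idx in enumerate(clustering.centers):
        center = by_id[clustering.ids[center_idx]]
        row = D.values[center_idx].copy()
        row[center_idx] = np.inf
        finite = np.flatnonzero(np.isfinite(row))
        nearest = finite[np.argsort(row[finite])][:2]
        neighbors = [by_id[clustering.ids[i]] for i in nearest]
        aos = build_aos(center, neighbors)
        _, thr, above, _ = similarity_threshold(aos, scored)
        above_sets[lbl] = above
        thresholds[lbl] = thr
    refined = merge_clusters(above_sets, overlap_min)
    for cid, member_ids in refined.clusters.items():
        members = [by_id[m] for m in member_ids]
        if members:
            refined.observables[cid] = cluster_observables(members, bin_width)
    return refined
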