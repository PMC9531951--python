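"""Block 2: Lc histogram, peak detection, peak score W and trace quality ratio.

A successful unfolding trace, transformed to contour-length space, piles its
points into a few sharp maxima (one per unfolding intermediate) separated by
deep minima.  Each histogram maximum gets a score

    W = exp(-2 f^2),   f = (P_left/P_max + P_right/P_max) / 2

where P_max is the density at the maximum and P_left/P_right the densities at
the flanking minima: an isolated peak (flanks near zero) scores ~1, a bump on
a plateau scores low.  Points are then scored by the peak they belong to, the
sub-30-pN points inherit the score of the next scored point within 75 nm, and
the ratio S_w / length decides whether the trace is kept (>= 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessedTrace, TRACE_FORCE_FLOOR_PN
from .wlc_transform import LcProfile, WlcParams, trace_to_lc_profile

DEFAULT_BIN_WIDTH_NM = 8.0
MIN_PEAK_POINTS = 5
MIN_PEAK_FRACTION = 0.01
LOW_FORCE_WINDOW_NM = 75.0
QUALITY_CUT = 0.5


@dataclass
class LcHistogram:
    """Histogram of a trace's valid Lc values, edges anchored at 0."""

    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    total_valid: int

    @property
    def densities(self) -> np.ndarray:
        """Probability density per bin (counts / (total * width))."""
        if self.total_valid == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / (self.total_valid * self.bin_width)

    def bin_of(self, lc: np.ndarray) -> np.ndarray:
        """Bin index of each Lc value (edges anchored at 0)."""
        return np.floor(np.asarray(lc) / self.bin_width).astype(int)


@dataclass
class HistogramPeak:
    """A meaningful histogram maximum and its flanking minima."""

    peak_bin: int
    left_min_bin: int
    right_min_bin: int
    p_max: float
    p_left: float
    p_right: float
    n_points: int
    W: float
    lc_range: tuple[float, float]  # [left edge of first member bin, right edge of last)

    @property
    def member_bins(self) -> range:
        """Bins assigned to this peak: strictly between the flanking minima,
        the minima themselves belonging to no peak."""
        return range(self.left_min_bin + 1, self.right_min_bin)


@dataclass
class ScoredTrace:
    """A preprocessed trace with Lc profile, peaks and per-point quality."""

    trace: PreprocessedTrace
    lc_profile: LcProfile
    histogram: LcHistogram
    peaks: list[HistogramPeak] = field(default_factory=list)
    point_scores: np.ndarray = None
    s_w: float = 0.0
    quality_ratio: float = 0.0

    @property
    def curve_id(self) -> str:
        return self.trace.curve_id

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def last_peak_x(self) -> float:
        """Separation (nm) of the last force peak above the 30-pN floor."""
        return last_force_peak_x(self.trace)

    @property
    def force_peak_values(self) -> np.ndarray:
        """Forces (pN) at local force maxima above the floor."""
        return force_peaks(self.trace)[1]


def peak_score(p_max: float, p_left: float, p_right: float) -> float:
    """Peak score W = exp(-2 f^2) with f the mean flank-to-peak density ratio."""
    if p_max <= 0:
        raise ValueError("p_max must be positive")
    f = 0.5 * (p_left / p_max + p_right / p_max)
    return float(np.exp(-2.0 * f * f))


def build_lc_histogram(profile: LcProfile, bin_width: float = DEFAULT_BIN_WIDTH_NM) -> LcHistogram:
    """Histogram of the profile's valid Lc values on bins [0, w), [w, 2w), ..."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lc = profile.valid_lc
    if len(lc) == 0:
        return LcHistogram(bin_width, np.array([0.0, bin_width]), np.zeros(1, dtype=int), 0)
    n_bins = int(np.floor(lc.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lc, bins=edges)
    return LcHistogram(bin_width, edges, counts.astype(int), int(len(lc)))


def _local_maxima(counts: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local maxima; plateaus keep the leftmost bin."""
    n = len(counts)
    maxima = []
    i = 0
    while i < n:
        if counts[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_ok = i == 0 or counts[i - 1] < counts[i]
        right_ok = j == n - 1 or counts[j + 1] < counts[i]
        if left_ok and right_ok:
            maxima.append(i)
        i = j + 1
    return maxima


def detect_histogram_peaks(
    hist: LcHistogram,
    min_points: int = MIN_PEAK_POINTS,
    min_fraction: float = MIN_PEAK_FRACTION,
) -> list[HistogramPeak]:
    """Meaningful maxima of the Lc histogram with their W scores.

    A maximum is meaningful if its member points exceed ``min_points`` and
    ``min_fraction`` of the trace's valid force measures.  Flanking minima are
    the lowest bins between the maximum and its neighbouring maxima (or the
    histogram edge, which counts as density 0).
    """
    counts = hist.counts
    dens = hist.densities
    maxima = _local_maxima(counts)
    peaks: list[HistogramPeak] = []
    for idx, m in enumerate(maxima):
        # left flank: minimum bin between previous maximum (or edge) and m
        if idx == 0:
            lo = 0
            left_min = int(np.argmin(counts[lo:m]) + lo) if m > lo else -1
        else:
            lo = maxima[idx - 1]
            seg = counts[lo + 1 : m]
            left_min = int(np.argmin(seg) + lo + 1) if len(seg) else lo
        if idx == len(maxima) - 1:
            hi = len(counts)
            seg = counts[m + 1 : hi]
            right_min = int(np.argmin(seg) + m + 1) if len(seg) else len(counts)
        else:
            hi = maxima[idx + 1]
            seg = counts[m + 1 : hi]
            right_min = int(np.argmin(seg) + m + 1) if len(seg) else m + 1

        p_left = dens[left_min] if 0 <= left_min < len(dens) else 0.0
        p_right = dens[right_min] if 0 <= right_min < len(dens) else 0.0
        member = range(left_min + 1, right_min)
        n_points = int(counts[member.start : member.stop].sum())
        if n_points <= min_points or n_points <= min_fraction * hist.total_valid:
            continue
        w = peak_score(dens[m], p_left, p_right)
        peaks.append(
            HistogramPeak(
                peak_bin=int(m),
                left_min_bin=int(left_min),
                right_min_bin=int(right_min),
                p_max=float(dens[m]),
                p_left=float(p_left),
                p_right=float(p_right),
                n_points=n_points,
                W=w,
                lc_range=(
                    float(member.start * hist.bin_width),
                    float(member.stop * hist.bin_width),
                ),
            )
        )
    return peaks


FORCE_PEAK_SMOOTH_NM = 5
FORCE_PEAK_PROMINENCE_PN = 30.0


def force_peaks(
    trace: PreprocessedTrace,
    floor: float = TRACE_FORCE_FLOOR_PN,
    smooth_nm: int = FORCE_PEAK_SMOOTH_NM,
    prominence: float = FORCE_PEAK_PROMINENCE_PN,
):
    """Rupture-peak candidates on the 1-nm grid: (x, F) arrays.

    The force is smoothed with a short moving average so baseline noise
    cannot masquerade as a rupture, then local maxima above the floor with
    at least ``prominence`` pN of prominence are kept (a rupture drops to
    baseline, so real peaks are highly prominent).
    """
    from scipy.signal import find_peaks

    f = trace.force
    if len(f) < 3:
        return np.array([]), np.array([])
    w = max(int(smooth_nm), 1)
    if w > 1:
        kernel = np.ones(w) / w
        fs = np.convolve(f, kernel, mode="same")
    else:
        fs = f
    idx, _ = find_peaks(fs, height=floor, prominence=prominence)
    # peak height from the raw trace near the smoothed maximum
    heights = np.array([f[max(i - 2, 0) : i + 3].max() for i in idx])
    return trace.x[idx], heights


def last_force_peak_x(trace: PreprocessedTrace, floor: float = TRACE_FORCE_FLOOR_PN) -> float:
    """Separation of the last force peak above the floor (0 when none)."""
    xs, _ = force_peaks(trace, floor)
    return float(xs[-1]) if len(xs) else 0.0


def score_trace(
    trace: PreprocessedTrace,
    profile: LcProfile,
    peaks: list[HistogramPeak],
    histogram: LcHistogram,
    low_force_window: float = LOW_FORCE_WINDOW_NM,
    force_floor: float = TRACE_FORCE_FLOOR_PN,
) -> ScoredTrace:
    """Assign per-point scores and compute the trace quality ratio.

    Valid points falling in a peak's member bins inherit that peak's W;
    sub-floor points inherit the score of the next (larger-separation) point
    above the floor, provided they sit within ``low_force_window`` nm of it;
    everything else scores 0.  The quality ratio divides the score sum by the
    trace length in grid points (contact to last above-floor point).
    """
    n = len(trace.x)
    scores = np.zeros(n)

    bin_w = np.zeros(len(histogram.counts))
    for pk in peaks:
        mb = pk.member_bins
        bin_w[mb.start : mb.stop] = pk.W

    valid_idx = np.flatnonzero(profile.valid_mask)
    if len(valid_idx):
        bins = histogram.bin_of(profile.lc_values[valid_idx])
        in_range = (bins >= 0) & (bins < len(bin_w))
        scores[valid_idx[in_range]] = bin_w[bins[in_range]]

    # propagate scores backwards onto sub-floor points within the window
    above = trace.force > force_floor
    next_scored_x = np.inf
    next_score = 0.0
    for i in range(n - 1, -1, -1):
        if above[i]:
            if scores[i] > 0:
                next_scored_x = trace.x[i]
                next_score = scores[i]
            else:
                next_scored_x, next_score = np.inf, 0.0
        elif next_score > 0 and (next_scored_x - trace.x[i]) <= low_force_window:
            scores[i] = next_score

    length = trace.length_points
    s_w = float(scores[:length].sum()) if length else 0.0
    ratio = s_w / length if length else 0.0
    return ScoredTrace(
        trace=trace,
        lc_profile=profile,
        histogram=histogram,
        peaks=peaks,
        point_scores=scores,
        s_w=s_w,
        quality_ratio=min(ratio, 1.0),
    )


def score_traces(
    traces: list[PreprocessedTrace],
    params: WlcParams | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    quality_cut: float = QUALITY_CUT,
) -> tuple[list[ScoredTrace], dict[str, str]]:
    """Score a batch and apply the quality-ratio cut.

    Returns the kept ScoredTraces and a map id -> "low_quality" for the rest.
    """
    params = params or WlcParams()
    kept: list[ScoredTrace] = []
    rejected: dict[str, str] = {}
    for tr in traces:
        profile = trace_to_lc_profile(tr, params)
        hist = build_lc_histogram(profile, bin_width)
        peaks = detect_histogram_peaks(hist)
        scored = score_trace(tr, profile, peaks, hist)
        if scored.quality_ratio < quality_cut:
            rejected[tr.curve_id] = "low_quality"
        else:
            kept.append(scored)
    return kept, rejected
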