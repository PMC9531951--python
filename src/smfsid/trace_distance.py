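"""Block 3: pairwise trace distances via global alignment of force profiles.

Two resampled force arrays are compared with a Needleman-Wunsch-style global
alignment whose match/mismatch score is

    M(i, j) = 1 - |Fa(i) - Fb(j)| / F_scoring    if |Fa - Fb| < F_scoring
            =   - |Fa(i) - Fb(j)| / F_scoring    otherwise

with F_scoring = 4 * sigma_NOISE, so a force difference within the noise
band scores positively and anything larger is penalised in proportion.  The
distance is d_ab = 1 - SD / N_max, SD the optimal alignment score and N_max
the longer trace's length: identical traces score SD = N and d = 0, while
length mismatch dilutes SD relative to N_max.

To keep the O(N^2) alignment affordable over large batches, the distance is
only computed for trace pairs that could plausibly be the same pattern:
histogram peak counts differing by at most 2 and trace lengths by at most
20%.  Skipped pairs are treated as infinitely distant downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .quality_score import ScoredTrace

DEFAULT_F_SCORING_MULTIPLIER = 4.0
DEFAULT_MAX_PEAK_DIFF = 2
DEFAULT_MAX_LENGTH_DIFF = 0.20


@dataclass
class AlignmentConfig:
    """Alignment scoring and prefilter settings.

    f_scoring : force scale of the match score (pN), 4 * sigma_NOISE.
    gap_penalty : additive score per gapped position (<= 0; 0 by default, the
        mismatch branch being already negative).
    max_peak_diff / max_length_diff : prefilter bounds.
    prefilter_mode : "all" requires both bounds (default); "any" restores the
        literal either/or reading.
    """

    f_scoring: float
    gap_penalty: float = 0.0
    max_peak_diff: int = DEFAULT_MAX_PEAK_DIFF
    max_length_diff: float = DEFAULT_MAX_LENGTH_DIFF
    prefilter_mode: str = "all"

    def __post_init__(self) -> None:
        if self.f_scoring <= 0:
            raise ValueError("f_scoring must be positive")
        if self.gap_penalty > 0:
            raise ValueError("gap_penalty must be <= 0")
        if self.prefilter_mode not in ("all", "any"):
            raise ValueError("prefilter_mode must be 'all' or 'any'")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; uncomputed pairs are +inf."""

    ids: list[str]
    values: np.ndarray  # (n, n) float, inf where not computed
    computed_mask: np.ndarray  # (n, n) bool

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, trace_id: str) -> int:
        return self.ids.index(trace_id)


def match_score(f_a: float, f_b: float, f_scoring: float) -> float:
    """Eq.-3-style match/mismatch score of two force values."""
    if f_scoring <= 0:
        raise ValueError("f_scoring must be positive")
    delta = abs(f_a - f_b)
    if delta < f_scoring:
        return 1.0 - delta / f_scoring
    return -delta / f_scoring


@njit(cache=True)
def _align_score(fa, fb, f_scoring, gap):  # pragma: no cover - numba kernel
    na, nb = len(fa), len(fb)
    prev = np.empty(nb + 1)
    cur = np.empty(nb + 1)
    for j in range(nb + 1):
        prev[j] = gap * j
    for i in range(1, na + 1):
        cur[0] = gap * i
        fai = fa[i - 1]
        for j in range(1, nb + 1):
            delta = abs(fai - fb[j - 1])
            if delta < f_scoring:
                m = 1.0 - delta / f_scoring
            else:
                m = -delta / f_scoring
            best = prev[j - 1] + m
            up = prev[j] + gap
            if up > best:
                best = up
            left = cur[j - 1] + gap
            if left > best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev[nb]


def alignment_score(fa: np.ndarray, fb: np.ndarray, cfg: AlignmentConfig) -> float:
    """Optimal global-alignment score SD of two force arrays."""
    fa = np.ascontiguousarray(fa, dtype=np.float64)
    fb = np.ascontiguousarray(fb, dtype=np.float64)
    if len(fa) == 0 or len(fb) == 0:
        raise ValueError("cannot align an empty trace")
    return float(_align_score(fa, fb, cfg.f_scoring, cfg.gap_penalty))


def _profile(trace: ScoredTrace) -> np.ndarray:
    """Force array used for alignment: contact to last above-floor point."""
    n = max(trace.trace.length_points, 1)
    return trace.trace.force[:n]


def pair_distance(a: ScoredTrace, b: ScoredTrace, cfg: AlignmentConfig) -> float:
    """d_ab = 1 - SD(a, b) / N_max (0 for identical traces).

    Not clamped: grossly dissimilar computed pairs can exceed 1.
    """
    if a is b or (a.curve_id == b.curve_id and np.array_equal(_profile(a), _profile(b))):
        return 0.0
    fa, fb = _profile(a), _profile(b)
    n_max = max(len(fa), len(fb))
    sd = alignment_score(fa, fb, cfg)
    return 1.0 - sd / n_max


def _prefilter_ok(a: ScoredTrace, b: ScoredTrace, cfg: AlignmentConfig) -> bool:
    peaks_ok = abs(a.n_peaks - b.n_peaks) <= cfg.max_peak_diff
    la, lb = a.trace.length_points, b.trace.length_points
    longer = max(la, lb)
    length_ok = longer > 0 and abs(la - lb) / longer <= cfg.max_length_diff
    if cfg.prefilter_mode == "any":
        return peaks_ok or length_ok
    return peaks_ok and length_ok


def build_distance_matrix(traces: list[ScoredTrace], cfg: AlignmentConfig) -> DistanceMatrix:
    """Pairwise distance matrix over prefilter-passing pairs (others +inf)."""
    n = len(traces)
    values = np.full((n, n), np.inf)
    mask = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(mask, True)
    for i in range(n):
        for j in range(i + 1, n):
            if not _prefilter_ok(traces[i], traces[j], cfg):
                continue
            d = pair_distance(traces[i], traces[j], cfg)
            values[i, j] = values[j, i] = d
            mask[i, j] = mask[j, i] = True
    return DistanceMatrix(ids=[t.curve_id for t in traces], values=values, computed_mask=mask)
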