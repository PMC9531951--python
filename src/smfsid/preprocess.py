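"""Block 1: baseline zeroing, tip-sample-separation transform, 1-nm resampling
and coarse rejection of spurious traces.

A retraction trace is prepared for analysis in four steps:

1. the force baseline is zeroed by subtracting the mean of the non-contact
   tail (the final stretch of the trace, after the last unfolding event);
2. raw piezo positions are converted to tip-sample separation by removing the
   cantilever deflection, ``s = z - F/k`` (skipped when the input is already a
   separation axis);
3. the contact point — the transition from negative (adhesive) to positive
   force along the retraction — is located and the axis shifted so contact
   sits at 0;
4. the force is linearly interpolated onto a uniform 1-nm grid.

Coarse filtering then discards traces without a detectable contact point,
traces spanning absurd force ranges (> 5000 pN), and traces whose tail stays
wavy (tail sd above twice the batch noise level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fd_io import CurveSet, ForceDistanceCurve

GRID_NM = 1.0  # resampling pitch
FORCE_RANGE_PN = 5000.0  # |F| beyond this is instrumental nonsense
TRACE_FORCE_FLOOR_PN = 30.0  # end-of-trace definition shared with Block 2
DEFAULT_TAIL_FRACTION = 0.2
MIN_TAIL_POINTS = 50


class UnsortableTraceError(ValueError):
    """Separation not monotone after deflection correction."""


@dataclass
class PreprocessedTrace:
    """A baseline-zeroed trace resampled on the 1-nm separation grid."""

    curve_id: str
    x: np.ndarray  # separation grid, nm, x[0] == 0
    force: np.ndarray  # baseline-subtracted force, pN
    baseline_sigma: float  # sd of this trace's non-contact tail, pN
    length_points: int  # grid points from contact to last force > 30 pN
    sample_id: str = ""
    contact_found: bool = True  # raw trace had a negative-to-positive crossing

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class FilterReport:
    """Outcome of Block-1 filtering: kept ids and per-id rejection reasons."""

    kept: list[str] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def _tail_slice(n: int, tail_fraction: float) -> slice:
    """Final ``tail_fraction`` of the points, at least MIN_TAIL_POINTS."""
    k = max(int(round(n * tail_fraction)), min(MIN_TAIL_POINTS, n))
    return slice(n - k, n)


def estimate_batch_noise(
    curves: CurveSet | list[ForceDistanceCurve], tail_fraction: float = DEFAULT_TAIL_FRACTION
) -> float:
    """Batch noise level sigma_NOISE: mean over curves of the tail force sd.

    Each curve's baseline is subtracted (tail mean) before taking the sd, so
    the estimate reflects noise, not offset.  An all-constant batch returns 0
    with a warning.
    """
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must be in (0, 1)")
    curves = list(curves)
    if not curves:
        raise ValueError("empty batch")
    sds = []
    for c in curves:
        tail = c.force[_tail_slice(len(c.force), tail_fraction)]
        sds.append(float(np.std(tail - tail.mean(), ddof=1)) if len(tail) > 1 else 0.0)
    sigma = float(np.mean(sds))
    if sigma == 0.0:
        warnings.warn("all-constant batch: sigma_NOISE is 0", stacklevel=2)
    return sigma


def find_contact_index(force: np.ndarray) -> int | None:
    """Index of the contact point on a baseline-zeroed retraction trace.

    Scanning in acquisition order (ascending separation), contact is the
    first transition from negative (adhesive) to positive force.  Returns
    None when the trace never crosses from negative to positive — no
    detectable contact.
    """
    neg = force < 0
    pos = force > 0
    crossings = np.flatnonzero(neg[:-1] & pos[1:])
    if len(crossings) == 0:
        return None
    return int(crossings[0] + 1)


def preprocess_trace(
    curve: ForceDistanceCurve, tail_fraction: float = DEFAULT_TAIL_FRACTION
) -> PreprocessedTrace:
    """Zero the baseline, convert to separation, align contact, resample at 1 nm.

    Raises :class:`UnsortableTraceError` when the deflection-corrected
    separation is non-monotone beyond a 2-nm tolerance.
    """
    force = curve.force.astype(float).copy()
    tail = _tail_slice(len(force), tail_fraction)
    baseline = float(force[tail].mean())
    force -= baseline
    baseline_sigma = float(np.std(force[tail], ddof=1)) if len(force[tail]) > 1 else 0.0

    if curve.is_tss:
        s = curve.z.astype(float).copy()
    else:
        s = curve.z - force / curve.spring_constant

    # sign convention: separation increases away from the surface
    if s[-1] < s[0]:
        s = s[::-1]
        force = force[::-1]
    drops = np.diff(s)
    if np.any(drops < -2.0 * GRID_NM):
        raise UnsortableTraceError(
            f"{curve.curve_id}: separation non-monotone beyond 2 nm after correction"
        )
    if np.any(drops < 0):  # small rupture-induced wiggles: sort stably
        order = np.argsort(s, kind="stable")
        s, force = s[order], force[order]

    contact = find_contact_index(force)
    contact_found = contact is not None
    x0 = s[contact] if contact is not None else s[0]
    s = s - x0

    x_max = s[-1]
    if x_max <= 0:
        grid = np.array([0.0])
    else:
        grid = np.arange(0.0, np.floor(x_max) + 0.5, GRID_NM)
    f_grid = np.interp(grid, s, force)

    above = np.flatnonzero(f_grid > TRACE_FORCE_FLOOR_PN)
    length_points = int(above[-1] + 1) if len(above) else 0
    return PreprocessedTrace(
        curve_id=curve.curve_id,
        x=grid,
        force=f_grid,
        baseline_sigma=baseline_sigma,
        length_points=length_points,
        sample_id=curve.sample_id,
        contact_found=contact_found,
    )


def filter_block1(
    curves: CurveSet | list[ForceDistanceCurve],
    sigma_noise: float,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> tuple[list[PreprocessedTrace], FilterReport]:
    """Preprocess a batch and reject spurious traces.

    Rejection reasons (checked in order):

    - ``no_contact``: no negative-to-positive force transition about the
      zeroed baseline;
    - ``force_range``: any |force| above 5000 pN;
    - ``wavy_tail``: tail sd about zero exceeding ``2 * sigma_noise``;
    - ``unsortable``: separation not monotone after deflection correction.

    Total: every input id lands in exactly one of kept/rejected.
    """
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be >= 0")
    report = FilterReport()
    kept_traces: list[PreprocessedTrace] = []
    for curve in curves:
        try:
            trace = preprocess_trace(curve, tail_fraction=tail_fraction)
        except UnsortableTraceError:
            report.rejected[curve.curve_id] = "unsortable"
            continue
        if not trace.contact_found:
            report.rejected[curve.curve_id] = "no_contact"
            continue
        if np.any(np.abs(trace.force) > FORCE_RANGE_PN):
            report.rejected[curve.curve_id] = "force_range"
            continue
        tail = trace.force[_tail_slice(len(trace.force), tail_fraction)]
        tail_sd_about_zero = float(np.sqrt(np.mean(tail**2))) if len(tail) else 0.0
        if sigma_noise > 0 and tail_sd_about_zero > 2.0 * sigma_noise:
            report.rejected[curve.curve_id] = "wavy_tail"
            continue
        report.kept.append(curve.curve_id)
        kept_traces.append(trace)
    return kept_traces, report
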