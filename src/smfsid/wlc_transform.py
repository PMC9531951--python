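"""Worm-like-chain elasticity: force from extension and contour-length inversion.

The interpolation form of the WLC model gives the entropic restoring force of
a polymer of contour length ``Lc`` and persistence length ``lp`` stretched to
extension ``x``::

    F(x) = (kB*T/lp) * [ 1/4 (1 - x/Lc)^-2 - 1/4 + x/Lc ]

The constant term is -1/4 so that F(0) = 0 (the standard interpolation; a
``constant_term=+0.25`` switch reproduces the occasionally-typeset +1/4
variant).  For an unfolded polypeptide lp = 0.4 nm, and the model is trusted
in the 30-500 pN force window: below ~30 pN the entropic description is noisy,
above ~500 pN backbone enthalpic stretching takes over.

Inverting the relation per measured point (x, F) yields the contour length of
the polymer segment tethered at that instant; a trace's Lc profile is the
primary pattern descriptor used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

KB = 0.0138064852  # pN*nm/K


@dataclass
class WlcParams:
    """WLC model parameters and validity window.

    lp : persistence length (nm); 0.4 nm for unfolded polypeptide.
    T : temperature (K); experiments at 24 C.
    force_min, force_max : validity window (pN) for Lc inversion.
    constant_term : -0.25 for the F(0)=0 interpolation form.
    """

    lp: float = 0.4
    T: float = 297.0
    force_min: float = 30.0
    force_max: float = 500.0
    constant_term: float = -0.25

    def __post_init__(self) -> None:
        if self.lp <= 0 or self.T <= 0:
            raise ValueError("lp and T must be positive")
        if not 0 < self.force_min < self.force_max:
            raise ValueError("need 0 < force_min < force_max")

    @property
    def force_scale(self) -> float:
        """kB*T/lp in pN (10.25 pN at defaults)."""
        return KB * self.T / self.lp


@dataclass
class LcProfile:
    """Per-grid-point contour length of a preprocessed trace.

    ``lc_values[i]`` is defined (non-NaN) only where ``valid_mask[i]``: the
    force lies inside the WLC validity window and the extension is positive.
    """

    lc_values: np.ndarray
    valid_mask: np.ndarray

    @property
    def valid_lc(self) -> np.ndarray:
        return self.lc_values[self.valid_mask]


def wlc_force(x, Lc, params: WlcParams | None = None):
    """WLC force (pN) at extension ``x`` for contour length ``Lc`` (both nm).

    Accepts scalars or broadcastable arrays; requires 0 <= x < Lc.
    """
    params = params or WlcParams()
    x = np.asarray(x, dtype=float)
    Lc = np.asarray(Lc, dtype=float)
    if np.any(x < 0) or np.any(x >= Lc):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    u = x / Lc
    out = params.force_scale * (0.25 / (1.0 - u) ** 2 + params.constant_term + u)
    return float(out) if out.ndim == 0 else out


def _relative_extension(F: float, params: WlcParams) -> float:
    """Solve g(u) = 0.25/(1-u)^2 + c + u = F/(kBT/lp) for u in (0, 1).

    g is strictly increasing on (0,1), so the root is unique.
    """
    target = F / params.force_scale

    def g(u: float) -> float:
        return 0.25 / (1.0 - u) ** 2 + params.constant_term + u - target

    lo, hi = 1e-12, 1.0 - 1e-12
    if g(lo) >= 0:  # force at (or below) the u->0 limit
        return lo
    return brentq(g, lo, hi, xtol=1e-14, rtol=1e-15)


def invert_contour_length(x, F, params: WlcParams | None = None):
    """Contour length Lc (nm) solving wlc_force(x, Lc) = F.

    At fixed x the force decreases monotonically in Lc, so the solution is
    unique; it is obtained through the relative extension u = x/Lc, for which
    the model is strictly increasing.  Points with F outside
    [force_min, force_max] or x <= 0 are returned as NaN (excluded from
    histograms), not raised.
    """
    params = params or WlcParams()
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    F_arr = np.atleast_1d(np.asarray(F, dtype=float))
    x_arr, F_arr = np.broadcast_arrays(x_arr, F_arr)
    out = np.full(x_arr.shape, np.nan)
    ok = (x_arr > 0) & (F_arr >= params.force_min) & (F_arr <= params.force_max)
    # u depends only on F: cache repeated forces (common on resampled grids)
    cache: dict[float, float] = {}
    it = np.nditer(ok, flags=["multi_index"])
    for valid in it:
        if not valid:
            continue
        idx = it.multi_index
        f = float(F_arr[idx])
        u = cache.get(f)
        if u is None:
            u = _relative_extension(f, params)
            cache[f] = u
        out[idx] = x_arr[idx] / u
    if np.isscalar(x) and np.isscalar(F):
        return float(out.ravel()[0])
    return out


def trace_to_lc_profile(trace, params: WlcParams | None = None) -> LcProfile:
    """Pointwise Lc inversion of a preprocessed trace (see Block-2 pipeline).

    ``trace`` needs ``x`` and ``force`` arrays on the 1-nm grid.
    """
    params = params or WlcParams()
    lc = invert_contour_length(trace.x, trace.force, params)
    lc = np.atleast_1d(lc)
    valid = np.isfinite(lc)
    # Lc must exceed the extension; guard against degenerate roots at u->1
    valid &= np.where(valid, lc > np.atleast_1d(trace.x), False)
    lc = np.where(valid, lc, np.nan)
    return LcProfile(lc_values=lc, valid_mask=valid)
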