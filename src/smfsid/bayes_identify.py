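"""Bayesian molecular identification of unfolding clusters.

Each refined cluster is reduced to three observables — the maximal contour
length Lc_max, the mean unfolding force, and the normalised Lc peak profile —
and each candidate protein A in the proteome receives the posterior

    P(A | cluster) = P(Lc_max | L_A) * P(F | class_A) * P(peaks | loops_A)
                     * P(A) / N

with the prior P(A) = abundance_A * ismembrane_A (normalised), and N summing
the same product over the whole proteome.

Likelihoods
-----------
* Lc: across published membrane-protein unfolding experiments the measured
  Lc_max averages 89% of the nominal contour length (0.4 nm per residue),
  with a combined relative spread of 0.10 (effective-length scatter 0.05,
  persistence-length uncertainty 0.07, Lc_max measurement error 0.05, added
  in quadrature).  Proteins with a terminal soluble domain longer than twice
  that spread have an ill-defined anchoring point, so the Gaussian is
  replaced by a uniform density between L - L_domain and L.
* Force: per secondary-structure class density (lognormal calibration
  defaults; an unknown class is uninformative, likelihood 1).
* Peaks: unfolding peaks concentrate at membrane-protein loops, so the
  cluster profile is cross-correlated against a sum of 15-nm-FWHM Gaussians
  at the protein's loop centers (a flat line when no structure is known),
  taking the maximum over +-15 nm of lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cluster_refinement import ClusterObservables
from .fd_io import ProteinRecord

NM_PER_RESIDUE = 0.4
FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class LikelihoodConfig:
    """Parameters of the three likelihood factors.

    The relative sigmas are fractions of the nominal contour length; the
    force model maps ss_class -> (lognormal shape, scale/pN) and ships
    calibration values meant to be refit from literature force tables.
    """

    lc_scale: float = 0.89
    sigma_effective: float = 0.05
    sigma_p: float = 0.07
    sigma_lc: float = 0.05
    nm_per_residue: float = NM_PER_RESIDUE
    loop_fwhm: float = 15.0
    max_lag: float = 15.0
    profile_force_band: tuple[float, float] = (40.0, 100.0)
    force_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # calibration defaults: median unfolding force per structure class
            "helix": (0.45, 110.0),
            "sheet": (0.45, 200.0),
            "mixed": (0.55, 150.0),
        }
    )

    @property
    def sigma_likelihood(self) -> float:
        """Combined relative sigma (quadrature of the three components)."""
        return float(
            np.sqrt(self.sigma_effective**2 + self.sigma_p**2 + self.sigma_lc**2)
        )


@dataclass
class PosteriorTable:
    """Ranked per-cluster candidate table (posteriors sum to 1)."""

    cluster_id: str
    rows: list[dict]  # protein_id, prior, p_lc, p_force, p_peaks, posterior
    flagged_uninformative: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["protein_id", "prior", "p_lc", "p_force", "p_peaks", "posterior"],
        )

    def top(self, n: int = 4) -> list[str]:
        return [r["protein_id"] for r in self.rows[:n]]


def build_prior(proteome: list[ProteinRecord]) -> np.ndarray:
    """Normalised abundance * ismembrane prior over the proteome."""
    w = np.array([p.abundance * p.is_membrane for p in proteome], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("empty_prior: no membrane protein with positive abundance")
    return w / total


def lc_likelihood(lc_max: float, protein: ProteinRecord, cfg: LikelihoodConfig | None = None) -> float:
    """Density (1/nm) of observing ``lc_max`` from protein A's unfolding.

    Gaussian centered at 0.89 L with sd 0.10 L; uniform on (L - L_domain, L)
    when the terminal domain exceeds twice the combined sigma.
    """
    cfg = cfg or LikelihoodConfig()
    if lc_max <= 0:
        return 0.0
    L = protein.n_residues * cfg.nm_per_residue
    sigma = cfg.sigma_likelihood * L
    if protein.final_domain_nm >= 2.0 * sigma:
        lo, hi = L - protein.final_domain_nm, L
        return 1.0 / protein.final_domain_nm if lo < lc_max < hi else 0.0
    return float(stats.norm.pdf(lc_max, loc=cfg.lc_scale * L, scale=sigma))


def force_likelihood(mean_force: float, protein: ProteinRecord, cfg: LikelihoodConfig | None = None) -> float:
    """Density (1/pN) of the cluster's mean unfolding force under protein A's
    structure class; an unknown class is uninformative (constant 1)."""
    cfg = cfg or LikelihoodConfig()
    if mean_force <= 0:
        raise ValueError("mean_force must be positive")
    model = cfg.force_model.get(protein.ss_class)
    if model is None:
        return 1.0
    shape, scale = model
    return float(stats.lognorm.pdf(mean_force, s=shape, scale=scale))


def structure_profile(
    protein: ProteinRecord, grid: np.ndarray, cfg: LikelihoodConfig | None = None
) -> np.ndarray:
    """Unit-area loop-position profile: sum of FWHM-15-nm Gaussians at the
    protein's loop centers, or a flat line when no loops are annotated."""
    cfg = cfg or LikelihoodConfig()
    if len(grid) < 2:
        return np.ones_like(grid)
    step = grid[1] - grid[0]
    if protein.loop_centers_nm:
        sd = cfg.loop_fwhm / FWHM_TO_SD
        prof = np.zeros_like(grid, dtype=float)
        for c in protein.loop_centers_nm:
            prof += np.exp(-0.5 * ((grid - c) / sd) ** 2)
    else:
        prof = np.ones_like(grid, dtype=float)
    area = prof.sum() * step
    return prof / area if area > 0 else prof


def _upsample_profile(obs: ClusterObservables) -> tuple[np.ndarray, np.ndarray]:
    """Cluster peak profile linearly upsampled from its histogram bins to a
    1-nm grid, renormalised to unit area."""
    edges = obs.profile_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    grid = np.arange(edges[0], edges[-1] + 0.5, 1.0)
    dens = np.interp(grid, centers, obs.peak_profile, left=0.0, right=0.0)
    area = dens.sum() * 1.0
    if area > 0:
        dens = dens / area
    return grid, dens


def peaks_likelihood(
    obs: ClusterObservables, protein: ProteinRecord, cfg: LikelihoodConfig | None = None
) -> float:
    """Maximum cross-correlation (over +-15 nm lag) between the cluster's
    unit-area Lc peak profile and the protein's loop-position profile."""
    cfg = cfg or LikelihoodConfig()
    grid, cluster_prof = _upsample_profile(obs)
    if len(grid) < 2 or cluster_prof.sum() == 0:
        return 1.0
    step = grid[1] - grid[0]
    prot_prof = structure_profile(protein, grid, cfg)
    max_lag = int(round(cfg.max_lag / step))
    best = 0.0
    n = len(grid)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a = cluster_prof[: n - lag]
            b = prot_prof[lag:]
        else:
            a = cluster_prof[-lag:]
            b = prot_prof[: n + lag]
        c = float(np.sum(a * b) * step)
        if c > best:
            best = c
    return best


def posterior_table(
    obs: ClusterObservables,
    proteome: list[ProteinRecord],
    cfg: LikelihoodConfig | None = None,
    cluster_id: str = "",
) -> PosteriorTable:
    """Eq.-8-style posterior over the proteome for one cluster's observables."""
    cfg = cfg or LikelihoodConfig()
    prior = build_prior(proteome)
    rows = []
    products = np.zeros(len(proteome))
    for i, prot in enumerate(proteome):
        p_lc = lc_likelihood(obs.lc_max, prot, cfg)
        p_force = force_likelihood(obs.mean_force, prot, cfg) if obs.mean_force > 0 else 1.0
        p_peaks = peaks_likelihood(obs, prot, cfg)
        products[i] = p_lc * p_force * p_peaks * prior[i]
        rows.append(
            {
                "protein_id": prot.protein_id,
                "prior": float(prior[i]),
                "p_lc": p_lc,
                "p_force": p_force,
                "p_peaks": p_peaks,
                "posterior": 0.0,
            }
        )
    total = products.sum()
    flagged = False
    if total > 0:
        post = products / total
    else:  # uninformative evidence: uniform over the prior's support
        support = prior > 0
        post = support / support.sum()
        flagged = True
    for r, p in zip(rows, post):
        r["posterior"] = float(p)
    rows.sort(key=lambda r: (-r["posterior"], r["protein_id"]))
    return PosteriorTable(cluster_id=cluster_id, rows=rows, flagged_uninformative=flagged)


def required_sampling(
    n1c: float,
    ntot: float | None = None,
    p2d: float | None = None,
    k_factor: float | None = None,
):
    """Solve the sampling-yield relation N1c = K * Ntot * P2D.

    Exactly one of (``k_factor``) or (``ntot`` and ``p2d``) must be missing:
    given Ntot and P2D the pulling-efficiency factor K (um^2) is returned;
    given K the required Ntot * P2D product (traces * protein / um^2) is
    returned.
    """
    if n1c <= 0:
        raise ValueError("n1c must be positive")
    if k_factor is None:
        if ntot is None or p2d is None or ntot <= 0 or p2d <= 0:
            raise ValueError("need positive ntot and p2d to solve for K")
        return n1c / (ntot * p2d)
    if k_factor <= 0:
        raise ValueError("k_factor must be positive")
    if ntot is not None and p2d is not None:
        raise ValueError("over-determined: give either k_factor or (ntot, p2d)")
    return n1c / k_factor


class BayesianProteinIdentifier(BaseEstimator):
    """Posterior protein identification for unfolding clusters.

    Fit on a proteome (list of :class:`ProteinRecord`); ``predict_proba``
    maps cluster observables to a posterior matrix, ``predict`` to the
    top-ranked protein id per cluster.
    """

    def __init__(self, cfg: LikelihoodConfig | None = None):
        self.cfg = cfg

    def fit(self, proteome: list[ProteinRecord], y=None):
        if not proteome:
            raise ValueError("empty proteome")
        self.proteome_ = list(proteome)
        self.prior_ = build_prior(self.proteome_)
        self.protein_ids_ = [p.protein_id for p in self.proteome_]
        return self

    def _check_fitted(self):
        if not hasattr(self, "proteome_"):
            raise ValueError("identifier is not fitted; call fit(proteome) first")

    def tables(self, observables: list[ClusterObservables]) -> list[PosteriorTable]:
        self._check_fitted()
        cfg = self.cfg or LikelihoodConfig()
        return [
            posterior_table(obs, self.proteome_, cfg, cluster_id=str(i))
            for i, obs in enumerate(observables)
        ]

    def predict_proba(self, observables: list[ClusterObservables]) -> np.ndarray:
        """(n_clusters, n_proteins) posterior matrix in proteome order."""
        tabs = self.tables(observables)
        out = np.zeros((len(tabs), len(self.proteome_)))
        idx = {pid: j for j, pid in enumerate(self.protein_ids_)}
        for i, t in enumerate(tabs):
            for r in t.rows:
                out[i, idx[r["protein_id"]]] = r["posterior"]
        return out

    def predict(self, observables: list[ClusterObservables]) -> list[str]:
        return [t.rows[0]["protein_id"] for t in self.tables(observables)]
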