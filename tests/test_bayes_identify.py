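"""Prior, likelihood factors, posterior normalization and sampling yield."""

import numpy as np
import pytest
from scipy import integrate

from smfsid.bayes_identify import (
    BayesianProteinIdentifier,
    LikelihoodConfig,
    build_prior,
    force_likelihood,
    lc_likelihood,
    peaks_likelihood,
    posterior_table,
    required_sampling,
    structure_profile,
)
from smfsid.cluster_refinement import ClusterObservables
from smfsid.fd_io import ProteinRecord


def _protein(pid="P", n_res=500, ab=1.0, mem=1, ss="unknown", fd=0.0, loops=()):
    return ProteinRecord(pid, n_res, ab, mem, ss, fd, list(loops))


def _obs(lc_max=178.0, mean_force=120.0, profile=None, edges=None):
    if profile is None:
        edges = np.arange(0.0, 208.0, 8.0)
        profile = np.zeros(len(edges) - 1)
        profile[10] = 1.0 / 8.0
    return ClusterObservables(
        lc_max=lc_max,
        mean_force=mean_force,
        peak_profile=np.asarray(profile, float),
        profile_edges=np.asarray(edges, float),
        n_members=10,
    )


class TestPrior:
    def test_membrane_weighted_normalization(self):
        prots = [
            _protein("A", ab=2.0, mem=1),
            _protein("B", ab=1.0, mem=1),
            _protein("C", ab=1.0, mem=0),
        ]
        np.testing.assert_allclose(build_prior(prots), [2 / 3, 1 / 3, 0.0])

    def test_single_membrane_protein(self):
        assert build_prior([_protein("A", ab=0.5, mem=1)])[0] == 1.0

    def test_random_tables_sum_to_one(self, rng):
        for _ in range(20):
            prots = [
                _protein(f"P{i}", ab=float(rng.uniform(0, 5)), mem=int(rng.integers(0, 2)))
                for i in range(10)
            ]
            if sum(p.abundance * p.is_membrane for p in prots) == 0:
                continue
            assert build_prior(prots).sum() == pytest.approx(1.0)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="empty_prior"):
            build_prior([_protein("A", ab=1.0, mem=0)])


class TestLcLikelihood:
    def test_gaussian_mode_density(self):
        # 500 aa -> L = 200 nm, sd = sigma_likelihood * L (~20 nm, the exact
        # quadrature 0.0995 is used, printed as 0.10); density at the mode
        p = _protein(n_res=500)
        cfg = LikelihoodConfig()
        val = lc_likelihood(0.89 * 200.0, p, cfg)
        sd = cfg.sigma_likelihood * 200.0
        assert val == pytest.approx(1.0 / (sd * np.sqrt(2 * np.pi)), rel=1e-9)
        assert val == pytest.approx(0.0199, abs=2e-4)

    def test_long_final_domain_switches_to_uniform(self):
        # 2 sigma = 40 nm, final domain 60 nm -> uniform on (140, 200)
        p = _protein(n_res=500, fd=60.0)
        assert lc_likelihood(170.0, p) == pytest.approx(1.0 / 60.0)
        assert lc_likelihood(130.0, p) == 0.0

    def test_mode_maximizes_gaussian_branch(self):
        p = _protein(n_res=500)
        grid = np.linspace(100.0, 260.0, 321)
        vals = [lc_likelihood(x, p) for x in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.89 * 200.0, abs=0.5)


class TestForceLikelihood:
    def test_unknown_class_uninformative(self):
        p = _protein(ss="unknown")
        assert force_likelihood(50.0, p) == 1.0
        assert force_likelihood(400.0, p) == 1.0

    def test_class_densities_order_band_forces(self):
        helix, sheet = _protein(ss="helix"), _protein(ss="sheet")
        assert force_likelihood(110.0, helix) > force_likelihood(110.0, sheet)
        assert force_likelihood(250.0, sheet) > force_likelihood(250.0, helix)

    @pytest.mark.parametrize("ss", ["helix", "sheet", "mixed"])
    def test_density_normalized_over_force_axis(self, ss):
        p = _protein(ss=ss)
        total, _ = integrate.quad(lambda f: force_likelihood(f, p), 1e-6, 2000.0)
        assert total == pytest.approx(1.0, abs=1e-3)


class TestPeaksLikelihood:
    def _profile_obs(self, centers, lc_span=200.0):
        cfg = LikelihoodConfig()
        edges = np.arange(0.0, lc_span + 8.0, 8.0)
        grid = 0.5 * (edges[:-1] + edges[1:])
        sd = cfg.loop_fwhm / 2.3548
        prof = np.zeros_like(grid)
        for c in centers:
            prof += np.exp(-0.5 * ((grid - c) / sd) ** 2)
        prof /= prof.sum() * 8.0
        return _obs(profile=prof, edges=edges)

    def test_matching_profile_scores_self_correlation(self):
        p = _protein(n_res=500, loops=[60.0, 120.0])
        obs = self._profile_obs([60.0, 120.0])
        score = peaks_likelihood(obs, p)
        mismatch = peaks_likelihood(self._profile_obs([30.0, 170.0]), p)
        assert score > mismatch

    def test_shift_within_lag_window_recovered(self):
        p = _protein(n_res=500, loops=[60.0, 120.0])
        aligned = peaks_likelihood(self._profile_obs([60.0, 120.0]), p)
        shifted = peaks_likelihood(self._profile_obs([70.0, 130.0]), p)
        assert shifted == pytest.approx(aligned, rel=0.05)

    def test_empty_loop_list_gives_flat_line_correlation(self):
        p = _protein(n_res=500, loops=[])
        obs = self._profile_obs([60.0, 120.0])
        grid_len = len(np.arange(obs.profile_edges[0], obs.profile_edges[-1] + 0.5, 1.0))
        expected_flat = 1.0 / (grid_len * 1.0)
        score = peaks_likelihood(obs, p)
        # flat unit-area profile: cross-correlation is bounded by the flat level
        assert score == pytest.approx(expected_flat, rel=0.05)

    def test_structure_profile_unit_area(self):
        p = _protein(n_res=500, loops=[50.0, 100.0, 150.0])
        grid = np.arange(0.0, 200.0, 1.0)
        prof = structure_profile(p, grid)
        assert prof.sum() * 1.0 == pytest.approx(1.0, rel=1e-6)


class TestPosterior:
    def test_single_membrane_protein_posterior_one(self):
        t = posterior_table(_obs(), [_protein("A", n_res=500)])
        assert t.rows[0]["posterior"] == pytest.approx(1.0)

    def test_prior_ratio_carries_through_identical_likelihoods(self):
        prots = [
            _protein("A", n_res=500, ab=3.0),
            _protein("B", n_res=500, ab=1.0),
        ]
        t = posterior_table(_obs(), prots)
        post = {r["protein_id"]: r["posterior"] for r in t.rows}
        assert post["A"] == pytest.approx(0.75, abs=1e-9)
        assert post["B"] == pytest.approx(0.25, abs=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        prots = [
            _protein(f"P{i}", n_res=int(rng.integers(100, 1200)), ab=float(rng.uniform(0.1, 5)))
            for i in range(30)
        ]
        t = posterior_table(_obs(lc_max=150.0), prots)
        assert sum(r["posterior"] for r in t.rows) == pytest.approx(1.0, abs=1e-9)
        assert all(r["posterior"] >= 0 for r in t.rows)

    def test_abundance_monotonicity(self):
        base = [
            _protein("A", n_res=480, ab=1.0),
            _protein("B", n_res=520, ab=1.0),
        ]
        boosted = [
            _protein("A", n_res=480, ab=2.0),
            _protein("B", n_res=520, ab=1.0),
        ]
        obs = _obs(lc_max=178.0)
        pa0 = {r["protein_id"]: r["posterior"] for r in posterior_table(obs, base).rows}["A"]
        pa1 = {r["protein_id"]: r["posterior"] for r in posterior_table(obs, boosted).rows}["A"]
        assert pa1 >= pa0

    def test_sigma_likelihood_quadrature(self):
        cfg = LikelihoodConfig()
        assert cfg.sigma_likelihood == pytest.approx(
            np.sqrt(0.05**2 + 0.07**2 + 0.05**2)
        )
        assert round(cfg.sigma_likelihood, 2) == 0.10

    def test_estimator_interface(self):
        prots = [_protein("A", n_res=500), _protein("B", n_res=300)]
        ident = BayesianProteinIdentifier().fit(prots)
        proba = ident.predict_proba([_obs(lc_max=178.0), _obs(lc_max=107.0)])
        assert proba.shape == (2, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert ident.predict([_obs(lc_max=178.0)]) == ["A"]


class TestRequiredSampling:
    def test_pulling_efficiency_from_disc_cluster(self):
        k = required_sampling(285, ntot=106528, p2d=3e4)
        assert k == pytest.approx(8.9e-8, rel=0.01)
        assert float(f"{k:.0e}") == pytest.approx(9e-8)

    def test_required_product_for_fifty_traces(self):
        prod = required_sampling(50, k_factor=9e-8)
        assert prod == pytest.approx(5.6e8, rel=0.01)

    def test_identity_case(self):
        assert required_sampling(100, k_factor=1.0) == pytest.approx(100.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_sampling(0, ntot=1, p2d=1)
        with pytest.raises(ValueError):
            required_sampling(10)
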