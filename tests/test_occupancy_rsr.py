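"""Restricted-spatial-regression occupancy: basis, Gibbs sampler, PPLC."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import chisquare, gamma

import trapstat as ts
from trapstat.errors import DesignError, InvalidParameterError
from trapstat.occupancy_rsr import Adjacency, tau_full_conditional


class TestAdjacency:
    def test_points_within_threshold_are_neighbours(self):
        adj = ts.build_adjacency(np.array([[0.0, 0], [5000.0, 0]]), 8700)
        assert len(adj.pairs) == 1

    def test_exact_threshold_included(self):
        adj = ts.build_adjacency(np.array([[0.0, 0], [8700.0, 0]]), 8700)
        assert len(adj.pairs) == 1

    def test_beyond_threshold_excluded(self):
        adj = ts.build_adjacency(np.array([[0.0, 0], [8700.01, 0]]), 8700)
        assert len(adj.pairs) == 0

    def test_single_point_no_pairs(self):
        adj = ts.build_adjacency(np.array([[0.0, 0.0]]), 8700)
        assert len(adj.pairs) == 0

    def test_duplicate_coordinates_warn_but_connect(self):
        with pytest.warns(UserWarning):
            adj = ts.build_adjacency(np.array([[0.0, 0], [0.0, 0]]), 100)
        assert len(adj.pairs) == 1
        A = adj.matrix()
        assert A[0, 0] == 0 and A[0, 1] == 1


class TestMoranCut:
    @pytest.mark.parametrize(
        "n,frac,expected", [(849, 0.1, 85), (100, 0.1, 10), (10, 0.1, 1)]
    )
    def test_values(self, n, frac, expected):
        assert ts.moran_cut(n, frac) == expected

    def test_half_up_rounding(self):
        assert ts.moran_cut(849) == 85  # 84.9 rounds up
        assert ts.moran_cut(845) == 85  # 84.5 rounds half up
        assert ts.moran_cut(844) == 84  # 84.4 rounds down

    def test_invalid_fraction(self):
        with pytest.raises(InvalidParameterError):
            ts.moran_cut(100, 1.5)


def _path_graph(n):
    pairs = np.array([[i, i + 1] for i in range(n - 1)])
    return Adjacency(n_sites=n, pairs=pairs, threshold=1.0)


class TestMoranBasis:
    def test_path_graph_matches_dense_eigendecomposition(self):
        """4-node path, intercept-only X: compare to an independent dense
        linear-algebra construction of the projected operator."""
        adj = _path_graph(4)
        X = np.ones((4, 1))
        basis = ts.moran_basis(adj, X, q=2)
        A = adj.matrix()
        P = np.eye(4) - np.ones((4, 4)) / 4
        Omega = (4 / A.sum()) * P @ A @ P
        vals, vecs = np.linalg.eigh(Omega)
        top = vals[::-1][:2]
        assert np.allclose(basis.eigenvalues, top, atol=1e-8)
        # eigenvectors match up to sign
        for j in range(2):
            v = vecs[:, ::-1][:, j]
            assert min(
                np.abs(basis.K[:, j] - v).max(),
                np.abs(basis.K[:, j] + v).max(),
            ) < 1e-8

    def test_basis_orthogonal_to_fixed_effects(self, small_landscape):
        stations, _ = small_landscape
        covs, _ = ts.zscore(stations, ["elevation", "forest"])
        X = np.column_stack([
            np.ones(len(covs)), covs[["elevation", "forest"]].to_numpy()
        ])
        adj = ts.build_adjacency(stations[["x", "y"]].to_numpy(), 8700)
        basis = ts.moran_basis(adj, X, q=15)
        assert np.abs(basis.K.T @ X).max() < 1e-8
        assert np.allclose(basis.K.T @ basis.K, np.eye(15), atol=1e-8)

    def test_eigenvalues_nonincreasing(self, small_landscape):
        stations, _ = small_landscape
        adj = ts.build_adjacency(stations[["x", "y"]].to_numpy(), 8700)
        basis = ts.moran_basis(adj, np.ones((len(stations), 1)), q=20)
        assert (np.diff(basis.eigenvalues) <= 1e-10).all()

    def test_edgeless_graph_rejected(self):
        adj = Adjacency(n_sites=3, pairs=np.zeros((0, 2), int), threshold=1.0)
        with pytest.raises(DesignError):
            ts.moran_basis(adj, np.ones((3, 1)), q=1)


class TestTauConjugacy:
    def test_full_conditional_matches_analytic_gamma(self):
        """chi-square test of 10,000 draws against
        Gamma(0.5 + q/2, rate 0.0005 + alpha'K'QK alpha / 2) with alpha frozen."""
        rng = np.random.default_rng(123)
        adj = _path_graph(30)
        basis = ts.moran_basis(adj, np.ones((30, 1)), q=8)
        M0 = basis.K.T @ basis.Q @ basis.K
        alpha = rng.normal(size=8)
        draws = tau_full_conditional(rng, alpha, M0, size=10000)
        a = 0.5 + 4.0
        rate = 0.0005 + float(alpha @ M0 @ alpha) / 2
        edges = gamma.ppf(np.linspace(0, 1, 21), a, scale=1 / rate)
        counts, _ = np.histogram(draws, bins=edges)
        stat, p = chisquare(counts)
        assert p > 0.01


class TestSampler:
    def test_same_seed_identical_draws(self, small_survey):
        covs, occ, _ = small_survey
        kw = dict(iterations=400, burn_in=100, thin=1, seed=5)
        a = ts.fit_nonspatial_bayes(occ, covs, ["elevation"], ["effort"], **kw)
        b = ts.fit_nonspatial_bayes(occ, covs, ["elevation"], ["effort"], **kw)
        assert np.array_equal(a.beta_psi, b.beta_psi)
        assert np.array_equal(a.tau, b.tau)

    def test_draw_count_follows_schedule(self, small_survey):
        covs, occ, _ = small_survey
        post = ts.fit_nonspatial_bayes(
            occ, covs, ["elevation"], [], iterations=1000, burn_in=200, thin=4,
            seed=0,
        )
        assert post.n_draws == 200

    def test_complete_detection_posterior_matches_occupied_fraction(self):
        rng = np.random.default_rng(3)
        n = 300
        z = rng.random(n) < 0.45
        y = np.repeat(z[:, None], 6, axis=1).astype(float)
        from trapstat.detections import OccasionMatrix

        occ = OccasionMatrix(
            [f"s{i}" for i in range(n)], y, np.full((n, 6), 15.0), 15
        )
        covs = pd.DataFrame(index=range(n))
        post = ts.fit_nonspatial_bayes(
            occ, covs, [], [], iterations=2000, burn_in=500, thin=1, seed=4
        )
        assert post.mean_psi_chain().mean() == pytest.approx(z.mean(), abs=0.04)

    def test_all_zero_detections_low_psi_and_no_crash(self, small_survey):
        covs, occ, _ = small_survey
        y0 = np.where(np.isnan(occ.y), np.nan, 0.0)
        from trapstat.detections import OccasionMatrix

        occ0 = OccasionMatrix(occ.stations, y0, occ.effort, occ.occasion_length)
        post = ts.fit_nonspatial_bayes(
            occ0, covs, [], [], iterations=800, burn_in=200, thin=1, seed=6
        )
        # with nothing detected, occupancy is weakly identified but the
        # posterior predictive of detection stays low
        p_det = ndtr(post.beta_p[:, 0])
        psi = post.mean_psi_chain()
        assert np.median(psi * p_det) < 0.2

    def test_probit_scale_tracks_ml_logit_over_1p6(self, small_survey):
        covs, occ, _ = small_survey
        fit = ts.fit_occupancy(
            ts.OccupancyModelSpec(psi_terms=["forest"], p_terms=[]),
            occ, covs, n_starts=3, seed=0,
        )
        post = ts.fit_nonspatial_bayes(
            occ, covs, ["forest"], [], iterations=3000, burn_in=500, thin=2,
            seed=7,
        )
        b_bayes = post.beta_psi[:, 1].mean()
        b_ml = fit.beta_psi["forest"]
        assert np.sign(b_bayes) == np.sign(b_ml)
        assert b_bayes == pytest.approx(b_ml / 1.6, abs=0.25)

    def test_spatial_prior_limit_small_eta(self, small_landscape):
        """tau fixed huge implies var(eta) ~ 0 in the prior draw."""
        stations, _ = small_landscape
        covs, _ = ts.zscore(stations, ["elevation"])
        sds = []
        for rep in range(50):
            _, truth = ts.simulate_occupancy_detections(
                covs, beta_psi=[0.0, 0.3], beta_p=[-1.0],
                psi_terms=["elevation"], tau=1e6, seed=rep,
            )
            sds.append(truth.eta.std())
        assert np.mean(sds) < 0.05


class TestPPLC:
    def test_two_draw_toy_hand_computation(self):
        """PPLC terms computed by hand for a 2-draw posterior on 1 site."""
        from trapstat.detections import OccasionMatrix
        from trapstat.occupancy_rsr import RSRPosterior

        y = np.array([[1.0, 0.0]])
        occ = OccasionMatrix(["a"], y, np.full((1, 2), 15.0), 15)
        covs = pd.DataFrame(index=range(1))
        # two draws: (beta0, gamma0) giving (psi, p) = (.5, .5) then (.8413, .5)
        post = RSRPosterior(
            beta_psi=np.array([[0.0], [1.0]]),
            beta_p=np.array([[0.0], [0.0]]),
            alpha=np.zeros((2, 0)), tau=np.ones(2),
            psi_site=ndtr(np.array([[0.0], [1.0]])),
            z=np.ones((2, 1), np.int8),
            psi_names=["(Intercept)"], p_names=["(Intercept)"],
        )
        res = ts.pplc(post, occ, covs)
        m = np.mean([0.5 * 0.5, ndtr(1.0) * 0.5])  # per-cell predictive mean
        G = (1 - m) ** 2 + (0 - m) ** 2
        P = 2 * m * (1 - m)
        assert res["G"] == pytest.approx(G, abs=1e-12)
        assert res["P"] == pytest.approx(P, abs=1e-12)
        assert res["D"] == pytest.approx(G + P, abs=1e-12)

    def test_sharp_posterior_gives_small_G(self):
        from trapstat.detections import OccasionMatrix
        from trapstat.occupancy_rsr import RSRPosterior

        y = np.ones((1, 3))
        occ = OccasionMatrix(["a"], y, np.full((1, 3), 15.0), 15)
        covs = pd.DataFrame(index=range(1))
        post = RSRPosterior(
            beta_psi=np.full((5, 1), 8.0), beta_p=np.full((5, 1), 8.0),
            alpha=np.zeros((5, 0)), tau=np.ones(5),
            psi_site=np.ones((5, 1)), z=np.ones((5, 1), np.int8),
            psi_names=["(Intercept)"], p_names=["(Intercept)"],
        )
        res = ts.pplc(post, occ, covs)
        assert res["G"] < 1e-10


class TestSummaries:
    def _post(self, draws):
        from trapstat.occupancy_rsr import RSRPosterior

        S = len(draws)
        return RSRPosterior(
            beta_psi=np.asarray(draws)[:, None], beta_p=np.zeros((S, 1)),
            alpha=np.zeros((S, 0)), tau=np.ones(S),
            psi_site=np.full((S, 2), 0.5), z=np.ones((S, 2), np.int8),
            psi_names=["(Intercept)"], p_names=["(Intercept)"],
        )

    def test_symmetric_draws_not_flagged(self):
        post = self._post(np.tile([-1.0, 1.0], 100))
        s = ts.summarize_posterior(post)
        row = s.loc["psi:(Intercept)"]
        assert abs(row["mean"]) < 1e-12 and not row["strong"]

    def test_all_positive_draws_flagged(self):
        post = self._post(np.linspace(0.5, 1.5, 200))
        assert ts.summarize_posterior(post).loc["psi:(Intercept)", "strong"]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            ts.summarize_posterior(self._post(np.ones(50)))


class TestPredictMap:
    def _post(self, b0=-0.47, b1=0.5, S=200):
        from trapstat.occupancy_rsr import RSRPosterior

        return RSRPosterior(
            beta_psi=np.column_stack([np.full(S, b0), np.full(S, b1)]),
            beta_p=np.zeros((S, 1)), alpha=np.zeros((S, 0)), tau=np.ones(S),
            psi_site=np.full((S, 2), 0.5), z=np.ones((S, 2), np.int8),
            psi_names=["(Intercept)", "forest"], p_names=["(Intercept)"],
        )

    def test_point_mass_intercept_maps_through_probit(self):
        """beta0 = -0.47 at covariate means: psi = Phi(-0.47) = 0.319."""
        post = self._post()
        grid = pd.DataFrame({"forest": [0.0]})
        out = ts.predict_psi_map(post, grid)
        assert out["psi_mean"].iloc[0] == pytest.approx(ndtr(-0.47), abs=1e-12)
        assert out["psi_mean"].iloc[0] == pytest.approx(0.319, abs=5e-4)

    def test_monotone_in_positive_covariate(self):
        post = self._post()
        grid = pd.DataFrame({"forest": np.linspace(-2, 2, 30)})
        out = ts.predict_psi_map(post, grid)
        assert (np.diff(out["psi_mean"]) > 0).all()

    def test_single_pixel_region_mean_equals_pixel(self):
        post = self._post()
        grid = pd.DataFrame({"forest": [0.3, 1.0], "region": ["a", "b"]})
        out = ts.predict_psi_map(post, grid, region_col="region")
        reg = out.attrs["regional"]
        assert reg.loc["b", "mean_psi"] == pytest.approx(out["psi_mean"].iloc[1])

    def test_unknown_covariate_rejected(self):
        post = self._post()
        with pytest.raises(KeyError):
            ts.predict_psi_map(post, pd.DataFrame({"elev": [0.0]}))
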