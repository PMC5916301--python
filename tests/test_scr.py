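"""Spatially explicit capture-recapture: mask, likelihood, samplers, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import trapstat as ts
from trapstat.errors import IdentifiabilityError, InvalidParameterError
from trapstat.scr import CaptureHistory, _ml_neg_ll


class TestHalfNormal:
    def test_zero_distance_returns_base(self):
        assert ts.halfnormal(0.0, 0.3, 5000.0) == 0.3

    def test_analytic_factors(self):
        s = 4000.0
        assert ts.halfnormal(s, 1.0, s) == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert ts.halfnormal(2 * s, 1.0, s) == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(InvalidParameterError):
            ts.halfnormal(1.0, 0.5, 0.0)


class TestMask:
    def test_single_trap_disc_area(self):
        mask = ts.build_mask(np.array([[0.0, 0.0]]), buffer=25000, spacing=500)
        assert mask.pixel_area_km2 == pytest.approx(0.25)
        disc = np.pi * 25.0**2
        assert mask.area_km2 == pytest.approx(disc, rel=0.02)

    def test_pixel_area_from_spacing(self):
        mask = ts.build_mask(np.array([[0.0, 0.0]]), buffer=5000, spacing=500)
        assert mask.pixel_area_km2 == 0.25

    def test_all_unsuitable_rejected(self):
        grid = pd.DataFrame({"x": [0.0], "y": [0.0], "habitat": [0]})
        with pytest.raises(InvalidParameterError):
            ts.build_mask(np.array([[0.0, 0.0]]), buffer=2000, spacing=1000,
                          suitability=grid)

    def test_small_buffer_warns_against_sigma_hint(self):
        with pytest.warns(UserWarning):
            ts.build_mask(np.array([[0.0, 0.0]]), buffer=5000, spacing=1000,
                          sigma_hint=8700.0)


def _toy_capture(counts, trap_xy, n_occ=5):
    J = len(trap_xy)
    return CaptureHistory(
        individuals=[f"A{i}" for i in range(len(counts))],
        counts=np.asarray(counts), trap_xy=np.asarray(trap_xy, float),
        usage=np.ones((J, n_occ)),
    )


class TestMLFit:
    def test_likelihood_matches_hand_derived_closed_form(self):
        """1 suitable pixel, 1 trap: the integrated likelihood reduces to
        -D*a*p. + n log D + sum_i log(a * binom-likelihood)."""
        mask = ts.HabitatMask(
            centers=np.array([[0.0, 0.0]]), suitable=np.array([True]),
            spacing=1000.0,
        )
        cap = _toy_capture([[2], [1]], [[300.0, 0.0]], n_occ=5)
        theta = np.array([np.log(0.004), 0.0, np.log(800.0)])  # D, logit g0, log sig
        d2 = np.array([[300.0**2]])
        nll = _ml_neg_ll(theta, cap.counts.astype(float), cap.trap_effort(),
                         d2, mask.pixel_area_km2)
        from scipy.special import expit

        g0, sig, D, A = expit(0.0), 800.0, 0.004, 1.0
        p = g0 * np.exp(-(300.0**2) / (2 * sig**2))
        pdot = 1 - (1 - p) ** 5
        hand = (
            -D * A * pdot + 2 * np.log(D)
            + np.log(A * p**2 * (1 - p) ** 3)
            + np.log(A * p**1 * (1 - p) ** 4)
        )
        assert -nll == pytest.approx(hand, abs=1e-10)

    def test_two_pixel_likelihood_matches_exhaustive_mixture(self):
        """2 pixels, 2 traps, 1 individual: integral equals the explicit sum
        over pixel assignments."""
        centers = np.array([[0.0, 0.0], [2000.0, 0.0]])
        traps = np.array([[500.0, 0.0], [1500.0, 0.0]])
        cap = _toy_capture([[1, 1]], traps, n_occ=4)
        theta = np.array([np.log(0.01), -1.0, np.log(1200.0)])
        d2 = ((traps[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        A = 1.0  # spacing 1000 m
        nll = _ml_neg_ll(theta, cap.counts.astype(float), cap.trap_effort(),
                         d2, A)
        from scipy.special import expit

        D, g0, sig = 0.01, expit(-1.0), 1200.0
        p = g0 * np.exp(-d2 / (2 * sig**2))  # (trap, pixel)
        lik_int = 0.0
        pdot_int = 0.0
        for m in range(2):
            li = 1.0
            for j in range(2):
                li *= p[j, m] ** cap.counts[0, j] * (1 - p[j, m]) ** (
                    4 - cap.counts[0, j]
                )
            lik_int += li * A
            pdot_int += (1 - (1 - p[0, m]) ** 4 * (1 - p[1, m]) ** 4) * A
        hand = -D * pdot_int + 1 * np.log(D) + np.log(lik_int)
        assert -nll == pytest.approx(hand, abs=1e-10)

    def test_mle_matches_grid_search_on_small_instance(self, small_scr):
        mask, traps, truth = small_scr
        fit = ts.scr_ml_fit(truth.captures, mask)
        assert fit.converged
        # profile a coarse grid around the MLE: no grid point beats it
        counts = truth.captures.counts.astype(float)
        effort = truth.captures.trap_effort()
        pix = mask.suitable_centers
        d2 = ((truth.captures.trap_xy[:, None, :] - pix[None, :, :]) ** 2).sum(axis=2)
        from scipy.special import logit

        best = -_ml_neg_ll(
            np.array([np.log(fit.D / 100), logit(fit.g0), np.log(fit.sigma)]),
            counts, effort, d2, mask.pixel_area_km2,
        )
        rng = np.random.default_rng(0)
        for _ in range(40):
            theta = np.array([
                np.log(fit.D / 100) + rng.normal(0, 0.3),
                logit(fit.g0) + rng.normal(0, 0.3),
                np.log(fit.sigma) + rng.normal(0, 0.2),
            ])
            assert -_ml_neg_ll(theta, counts, effort, d2, mask.pixel_area_km2) <= best + 1e-6

    def test_recovers_simulation_truth(self, small_scr):
        mask, traps, truth = small_scr
        fit = ts.scr_ml_fit(truth.captures, mask)
        assert fit.ci["sigma"][0] < truth.sigma < fit.ci["sigma"][1]
        realized_D = truth.N_true / mask.area_km2 * 100
        assert fit.ci["D"][0] < realized_D * 1.3
        assert fit.ci["D"][1] > realized_D * 0.7

    def test_no_spatial_recaptures_rejected(self):
        cap = _toy_capture([[2, 0], [1, 0]], [[0.0, 0], [5000.0, 0]])
        mask = ts.build_mask(cap.trap_xy, buffer=5000, spacing=1000)
        with pytest.raises(IdentifiabilityError):
            ts.scr_ml_fit(cap, mask)

    def test_density_insensitive_to_mask_refinement(self, small_scr):
        mask, traps, truth = small_scr
        fit1 = ts.scr_ml_fit(truth.captures, mask)
        finer = ts.build_mask(traps, buffer=15000.0, spacing=1000.0)
        fit2 = ts.scr_ml_fit(truth.captures, finer)
        assert fit2.D == pytest.approx(fit1.D, rel=0.03)


@pytest.fixture(scope="module")
def posterior(small_scr):
    mask, traps, truth = small_scr
    return (
        ts.scr_bayes_fit(truth.captures, mask, iterations=3000,
                         burn_in=1000, seed=2),
        mask, truth,
    )


class TestBayesFit:
    def test_default_augmentation_rule(self):
        assert ts.default_augmentation(19) == 190

    def test_recovers_density_and_sigma(self, posterior):
        post, mask, truth = posterior
        lo, hi = ts.hpdi(post.D)
        realized_D = truth.N_true / mask.area_km2 * 100
        assert lo < realized_D < hi
        slo, shi = ts.hpdi(post.sigma)
        assert slo < truth.sigma * 1.25 and shi > truth.sigma * 0.75

    def test_bayes_p_value_reasonable_for_well_specified_model(self, posterior):
        post, _, _ = posterior
        assert 0.02 < post.bayes_p < 0.98

    def test_density_surface_conserves_population(self, posterior):
        post, mask, _ = posterior
        surf = ts.density_surface(post, mask)
        integral = surf["density"].sum() * mask.pixel_area_km2
        assert integral == pytest.approx(post.N_super.mean(), rel=0.05)

    def test_surface_mode_near_capture_cluster(self, posterior):
        post, mask, truth = posterior
        surf = ts.density_surface(post, mask)
        # captures concentrate activity centres: the surface peak lies within
        # 2 sigma of the centroid of capture locations
        w = truth.captures.counts.sum(axis=0).astype(float)
        centroid = (truth.captures.trap_xy * w[:, None]).sum(axis=0) / w.sum()
        peak = surf.loc[surf["density"].idxmax(), ["x", "y"]].to_numpy()
        assert np.linalg.norm(peak - centroid) < 2 * truth.sigma

    def test_agreement_with_ml(self, posterior, small_scr):
        post, mask, truth = posterior
        fit = ts.scr_ml_fit(truth.captures, mask)
        lo, hi = ts.hpdi(post.D)
        assert lo < fit.D < hi


class TestBayesSigmaMarginal:
    def test_sparse_data_sigma_matches_integrated_marginal(self):
        """On sparse captures (the regime where sigma and the centre cloud
        are strongly coupled) the sampler's sigma median agrees with a
        brute-force integration of the marginal posterior over a
        (lambda0, sigma, N) grid."""
        from scipy.special import gammaln, logsumexp

        gx, gy = np.meshgrid(np.arange(6), np.arange(6))
        traps = np.column_stack([gx.ravel(), gy.ravel()]) * 5000.0
        sigma_t = 8698.0
        mask = ts.build_mask(traps, buffer=2 * sigma_t, spacing=2000.0)
        truth = ts.simulate_scr_population(
            mask, traps, D_per_100km2=0.8, lambda0=0.0025, sigma=sigma_t,
            n_occasions=60, seed=4,
        )
        y = truth.captures.counts.astype(float)
        n = y.shape[0]
        pix = mask.suitable_centers
        d2 = ((pix[:, None, :] - traps[None, :, :]) ** 2).sum(axis=2)
        M = 11 * n

        def log_marg(lam, sig):
            mu = lam * 60 * np.exp(-d2 / (2 * sig**2))
            A = y @ np.log(mu).T - mu.sum(axis=1)[None, :]
            li = (logsumexp(A, axis=1) - np.log(len(pix))).sum()
            lp0 = logsumexp(-mu.sum(axis=1)) - np.log(len(pix))
            Ns = np.arange(n, M + 1)
            return li + logsumexp(
                gammaln(Ns + 1) - gammaln(Ns - n + 1) + (Ns - n) * lp0
            )

        sigs = np.geomspace(3000, 60000, 25)
        lams = np.geomspace(2e-4, 0.03, 30)
        post = np.array([
            logsumexp([log_marg(lm, sg) - np.log(sg) - np.log(lm) for lm in lams])
            for sg in sigs
        ])
        wts = np.exp(post - post.max())
        wts /= wts.sum()
        med_exact = np.interp(0.5, np.cumsum(wts), sigs)
        p = ts.scr_bayes_fit(truth.captures, mask, iterations=12000,
                             burn_in=4000, seed=9)
        assert np.median(p.sigma) == pytest.approx(med_exact, rel=0.25)


class TestGeweke:
    def test_iid_chain_rarely_flagged(self):
        rng = np.random.default_rng(0)
        zs = [ts.geweke(rng.standard_normal(10000)) for _ in range(200)]
        assert np.mean(np.abs(zs) < 3) >= 0.97

    def test_trending_chain_flagged(self):
        assert abs(ts.geweke(np.linspace(0, 1, 5000))) > 5

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError):
            ts.geweke(np.ones(1000))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            ts.geweke(np.arange(50))


class TestHPDI:
    def test_symmetric_sample_close_to_equal_tailed(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20000)
        lo, hi = ts.hpdi(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        se = 2 * 1.96 / np.sqrt(len(x)) * 3  # generous MC margin
        assert lo == pytest.approx(qlo, abs=0.1)
        assert hi == pytest.approx(qhi, abs=0.1)

    def test_point_mass_zero_width(self):
        lo, hi = ts.hpdi(np.full(500, 3.14))
        assert lo == hi == 3.14

    def test_exponential_matches_brute_force_and_beats_equal_tailed(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.exponential(size=5000))
        lo, hi = ts.hpdi(x, 0.9)
        m = int(np.ceil(0.9 * len(x)))
        # brute force over all m-windows
        widths = [(x[j + m - 1] - x[j], j) for j in range(len(x) - m + 1)]
        wbest, jbest = min(widths)
        assert (hi - lo) == pytest.approx(wbest, abs=1e-12)
        qlo, qhi = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) < (qhi - qlo)
        assert lo < x[int(0.01 * len(x))]  # left endpoint near the minimum
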