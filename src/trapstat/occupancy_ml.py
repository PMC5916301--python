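"""Single-season occupancy models by maximum likelihood (logit links).

Implements the standard zero-inflated detection-history likelihood

    L_i = psi_i * prod_k p_ik^y_ik (1-p_ik)^(1-y_ik)  +  (1-psi_i) * I(y_i == 0)

with products over non-missing occasions only, plus AICc ranking, Akaike-weight
model averaging, Wald prediction intervals and the parametric-bootstrap
(MacKenzie-Bailey) goodness-of-fit test with its overdispersion ratio c-hat.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .detections import OccasionMatrix, naive_occupancy  # noqa: F401
from .errors import DesignError

_EFFORT = "effort"
_SURVEY_AREA = "survey_area"


@dataclass(frozen=True)
class OccupancyModelSpec:
    """Terms entering the occupancy (psi) and detection (p) linear predictors.

    Covariate names resolve against the site-covariate table; ``p_terms`` may
    additionally use ``"effort"`` (per-occasion active days, standardized) and
    ``"survey_area"`` (categorical, expanded to treatment-coded dummies).
    """

    psi_terms: tuple = ()
    p_terms: tuple = ()

    def __init__(self, psi_terms=(), p_terms=()):
        object.__setattr__(self, "psi_terms", tuple(psi_terms))
        object.__setattr__(self, "p_terms", tuple(p_terms))
        if len(set(self.psi_terms)) != len(self.psi_terms):
            raise DesignError("duplicate psi terms")
        if len(set(self.p_terms)) != len(self.p_terms):
            raise DesignError("duplicate p terms")

    def label(self) -> str:
        psi = "+".join(self.psi_terms) or "."
        p = "+".join(self.p_terms) or "."
        return f"psi({psi}) p({p})"


@dataclass
class OccupancyFitML:
    """Maximum-likelihood fit: estimates on the logit scale with SEs."""

    spec: OccupancyModelSpec
    beta_psi: pd.Series
    beta_p: pd.Series
    se_psi: pd.Series
    se_p: pd.Series
    loglik: float
    K: int
    n_sites: int
    converged: bool
    vcov: np.ndarray = field(repr=False)
    _designs: tuple = field(repr=False, default=None)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta_psi.to_numpy(), self.beta_p.to_numpy()])

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.K, self.n_sites)


def build_designs(
    spec: OccupancyModelSpec, occ: OccasionMatrix, covs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Construct X_psi (n, P) and the per-occasion X_p (n, K, Pp).

    Effort is standardized over non-missing cells (training moments are not
    needed downstream: detection is never mapped to new sites). Survey area is
    treatment-coded against its first level.
    """
    n, K = occ.y.shape
    cols_psi = [np.ones(n)]
    names_psi = ["(Intercept)"]
    for t in spec.psi_terms:
        if t not in covs:
            raise DesignError(f"unknown psi covariate {t!r}")
        cols_psi.append(covs[t].to_numpy(dtype=float))
        names_psi.append(t)
    X_psi = np.column_stack(cols_psi)

    mats = [np.ones((n, K))]
    names_p = ["(Intercept)"]
    for t in spec.p_terms:
        if t == _EFFORT:
            eff = occ.effort.copy()
            obs = ~np.isnan(occ.y)
            m = eff[obs].mean()
            s = eff[obs].std(ddof=1)
            if s == 0:
                s = 1.0
            e = (eff - m) / s
            e[~obs] = 0.0
            mats.append(e)
            names_p.append(_EFFORT)
        elif t == _SURVEY_AREA:
            if _SURVEY_AREA not in covs:
                raise DesignError("survey_area column absent from covariates")
            levels = pd.unique(covs[_SURVEY_AREA])
            for lv in levels[1:]:
                d = (covs[_SURVEY_AREA] == lv).to_numpy(dtype=float)
                mats.append(np.repeat(d[:, None], K, axis=1))
                names_p.append(f"{_SURVEY_AREA}[{lv}]")
        elif t in covs:
            x = covs[t].to_numpy(dtype=float)
            mats.append(np.repeat(x[:, None], K, axis=1))
            names_p.append(t)
        else:
            raise DesignError(f"unknown p covariate {t!r}")
    X_p = np.stack(mats, axis=2)

    flat = X_psi
    if np.linalg.matrix_rank(flat) < flat.shape[1]:
        raise DesignError("psi design is rank deficient")
    return X_psi, X_p, names_psi, names_p


def occupancy_loglik(
    params: np.ndarray,
    y: np.ndarray,
    X_psi: np.ndarray,
    X_p: np.ndarray,
) -> float:
    """Marginal log-likelihood of the detection histories.

    ``y`` is (n, K) with NaN for zero-effort occasions; their factors are
    skipped. A site with all occasions missing contributes 0. Non-finite
    linear predictors yield -inf, which quasi-Newton optimizers treat as a
    rejected step.
    """
    P = X_psi.shape[1]
    b_psi = params[:P]
    b_p = params[P:]
    eta_psi = X_psi @ b_psi
    eta_p = X_p @ b_p
    if not (np.all(np.isfinite(eta_psi)) and np.all(np.isfinite(eta_p))):
        return -np.inf
    obs = ~np.isnan(y)
    # log p and log(1-p) via stable softplus forms
    log_p = -np.logaddexp(0.0, -eta_p)
    log_q = -np.logaddexp(0.0, eta_p)
    yy = np.where(obs, y, 0.0)
    lp_det = np.where(obs, yy * log_p + (1.0 - yy) * log_q, 0.0).sum(axis=1)
    log_psi = -np.logaddexp(0.0, -eta_psi)
    log_1mpsi = -np.logaddexp(0.0, eta_psi)
    any_det = (yy * obs).sum(axis=1) > 0
    has_obs = obs.any(axis=1)
    ll_det = log_psi + lp_det
    ll = np.where(any_det, ll_det, np.logaddexp(ll_det, log_1mpsi))
    ll = np.where(has_obs, ll, 0.0)
    return float(ll.sum())


def _neg_ll(params, y, X_psi, X_p):
    v = occupancy_loglik(params, y, X_psi, X_p)
    return np.inf if not np.isfinite(v) else -v


def _num_hessian(f, x, eps=1e-4):
    """Central-difference Hessian; adequate for smooth low-dimensional fits."""
    d = len(x)
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_occupancy(
    spec: OccupancyModelSpec,
    occ: OccasionMatrix,
    covs: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> OccupancyFitML:
    """Fit the model by multi-start quasi-Newton (BFGS) maximization.

    Standard errors come from the inverted observed information (numerical
    Hessian at the optimum); ties between starts are broken by log-likelihood.
    """
    y = occ.y
    if not (~np.isnan(y)).any():
        raise DesignError("all observations missing")
    X_psi, X_p, names_psi, names_p = build_designs(spec, occ, covs)
    d = X_psi.shape[1] + X_p.shape[2]
    rng = np.random.default_rng(seed)

    naive = np.clip(naive_occupancy(occ), 0.05, 0.95)
    base = np.zeros(d)
    base[0] = logit(naive)
    starts = [base]
    if start is not None:
        starts.insert(0, np.asarray(start, dtype=float))
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(base + rng.normal(0, 1.0, size=d))

    best = None
    for x0 in starts:
        # gtol sits just above the finite-difference noise floor of the
        # numerical gradient; tighter settings spuriously report failure
        res = minimize(
            _neg_ll, x0, args=(y, X_psi, X_p), method="BFGS",
            options={"gtol": 1e-5, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    H = _num_hessian(lambda p: _neg_ll(p, y, X_psi, X_p), best.x)
    try:
        vcov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    except np.linalg.LinAlgError:
        vcov = np.full((d, d), np.nan)
        se = np.full(d, np.nan)
    P = X_psi.shape[1]
    return OccupancyFitML(
        spec=spec,
        beta_psi=pd.Series(best.x[:P], index=names_psi),
        beta_p=pd.Series(best.x[P:], index=names_p),
        se_psi=pd.Series(se[:P], index=names_psi),
        se_p=pd.Series(se[P:], index=names_p),
        loglik=-best.fun,
        K=d,
        n_sites=occ.n_stations,
        converged=bool(best.success),
        vcov=vcov,
        _designs=(y, X_psi, X_p),
    )


def aicc(loglik: float, K: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    AICc = -2 logLik + 2K + 2K(K+1)/(n-K-1); n is the number of sites.
    """
    if n <= K + 1:
        raise ValueError("AICc undefined: n must exceed K + 1")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def rank_models(fits: list[OccupancyFitML]) -> pd.DataFrame:
    """AICc ranking table: model, AICc, delta, Akaike weight, logLik, K."""
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n_sites for f in fits}
    if len(ns) > 1:
        raise ValueError("fits use different data (site counts differ)")
    rows = [
        {"model": f.spec.label(), "AICc": f.aicc, "logLik": f.loglik, "K": f.K}
        for f in fits
    ]
    tab = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    rel = np.exp(-0.5 * tab["delta_AICc"].to_numpy())
    tab["AICc_wt"] = rel / rel.sum()
    return tab[["model", "AICc", "delta_AICc", "AICc_wt", "logLik", "K"]]


def model_average(
    fits: list[OccupancyFitML], delta_max: float = 2.0
) -> pd.DataFrame:
    """Full-model averaging of psi coefficients over the delta < ``delta_max`` set.

    A term absent from a model contributes a coefficient of 0 (full averaging).
    The unconditional SE follows the standard model-averaging variance
    formula sqrt(sum_m w_m (se_m^2 + (b_m - bbar)^2)).
    """
    if not fits:
        raise ValueError("empty candidate set")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    keep = [f for f, d in zip(fits, delta) if d < delta_max]
    dd = delta[delta < delta_max]
    w = np.exp(-0.5 * dd)
    w = w / w.sum()
    terms: list[str] = []
    for f in keep:
        for t in f.beta_psi.index:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        b = np.array([f.beta_psi.get(t, 0.0) for f in keep])
        s = np.array([f.se_psi.get(t, 0.0) for f in keep])
        bbar = float(w @ b)
        se_u = float(np.sqrt(w @ (s**2 + (b - bbar) ** 2)))
        rows.append({"term": t, "estimate": bbar, "se_unconditional": se_u})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# goodness of fit


def _expected_chi2(fit: OccupancyFitML, y: np.ndarray) -> float:
    """Detection-history chi-square with cohorts by missingness pattern.

    Within each cohort (identical pattern of observed occasions) the expected
    count of every possible history is accumulated site by site from the
    fitted psi_i and p_ik, and compared with observed counts over all cells
    with non-negligible expectation.
    """
    _, X_psi, X_p = fit._designs
    psi = expit(X_psi @ fit.beta_psi.to_numpy())
    p = expit(X_p @ fit.beta_p.to_numpy())
    obs = ~np.isnan(y)
    chi2 = 0.0
    patterns: dict[tuple, list[int]] = {}
    for i in range(y.shape[0]):
        patterns.setdefault(tuple(obs[i]), []).append(i)
    for pat, idx in patterns.items():
        ks = [k for k, o in enumerate(pat) if o]
        if not ks:
            continue
        k = len(ks)
        H = np.array(list(itertools.product((0, 1), repeat=k)), dtype=float)
        idx = np.asarray(idx)
        pi = np.clip(p[np.ix_(idx, ks)], 1e-12, 1 - 1e-12)
        # P(history | present), all sites in cohort at once: (m, 2^k)
        ph = np.exp(np.log(pi) @ H.T + np.log1p(-pi) @ (1.0 - H).T)
        probs = psi[idx, None] * ph
        probs[:, 0] += 1.0 - psi[idx]  # all-zero history is row 0 of H
        E = probs.sum(axis=0)
        powers = 2 ** np.arange(k)[::-1]
        code = (y[np.ix_(idx, ks)].astype(int) @ powers).astype(int)
        O = np.bincount(code, minlength=2**k).astype(float)
        mask = E > 1e-12
        chi2 += float((((O - E) ** 2) / E)[mask].sum())
    return chi2


def mb_gof(
    fit: OccupancyFitML,
    occ: OccasionMatrix,
    covs: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Parametric-bootstrap goodness of fit for an occupancy model.

    Returns (chi2_obs, p_value, c_hat) where the p-value is
    Pr(chi2_boot >= chi2_obs) under data simulated from the fitted model and
    c-hat = chi2_obs / mean(chi2_boot) measures overdispersion.
    """
    y, X_psi, X_p = fit._designs
    if y.shape[0] < 2:
        raise ValueError("goodness of fit degenerate with fewer than 2 sites")
    chi2_obs = _expected_chi2(fit, y)
    psi = expit(X_psi @ fit.beta_psi.to_numpy())
    p = expit(X_p @ fit.beta_p.to_numpy())
    obs = ~np.isnan(y)
    rng = np.random.default_rng(seed)
    boots = []
    failures = 0
    for _ in range(n_boot):
        z = rng.random(y.shape[0]) < psi
        ysim = np.where(
            obs, (rng.random(y.shape) < p) & z[:, None], np.nan
        ).astype(float)
        ysim[~obs] = np.nan
        occ_b = OccasionMatrix(
            stations=occ.stations, y=ysim, effort=occ.effort,
            occasion_length=occ.occasion_length,
        )
        try:
            fb = fit_occupancy(
                fit.spec, occ_b, covs, n_starts=1, seed=0, start=fit.params
            )
            boots.append(_expected_chi2(fb, ysim))
        except Exception:  # noqa: BLE001 - counted as refit failure
            failures += 1
    if failures > 0.1 * n_boot:
        import warnings

        warnings.warn(
            f"{failures}/{n_boot} bootstrap refits failed; GoF unreliable",
            stacklevel=2,
        )
    boots = np.asarray(boots)
    p_value = float(np.mean(boots >= chi2_obs))
    c_hat = float(chi2_obs / boots.mean())
    return chi2_obs, p_value, c_hat


def predict_psi_ml(
    fit: OccupancyFitML, newdata: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Predicted use probability with delta-method CI on the link scale.

    ``newdata`` must already be standardized with the training moments. The
    Wald interval is formed for the linear predictor and mapped through the
    inverse logit, so endpoints always lie inside (0, 1).
    """
    from scipy.stats import norm

    names = list(fit.beta_psi.index)
    X = np.column_stack(
        [np.ones(len(newdata))]
        + [newdata[t].to_numpy(dtype=float) for t in names if t != "(Intercept)"]
    )
    b = fit.beta_psi.to_numpy()
    eta = X @ b
    V = fit.vcov[: len(b), : len(b)]
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
    zq = norm.ppf(0.5 + level / 2)
    return pd.DataFrame(
        {
            "psi": expit(eta),
            "se_link": se_eta,
            "lower": expit(eta - zq * se_eta),
            "upper": expit(eta + zq * se_eta),
        },
        index=newdata.index,
    )
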