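"""Detection histories, occasion collapsing and site-covariate preparation.

Daily camera-trap records are reduced to station x occasion detection and
effort matrices; continuous site covariates are z-standardized and screened
for collinearity before entering occupancy models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, DesignError, SchemaError

#: survey window retained per station (days); longer histories are truncated
#: to limit closure violations.
MAX_DAYS = 120

#: default pooling block (days per sampling occasion).
DEFAULT_OCCASION_LENGTH = 15


@dataclass
class DailyDetections:
    """Binary daily detection and activity matrices for a set of stations.

    ``detected[i, d]`` is 1 if the species was photographed at station ``i``
    on day ``d``; ``active[i, d]`` is 1 if the camera was functioning.
    A detection on an inactive day is a contradiction and rejected upstream.
    """

    stations: list
    detected: np.ndarray
    active: np.ndarray

    def __post_init__(self):
        self.detected = np.asarray(self.detected, dtype=np.int8)
        self.active = np.asarray(self.active, dtype=np.int8)
        if self.detected.shape != self.active.shape:
            raise SchemaError("detected and active must have identical shape")
        if len(self.stations) != self.detected.shape[0]:
            raise SchemaError("station list does not match matrix rows")
        if np.any(self.detected > self.active):
            raise DataIntegrityError("detection recorded on an inactive day")

    @property
    def n_stations(self) -> int:
        return self.detected.shape[0]

    @property
    def n_days(self) -> int:
        return self.detected.shape[1]


@dataclass
class OccasionMatrix:
    """Station x occasion detection (`y`) and effort matrices.

    ``y`` is 1 if any detection fell in the occasion, 0 if none did while the
    camera ran at least one day, and NaN when the occasion had zero active
    days (zero effort carries no information, so the likelihood must skip it).
    ``effort`` counts active days per occasion.
    """

    stations: list
    y: np.ndarray
    effort: np.ndarray
    occasion_length: int

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        bad = np.isnan(self.y) != (self.effort == 0)
        if np.any(bad):
            raise DataIntegrityError("y must be missing exactly where effort is 0")

    @property
    def n_stations(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def detected_any(self) -> np.ndarray:
        """Boolean per station: at least one detection in any occasion."""
        return np.nansum(self.y, axis=1) > 0


@dataclass
class Standardization:
    """Per-column means and standard deviations from a training table.

    Kept so that prediction grids can be scaled with the *training* moments
    and so that coefficients can be mapped back to natural units.
    """

    means: pd.Series
    sds: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.means.index:
            if c in out:
                out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.means.index:
            if c in out:
                out[c] = out[c] * self.sds[c] + self.means[c]
        return out


def build_daily_matrix(
    records: pd.DataFrame,
    stations: pd.DataFrame,
    max_days: int = MAX_DAYS,
) -> DailyDetections:
    """Pivot long-format daily records into station x day matrices.

    ``records`` columns: station_id, day_index (0-based), detected, active.
    Days at index >= ``max_days`` are dropped. Records must not claim a
    detection on an inactive day, and every station_id must exist in the
    station table. Stations with no records get all-inactive rows.
    """
    required = {"station_id", "day_index", "detected", "active"}
    missing = required - set(records.columns)
    if missing:
        raise SchemaError(f"daily records missing columns: {sorted(missing)}")
    ids = list(stations["station_id"])
    index = {s: i for i, s in enumerate(ids)}
    unknown = set(records["station_id"]) - set(ids)
    if unknown:
        raise KeyError(f"records reference unknown stations: {sorted(unknown)[:5]}")
    day = records["day_index"].to_numpy()
    if np.any(day < 0):
        raise SchemaError("negative day_index")
    keep = day < max_days
    rec = records.loc[keep]
    n_days = max_days if len(records) else max_days
    det = np.zeros((len(ids), n_days), dtype=np.int8)
    act = np.zeros_like(det)
    rows = rec["station_id"].map(index).to_numpy(dtype=int)
    cols = rec["day_index"].to_numpy(dtype=int)
    dv = rec["detected"].to_numpy()
    av = rec["active"].to_numpy()
    if not np.isin(dv, (0, 1)).all() or not np.isin(av, (0, 1)).all():
        bad = np.flatnonzero(~np.isin(dv, (0, 1)) | ~np.isin(av, (0, 1)))[0]
        raise SchemaError(f"non-binary detected/active value at record row {bad}")
    if np.any(dv > av):
        bad = np.flatnonzero(dv > av)[0]
        raise DataIntegrityError(f"detection on inactive day at record row {bad}")
    det[rows, cols] = dv
    act[rows, cols] = av
    return DailyDetections(stations=ids, detected=det, active=act)


def collapse_occasions(
    daily: DailyDetections, occasion_length: int = DEFAULT_OCCASION_LENGTH
) -> OccasionMatrix:
    """Pool consecutive days into sampling occasions.

    An occasion records a detection if any active day within it did; effort is
    the number of active days. Zero-effort occasions are missing (NaN).
    """
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1")
    n, D = daily.detected.shape
    K = int(np.ceil(D / occasion_length))
    y = np.full((n, K), np.nan)
    eff = np.zeros((n, K))
    for k in range(K):
        sl = slice(k * occasion_length, min((k + 1) * occasion_length, D))
        eff[:, k] = daily.active[:, sl].sum(axis=1)
        hit = daily.detected[:, sl].max(axis=1, initial=0)
        y[:, k] = np.where(eff[:, k] > 0, hit, np.nan)
    return OccasionMatrix(
        stations=daily.stations, y=y, effort=eff, occasion_length=occasion_length
    )


def naive_occupancy(occ: OccasionMatrix) -> float:
    """Raw fraction of stations with at least one detection.

    A lower bound on use probability, biased downward by imperfect detection.
    """
    if occ.n_stations == 0:
        raise ValueError("no stations")
    return float(occ.detected_any().sum()) / occ.n_stations


def zscore(
    table: pd.DataFrame, columns: list | None = None
) -> tuple[pd.DataFrame, Standardization]:
    """z-standardize continuous covariates to mean 0, sd 1 (sample sd, n-1).

    Returns the transformed table and the standardization record used to
    scale prediction grids with the training moments.
    """
    if columns is None:
        columns = [
            c for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c])
        ]
    means, sds = {}, {}
    out = table.copy()
    for c in columns:
        x = table[c].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise SchemaError(f"covariate {c!r} has missing values")
        m, s = x.mean(), x.std(ddof=1)
        if s == 0:
            raise DesignError(f"covariate {c!r} is constant; cannot standardize")
        out[c] = (x - m) / s
        means[c], sds[c] = m, s
    return out, Standardization(means=pd.Series(means), sds=pd.Series(sds))


@dataclass
class ScreenResult:
    """Outcome of the pairwise collinearity screen."""

    retained: list
    dropped: list
    report: pd.DataFrame = field(repr=False)


def correlation_screen(
    table: pd.DataFrame,
    occ: OccasionMatrix,
    columns: list | None = None,
    threshold: float = 0.6,
) -> ScreenResult:
    """Drop one member of every covariate pair with \\|r\\| >= threshold.

    Pairs are resolved in descending \\|r\\| order; within a pair the member with
    the lower AICc in a univariate psi(covariate) p(.) occupancy model is
    retained. Already-dropped covariates do not trigger further removals.
    """
    from .occupancy_ml import OccupancyModelSpec, aicc, fit_occupancy

    if columns is None:
        columns = [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        ]
    corr = table[columns].corr().to_numpy()
    pairs = []
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            r = corr[i, j]
            if abs(r) >= threshold:
                pairs.append((abs(r), r, columns[i], columns[j]))
    pairs.sort(reverse=True)

    uni_aicc: dict[str, float] = {}

    def _uni(c: str) -> float:
        if c not in uni_aicc:
            fit = fit_occupancy(
                OccupancyModelSpec(psi_terms=[c], p_terms=[]),
                occ, table, n_starts=3, seed=0,
            )
            uni_aicc[c] = aicc(fit.loglik, fit.K, fit.n_sites)
        return uni_aicc[c]

    dropped: set[str] = set()
    rows = []
    for absr, r, a, b in pairs:
        if a in dropped or b in dropped:
            rows.append((a, b, r, "pair already resolved", None, None))
            continue
        aa, ab = _uni(a), _uni(b)
        loser = b if aa <= ab else a
        dropped.add(loser)
        rows.append((a, b, r, f"dropped {loser}", aa, ab))
    report = pd.DataFrame(
        rows, columns=["cov_a", "cov_b", "r", "decision", "aicc_a", "aicc_b"]
    )
    retained = [c for c in columns if c not in dropped]
    return ScreenResult(retained=retained, dropped=sorted(dropped), report=report)


def select_occasion_length(
    daily: DailyDetections,
    covs: pd.DataFrame,
    psi_terms: list,
    p_terms: list,
    candidate_lengths: list[int] = (1, 5, 10, 15),
    n_boot: int = 100,
    gof_p_min: float = 0.05,
    c_hat_max: float = 1.5,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the pooling block length by goodness of fit of the global model.

    The global (most parameterized) model is fitted at each candidate length
    and checked with the parametric-bootstrap chi-square test. A length is
    adequate when the bootstrap p-value exceeds ``gof_p_min`` and the
    overdispersion ratio c-hat is at most ``c_hat_max``; the smallest adequate
    length wins. If none is adequate the length with the smallest c-hat is
    returned, flagged in the report.
    """
    from .occupancy_ml import OccupancyModelSpec, fit_occupancy, mb_gof

    lengths = sorted(set(int(c) for c in candidate_lengths))
    if len(lengths) == 1:
        report = pd.DataFrame(
            [{"length": lengths[0], "chi2": np.nan, "p": np.nan,
              "c_hat": np.nan, "adequate": True, "note": "single candidate"}]
        )
        return lengths[0], report

    rows = []
    for L in lengths:
        occ = collapse_occasions(daily, L)
        try:
            fit = fit_occupancy(
                OccupancyModelSpec(psi_terms=list(psi_terms), p_terms=list(p_terms)),
                occ, covs, n_starts=3, seed=seed,
            )
            chi2, p, c_hat = mb_gof(fit, occ, covs, n_boot=n_boot, seed=seed + L)
            ok = bool(fit.converged and p > gof_p_min and c_hat <= c_hat_max)
            rows.append({"length": L, "chi2": chi2, "p": p, "c_hat": c_hat,
                         "adequate": ok, "note": ""})
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            rows.append({"length": L, "chi2": np.nan, "p": np.nan,
                         "c_hat": np.nan, "adequate": False,
                         "note": f"fit failed: {exc}"})
    report = pd.DataFrame(rows)
    ok = report[report["adequate"]]
    if len(ok):
        return int(ok["length"].iloc[0]), report
    best = report.loc[report["c_hat"].idxmin(), "length"]
    return int(best), report
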