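"""Stratified Poisson regression of second-cancer rates on adjuvant treatments.

The model is log-linear in the exposures with a log person-time offset and one
free intercept per stratum.  Strata are absorbed by profiling: for fixed
exposure coefficients beta the stratum intercepts have a closed form, and the
profile likelihood is the conditional (multinomial) likelihood

    ll(beta) = sum_cells d_i * log(mu_i * O_s / M_s),  M_s = sum_{i in s} mu_i,
    mu_i = py_i * exp(x_i' beta),

which a Newton iteration maximises directly; this agrees exactly with a
one-dummy-per-stratum GLM but stays stable with thousands of strata.

Exposure coding follows the recording conventions: women treated with
breast-conserving surgery count as radiotherapy-recorded and women with
ER-positive disease count as endocrine-recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import WomanRecord
from .errors import ConfigurationError, DataError
from .persontime import AnalysisSpec, at_risk_interval
from .rates import band_start

TREATMENT_EXPOSURES = ("radiotherapy", "endocrine", "chemotherapy")
ADJUSTMENT_EXTRAS = ("mastectomy",)

#: (exposure, cancer-type) pairs where the flag fires on a *protective* rate ratio
PROTECTIVE_PAIRS = frozenset({("endocrine", "contralateral_breast"),
                              ("endocrine", "breast")})


def exposure_coding(w: WomanRecord) -> dict[str, int]:
    """Recorded-exposure indicators used throughout the regression module."""
    return {
        "radiotherapy": int(w.radiotherapy or w.surgery == "bcs"),
        "endocrine": int(w.endocrine or w.covariates.get("er_status") == "positive"),
        "chemotherapy": int(w.chemotherapy),
        "mastectomy": int(w.surgery == "mastectomy"),
    }


def build_regression_table(cohort: list[WomanRecord], spec: AnalysisSpec,
                           age_band_width: int = 5, fu_band_width: int = 5,
                           diag_year_width: int = 5) -> pd.DataFrame:
    """Event / person-time records per stratum x exposure-pattern cell.

    Strata: age at index diagnosis (5-year bands), calendar year of diagnosis
    (grouped), time since diagnosis (5-year follow-up intervals), deprivation
    fifth.  Cells with zero person-time are dropped.
    """
    rows = []
    for w in cohort:
        interval = at_risk_interval(w, spec)
        if interval is None:
            continue
        expo = exposure_coding(w)
        age_band = band_start(w.age_dx, age_band_width)
        year_band = (w.diag_year // diag_year_width) * diag_year_width
        # events belong to the follow-up band containing their time (half-open
        # bands, so an event exactly on a boundary goes to the later band)
        events_by_band: dict[int, int] = {}
        for ev in interval.target_events:
            b = int((ev + 1e-9) // fu_band_width) * fu_band_width
            events_by_band[b] = events_by_band.get(b, 0) + 1
        t = interval.entry
        while t < interval.exit - 1e-12:
            fu_band = int(t // fu_band_width) * fu_band_width
            seg_end = min(interval.exit, float(fu_band + fu_band_width))
            rows.append((age_band, year_band, fu_band, w.imd,
                         expo["radiotherapy"], expo["endocrine"],
                         expo["chemotherapy"], expo["mastectomy"],
                         events_by_band.pop(fu_band, 0), seg_end - t))
            t = seg_end
        for b, d in events_by_band.items():   # boundary event past the last segment
            rows.append((age_band, year_band, b, w.imd,
                         expo["radiotherapy"], expo["endocrine"],
                         expo["chemotherapy"], expo["mastectomy"], d, 0.0))
    if not rows:
        raise DataError("no person-time available for regression")
    df = pd.DataFrame(rows, columns=["age_band", "diag_year_band", "fu_band",
                                     "imd_fifth", "radiotherapy", "endocrine",
                                     "chemotherapy", "mastectomy", "events", "py"])
    grouped = (df.groupby(["age_band", "diag_year_band", "fu_band", "imd_fifth",
                           "radiotherapy", "endocrine", "chemotherapy", "mastectomy"],
                          as_index=False)
                 .agg(events=("events", "sum"), py=("py", "sum")))
    keep = (grouped["py"] > 0) | (grouped["events"] > 0)
    return grouped[keep].reset_index(drop=True)


def split_by_period(table: pd.DataFrame, boundary: float = 10.0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a regression table at ``boundary`` years of follow-up
    (half-open: a cell starting exactly at the boundary goes to the late table)."""
    if "fu_band" not in table.columns:
        raise ConfigurationError("regression table lacks the fu_band column")
    early = table[table["fu_band"] < boundary].reset_index(drop=True)
    late = table[table["fu_band"] >= boundary].reset_index(drop=True)
    return early, late


STRATA_COLUMNS = ("age_band", "diag_year_band", "fu_band", "imd_fifth")


@dataclass(frozen=True)
class RateRatioEstimate:
    cancer_type: str
    exposure: str
    adjusted: bool
    period: str                      # "all" | "0-9" | ">=10"
    rr: float
    lo: float
    hi: float
    p: float
    level: float
    flagged: bool = False
    degenerate: bool = False


class _ConditionalPoisson:
    """Newton maximiser of the stratum-profiled Poisson likelihood."""

    def __init__(self, X: np.ndarray, d: np.ndarray, py: np.ndarray,
                 strata: np.ndarray):
        self.X = X
        self.d = d.astype(float)
        self.py = py.astype(float)
        self.strata = strata
        self.n_strata = int(strata.max()) + 1 if len(strata) else 0
        self.O_s = np.bincount(strata, weights=self.d, minlength=self.n_strata)

    def _fitted(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta if self.X.shape[1] else np.zeros(len(self.d))
        eta = np.clip(eta, -500, 500)
        mu = self.py * np.exp(eta)
        M_s = np.bincount(self.strata, weights=mu, minlength=self.n_strata)
        safe = np.where(M_s > 0, M_s, 1.0)
        return mu * (self.O_s / safe)[self.strata]

    def loglik(self, beta: np.ndarray) -> float:
        f = self._fitted(beta)
        mask = self.d > 0
        if np.any(f[mask] <= 0):
            return -np.inf
        return float(self.d[mask] @ np.log(f[mask]))

    def fit(self, max_iter: int = 50, tol: float = 1e-10
            ) -> tuple[np.ndarray, np.ndarray, bool]:
        k = self.X.shape[1]
        beta = np.zeros(k)
        if k == 0:
            return beta, np.zeros((0, 0)), True
        converged = False
        H = np.eye(k)
        for _ in range(max_iter):
            f = self._fitted(beta)
            grad = self.X.T @ (self.d - f)
            T = np.zeros((self.n_strata, k))
            np.add.at(T, self.strata, f[:, None] * self.X)
            A = self.X.T @ (f[:, None] * self.X)
            active = self.O_s > 0
            H = A - (T[active].T / self.O_s[active]) @ T[active]
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(k), grad)
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -5, 5)
            beta = beta + step
            if np.abs(grad).max() < tol and np.abs(step).max() < 1e-8:
                converged = True
                break
        if np.abs(beta).max() > 15:
            converged = False
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        return beta, cov, converged


def _design(table: pd.DataFrame, exposures: list[str]) -> tuple[np.ndarray, ...]:
    for col in exposures:
        if col not in table.columns:
            raise ConfigurationError(f"unknown exposure column {col!r}")
    strata_key = pd.MultiIndex.from_frame(table[list(STRATA_COLUMNS)])
    strata = pd.factorize(strata_key)[0]
    X = table[exposures].to_numpy(dtype=float)
    return X, table["events"].to_numpy(), table["py"].to_numpy(), strata


def fit_rate_ratios(table: pd.DataFrame, exposures=TREATMENT_EXPOSURES,
                    adjust: bool = True, level: float = 0.99,
                    cancer_type: str = "", period: str = "all"
                    ) -> list[RateRatioEstimate]:
    """Rate ratios for each exposure: adjusted fits include all exposures plus
    surgery type in one model; unadjusted fits refit one exposure at a time.
    P values are likelihood-ratio; intervals are Wald at ``level``.  Complete
    separation yields a flagged degenerate estimate with an infinite bound."""
    exposures = list(exposures)
    estimates = []
    if adjust:
        model_cols = exposures + [c for c in ADJUSTMENT_EXTRAS
                                  if c in table.columns and c not in exposures
                                  and table[c].nunique() > 1]
        X, d, py, strata = _design(table, model_cols)
        full = _ConditionalPoisson(X, d, py, strata)
        beta, cov, ok = full.fit()
        ll_full = full.loglik(beta)
        for j, expo in enumerate(exposures):
            reduced_cols = [c for c in model_cols if c != expo]
            Xr = table[reduced_cols].to_numpy(dtype=float)
            red = _ConditionalPoisson(Xr, d, py, strata)
            beta_r, _, _ = red.fit()
            lr = max(2.0 * (ll_full - red.loglik(beta_r)), 0.0)
            estimates.append(_estimate(cancer_type, expo, True, period, beta[j],
                                       cov[j, j] if cov.size else np.nan, lr,
                                       level, ok, d, X[:, j]))
    else:
        for expo in exposures:
            X, d, py, strata = _design(table, [expo])
            model = _ConditionalPoisson(X, d, py, strata)
            beta, cov, ok = model.fit()
            null = _ConditionalPoisson(np.zeros((len(d), 0)), d, py, strata)
            lr = max(2.0 * (model.loglik(beta) - null.loglik(np.zeros(0))), 0.0)
            estimates.append(_estimate(cancer_type, expo, False, period, beta[0],
                                       cov[0, 0] if cov.size else np.nan, lr,
                                       level, ok, d, X[:, 0]))
    return estimates


def _estimate(cancer_type, exposure, adjusted, period, b, var, lr, level,
              converged, d, x) -> RateRatioEstimate:
    events_exposed = float(d @ (x > 0.5))
    events_unexposed = float(d.sum() - events_exposed)
    degenerate = (not converged) or not np.isfinite(var) or var <= 0 \
        or events_exposed == 0 or events_unexposed == 0
    if degenerate:
        rr = math.exp(min(max(b, -15), 15))
        lo, hi = (0.0, math.inf)
        p = 1.0 if lr <= 0 else float(stats.chi2.sf(lr, 1))
    else:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = math.sqrt(var)
        rr = math.exp(b)
        lo, hi = math.exp(b - z * se), math.exp(b + z * se)
        p = float(stats.chi2.sf(lr, 1))
    est = RateRatioEstimate(cancer_type=cancer_type, exposure=exposure,
                            adjusted=adjusted, period=period, rr=rr, lo=lo,
                            hi=hi, p=p, level=level, degenerate=degenerate)
    return RateRatioEstimate(**{**est.__dict__, "flagged": decision_rule(est)})


def decision_rule(est: RateRatioEstimate) -> bool:
    """Flag rate ratios > 1 with P < 0.01 — protective direction (< 1) for
    endocrine therapy against contralateral breast cancer."""
    if not (est.p < 0.01):
        return False
    if (est.exposure, est.cancer_type) in PROTECTIVE_PAIRS:
        return est.rr < 1.0
    return est.rr > 1.0


def estimates_frame(estimates: list[RateRatioEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])
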