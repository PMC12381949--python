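"""Two-step cumulative-risk estimator under competing risks, with an "expected"
counterpart built from reference rates.

Follow-up since entry (diagnosis + 3 months) is cut into annual windows
w = 1..W.  The observed curve is

    p_k(w) = d_k(w) / n*(w),   S(1) = 1,
    S(w+1) = S(w) * (1 - (d_k(w) + c(w)) / n*(w)),
    R_obs(t) = sum_{w<=t} S(w) * p_k(w)

where d_k counts target events, c counts competing events (any other second
cancer or death), and n*(w) is the number at risk at the window start with an
optional actuarial half-unit correction for within-window censoring
(administrative or 85th-birthday exits).

The expected curve replaces only the target-cause hazard with its reference
value: e_hat(w) is the person-time-weighted mean reference rate over women at
risk in window w (breast rates halved for contralateral analyses), converted to
a window probability 1 - exp(-e_hat); the survival recursion keeps the
cohort's observed competing hazard.  This keeps the expected curve consistent
with the standardised incidence ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import WomanRecord
from .errors import ConfigurationError, DataError
from .persontime import (AnalysisSpec, at_risk_interval, lexis_split,
                         EXIT_EVENT, EXIT_COMPETING, EXIT_DEATH)
from .rates import ReferenceRateTable

KIND_TARGET, KIND_COMPETING, KIND_CENSORED = 0, 1, 2


@dataclass
class PersonWindowData:
    """Per-woman window summaries for a cohort under one analysis spec.

    exit_window : 1-based window containing each woman's exit
    exit_kind   : KIND_TARGET / KIND_COMPETING / KIND_CENSORED
    person_time : (n, W) time at risk within each window
    rate_time   : (n, W) integral of the reference target-cause rate over that time
    """
    exit_window: np.ndarray
    exit_kind: np.ndarray
    person_time: np.ndarray
    rate_time: np.ndarray

    @property
    def n_women(self) -> int:
        return len(self.exit_window)

    @property
    def n_windows(self) -> int:
        return self.person_time.shape[1]


def build_person_windows(cohort: list[WomanRecord], spec: AnalysisSpec,
                         table: ReferenceRateTable, n_windows: int | None = None,
                         band_width: int = 5) -> PersonWindowData:
    """Reduce each woman to her window-level exposure and exit summary.

    Women whose at-risk interval is empty are dropped (they contribute to no
    window).  Uses first-event selection: the cumulative-risk estimand is the
    probability of the target cancer as the *first* subsequent event.
    """
    if spec.mode != "first-event":
        raise ConfigurationError("cumulative risk requires first-event selection")
    rows = []
    max_w = 0
    for w in cohort:
        interval = at_risk_interval(w, spec)
        if interval is None:
            continue
        duration = interval.exit - interval.entry
        exit_window = int(math.floor(duration + 1e-12)) + 1
        if interval.reason == EXIT_EVENT:
            kind = KIND_TARGET
        elif interval.reason in (EXIT_COMPETING, EXIT_DEATH):
            kind = KIND_COMPETING
        else:
            kind = KIND_CENSORED
        segs = lexis_split(interval, w, band_width, table, spec)
        rows.append((exit_window, kind, interval.entry, segs))
        max_w = max(max_w, exit_window)
    if not rows:
        raise DataError("no women contribute person-time to the cumulative-risk grid")
    W = n_windows if n_windows is not None else max_w
    n = len(rows)
    ew = np.zeros(n, dtype=np.int64)
    ek = np.zeros(n, dtype=np.int64)
    pt = np.zeros((n, W))
    rt = np.zeros((n, W))
    for i, (exit_window, kind, entry, segs) in enumerate(rows):
        ew[i] = min(exit_window, W + 1) if exit_window > W else exit_window
        ek[i] = kind if exit_window <= W else KIND_CENSORED
        t = 0.0  # time since entry
        for _key, length, rate in segs:
            a, b = t, t + length
            w0 = int(math.floor(a + 1e-12))
            while a < b - 1e-12 and w0 < W:
                upper = min(b, float(w0 + 1))
                dt = upper - a
                pt[i, w0] += dt
                rt[i, w0] += dt * rate
                a = upper
                w0 += 1
            t += length
    return PersonWindowData(exit_window=ew, exit_kind=ek, person_time=pt, rate_time=rt)


@dataclass
class WindowTallies:
    """Aggregated window counts for the two-step estimators."""
    n: np.ndarray          # at risk at window start
    d_target: np.ndarray
    d_competing: np.ndarray
    censored: np.ndarray
    person_time: np.ndarray
    rate_time: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.n)

    def validate(self) -> None:
        W = self.n_windows
        for w in range(W - 1):
            expected_next = self.n[w] - self.d_target[w] - self.d_competing[w] \
                - self.censored[w]
            if abs(self.n[w + 1] - expected_next) > 1e-9:
                raise DataError(f"inconsistent window tallies at window {w + 1}")
        for w in range(W):
            if self.n[w] == 0 and (self.d_target[w:].sum() or self.d_competing[w:].sum()):
                raise DataError(f"events after window {w + 1} but nobody at risk")


def window_tallies(data: PersonWindowData, weights: np.ndarray | None = None
                   ) -> WindowTallies:
    """Aggregate per-woman summaries into window counts.  ``weights`` supports
    bootstrap resampling (how many times each woman is included)."""
    W = data.n_windows
    wts = np.ones(data.n_women) if weights is None else np.asarray(weights, dtype=float)
    n = np.zeros(W)
    d_t = np.zeros(W)
    d_c = np.zeros(W)
    cen = np.zeros(W)
    ew = data.exit_window
    in_range = ew <= W
    for kind, arr in ((KIND_TARGET, d_t), (KIND_COMPETING, d_c), (KIND_CENSORED, cen)):
        mask = in_range & (data.exit_kind == kind)
        np.add.at(arr, ew[mask] - 1, wts[mask])
    # n(w) = weighted count of women with exit_window >= w
    exits_per_window = np.zeros(W + 1)
    np.add.at(exits_per_window, np.minimum(ew, W + 1) - 1, wts)
    total = wts.sum()
    n[0] = total
    for w in range(1, W):
        n[w] = n[w - 1] - exits_per_window[w - 1]
    pt = wts @ data.person_time
    rt = wts @ data.rate_time
    return WindowTallies(n=n, d_target=d_t, d_competing=d_c, censored=cen,
                         person_time=pt, rate_time=rt)


@dataclass
class CIFCurve:
    """Observed, expected and excess cumulative risk on the annual grid."""
    windows: np.ndarray        # 1..W
    n: np.ndarray
    d_target: np.ndarray
    d_competing: np.ndarray
    censored: np.ndarray
    surv: np.ndarray           # S(w), event-free survival to window start
    p_target: np.ndarray
    e_hat: np.ndarray          # expected window probability of the target cause
    r_obs: np.ndarray          # cumulative, value at end of window w
    r_exp: np.ndarray
    excess: np.ndarray
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None

    def at(self, t: int, curve: str = "excess") -> float:
        if not (1 <= t <= len(self.windows)):
            raise ConfigurationError(f"time {t} outside the {len(self.windows)}-window grid")
        return float(getattr(self, {"obs": "r_obs", "exp": "r_exp",
                                    "excess": "excess"}[curve])[t - 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "window": self.windows, "n": self.n, "d_target": self.d_target,
            "d_competing": self.d_competing, "censored": self.censored,
            "S": self.surv, "p_target": self.p_target, "e_hat": self.e_hat,
            "R_obs": self.r_obs, "R_exp": self.r_exp, "excess": self.excess})
        if self.band_lo is not None:
            df["band_lo"] = self.band_lo
            df["band_hi"] = self.band_hi
        return df


def _effective_n(t: WindowTallies, actuarial: bool) -> np.ndarray:
    return t.n - 0.5 * t.censored if actuarial else t.n.copy()


def observed_cif(tallies: WindowTallies, actuarial: bool = True) -> CIFCurve:
    """Two-step observed cumulative risk (competing risks respected)."""
    tallies.validate()
    W = tallies.n_windows
    n_eff = _effective_n(tallies, actuarial)
    p = np.zeros(W)
    q = np.zeros(W)
    surv = np.ones(W)
    r = np.zeros(W)
    acc = 0.0
    s = 1.0
    for w in range(W):
        if n_eff[w] <= 0:
            if tallies.d_target[w] or tallies.d_competing[w]:
                raise DataError(f"window {w + 1}: events but no one at risk")
            surv[w] = s
            r[w] = acc
            continue
        p[w] = tallies.d_target[w] / n_eff[w]
        q[w] = (tallies.d_target[w] + tallies.d_competing[w]) / n_eff[w]
        surv[w] = s
        acc += s * p[w]
        r[w] = acc
        s *= max(1.0 - q[w], 0.0)
    return CIFCurve(windows=np.arange(1, W + 1), n=tallies.n,
                    d_target=tallies.d_target, d_competing=tallies.d_competing,
                    censored=tallies.censored, surv=surv, p_target=p,
                    e_hat=np.zeros(W), r_obs=r, r_exp=np.zeros(W), excess=r.copy())


def expected_cif(tallies: WindowTallies, actuarial: bool = True,
                 observed_survival: bool = False) -> np.ndarray:
    """Expected cumulative risk from reference rates under the cohort's
    competing risks.  Returns R_exp on the window grid.

    By default the survival recursion combines the expected target-cause window
    probability with the cohort's observed competing-event probability; with
    ``observed_survival`` the fully observed S(w) is used instead (sensitivity).
    """
    W = tallies.n_windows
    n_eff = _effective_n(tallies, actuarial)
    r_exp = np.zeros(W)
    acc = 0.0
    s = 1.0
    for w in range(W):
        if tallies.person_time[w] > 0:
            mean_rate = tallies.rate_time[w] / tallies.person_time[w]
        else:
            mean_rate = 0.0
        e_hat = 1.0 - math.exp(-mean_rate)
        if n_eff[w] > 0:
            q_comp = tallies.d_competing[w] / n_eff[w]
            q_obs = (tallies.d_target[w] + tallies.d_competing[w]) / n_eff[w]
        else:
            q_comp = q_obs = 0.0
        acc += s * e_hat
        r_exp[w] = acc
        if observed_survival:
            s *= max(1.0 - q_obs, 0.0)
        else:
            s *= max(1.0 - e_hat - q_comp, 0.0)
    return r_exp


def cif_analysis(cohort: list[WomanRecord], spec: AnalysisSpec,
                 table: ReferenceRateTable, n_windows: int | None = None,
                 band_width: int = 5, actuarial: bool = True,
                 bootstrap: int = 0, level: float = 0.95,
                 seed: int = 0) -> CIFCurve:
    """Full observed/expected/excess curve with optional bootstrap bands.

    Bands are pointwise percentile intervals over woman-level bootstrap
    resamples of the excess curve (reference rates treated as fixed).
    """
    data = build_person_windows(cohort, spec, table, n_windows, band_width)
    tallies = window_tallies(data)
    curve = observed_cif(tallies, actuarial)
    r_exp = expected_cif(tallies, actuarial)
    W = tallies.n_windows
    e_hat = np.zeros(W)
    nonzero = tallies.person_time > 0
    e_hat[nonzero] = 1.0 - np.exp(-tallies.rate_time[nonzero] / tallies.person_time[nonzero])
    curve.e_hat = e_hat
    curve.r_exp = r_exp
    curve.excess = curve.r_obs - r_exp
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = data.n_women
        reps = np.empty((bootstrap, W))
        for b in range(bootstrap):
            counts = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(float)
            t_b = window_tallies(data, weights=counts)
            try:
                obs_b = observed_cif(t_b, actuarial).r_obs
            except DataError:
                obs_b = observed_cif(window_tallies(data), actuarial).r_obs
            reps[b] = obs_b - expected_cif(t_b, actuarial)
        alpha = 1.0 - level
        curve.band_lo = np.quantile(reps, alpha / 2.0, axis=0)
        curve.band_hi = np.quantile(reps, 1.0 - alpha / 2.0, axis=0)
    return curve


def excess_risk(curve: CIFCurve, t: int) -> tuple[float, float | None, float | None]:
    """Excess cumulative risk at ``t`` whole years since entry, with its band."""
    if not (1 <= t <= len(curve.windows)):
        raise ConfigurationError(f"time {t} beyond the {len(curve.windows)}-window grid")
    lo = float(curve.band_lo[t - 1]) if curve.band_lo is not None else None
    hi = float(curve.band_hi[t - 1]) if curve.band_hi is not None else None
    return float(curve.excess[t - 1]), lo, hi
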