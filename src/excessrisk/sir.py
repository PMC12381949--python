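"""Standardised incidence ratios and absolute excess rates with exact intervals.

Observed counts are treated as Poisson and expected counts as fixed.  Intervals
for the Poisson mean are exact (Garwood) via chi-square quantiles:

    lower = qchisq(alpha/2, 2*O) / 2,   upper = qchisq(1 - alpha/2, 2*(O+1)) / 2

with lower bound 0 when O = 0.  SIR intervals divide these by E; AER intervals
transform the same O-interval holding E and the woman-years fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ConfigurationError

CI_METHOD = "exact-poisson-garwood"


def poisson_mean_ci(o: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided confidence interval for a Poisson mean given count ``o``."""
    if o < 0 or o != int(o):
        raise ConfigurationError(f"observed count must be a non-negative integer, got {o}")
    alpha = 1.0 - level
    lo = 0.0 if o == 0 else stats.chi2.ppf(alpha / 2.0, 2 * o) / 2.0
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * (o + 1)) / 2.0
    return float(lo), float(hi)


@dataclass(frozen=True)
class SIRResult:
    cancer_type: str
    O: int
    E: float
    PY: float
    sir: float
    sir_lo: float
    sir_hi: float
    aer: float
    aer_lo: float
    aer_hi: float
    level: float
    scale: float = 10_000.0
    ci_method: str = CI_METHOD


def sir_with_ci(o: int, e: float, level: float = 0.95) -> tuple[float, float, float]:
    """(SIR, lower, upper) = O/E with the exact Poisson interval divided by E."""
    if not (e > 0):
        raise ConfigurationError(f"expected count must be > 0, got {e}")
    lo, hi = poisson_mean_ci(o, level)
    return o / e, lo / e, hi / e


def aer_with_ci(o: int, e: float, py: float, scale: float = 10_000.0,
                level: float = 0.95) -> tuple[float, float, float]:
    """(AER, lower, upper): (O-E)/PY scaled, interval from the exact O-interval
    with E and PY held fixed."""
    if not (py > 0):
        raise ConfigurationError(f"woman-years must be > 0, got {py}")
    lo, hi = poisson_mean_ci(o, level)
    return ((o - e) / py * scale, (lo - e) / py * scale, (hi - e) / py * scale)


def sir_aer(cancer_type: str, o: int, e: float, py: float,
            level: float = 0.95, scale: float = 10_000.0) -> SIRResult:
    s, s_lo, s_hi = sir_with_ci(o, e, level)
    a, a_lo, a_hi = aer_with_ci(o, e, py, scale, level)
    return SIRResult(cancer_type=cancer_type, O=o, E=e, PY=py,
                     sir=s, sir_lo=s_lo, sir_hi=s_hi,
                     aer=a, aer_lo=a_lo, aer_hi=a_hi, level=level, scale=scale)


def excess_share(aer_a: float, aer_b: float) -> float:
    """Share of the combined absolute excess contributed by the first component."""
    denom = aer_a + aer_b
    if denom == 0:
        raise ConfigurationError("excess shares undefined: combined excess rate is zero")
    return aer_a / denom
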