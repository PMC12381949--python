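"""Reference ("national") incidence-rate tables on an attained-age x calendar-year
x deprivation grid, and a deterministic generator for synthetic tables.

Rates are annual: events per woman-year.  The grid holds one incidence rate per
cancer-type group per cell, plus an all-cause mortality rate used only when
simulating cohorts.  Deprivation fifth 0 denotes "unknown" and, when present,
carries the across-fifth mean rate so that women with unknown deprivation keep
their own stratum rather than being dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

AGE_MIN = 20
AGE_MAX = 85  # exclusive upper support: bands cover [20, 85)


def band_start(age: float, width: int = 5) -> int:
    """Start of the attained-age band containing ``age`` (half-open bands)."""
    return AGE_MIN + width * int((age - AGE_MIN) // width)


class ReferenceRateTable:
    """Dense rate grid keyed by (age-band start, calendar year, deprivation fifth).

    Parameters
    ----------
    band_starts : sorted band start ages, 5-year bins spanning 20-84 by default.
    years : sorted calendar years covered.
    fifths : deprivation levels (1..5, optionally 0 = unknown).
    cancer_types : cancer-type group names, disjoint by construction.
    incidence : array (n_bands, n_years, n_fifths, n_types) of rates/woman-year.
    mortality : array (n_bands, n_years, n_fifths) of all-cause death rates.
    """

    def __init__(self, band_starts, years, fifths, cancer_types,
                 incidence, mortality, band_width: int = 5):
        self.band_starts = [int(b) for b in band_starts]
        self.years = [int(y) for y in years]
        self.fifths = [int(f) for f in fifths]
        self.cancer_types = list(cancer_types)
        self.band_width = int(band_width)
        self.incidence = np.asarray(incidence, dtype=float)
        self.mortality = np.asarray(mortality, dtype=float)
        self._band_index = {b: i for i, b in enumerate(self.band_starts)}
        self._year_index = {y: i for i, y in enumerate(self.years)}
        self._fifth_index = {f: i for i, f in enumerate(self.fifths)}
        self._type_index = {t: i for i, t in enumerate(self.cancer_types)}
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        shape = (len(self.band_starts), len(self.years), len(self.fifths))
        if self.incidence.shape != shape + (len(self.cancer_types),):
            raise ConfigurationError(
                f"incidence array shape {self.incidence.shape} does not match grid "
                f"{shape + (len(self.cancer_types),)}")
        if self.mortality.shape != shape:
            raise ConfigurationError(
                f"mortality array shape {self.mortality.shape} does not match grid {shape}")
        if not np.all(np.isfinite(self.incidence)) or np.any(self.incidence < 0):
            raise ConfigurationError("all incidence rates must be finite and >= 0")
        if not np.all(np.isfinite(self.mortality)) or np.any(self.mortality < 0):
            raise ConfigurationError("all mortality rates must be finite and >= 0")
        if len(set(self.cancer_types)) != len(self.cancer_types):
            raise ConfigurationError("cancer-type groups must be disjoint (duplicate name)")
        if sorted(self.band_starts) != self.band_starts or sorted(self.years) != self.years:
            raise ConfigurationError("band starts and years must be sorted")
        for prev, cur in zip(self.band_starts, self.band_starts[1:]):
            if cur - prev != self.band_width:
                raise ConfigurationError(
                    f"age bands must be contiguous with width {self.band_width}: "
                    f"gap between {prev} and {cur}")

    # -- index helpers ------------------------------------------------------
    def band_of(self, age: float, *, clamp: bool = False) -> int:
        b = band_start(age, self.band_width)
        if b in self._band_index:
            return b
        if clamp:
            return min(max(b, self.band_starts[0]), self.band_starts[-1])
        raise DataError(f"no age band covering age {age:.3f} (band {b}) in rate table")

    def _cell(self, band: int, year: int, fifth: int, *, clamp: bool = False):
        bi = self._band_index.get(band)
        yi = self._year_index.get(year)
        fi = self._fifth_index.get(fifth)
        if clamp:
            if bi is None:
                bi = self._band_index[min(max(band, self.band_starts[0]), self.band_starts[-1])]
            if yi is None:
                yi = self._year_index[min(max(year, self.years[0]), self.years[-1])]
        if bi is None or yi is None or fi is None:
            raise DataError(
                f"rate table has no cell (age band {band}, year {year}, fifth {fifth})")
        return bi, yi, fi

    # -- lookups ------------------------------------------------------------
    def rate(self, band: int, year: int, fifth: int, cancer_type: str,
             *, clamp: bool = False) -> float:
        bi, yi, fi = self._cell(band, year, fifth, clamp=clamp)
        ti = self._type_index.get(cancer_type)
        if ti is None:
            raise DataError(f"unknown cancer type {cancer_type!r} in rate table")
        return float(self.incidence[bi, yi, fi, ti])

    def incidence_vector(self, band: int, year: int, fifth: int,
                         *, clamp: bool = False) -> np.ndarray:
        bi, yi, fi = self._cell(band, year, fifth, clamp=clamp)
        return self.incidence[bi, yi, fi]

    def mortality_rate(self, band: int, year: int, fifth: int,
                       *, clamp: bool = False) -> float:
        bi, yi, fi = self._cell(band, year, fifth, clamp=clamp)
        return float(self.mortality[bi, yi, fi])

    def type_index(self, cancer_type: str) -> int:
        try:
            return self._type_index[cancer_type]
        except KeyError:
            raise DataError(f"unknown cancer type {cancer_type!r} in rate table") from None

    # -- serialisation ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, b in enumerate(self.band_starts):
            for yi, y in enumerate(self.years):
                for fi, f in enumerate(self.fifths):
                    for ti, t in enumerate(self.cancer_types):
                        rows.append((b, y, f, t, self.incidence[bi, yi, fi, ti]))
                    rows.append((b, y, f, "_mortality", self.mortality[bi, yi, fi]))
        return pd.DataFrame(rows, columns=["age_band_start", "year", "imd_fifth",
                                           "cancer_type", "rate"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, band_width: int = 5) -> "ReferenceRateTable":
        required = {"age_band_start", "year", "imd_fifth", "cancer_type", "rate"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"rate table missing columns: {sorted(missing)}")
        bands = sorted(frame["age_band_start"].unique())
        years = sorted(frame["year"].unique())
        fifths = sorted(frame["imd_fifth"].unique())
        types = [t for t in frame["cancer_type"].unique() if t != "_mortality"]
        inc = np.full((len(bands), len(years), len(fifths), len(types)), np.nan)
        mort = np.zeros((len(bands), len(years), len(fifths)))
        b_i = {b: i for i, b in enumerate(bands)}
        y_i = {y: i for i, y in enumerate(years)}
        f_i = {f: i for i, f in enumerate(fifths)}
        t_i = {t: i for i, t in enumerate(types)}
        for row in frame.itertuples(index=False):
            if row.cancer_type == "_mortality":
                mort[b_i[row.age_band_start], y_i[row.year], f_i[row.imd_fifth]] = row.rate
            else:
                inc[b_i[row.age_band_start], y_i[row.year], f_i[row.imd_fifth],
                    t_i[row.cancer_type]] = row.rate
        if np.isnan(inc).any():
            idx = np.argwhere(np.isnan(inc))[0]
            raise DataError(
                f"rate table grid incomplete: missing cell (age band {bands[idx[0]]}, "
                f"year {years[idx[1]]}, fifth {fifths[idx[2]]}, type {types[idx[3]]})")
        return cls(bands, years, fifths, types, inc, mort, band_width=band_width)


@dataclass
class RateShapeSpec:
    """Parameters for the synthetic reference-rate generator.

    Baseline incidence is log-linear in attained age (evaluated at band
    midpoints) with optional calendar drift, a multiplicative deprivation
    gradient, and optional lognormal jitter (off by default, so tables are
    analytic functions of the spec).
    """

    cancer_types: dict[str, float] = field(default_factory=lambda: {
        "breast": 2.0e-3, "lung": 8.0e-4, "uterus": 4.0e-4,
        "leukaemia": 1.0e-4, "other": 3.0e-3})
    age_slope: dict[str, float] | float = math.log(2.0) / 10.0  # log-rate per year of age
    reference_age: float = 52.5
    year_range: tuple[int, int] = (1993, 2022)
    calendar_drift: float = 0.0          # log-rate per calendar year
    deprivation_gradient: float = 0.0    # log-rate per fifth above 3
    mortality_rate_at_reference: float = 4.0e-3
    mortality_age_slope: float = math.log(2.0) / 8.0
    jitter_sd: float = 0.0
    band_width: int = 5
    include_unknown_fifth: bool = True

    def slope_for(self, cancer_type: str) -> float:
        if isinstance(self.age_slope, dict):
            return float(self.age_slope.get(cancer_type, 0.0))
        return float(self.age_slope)


def make_reference_rates(spec: RateShapeSpec, seed: int = 0) -> ReferenceRateTable:
    """Build a complete synthetic rate table from ``spec``, deterministic given seed."""
    y0, y1 = spec.year_range
    if y1 < y0:
        raise ConfigurationError(f"year range {spec.year_range} is empty")
    width = spec.band_width
    n_bands = (AGE_MAX - AGE_MIN) // width
    if AGE_MIN + n_bands * width != AGE_MAX:
        raise ConfigurationError(f"band width {width} does not tile ages {AGE_MIN}-{AGE_MAX}")
    bands = [AGE_MIN + width * i for i in range(n_bands)]
    years = list(range(y0, y1 + 1))
    fifths = ([0] if spec.include_unknown_fifth else []) + [1, 2, 3, 4, 5]
    types = list(spec.cancer_types)
    if not types:
        raise ConfigurationError("at least one cancer type is required")

    rng = np.random.default_rng(seed)
    known = [f for f in fifths if f != 0]
    inc = np.zeros((len(bands), len(years), len(fifths), len(types)))
    mort = np.zeros((len(bands), len(years), len(fifths)))
    mid = np.array([b + width / 2.0 for b in bands])
    for yi, year in enumerate(years):
        for fi, fifth in enumerate(fifths):
            if fifth == 0:
                continue
            dep = math.exp(spec.deprivation_gradient * (fifth - 3))
            cal = math.exp(spec.calendar_drift * (year - y0))
            for ti, t in enumerate(types):
                base = spec.cancer_types[t]
                rate = base * np.exp(spec.slope_for(t) * (mid - spec.reference_age)) * dep * cal
                inc[:, yi, fi, ti] = rate
            mort[:, yi, fi] = (spec.mortality_rate_at_reference
                               * np.exp(spec.mortality_age_slope * (mid - spec.reference_age))
                               * dep)
    if spec.jitter_sd > 0:
        jit = rng.lognormal(mean=0.0, sigma=spec.jitter_sd, size=inc.shape)
        inc = inc * jit
    if spec.include_unknown_fifth:
        fi0 = fifths.index(0)
        known_idx = [fifths.index(f) for f in known]
        inc[:, :, fi0, :] = inc[:, :, known_idx, :].mean(axis=2)
        mort[:, :, fi0] = mort[:, :, known_idx].mean(axis=2)
    return ReferenceRateTable(bands, years, fifths, types, inc, mort, band_width=width)


def require_span(table: ReferenceRateTable, year_min: int, year_max: int) -> None:
    """Raise ConfigurationError naming missing cells if the table does not cover the span."""
    missing = [y for y in range(year_min, year_max + 1) if y not in table._year_index]
    if missing:
        raise ConfigurationError(
            f"rate table does not cover calendar years {missing[0]}-{missing[-1]} "
            f"(table spans {table.years[0]}-{table.years[-1]})")
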