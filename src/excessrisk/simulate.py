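"""Synthetic cohort generator with known ground truth.

Each woman's subsequent-cancer and death times are drawn from piecewise-constant
cause-specific hazards: the reference rate of each cause in her current
(attained-age band x calendar year x deprivation) stratum, multiplied by the
configured rate multipliers for her exposures.  Sampling within each
constant-hazard segment is exact inverse-transform on the exponential; no time
discretisation is involved.  With all multipliers at 1.0 the cohort's true
standardised incidence ratio is 1 for every cancer type, and a configured
multiplier m is the true SIR (and true rate ratio) for its type, which makes
every downstream stage testable by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import Event, WomanRecord
from .errors import ConfigurationError
from .rates import ReferenceRateTable

#: exposure keys usable in multiplier maps; "*" applies to every woman.
EXPOSURE_KEYS = ("*", "radiotherapy", "endocrine", "chemotherapy", "bcs", "mastectomy")

_DEFAULT_COVARIATE_DISTS = {
    "size": {"<20mm": 0.5, "20-49mm": 0.35, ">=50mm": 0.1, "Unknown": 0.05},
    "nodes": {"negative": 0.6, "positive": 0.3, "Unknown": 0.1},
    "grade": {"1": 0.2, "2": 0.45, "3": 0.3, "Unknown": 0.05},
    "er_status": {"positive": 0.7, "negative": 0.2, "Unknown": 0.1},
    "screen_detected": {"yes": 0.3, "no": 0.6, "not_eligible": 0.1},
    "morphology": {"ductal": 0.75, "lobular": 0.15, "other": 0.1},
    "index_laterality": {"left": 0.5, "right": 0.5},
}


@dataclass
class LogisticAssignment:
    """P(flag) = expit(intercept + age_coef*(age-50) + sum of level coefficients)."""
    intercept: float = 0.0
    age_coef: float = 0.0
    level_coefs: dict = field(default_factory=dict)  # {(covariate, level): beta}

    def prob(self, age: float, covariates: dict) -> float:
        z = self.intercept + self.age_coef * (age - 50.0)
        for (cov, level), beta in self.level_coefs.items():
            if covariates.get(cov) == level:
                z += beta
        return 1.0 / (1.0 + math.exp(-z))


@dataclass
class SimConfig:
    """Everything the simulator needs; a fixed seed gives a byte-identical cohort."""

    n: int = 1000
    seed: int = 0
    age_range: tuple[float, float] = (25.0, 75.0)
    year_range: tuple[int, int] = (2000, 2015)
    imd_probs: dict = field(default_factory=lambda: {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2})
    covariate_dists: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_COVARIATE_DISTS.items()})
    bcs_prob: float = 0.6
    treatment_models: dict = field(default_factory=lambda: {
        "radiotherapy": LogisticAssignment(intercept=0.5),
        "endocrine": LogisticAssignment(intercept=0.0),
        "chemotherapy": LogisticAssignment(intercept=-0.5),
    })
    #: {cancer_type: {exposure_key: multiplier}}; multiplied over matching exposures
    multipliers: dict = field(default_factory=dict)
    mortality_multiplier: float = 1.0
    admin_date: float = 2021.0 + 10.0 / 12.0   # 31 October 2021 at month resolution
    breast_group: str = "breast"
    laterality_probs: dict = field(default_factory=lambda: {
        "contralateral": 0.5, "ipsilateral": 0.5, "unknown": 0.0})
    noninvasive_probs: dict = field(default_factory=dict)   # {type: P(non-invasive)}
    endocrine_mask_prob: float = 0.0
    continue_after_event: bool = True
    # knobs for planting eligibility violations (all off by default)
    metastatic_prob: float = 0.0
    neoadjuvant_prob: float = 0.0
    noninvasive_morphology_prob: float = 0.0

    def validate(self, table: ReferenceRateTable) -> None:
        if self.n <= 0:
            raise ConfigurationError("cohort size must be positive")
        lo, hi = self.age_range
        if not (20.0 <= lo <= hi <= 75.0):
            raise ConfigurationError(f"age range {self.age_range} outside supported 20-75")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ConfigurationError(f"year range {self.year_range} is empty")
        for t, expo_map in self.multipliers.items():
            if t not in table.cancer_types:
                raise ConfigurationError(f"multiplier for unknown cancer type {t!r}")
            for key, m in expo_map.items():
                if key not in EXPOSURE_KEYS:
                    raise ConfigurationError(f"unknown exposure key {key!r} in multipliers")
                if not (m > 0):
                    raise ConfigurationError(
                        f"multiplier for ({t!r}, {key!r}) must be > 0, got {m}")
        if self.mortality_multiplier <= 0:
            raise ConfigurationError("mortality multiplier must be > 0")
        if y0 < table.years[0] or int(self.admin_date) > table.years[-1]:
            raise ConfigurationError(
                f"rate table years {table.years[0]}-{table.years[-1]} do not cover the "
                f"simulated span {y0}-{int(self.admin_date)}")


def _pick(rng, dist: dict):
    """Draw a key from {value: prob}; probabilities are normalised."""
    u = rng.random() * sum(dist.values())
    acc = 0.0
    for k, p in dist.items():
        acc += p
        if u <= acc:
            return k
    return k  # numerical slack


def _exposures(woman: WomanRecord) -> set[str]:
    """Recorded-exposure coding: BCS implies radiotherapy recorded, ER+ implies
    endocrine recorded.  Ground-truth endocrine exposure is used (masking is a
    recording artefact applied afterwards)."""
    out = {"*"}
    out.add("bcs" if woman.surgery == "bcs" else "mastectomy")
    if woman.radiotherapy or woman.surgery == "bcs":
        out.add("radiotherapy")
    if woman.endocrine_true or woman.covariates.get("er_status") == "positive":
        out.add("endocrine")
    if woman.chemotherapy:
        out.add("chemotherapy")
    return out


def true_multiplier(config: SimConfig, woman: WomanRecord, cancer_type: str) -> float:
    m = 1.0
    expo = _exposures(woman)
    for key, mult in config.multipliers.get(cancer_type, {}).items():
        if key in expo:
            m *= mult
    return m


def simulate_cohort(config: SimConfig, table: ReferenceRateTable) -> list[WomanRecord]:
    """Simulate ``config.n`` women against ``table``; deterministic given seed."""
    config.validate(table)
    rng = np.random.default_rng(config.seed)
    types = table.cancer_types

    cohort: list[WomanRecord] = []
    for wid in range(config.n):
        lo, hi = config.age_range
        age_dx = round((lo + (hi - lo) * rng.random()) * 12.0) / 12.0
        age_dx = min(max(age_dx, lo), hi)
        diag_year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        diag_frac = int(rng.integers(0, 12)) / 12.0
        imd = _pick(rng, config.imd_probs)
        cov = {name: _pick(rng, dist) for name, dist in config.covariate_dists.items()}
        if rng.random() < config.noninvasive_morphology_prob:
            cov["morphology"] = "non_invasive"
        w = WomanRecord(id=wid, diag_year=diag_year, diag_frac=diag_frac,
                        age_dx=age_dx, imd=imd, covariates=cov)
        w.surgery = "bcs" if rng.random() < config.bcs_prob else "mastectomy"
        for name, model in config.treatment_models.items():
            flag = rng.random() < model.prob(age_dx, cov)
            setattr(w, name, flag)
        w.endocrine_true = w.endocrine
        w.metastatic = rng.random() < config.metastatic_prob
        w.neoadjuvant = rng.random() < config.neoadjuvant_prob
        w.fu_end = max(config.admin_date - w.diag_date, 0.0)

        mult = np.array([true_multiplier(config, w, t) for t in types])
        _simulate_events(rng, w, table, mult, config)

        if w.endocrine and config.endocrine_mask_prob > 0:
            if rng.random() < config.endocrine_mask_prob:
                w.endocrine = False
        cohort.append(w)
    return cohort


def _simulate_events(rng, w: WomanRecord, table: ReferenceRateTable,
                     mult: np.ndarray, config: SimConfig) -> None:
    """Piecewise-constant competing-risks sampler for one woman (in place).

    Within each segment (constant attained-age band and calendar year) the
    waiting time is exponential with the total active hazard; the cause is then
    chosen proportionally to cause-specific hazards.  Only the first event of
    each cancer type is generated; simulation continues past cancer events
    (re-drawing from the remaining hazards) unless ``continue_after_event`` is
    off.  Ages past the table's last band reuse that band's rates.
    """
    types = table.cancer_types
    n_types = len(types)
    active = np.ones(n_types, dtype=bool)
    bi_type = table._type_index.get(config.breast_group)
    t = 0.0
    t_end = w.fu_end
    if t_end <= 0.0:
        return
    diag_date = w.diag_date
    age_dx = w.age_dx
    lat = config.laterality_probs
    eps = 1e-12

    draw = -math.log(rng.random())  # Exp(1), consumed across segments
    while t < t_end - eps:
        age = age_dx + t
        cal = diag_date + t
        band = table.band_of(age, clamp=True)
        year = int(math.floor(cal + eps))
        # next stratum boundary in follow-up time
        t_band = (band + table.band_width - age_dx) if age < table.band_starts[-1] else t_end
        t_year = (math.floor(cal + eps) + 1.0) - diag_date
        seg_end = min(t_end, t_band, t_year)
        if seg_end <= t + eps:
            t = t + eps * 4 if seg_end <= t else seg_end
            continue
        inc = table.incidence_vector(band, year, w.imd, clamp=True)
        haz = inc * mult * active
        total = float(haz.sum()) + table.mortality_rate(band, year, w.imd, clamp=True) \
            * config.mortality_multiplier
        if total <= 0.0:
            t = seg_end
            continue
        dt = draw / total
        if t + dt >= seg_end - eps:
            draw -= total * (seg_end - t)
            t = seg_end
            continue
        # event inside the segment
        t_event = t + dt
        u = rng.random() * total
        acc = 0.0
        cause = None
        for k in range(n_types):
            acc += haz[k]
            if u <= acc:
                cause = k
                break
        if cause is None:
            w.death_time = t_event
            return
        active[cause] = False
        laterality = "na"
        if cause == bi_type:
            laterality = _pick(rng, lat)
        invasive = not (rng.random() < config.noninvasive_probs.get(types[cause], 0.0))
        w.events.append(Event(time=t_event, group=types[cause],
                              laterality=laterality, invasive=invasive))
        if not config.continue_after_event:
            return
        t = t_event
        draw = -math.log(rng.random())
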