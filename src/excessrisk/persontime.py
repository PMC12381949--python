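"""Eligibility filtering, at-risk intervals, Lexis splitting and stratum tallies.

Follow-up runs from three months after the index diagnosis to the earliest of
the first qualifying second-cancer event, the 85th birthday, death, or the
administrative censoring date.  Person-time is split into strata of attained-age
band x calendar year x deprivation fifth; stratum intervals are half-open
[start, end), so an event or birthday exactly on a boundary belongs to the
later stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter

import pandas as pd

from .cohort import WomanRecord, Event
from .errors import ConfigurationError, DataError
from .rates import ReferenceRateTable

ENTRY_DELAY = 0.25   # three months, in years
AGE_CAP = 85.0
_EPS = 1e-9

EXIT_EVENT = "event"
EXIT_COMPETING = "competing-event"
EXIT_AGE85 = "age85"
EXIT_DEATH = "death"
EXIT_ADMIN = "admin"


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

@dataclass
class EligibilityRuleSet:
    """Sequentially applied exclusion rules; each independently toggleable.

    Application order mirrors the reporting order: age bounds, minimum
    follow-up, non-invasive morphology, early second invasive cancer,
    metastatic disease, neoadjuvant therapy.
    """
    age_bounds: tuple[float, float] | None = (20.0, 75.0)
    min_follow_up: float | None = ENTRY_DELAY
    exclude_noninvasive_morphology: bool = True
    exclude_early_second_invasive: bool = True   # within 3 months of index
    exclude_metastatic: bool = True
    exclude_neoadjuvant: bool = True

    def rules(self):
        if self.age_bounds is not None:
            lo, hi = self.age_bounds
            yield ("age_at_diagnosis", lambda w: not (lo <= w.age_dx <= hi))
        if self.min_follow_up is not None:
            yield ("short_follow_up",
                   lambda w: w.follow_up_end() < self.min_follow_up)
        if self.exclude_noninvasive_morphology:
            yield ("noninvasive_morphology",
                   lambda w: w.covariates.get("morphology") == "non_invasive")
        if self.exclude_early_second_invasive:
            yield ("second_invasive_within_3_months",
                   lambda w: any(ev.invasive and ev.time <= ENTRY_DELAY for ev in w.events))
        if self.exclude_metastatic:
            yield ("metastatic", lambda w: w.metastatic)
        if self.exclude_neoadjuvant:
            yield ("neoadjuvant", lambda w: w.neoadjuvant)


def apply_eligibility(cohort: list[WomanRecord], rules: EligibilityRuleSet
                      ) -> tuple[list[WomanRecord], dict[str, int]]:
    """Apply the rules in order; a woman excluded by rule i is not counted
    against later rules.  Returns (eligible cohort, ordered exclusion counts)."""
    remaining = list(cohort)
    counts: dict[str, int] = {}
    for name, pred in rules.rules():
        kept, dropped = [], 0
        for w in remaining:
            if pred(w):
                dropped += 1
            else:
                kept.append(w)
        counts[name] = dropped
        remaining = kept
    return remaining, counts


# ---------------------------------------------------------------------------
# analysis specification and event classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisSpec:
    """What counts as the target outcome and how follow-up ends.

    For contralateral analyses the target is the breast group: contralateral
    and unknown-laterality second breast cancers count as target events,
    ipsilateral ones are dropped as outcomes but still censor follow-up, and
    the reference breast rate is halved when computing expected counts.
    """
    target: str
    outcome_class: str = "invasive"      # "invasive" | "noninvasive"
    mode: str = "first-event"            # "first-event" | "any-time"
    contralateral: bool = False
    breast_group: str = "breast"

    def __post_init__(self):
        if self.outcome_class not in ("invasive", "noninvasive"):
            raise ConfigurationError(f"unknown outcome class {self.outcome_class!r}")
        if self.mode not in ("first-event", "any-time"):
            raise ConfigurationError(f"unknown event-selection mode {self.mode!r}")
        if self.contralateral and self.target != self.breast_group:
            raise ConfigurationError(
                "contralateral handling requires the breast group as target")

    @property
    def halve_reference(self) -> bool:
        return self.contralateral


def classify_event(ev: Event, spec: AnalysisSpec) -> str:
    """Classify one event as 'target', 'competing' or 'ignored' under ``spec``."""
    if spec.outcome_class == "invasive":
        if not ev.invasive:
            return "ignored"     # non-invasive cancers ignored entirely
        if ev.group == spec.target:
            if spec.contralateral:
                return "target" if ev.laterality in ("contralateral", "unknown") \
                    else "competing"
            return "target"
        return "competing"
    # non-invasive outcome: any invasive cancer censors; other non-invasive
    # events of different type/laterality compete as well
    if ev.invasive:
        return "competing"
    if ev.group == spec.target:
        if spec.contralateral:
            return "target" if ev.laterality in ("contralateral", "unknown") \
                else "competing"
        return "target"
    return "competing"


@dataclass
class AtRiskInterval:
    entry: float
    exit: float
    reason: str                          # one of the EXIT_* constants
    target_events: list[float] = field(default_factory=list)

    @property
    def length(self) -> float:
        return self.exit - self.entry


def at_risk_interval(w: WomanRecord, spec: AnalysisSpec) -> AtRiskInterval | None:
    """At-risk interval in time since diagnosis, or None if zero-length.

    The 85th-birthday exit applies even when events occur later.  Under
    first-event mode, follow-up ends at the first non-ignored event; under
    any-time mode events do not end follow-up and every qualifying target
    event inside the interval is counted.
    """
    entry = ENTRY_DELAY
    t85 = AGE_CAP - w.age_dx
    candidates = [(w.fu_end, EXIT_ADMIN), (t85, EXIT_AGE85)]
    if w.death_time is not None:
        candidates.append((w.death_time, EXIT_DEATH))
    exit_t, reason = min(candidates, key=lambda c: (c[0], _EXIT_ORDER[c[1]]))

    targets: list[float] = []
    if spec.mode == "first-event":
        for ev in w.events:                 # events are time-sorted
            if ev.time <= entry:
                continue                     # pre-entry events handled by eligibility
            kind = classify_event(ev, spec)
            if kind == "ignored":
                continue
            if ev.time <= exit_t:            # earliest non-ignored event wins
                exit_t = ev.time
                reason = EXIT_EVENT if kind == "target" else EXIT_COMPETING
                if kind == "target":
                    targets = [ev.time]
            break
    else:
        for ev in w.events:
            if not (entry < ev.time <= exit_t):
                continue
            if classify_event(ev, spec) == "target":
                targets.append(ev.time)
    if exit_t <= entry + _EPS:
        return None
    return AtRiskInterval(entry=entry, exit=exit_t, reason=reason, target_events=targets)


_EXIT_ORDER = {EXIT_EVENT: 0, EXIT_COMPETING: 1, EXIT_DEATH: 2, EXIT_AGE85: 3, EXIT_ADMIN: 4}


# ---------------------------------------------------------------------------
# Lexis splitting
# ---------------------------------------------------------------------------

def lexis_split(interval: AtRiskInterval, w: WomanRecord, band_width: int,
                table: ReferenceRateTable, spec: AnalysisSpec
                ) -> list[tuple[tuple[int, int, int], float, float]]:
    """Split an at-risk interval into (stratum key, time at risk, reference rate)
    segments.  Segments partition the interval exactly; each lies wholly inside
    one attained-age band and one calendar year.  Missing rate-table cells
    raise DataError naming the cell."""
    if table.band_width != band_width:
        raise ConfigurationError(
            f"band width {band_width} does not match rate table ({table.band_width})")
    halve = 0.5 if spec.halve_reference and spec.target == spec.breast_group else 1.0
    out = []
    t = interval.entry
    end = interval.exit
    while t < end - _EPS:
        age = w.age_dx + t
        cal = w.diag_date + t
        band = table.band_of(age + _EPS)
        year = int(math.floor(cal + _EPS))
        t_band = band + band_width - w.age_dx
        t_year = (year + 1) - w.diag_date
        seg_end = min(end, t_band, t_year)
        if seg_end <= t + _EPS:
            seg_end = min(end, t + 10 * _EPS)
        rate = table.rate(band, year, w.imd, spec.target) * halve
        out.append(((band, year, w.imd), seg_end - t, rate))
        t = seg_end
    return out


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

@dataclass
class StratumTally:
    """Observed events, expected events and woman-years for one stratum."""
    o: int = 0
    e: float = 0.0
    py: float = 0.0

    def __iadd__(self, other: "StratumTally"):
        self.o += other.o
        self.e += other.e
        self.py += other.py
        return self


@dataclass
class TallyResult:
    strata: dict[tuple[int, int, int], StratumTally]
    exit_reasons: Counter
    dropped_zero_length: int

    @property
    def O(self) -> int:
        return sum(s.o for s in self.strata.values())

    @property
    def E(self) -> float:
        return sum(s.e for s in self.strata.values())

    @property
    def PY(self) -> float:
        return sum(s.py for s in self.strata.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(k[0], k[1], k[2], s.o, s.e, s.py)
                for k, s in sorted(self.strata.items())]
        return pd.DataFrame(rows, columns=["age_band_start", "year", "imd_fifth",
                                           "o", "e", "py"])


def event_stratum(w: WomanRecord, t: float, band_width: int) -> tuple[int, int, int]:
    """Stratum of an event at follow-up time t (boundary events go to the later
    stratum via floor on the attained age / calendar year)."""
    age = w.age_dx + t
    band = 20 + band_width * int((age + _EPS - 20) // band_width)
    year = int(math.floor(w.diag_date + t + _EPS))
    return band, year, w.imd


def tally(cohort: list[WomanRecord], spec: AnalysisSpec, table: ReferenceRateTable,
          band_width: int = 5) -> TallyResult:
    """Observed / expected / woman-years per stratum over the whole cohort."""
    strata: dict[tuple[int, int, int], StratumTally] = {}
    reasons: Counter = Counter()
    dropped = 0
    for w in cohort:
        interval = at_risk_interval(w, spec)
        if interval is None:
            dropped += 1
            continue
        reasons[interval.reason] += 1
        for key, length, rate in lexis_split(interval, w, band_width, table, spec):
            s = strata.setdefault(key, StratumTally())
            s.e += length * rate
            s.py += length
        for t_ev in interval.target_events:
            key = event_stratum(w, t_ev, band_width)
            strata.setdefault(key, StratumTally()).o += 1
    return TallyResult(strata=strata, exit_reasons=reasons, dropped_zero_length=dropped)
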