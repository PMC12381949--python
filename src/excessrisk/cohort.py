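"""Person-level cohort records.

Time is continuous in years since diagnosis of the index breast cancer; months
are 1/12 of a year.  Calendar position is carried as a decimal year so attained
age and calendar year can be derived for any follow-up time without day-level
date arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError

#: laterality of a second breast cancer relative to the index cancer
LATERALITIES = ("contralateral", "ipsilateral", "unknown", "na")

COVARIATE_LEVELS = {
    "size": ("<20mm", "20-49mm", ">=50mm", "Unknown"),
    "nodes": ("negative", "positive", "Unknown"),
    "grade": ("1", "2", "3", "Unknown"),
    "er_status": ("positive", "negative", "Unknown"),
    "screen_detected": ("yes", "no", "not_eligible"),
    "morphology": ("ductal", "lobular", "other", "non_invasive"),
    "index_laterality": ("left", "right", "Unknown"),
}


@dataclass(frozen=True)
class Event:
    """One subsequent cancer event.

    time       : years since index diagnosis, strictly positive
    group      : cancer-type group name
    laterality : relative to the index cancer; "na" for non-breast events
    invasive   : False for in-situ / non-invasive registrations
    """
    time: float
    group: str
    laterality: str = "na"
    invasive: bool = True


@dataclass
class WomanRecord:
    """One woman: covariates, treatment flags, and event history."""

    id: int
    diag_year: int
    diag_frac: float              # month of diagnosis within the year, k/12
    age_dx: float                 # age at diagnosis in years, whole-month resolution
    imd: int                      # deprivation fifth 1..5, 0 = unknown
    covariates: dict = field(default_factory=dict)
    surgery: str = "bcs"          # "bcs" | "mastectomy"
    radiotherapy: bool = False
    endocrine: bool = False       # recorded flag (may be masked relative to truth)
    chemotherapy: bool = False
    endocrine_true: bool = False  # simulation ground truth before any masking
    metastatic: bool = False
    neoadjuvant: bool = False
    events: list[Event] = field(default_factory=list)
    death_time: float | None = None
    fu_end: float = 0.0           # administrative end of follow-up, years since diagnosis

    @property
    def diag_date(self) -> float:
        """Diagnosis date as a decimal calendar year."""
        return self.diag_year + self.diag_frac

    def age_at(self, t: float) -> float:
        return self.age_dx + t

    def validate(self) -> None:
        if self.surgery not in ("bcs", "mastectomy"):
            raise DataError(f"woman {self.id}: unknown surgery {self.surgery!r}")
        last = 0.0
        for ev in self.events:
            if ev.time <= 0:
                raise DataError(f"woman {self.id}: event time {ev.time} not positive")
            if ev.time < last:
                raise DataError(f"woman {self.id}: events not sorted")
            if self.death_time is not None and ev.time > self.death_time:
                raise DataError(f"woman {self.id}: event after death")
            if ev.laterality not in LATERALITIES:
                raise DataError(f"woman {self.id}: bad laterality {ev.laterality!r}")
            last = ev.time

    def follow_up_end(self) -> float:
        """End of observation: death or administrative censoring, whichever first."""
        if self.death_time is not None:
            return min(self.death_time, self.fu_end)
        return self.fu_end


def validate_cohort(cohort: list[WomanRecord]) -> None:
    seen: set[int] = set()
    for w in cohort:
        if w.id in seen:
            raise DataError(f"duplicate woman id {w.id}")
        seen.add(w.id)
        w.validate()
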