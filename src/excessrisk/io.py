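"""Delimited-text and JSON I/O: cohorts, events, rate tables, grouping maps,
run configuration.

All tabular files are comma-separated UTF-8 with a header row; dates are
decimal years.  Output tables carry a ``#``-prefixed metadata header with the
serialised run configuration hash and seed so any artefact can be traced to
the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import Event, WomanRecord, validate_cohort
from .errors import ConfigurationError, DataError
from .rates import ReferenceRateTable

SCHEMA_VERSION = "1"

_WOMAN_COLUMNS = ["id", "diag_year", "diag_frac", "age_dx", "imd", "surgery",
                  "radiotherapy", "endocrine", "chemotherapy", "endocrine_true",
                  "metastatic", "neoadjuvant", "death_time", "fu_end",
                  "size", "nodes", "grade", "er_status", "screen_detected",
                  "morphology", "index_laterality"]
_EVENT_COLUMNS = ["id", "time", "group", "laterality", "invasive"]
_COVARIATES = ["size", "nodes", "grade", "er_status", "screen_detected",
               "morphology", "index_laterality"]


def write_cohort(cohort: list[WomanRecord], women_path, events_path) -> None:
    wrows, erows = [], []
    for w in cohort:
        wrows.append([w.id, w.diag_year, w.diag_frac, w.age_dx, w.imd, w.surgery,
                      int(w.radiotherapy), int(w.endocrine), int(w.chemotherapy),
                      int(w.endocrine_true), int(w.metastatic), int(w.neoadjuvant),
                      "" if w.death_time is None else repr(w.death_time),
                      repr(w.fu_end)]
                     + [w.covariates.get(c, "Unknown") for c in _COVARIATES])
        for ev in w.events:
            erows.append([w.id, repr(ev.time), ev.group, ev.laterality,
                          int(ev.invasive)])
    pd.DataFrame(wrows, columns=_WOMAN_COLUMNS).to_csv(women_path, index=False,
                                                       float_format="%.17g")
    pd.DataFrame(erows, columns=_EVENT_COLUMNS).to_csv(events_path, index=False,
                                                       float_format="%.17g")


def read_cohort(women_path, events_path) -> list[WomanRecord]:
    women_path, events_path = Path(women_path), Path(events_path)
    if not women_path.exists():
        raise DataError(f"cohort file not found: {women_path}")
    if not events_path.exists():
        raise DataError(f"events file not found: {events_path}")
    wdf = pd.read_csv(women_path, comment="#", float_precision="round_trip")
    missing = set(_WOMAN_COLUMNS) - set(wdf.columns)
    if missing:
        raise DataError(f"{women_path}: missing columns {sorted(missing)} "
                        f"(schema version {SCHEMA_VERSION})")
    edf = pd.read_csv(events_path, comment="#", float_precision="round_trip")
    events_by_id: dict[int, list[Event]] = {}
    for i, row in enumerate(edf.itertuples(index=False), start=2):
        try:
            ev = Event(time=float(row.time), group=str(row.group),
                       laterality=str(row.laterality), invasive=bool(int(row.invasive)))
        except (TypeError, ValueError) as exc:
            raise DataError(f"{events_path}: line {i}: unparseable event row "
                            f"({exc})") from None
        events_by_id.setdefault(int(row.id), []).append(ev)
    cohort = []
    for i, row in enumerate(wdf.itertuples(index=False), start=2):
        try:
            death = None if pd.isna(row.death_time) or row.death_time == "" \
                else float(row.death_time)
            w = WomanRecord(
                id=int(row.id), diag_year=int(row.diag_year),
                diag_frac=float(row.diag_frac), age_dx=float(row.age_dx),
                imd=int(row.imd), surgery=str(row.surgery),
                radiotherapy=bool(int(row.radiotherapy)),
                endocrine=bool(int(row.endocrine)),
                chemotherapy=bool(int(row.chemotherapy)),
                endocrine_true=bool(int(row.endocrine_true)),
                metastatic=bool(int(row.metastatic)),
                neoadjuvant=bool(int(row.neoadjuvant)),
                death_time=death, fu_end=float(row.fu_end),
                covariates={c: str(getattr(row, c)) for c in _COVARIATES},
                events=sorted(events_by_id.get(int(row.id), []),
                              key=lambda e: e.time))
        except (TypeError, ValueError) as exc:
            raise DataError(f"{women_path}: line {i}: unparseable row ({exc})") from None
        cohort.append(w)
    validate_cohort(cohort)
    return cohort


def write_rates(table: ReferenceRateTable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_rates(path, band_width: int = 5) -> ReferenceRateTable:
    path = Path(path)
    if not path.exists():
        raise DataError(f"rate table file not found: {path}")
    return ReferenceRateTable.from_frame(pd.read_csv(path, comment="#",
                                                     float_precision="round_trip"),
                                         band_width=band_width)


# ---------------------------------------------------------------------------
# cancer-type grouping map
# ---------------------------------------------------------------------------

class CancerTypeGrouping:
    """Map from ICD-style diagnosis codes to analysis group names.

    Unmapped codes go to "unspecified" with a warning; longest-prefix matching
    lets a map entry like "C50" cover "C50.3".
    """

    UNSPECIFIED = "unspecified"

    def __init__(self, mapping: dict[str, str]):
        seen: dict[str, str] = {}
        for code, group in mapping.items():
            if code in seen and seen[code] != group:
                raise ConfigurationError(
                    f"code {code!r} mapped to both {seen[code]!r} and {group!r}")
            seen[code] = group
        self.mapping = dict(mapping)

    def group(self, code: str) -> str:
        code = code.strip().upper()
        for prefix_len in range(len(code), 0, -1):
            g = self.mapping.get(code[:prefix_len])
            if g is not None:
                return g
        warnings.warn(f"diagnosis code {code!r} not in grouping map; "
                      f"routed to {self.UNSPECIFIED!r}")
        return self.UNSPECIFIED

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @classmethod
    def from_json(cls, path) -> "CancerTypeGrouping":
        path = Path(path)
        if not path.exists():
            raise DataError(f"grouping map not found: {path}")
        return cls(json.loads(path.read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.mapping, indent=1))


# ---------------------------------------------------------------------------
# run configuration + stamped output
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration; serialised into every output header."""
    out_dir: str = "out"
    cohort_path: str | None = None
    events_path: str | None = None
    rates_path: str | None = None
    grouping_path: str | None = None
    targets: list[dict] = field(default_factory=lambda: [
        {"target": "lung", "outcome_class": "invasive"},
        {"target": "breast", "outcome_class": "invasive", "contralateral": True},
    ])
    band_width: int = 5
    confidence_level: float = 0.95
    treatment_level: float = 0.99
    bootstrap: int = 0
    n_windows: int = 20
    seed: int = 0
    simulate_n: int | None = None   # if set, simulate instead of reading a cohort

    def validate(self) -> None:
        if not (0 < self.confidence_level < 1) or not (0 < self.treatment_level < 1):
            raise ConfigurationError("confidence levels must lie in (0, 1)")
        if self.band_width <= 0 or self.n_windows <= 0 or self.bootstrap < 0:
            raise ConfigurationError("band width / windows / bootstrap must be positive")
        if self.simulate_n is None and (self.cohort_path is None or
                                        self.events_path is None):
            raise ConfigurationError(
                "either simulate_n or cohort_path+events_path must be given")
        for t in self.targets:
            if "target" not in t:
                raise ConfigurationError(f"analysis spec without target: {t}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, default=str)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"run config not found: {path}")
        data = json.loads(path.read_text())
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ConfigurationError(f"unknown run-config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def write_stamped(df: pd.DataFrame, path, config: RunConfig) -> None:
    """Write a CSV with a metadata header tracing it to the producing run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        fh.write(f"# config_hash: {config.digest}\n")
        fh.write(f"# seed: {config.seed}\n")
        fh.write(f"# config: {config.to_json()}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_stamped(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
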