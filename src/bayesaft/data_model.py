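"""Cohort representation, covariate coding and delimited-text I/O.

A cohort is a list of subject records (follow-up time in months, an event
code distinguishing heart-failure-related death, non-HF-related death and
right censoring, and raw covariate values) together with the covariate
coding specifications needed to expand them into a design matrix.

Competing risks are handled through *cause-specific views*: for a chosen
cause of death, subjects who died of the competing cause and subjects who
were censored both carry event indicator ``d = 0``, while deaths from the
chosen cause carry ``d = 1``.  The design matrix always carries a leading
intercept column.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "Cause",
    "CovariateKind",
    "CovariateSpec",
    "SubjectRecord",
    "Cohort",
    "CauseSpecificView",
    "CohortError",
    "encode_design",
    "cause_specific_view",
    "read_cohort",
    "write_cohort",
]


class Event(enum.IntEnum):
    """Outcome at end of follow-up."""

    CENSORED = 0
    HF_DEATH = 1
    NON_HF_DEATH = 2


class Cause(enum.Enum):
    """Cause of death analysed in a cause-specific model."""

    HF = "hf"
    NON_HF = "non_hf"


_CAUSE_EVENT = {Cause.HF: Event.HF_DEATH, Cause.NON_HF: Event.NON_HF_DEATH}

_EVENT_ALIASES = {
    "0": Event.CENSORED,
    "censored": Event.CENSORED,
    "1": Event.HF_DEATH,
    "hf_death": Event.HF_DEATH,
    "hf": Event.HF_DEATH,
    "2": Event.NON_HF_DEATH,
    "non_hf_death": Event.NON_HF_DEATH,
    "non_hf": Event.NON_HF_DEATH,
}


class CovariateKind(enum.Enum):
    BINARY = "binary"
    ORDINAL_TREND = "ordinal_trend"
    CATEGORICAL_REF = "categorical_ref"
    CONTINUOUS = "continuous"


class CohortError(ValueError):
    """Raised for invalid cohort files, records or coding specifications."""


@dataclass(frozen=True)
class CovariateSpec:
    """Coding rule for one covariate.

    Parameters
    ----------
    name:
        Column name in the cohort file.
    kind:
        BINARY covariates become a single 0/1 column (second level = 1).
        ORDINAL_TREND covariates become one column of consecutive integer
        scores 0, 1, 2, ... following the level order (a linear trend
        effect).  CATEGORICAL_REF covariates expand to one indicator per
        non-reference level.  CONTINUOUS covariates pass through as floats.
    levels:
        Ordered levels for the non-continuous kinds.  BINARY defaults to
        ``(0, 1)``.
    reference:
        Reference level, CATEGORICAL_REF only.
    """

    name: str
    kind: CovariateKind
    levels: tuple = None
    reference: object = None

    def __post_init__(self):
        if self.kind is CovariateKind.CONTINUOUS:
            return
        levels = self.levels
        if self.kind is CovariateKind.BINARY and levels is None:
            levels = (0, 1)
        if levels is None or len(levels) < 2:
            raise CohortError(f"covariate {self.name!r}: needs >= 2 levels")
        object.__setattr__(self, "levels", tuple(levels))
        if self.kind is CovariateKind.BINARY and len(self.levels) != 2:
            raise CohortError(f"covariate {self.name!r}: binary needs exactly 2 levels")
        if self.kind is CovariateKind.CATEGORICAL_REF:
            if self.reference is None:
                raise CohortError(f"covariate {self.name!r}: reference level required")
            if not any(str(self.reference) == str(l) for l in self.levels):
                raise CohortError(
                    f"covariate {self.name!r}: reference {self.reference!r} not a level"
                )

    def columns(self) -> list:
        """Design-matrix column names contributed by this covariate."""
        if self.kind is CovariateKind.CATEGORICAL_REF:
            return [
                f"{self.name}[{lvl}]"
                for lvl in self.levels
                if str(lvl) != str(self.reference)
            ]
        return [self.name]

    def encode(self, value) -> list:
        """Numeric design values for one raw value."""
        if self.kind is CovariateKind.CONTINUOUS:
            try:
                return [float(value)]
            except (TypeError, ValueError):
                raise CohortError(f"covariate {self.name!r}: non-numeric value {value!r}")
        sval = str(value)
        matches = [i for i, lvl in enumerate(self.levels) if str(lvl) == sval]
        if not matches:
            raise CohortError(
                f"covariate {self.name!r}: value {value!r} not among levels {self.levels}"
            )
        idx = matches[0]
        if self.kind is CovariateKind.BINARY:
            return [float(idx)]
        if self.kind is CovariateKind.ORDINAL_TREND:
            return [float(idx)]
        return [
            1.0 if i == idx else 0.0
            for i, lvl in enumerate(self.levels)
            if str(lvl) != str(self.reference)
        ]


@dataclass
class SubjectRecord:
    """One subject: identifier, follow-up time in months, outcome, covariates."""

    subject_id: str
    time: float
    event: Event
    covariates: Mapping

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time > 0):
            raise CohortError(
                f"subject {self.subject_id!r}: time must be positive, got {self.time!r}"
            )
        self.event = Event(self.event)


@dataclass
class Cohort:
    """Validated cohort: subject records plus covariate coding specs."""

    records: list
    specs: list
    n_excluded: int = 0

    def __post_init__(self):
        names = {s.name for s in self.specs}
        for rec in self.records:
            missing = names - set(rec.covariates)
            if missing:
                raise CohortError(
                    f"subject {rec.subject_id!r}: missing covariates {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def event_counts(self) -> dict:
        counts = {e: 0 for e in Event}
        for rec in self.records:
            counts[rec.event] += 1
        return counts

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([int(r.event) for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        cov_names = [s.name for s in self.specs]
        rows = []
        for rec in self.records:
            row = {"id": rec.subject_id, "time_months": rec.time, "event": int(rec.event)}
            for name in cov_names:
                row[name] = rec.covariates[name]
            rows.append(row)
        return pd.DataFrame(rows, columns=["id", "time_months", "event"] + cov_names)

    def subset(self, mask: Sequence[bool]) -> "Cohort":
        recs = [r for r, keep in zip(self.records, mask) if keep]
        return Cohort(records=recs, specs=list(self.specs))


@dataclass
class CauseSpecificView:
    """Cause-specific data for one AFT model fit.

    ``d[i] = 1`` iff subject i died of ``cause``; competing-cause deaths and
    censorings both give 0.  ``design`` includes a leading intercept column.
    ``cause is None`` denotes the all-cause (any-death) view used for pooled
    model comparison.
    """

    times: np.ndarray
    d: np.ndarray
    design: np.ndarray
    cause: Cause
    column_names: list

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.d = np.asarray(self.d, dtype=int)
        self.design = np.asarray(self.design, dtype=float)
        if not (self.times.shape[0] == self.d.shape[0] == self.design.shape[0]):
            raise CohortError("view arrays must have equal length")
        if not set(np.unique(self.d)) <= {0, 1}:
            raise CohortError("d must be 0/1")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.d.sum())


def encode_design(cohort: Cohort, specs: Sequence[CovariateSpec] = None):
    """Expand raw covariates into a design matrix with a leading intercept.

    Column order is spec order, then level order within a categorical spec;
    the expansion is deterministic given the specs.

    Returns
    -------
    (matrix, column_names) where ``column_names[0] == "intercept"``.
    """
    specs = list(cohort.specs if specs is None else specs)
    names = ["intercept"]
    for spec in specs:
        names.extend(spec.columns())
    rows = np.empty((len(cohort), len(names)), dtype=float)
    for i, rec in enumerate(cohort.records):
        vals = [1.0]
        for spec in specs:
            vals.extend(spec.encode(rec.covariates[spec.name]))
        rows[i] = vals
    return rows, names


def cause_specific_view(
    cohort: Cohort,
    cause: Cause = None,
    specs: Sequence[CovariateSpec] = None,
    check_rank: bool = True,
) -> CauseSpecificView:
    """Build the cause-specific event indicator and design matrix.

    With ``cause=None`` all deaths count as events (the pooled, all-cause
    view).  Raises if the requested cause has zero events (the censored-data
    likelihood would be degenerate) or if the design matrix is column-rank
    deficient.
    """
    design, names = encode_design(cohort, specs)
    events = cohort.events
    if cause is None:
        d = (events != int(Event.CENSORED)).astype(int)
    else:
        d = (events == int(_CAUSE_EVENT[Cause(cause)])).astype(int)
    if d.sum() == 0:
        raise CohortError(f"cause {cause}: no events in cohort")
    if check_rank and np.linalg.matrix_rank(design) < design.shape[1]:
        raise CohortError(
            f"design matrix is rank deficient (columns {names}); "
            "drop collinear covariates"
        )
    return CauseSpecificView(
        times=cohort.times, d=d, design=design, cause=cause, column_names=names
    )


def _parse_event(raw) -> Event:
    key = str(raw).strip().lower()
    if key.endswith(".0"):
        key = key[:-2]
    if key not in _EVENT_ALIASES:
        raise CohortError(f"unknown event code {raw!r}")
    return _EVENT_ALIASES[key]


def read_cohort(
    path,
    specs: Sequence[CovariateSpec],
    sep: str = None,
    time_units: str = "months",
) -> Cohort:
    """Read a delimited cohort file (header row: id, time_months, event, covariates).

    Event codes may be integers {0, 1, 2} or names
    {censored, hf_death, non_hf_death}.  Rows with a missing covariate value
    are excluded (count stored on ``Cohort.n_excluded``, mirroring an
    under-documented-record exclusion criterion); nonpositive or unparseable
    times and unknown event codes raise :class:`CohortError` naming the row.
    ``time_units='years'`` rescales loaded times to months.
    """
    if time_units not in ("months", "years"):
        raise CohortError(f"unsupported time_units {time_units!r}")
    if sep is None:  # sniff comma vs tab from the header line
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"id", "time_months", "event"}
    if not required <= set(frame.columns):
        raise CohortError(f"cohort file must have columns {sorted(required)}")
    spec_names = [s.name for s in specs]
    missing_cols = [n for n in spec_names if n not in frame.columns]
    if missing_cols:
        raise CohortError(f"cohort file lacks covariate columns {missing_cols}")
    records = []
    n_excluded = 0
    for i, row in frame.iterrows():
        try:
            t = float(row["time_months"])
        except (TypeError, ValueError):
            raise CohortError(f"row {i}: unparseable time {row['time_months']!r}")
        if not (math.isfinite(t) and t > 0):
            raise CohortError(f"row {i}: nonpositive time {row['time_months']!r}")
        if time_units == "years":
            t *= 12.0
        event = _parse_event(row["event"])
        covs = {}
        dropped = False
        for name in spec_names:
            val = row[name]
            if val is None or (isinstance(val, float) and math.isnan(val)) or (
                isinstance(val, str) and val.strip() == ""
            ):
                dropped = True
                break
            covs[name] = val
        if dropped:
            n_excluded += 1
            continue
        records.append(
            SubjectRecord(subject_id=str(row["id"]), time=t, event=event, covariates=covs)
        )
    return Cohort(records=records, specs=list(specs), n_excluded=n_excluded)


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write the cohort in the canonical delimited layout (round-trips with read_cohort)."""
    cohort.to_frame().to_csv(path, sep=sep, index=False)
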