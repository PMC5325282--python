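"""Tabular formats and calendar conventions for radio-telemetry data.

Everything downstream consumes the types defined here: seasonal (3-month)
intervals, per-individual capture histories with staggered entry and
censoring, nest-survey records, and the catalogue of fatality causes with
their anthropogenic classification.

Seasons follow the meteorological convention used in the field study:
Winter = Dec-Feb, Spring = Mar-May, Summer = Jun-Aug, Fall = Sep-Nov.
December is assigned to the Winter labelled by the January year
(Dec 1994 - Feb 1995 is "Winter 1995"), which keeps the interval sequence
contiguous.

The native on-disk format is plain CSV in either a *wide* dialect (one
state column per interval, named like ``Y1995_Spring``) or a *long*
dialect (one row per individual-interval).  A MARK-style live/dead (LD)
encounter export is provided for external cross-checking of known-fate
fits; parsing real MARK files is out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "SEASONS",
    "Season",
    "SeasonInterval",
    "season_of",
    "interval_for_month",
    "CaptureHistory",
    "NestSurveyRecord",
    "FatalityCause",
    "FATALITY_CAUSES",
    "TURBINE_CAUSES",
    "HUMAN_RELATED_CAUSES",
    "STATES",
    "STAGES",
    "read_capture_histories",
    "write_capture_histories",
    "read_nest_surveys",
    "write_nest_surveys",
    "write_mark_encounter_export",
]

# Within-year season order; Winter opens the calendar-labelled year
# because its December belongs to the previous calendar year.
SEASONS: tuple[str, ...] = ("Winter", "Spring", "Summer", "Fall")
Season = str

STATES: frozenset[str] = frozenset(
    {"alive-detected", "not-detected", "dead", "censored"}
)
TERMINAL_STATES: frozenset[str] = frozenset({"dead", "censored"})

STAGES: tuple[str, ...] = (
    "juvenile",
    "subadult1",
    "subadult2",
    "subadult3",
    "floater",
    "breeder",
)

SEXES: tuple[str, ...] = ("female", "male", "unknown")

_SEASON_OF_MONTH = {
    12: "Winter", 1: "Winter", 2: "Winter",
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Fall", 10: "Fall", 11: "Fall",
}


def season_of(month: int) -> Season:
    """Season label for a calendar month (1-12)."""
    if month not in _SEASON_OF_MONTH:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return _SEASON_OF_MONTH[month]


@dataclass(frozen=True)
class SeasonInterval:
    """One 3-month interval of the study timeline.

    Ordering is chronological; ``index`` is the ordinal position relative
    to Winter of ``origin_year`` (index 0), so indices strictly increase
    with time.
    """

    year: int
    season: Season

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")

    @property
    def _key(self) -> int:
        return self.year * 4 + SEASONS.index(self.season)

    def __lt__(self, other: "SeasonInterval") -> bool:  # chronological
        return self._key < other._key

    def __le__(self, other: "SeasonInterval") -> bool:
        return self._key <= other._key

    def index(self, origin_year: int) -> int:
        return self._key - origin_year * 4

    def next(self) -> "SeasonInterval":
        k = self._key + 1
        return SeasonInterval(k // 4, SEASONS[k % 4])

    def __str__(self) -> str:
        return f"{self.year} {self.season}"


def interval_for_month(year: int, month: int) -> SeasonInterval:
    """The SeasonInterval containing a calendar date.

    December belongs to the Winter labelled by the following year.
    """
    season = season_of(month)
    if month == 12:
        year += 1
    return SeasonInterval(year, season)


# --------------------------------------------------------------------------
# Fatality causes (anthropogenic: "yes" / "no" / "unknown")

@dataclass(frozen=True)
class FatalityCause:
    category: str
    anthropogenic: str  # "yes" | "no" | "unknown"


FATALITY_CAUSES: dict[str, FatalityCause] = {
    c.category: c
    for c in (
        FatalityCause("Wind turbine blade-strike", "yes"),
        FatalityCause("Undiagnosed fatality", "unknown"),
        FatalityCause("Electrocution", "yes"),
        FatalityCause("Fledgling mishap", "no"),
        FatalityCause("Killed by eagle", "no"),
        FatalityCause("Wire strike", "yes"),
        FatalityCause("Vehicular strike", "yes"),
        FatalityCause("Lead", "yes"),
        FatalityCause("Botulism", "no"),
        FatalityCause("Brodifacoum poisoning", "yes"),
        FatalityCause("Gunshot", "yes"),
    )
}

TURBINE_CAUSES: frozenset[str] = frozenset({"Wind turbine blade-strike"})

#: All categories classified anthropogenic with certainty; undiagnosed
#: deaths are "unknown" and deliberately not in this set.
HUMAN_RELATED_CAUSES: frozenset[str] = frozenset(
    c.category for c in FATALITY_CAUSES.values() if c.anthropogenic == "yes"
)


# --------------------------------------------------------------------------
# Capture histories

@dataclass
class CaptureHistory:
    """Staggered-entry seasonal encounter/fate record for one individual.

    ``records`` is an ordered list of ``(interval, state)``; at most one
    terminal state (``dead`` or ``censored``) is allowed and it must end
    the record.  ``cause`` is set iff the record ends in a death.
    """

    individual_id: str
    sex: str
    stage_at_entry: str
    entry: SeasonInterval
    records: list[tuple[SeasonInterval, str]] = field(default_factory=list)
    cause: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(
                f"{self.individual_id}: unknown sex {self.sex!r}"
            )
        if self.stage_at_entry not in STAGES:
            raise ValueError(
                f"{self.individual_id}: unknown stage {self.stage_at_entry!r}"
            )
        prev: Optional[SeasonInterval] = None
        seen_terminal = False
        for iv, state in self.records:
            if state not in STATES:
                raise ValueError(
                    f"{self.individual_id}: unknown state {state!r}"
                )
            if seen_terminal:
                raise ValueError(
                    f"{self.individual_id}: event after terminal state"
                )
            if iv < self.entry:
                raise ValueError(
                    f"{self.individual_id}: record at {iv} precedes entry "
                    f"{self.entry}"
                )
            if prev is not None and not prev < iv:
                raise ValueError(
                    f"{self.individual_id}: intervals not strictly "
                    f"increasing at {iv}"
                )
            if state in TERMINAL_STATES:
                seen_terminal = True
            prev = iv
        is_dead = bool(self.records) and self.records[-1][1] == "dead"
        if is_dead and self.cause is None:
            raise ValueError(f"{self.individual_id}: death without a cause")
        if not is_dead and self.cause is not None:
            raise ValueError(
                f"{self.individual_id}: cause set without a death"
            )
        if self.cause is not None and self.cause not in FATALITY_CAUSES:
            raise ValueError(
                f"{self.individual_id}: unknown cause {self.cause!r}"
            )

    @property
    def terminal_state(self) -> Optional[str]:
        if self.records and self.records[-1][1] in TERMINAL_STATES:
            return self.records[-1][1]
        return None

    def copy(self) -> "CaptureHistory":
        return CaptureHistory(
            individual_id=self.individual_id,
            sex=self.sex,
            stage_at_entry=self.stage_at_entry,
            entry=self.entry,
            records=list(self.records),
            cause=self.cause,
        )


# --------------------------------------------------------------------------
# Nest surveys

@dataclass(frozen=True)
class NestSurveyRecord:
    year: int
    pairs_surveyed: int
    fledglings: int
    fledged_broods: int

    def __post_init__(self) -> None:
        if min(self.pairs_surveyed, self.fledglings, self.fledged_broods) < 0:
            raise ValueError("nest-survey counts must be non-negative")
        if self.fledglings < self.fledged_broods:
            raise ValueError(
                f"year {self.year}: fledglings < fledged broods"
            )
        if self.pairs_surveyed < self.fledged_broods:
            raise ValueError(
                f"year {self.year}: more fledged broods than pairs surveyed"
            )


# --------------------------------------------------------------------------
# CSV I/O

_META_COLS = ("individual_id", "sex", "stage_at_entry",
              "entry_year", "entry_season")


def _parse_interval_col(name: str) -> SeasonInterval:
    # wide-dialect state columns look like "Y1995_Spring"
    try:
        year_s, season = name[1:].split("_")
        return SeasonInterval(int(year_s), season)
    except Exception:
        raise ValueError(f"malformed interval column name {name!r}") from None


def _interval_col(iv: SeasonInterval) -> str:
    return f"Y{iv.year}_{iv.season}"


def read_capture_histories(path: str | Path) -> list[CaptureHistory]:
    """Read a capture-history CSV in either the wide or the long dialect.

    The dialect is detected from the header: a ``state`` column marks the
    long format, columns named ``Y<year>_<season>`` mark the wide format.
    Parse and validation failures name the offending row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _META_COLS:
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        rows = list(reader)
    if "state" in header:
        return _histories_from_long(rows, path)
    iv_cols = [c for c in header if c.startswith("Y") and "_" in c]
    if not iv_cols:
        if not rows:
            return []  # valid empty table: header only
        raise ValueError(
            f"{path}: neither a 'state' column nor Y<year>_<season> columns"
        )
    return _histories_from_wide(rows, iv_cols, path)


def _meta_from_row(row: dict, where: str) -> tuple[str, str, str, SeasonInterval]:
    try:
        entry = SeasonInterval(int(row["entry_year"]), row["entry_season"])
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from None
    return row["individual_id"], row["sex"], row["stage_at_entry"], entry


def _histories_from_wide(
    rows: list[dict], iv_cols: list[str], path: Path
) -> list[CaptureHistory]:
    intervals = sorted(
        ((_parse_interval_col(c), c) for c in iv_cols), key=lambda t: t[0]
    )
    out = []
    for lineno, row in enumerate(rows, start=2):
        ind, sex, stage, entry = _meta_from_row(row, f"{path}:{lineno}")
        records = []
        for iv, col in intervals:
            state = (row.get(col) or "").strip()
            if not state:
                continue
            if state not in STATES:
                raise ValueError(
                    f"{path}:{lineno}: malformed state code {state!r} "
                    f"in column {col}"
                )
            records.append((iv, state))
        cause = (row.get("cause") or "").strip() or None
        try:
            out.append(CaptureHistory(ind, sex, stage, entry, records, cause))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def _histories_from_long(rows: list[dict], path: Path) -> list[CaptureHistory]:
    by_ind: dict[str, dict] = {}
    for lineno, row in enumerate(rows, start=2):
        ind, sex, stage, entry = _meta_from_row(row, f"{path}:{lineno}")
        state = (row.get("state") or "").strip()
        if state not in STATES:
            raise ValueError(
                f"{path}:{lineno}: malformed state code {state!r}"
            )
        iv = SeasonInterval(int(row["year"]), row["season"])
        slot = by_ind.setdefault(
            ind,
            {"sex": sex, "stage": stage, "entry": entry,
             "records": [], "cause": None},
        )
        slot["records"].append((iv, state))
        cause = (row.get("cause") or "").strip()
        if cause:
            slot["cause"] = cause
    out = []
    for ind, slot in by_ind.items():
        slot["records"].sort(key=lambda t: t[0])
        out.append(
            CaptureHistory(
                ind, slot["sex"], slot["stage"], slot["entry"],
                slot["records"], slot["cause"],
            )
        )
    return out


def write_capture_histories(
    histories: Sequence[CaptureHistory],
    path: str | Path,
    dialect: str = "wide",
) -> None:
    """Write histories as CSV; ``dialect`` is ``"wide"`` or ``"long"``."""
    path = Path(path)
    if dialect == "wide":
        all_ivs = sorted({iv for h in histories for iv, _ in h.records})
        cols = list(_META_COLS) + [_interval_col(iv) for iv in all_ivs] + ["cause"]
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for h in histories:
                state_by_iv = {iv: s for iv, s in h.records}
                w.writerow(
                    [h.individual_id, h.sex, h.stage_at_entry,
                     h.entry.year, h.entry.season]
                    + [state_by_iv.get(iv, "") for iv in all_ivs]
                    + [h.cause or ""]
                )
    elif dialect == "long":
        cols = list(_META_COLS) + ["year", "season", "state", "cause"]
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for h in histories:
                for iv, state in h.records:
                    w.writerow(
                        [h.individual_id, h.sex, h.stage_at_entry,
                         h.entry.year, h.entry.season,
                         iv.year, iv.season, state,
                         (h.cause or "") if state == "dead" else ""]
                    )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_nest_surveys(path: str | Path) -> list[NestSurveyRecord]:
    path = Path(path)
    out = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                out.append(
                    NestSurveyRecord(
                        year=int(row["year"]),
                        pairs_surveyed=int(row["pairs_surveyed"]),
                        fledglings=int(row["fledglings"]),
                        fledged_broods=int(row["fledged_broods"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_nest_surveys(
    surveys: Sequence[NestSurveyRecord], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "pairs_surveyed", "fledglings", "fledged_broods"])
        for s in surveys:
            w.writerow([s.year, s.pairs_surveyed, s.fledglings,
                        s.fledged_broods])


# --------------------------------------------------------------------------
# MARK-style LD export

def write_mark_encounter_export(
    histories: Sequence[CaptureHistory],
) -> str:
    """Encode histories in the live/dead (LD) known-fate format.

    One line per individual, one ``LD`` pair per interval of the common
    timeline: ``10`` relocated alive, ``11`` died during the interval,
    ``00`` not in the sample (before entry, not relocated, or censored).
    """
    if not histories:
        return ""
    ivs = sorted({iv for h in histories for iv, _ in h.records})
    first, last = ivs[0], ivs[-1]
    timeline = []
    iv = first
    while iv <= last:
        timeline.append(iv)
        iv = iv.next()
    lines = []
    code = {"alive-detected": "10", "dead": "11",
            "not-detected": "00", "censored": "00"}
    for h in histories:
        state_by_iv = {iv: s for iv, s in h.records}
        lines.append(
            " ".join(code[state_by_iv[iv]] if iv in state_by_iv else "00"
                     for iv in timeline)
        )
    return "\n".join(lines) + "\n"
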