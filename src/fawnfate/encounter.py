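"""Staggered-entry known-fate encounter histories.

Capture records plus an age calibration become live/dead histories over
discrete occasions on the *estimated-age* timeline: an animal whose
estimated age class is ``c`` at capture enters the analysis on age day
``c + 1`` (class 0 = 0-24 h old enters the first interval, class 1 the
second, and so on), and an event ``t`` calendar days after capture maps to
age day ``c + t``.

Occasions are one-day blocks (daily resolution) or week blocks (weekly
resolution).  Weekly blocking is phase-wise: 7-day blocks over days 1-30
with the 2-day remainder merged into the 4th block (1-7, 8-14, 15-21,
22-30), then 7-day blocks over days 31..horizon with any short remainder
merged into the final block — so a 120-day horizon has 16 weekly occasions.

Censoring follows telemetry practice: a prematurely shed collar ends the
history without a death.  During daily monitoring the censor day is the
retrieval day; during weekly monitoring it is the floored midpoint between
the last relocation alive and the retrieval day.  A censored animal counts
as surviving every occasion through the one containing its censor day (the
occasion coded "10" last in a MARK input row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .age_models import HoofGrowthModel, estimate_age
from .cohort_sim import CaptureRecord

__all__ = [
    "KNOWN_AGE_LABEL",
    "OccasionMap",
    "EncounterHistory",
    "make_occasion_map",
    "censored_exit_day",
    "build_history",
    "build_histories",
    "write_mark_inp",
    "read_mark_inp",
    "histories_to_dataframe",
    "dataframe_to_histories",
]

KNOWN_AGE_LABEL = "KA"

DIED = "died"
CENSORED = "censored"
SURVIVED = "survived_to_horizon"


@dataclass(frozen=True)
class OccasionMap:
    """Partition of age days 1..horizon into inclusive occasion blocks."""

    horizon: int
    resolution: str  # "daily" or "weekly"
    blocks: tuple[tuple[int, int], ...]

    @property
    def n_occasions(self) -> int:
        return len(self.blocks)

    def block_of(self, day: int) -> int:
        """1-based index of the block containing ``day``."""
        for i, (lo, hi) in enumerate(self.blocks, start=1):
            if lo <= day <= hi:
                return i
        raise ValueError(f"day {day} outside 1..{self.horizon}")

    def block_length(self, occasion: int) -> int:
        lo, hi = self.blocks[occasion - 1]
        return hi - lo + 1


def _phase_blocks(start: int, end: int) -> list[tuple[int, int]]:
    """7-day blocks over [start, end], remainder merged into the last."""
    length = end - start + 1
    n_blocks = max(1, length // 7)
    blocks = [(start + 7 * i, start + 7 * i + 6) for i in range(n_blocks)]
    blocks[-1] = (blocks[-1][0], end)
    return blocks


def make_occasion_map(horizon: int, resolution: str = "daily") -> OccasionMap:
    """Build the daily or weekly occasion structure for a horizon."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if resolution == "daily":
        blocks = tuple((d, d) for d in range(1, horizon + 1))
    elif resolution == "weekly":
        blocks = _phase_blocks(1, min(30, horizon))
        if horizon > 30:
            blocks += _phase_blocks(31, horizon)
        blocks = tuple(blocks)
    else:
        raise ValueError(f"resolution must be 'daily' or 'weekly', got {resolution!r}")
    return OccasionMap(horizon=horizon, resolution=resolution, blocks=blocks)


@dataclass(frozen=True)
class EncounterHistory:
    animal_id: str
    cohort_label: str
    n_occasions: int
    entry_occasion: int
    exit_occasion: int
    fate: str  # died | censored | survived_to_horizon

    def __post_init__(self) -> None:
        if not (1 <= self.entry_occasion <= self.exit_occasion <= self.n_occasions):
            raise ValueError(
                f"need 1 <= entry ({self.entry_occasion}) <= exit "
                f"({self.exit_occasion}) <= n_occasions ({self.n_occasions})"
            )
        if self.fate not in (DIED, CENSORED, SURVIVED):
            raise ValueError(f"unknown fate {self.fate!r}")


def censored_exit_day(last_alive_age: int, retrieval_age: int, daily_phase: bool) -> int:
    """Day at which a shed-collar animal leaves the risk set.

    Daily monitoring: the collar retrieval day.  Weekly monitoring: the
    midpoint between last relocation alive and retrieval, rounded down.
    """
    if retrieval_age < last_alive_age:
        raise ValueError(
            f"retrieval ({retrieval_age}) before last relocation alive ({last_alive_age})"
        )
    if daily_phase:
        return retrieval_age
    return (last_alive_age + retrieval_age) // 2


def build_history(
    record: CaptureRecord,
    age_model: HoofGrowthModel | None,
    occasion_map: OccasionMap,
    daily_monitoring_until: int = 30,
    cohort_label: str | None = None,
) -> EncounterHistory | None:
    """Convert one capture record into an encounter history.

    ``age_model=None`` means the known-age cohort (entry class equals the
    true capture age, zero for filtered newborns).  Returns ``None``, with a
    warning, if the estimated entry day already exceeds the horizon.
    """
    if age_model is None:
        entry_class = record.true_age_at_capture
        label = cohort_label or KNOWN_AGE_LABEL
    else:
        if record.hoof_growth is None:
            raise ValueError(f"record {record.id} lacks a hoof-growth measurement")
        entry_class = estimate_age(age_model, record.hoof_growth).age_class
        label = cohort_label or age_model.label

    entry_day = entry_class + 1
    if entry_day > occasion_map.horizon:
        warnings.warn(
            f"animal {record.id}: estimated entry day {entry_day} exceeds "
            f"horizon {occasion_map.horizon}; excluded from the analysis",
            stacklevel=2,
        )
        return None
    entry_occ = occasion_map.block_of(entry_day)
    n_occ = occasion_map.n_occasions
    shift = entry_class - record.true_age_at_capture  # calendar day -> estimated age day

    if record.death_age is not None:
        est_day = record.death_age + shift
        if est_day > occasion_map.horizon:
            exit_occ, fate = n_occ, SURVIVED
        else:
            exit_occ, fate = occasion_map.block_of(est_day), DIED
    elif record.shed_age is not None:
        censor_day = censored_exit_day(
            record.last_alive_age,
            record.shed_age,
            daily_phase=record.shed_age <= daily_monitoring_until,
        )
        est_day = censor_day + shift
        if est_day > occasion_map.horizon:
            exit_occ, fate = n_occ, SURVIVED
        else:
            exit_occ, fate = max(occasion_map.block_of(est_day), entry_occ), CENSORED
    else:
        exit_occ, fate = n_occ, SURVIVED

    return EncounterHistory(
        animal_id=record.id,
        cohort_label=label,
        n_occasions=n_occ,
        entry_occasion=entry_occ,
        exit_occasion=exit_occ,
        fate=fate,
    )


def build_histories(
    records: Sequence[CaptureRecord],
    age_model: HoofGrowthModel | None,
    occasion_map: OccasionMap,
    daily_monitoring_until: int = 30,
    cohort_label: str | None = None,
) -> list[EncounterHistory]:
    out = []
    for r in records:
        h = build_history(
            r, age_model, occasion_map, daily_monitoring_until, cohort_label
        )
        if h is not None:
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# Program MARK known-fate .inp dialect (LDLD coding)
# ---------------------------------------------------------------------------

def _ldld_row(h: EncounterHistory) -> str:
    pairs = []
    for occ in range(1, h.n_occasions + 1):
        if occ < h.entry_occasion:
            pairs.append("00")
        elif occ < h.exit_occasion:
            pairs.append("10")
        elif occ == h.exit_occasion:
            pairs.append("11" if h.fate == DIED else "10")
        else:
            pairs.append("00")
    return " ".join(pairs)


def write_mark_inp(
    histories: Sequence[EncounterHistory],
    grouping: Sequence[str] | None = None,
    occasion_map: OccasionMap | None = None,
) -> str:
    """Emit Program MARK known-fate LDLD rows with per-group frequency
    columns.  All histories must share one occasion structure."""
    if not histories:
        raise ValueError("no histories to write")
    n_occ = {h.n_occasions for h in histories}
    if len(n_occ) != 1:
        raise ValueError(f"mixed occasion structures: {sorted(n_occ)}")
    if grouping is None:
        grouping = sorted({h.cohort_label for h in histories})
    unknown = {h.cohort_label for h in histories} - set(grouping)
    if unknown:
        raise ValueError(f"histories carry labels missing from grouping: {sorted(unknown)}")

    lines = [f"/* known-fate LDLD; groups: {' '.join(grouping)} */"]
    if occasion_map is not None:
        spans = " ".join(f"{lo}-{hi}" for lo, hi in occasion_map.blocks)
        lines.append(f"/* occasions (age days): {spans} */")
    for h in histories:
        freqs = " ".join("1" if g == h.cohort_label else "0" for g in grouping)
        lines.append(f"/* {h.animal_id} */ {_ldld_row(h)} {freqs};")
    return "\n".join(lines) + "\n"


def read_mark_inp(text: str) -> list[EncounterHistory]:
    """Parse an emitted ``.inp`` back into encounter histories.

    A censor in the final occasion is indistinguishable from survival to the
    horizon in LDLD coding (identical rows, identical likelihood); such rows
    parse as ``survived_to_horizon``.
    """
    groups: list[str] = []
    histories: list[EncounterHistory] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("/*") and line.endswith("*/"):
            body = line[2:-2].strip()
            if "groups:" in body:
                groups = body.split("groups:", 1)[1].split()
            continue
        animal_id = ""
        if line.startswith("/*"):
            end = line.index("*/")
            animal_id = line[2:end].strip()
            line = line[end + 2 :].strip()
        if not line.endswith(";"):
            raise ValueError(f"malformed .inp row: {raw!r}")
        tokens = line[:-1].split()
        if not groups:
            raise ValueError("missing groups header comment")
        pairs, freqs = tokens[: -len(groups)], tokens[-len(groups) :]
        label = groups[[int(f) for f in freqs].index(1)]
        n_occ = len(pairs)
        live = [i + 1 for i, p in enumerate(pairs) if p in ("10", "11")]
        entry, exit_ = live[0], live[-1]
        if pairs[exit_ - 1] == "11":
            fate = DIED
        elif exit_ == n_occ:
            fate = SURVIVED
        else:
            fate = CENSORED
        histories.append(
            EncounterHistory(
                animal_id=animal_id,
                cohort_label=label,
                n_occasions=n_occ,
                entry_occasion=entry,
                exit_occasion=exit_,
                fate=fate,
            )
        )
    return histories


_HCOLS = ["animal_id", "cohort_label", "n_occasions", "entry_occasion", "exit_occasion", "fate"]


def histories_to_dataframe(histories: Sequence[EncounterHistory]) -> pd.DataFrame:
    df = pd.DataFrame([{c: getattr(h, c) for c in _HCOLS} for h in histories])
    return df if not df.empty else pd.DataFrame(columns=_HCOLS)


def dataframe_to_histories(df: pd.DataFrame) -> list[EncounterHistory]:
    return [
        EncounterHistory(
            animal_id=str(r.animal_id),
            cohort_label=str(r.cohort_label),
            n_occasions=int(r.n_occasions),
            entry_occasion=int(r.entry_occasion),
            exit_occasion=int(r.exit_occasion),
            fate=str(r.fate),
        )
        for r in df.itertuples(index=False)
    ]
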