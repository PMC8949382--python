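"""Minute-epoch accelerometer processing.

Turns per-day count streams into wear/non-wear annotations, intensity
classes, bouts and day-level summaries, and applies the wear-time validity
filter at the participant-wave level.

Conventions implemented here:

* Non-wear: a maximal run of zero-count epochs totalling at least
  ``nonwear_window`` zero minutes, which may absorb interruptions of at most
  ``nonwear_allowance`` consecutive non-zero minutes.  Absorbed interruption
  minutes count as non-wear.  A stricter variant additionally requiring
  long zero runs flanking each interruption is available via
  ``strict_flanks``.
* Intensity classes for wear minutes: sedentary below 100 counts/min, light
  from 100 to 1951, moderate-to-vigorous at 1952 and above.
* Bouts are strictly consecutive runs of one class meeting a minimum
  length; runs truncated by the day boundary still count.
* A day is valid with >= 600 wear minutes; a participant-wave is retained
  with >= 3 valid days, and only valid days feed downstream features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: integer codes used for per-epoch intensity classes
NONWEAR, SB, LIPA, MVPA = 0, 1, 2, 3
INTENSITY_LABELS = {NONWEAR: "nonwear", SB: "SB", LIPA: "LIPA", MVPA: "MVPA"}

DAY_KEY = ["participant_id", "wave_month", "day_index"]
WAVE_KEY = ["participant_id", "wave_month"]


@dataclass(frozen=True)
class ProcessingRules:
    """Thresholds for wear, intensity, bout and validity rules."""

    nonwear_window: int = 90
    nonwear_allowance: int = 2
    sb_upper: int = 99
    lipa_upper: int = 1951
    mvpa_lower: int = 1952
    mvpa_bout_min: int = 10
    sb_bout_min: int = 30
    valid_day_wear: int = 600
    valid_file_days: int = 3
    guideline_weekly_mvpa: float = 150.0
    strict_flanks: bool = False
    flank_window: int = 30

    def __post_init__(self) -> None:
        if not (0 <= self.sb_upper < self.lipa_upper):
            raise ValueError("require sb_upper < lipa_upper")
        if self.mvpa_lower != self.lipa_upper + 1:
            raise ValueError("mvpa_lower must equal lipa_upper + 1")
        for name in ("nonwear_window", "mvpa_bout_min", "sb_bout_min",
                     "valid_day_wear", "valid_file_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nonwear_allowance < 0:
            raise ValueError("nonwear_allowance must be >= 0")


def _rle(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a 1-d array -> (starts, lengths, run values)."""
    n = len(values)
    if n == 0:
        return (np.empty(0, dtype=int),) * 3
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths, values[starts]


def detect_nonwear(counts: Sequence[int], rules: ProcessingRules | None = None) -> np.ndarray:
    """Return a boolean wear flag per epoch (True = worn).

    Scans maximal chains of zero runs linked by interruptions of at most
    ``nonwear_allowance`` consecutive non-zero epochs; a chain with at least
    ``nonwear_window`` zero minutes in total is marked non-wear end to end,
    interruptions included.
    """
    rules = rules or ProcessingRules()
    counts = np.asarray(counts)
    if counts.size == 0:
        return np.zeros(0, dtype=bool)
    if (counts < 0).any():
        raise ValueError("negative counts are not valid epoch data")
    starts, lengths, zero = _rle(counts == 0)
    wear = np.ones(counts.size, dtype=bool)
    n_runs = len(starts)
    i = 0
    while i < n_runs:
        if not zero[i]:
            i += 1
            continue
        zero_total = int(lengths[i])
        last = i
        j = i + 1
        # absorb (interruption, zero-run) pairs while the interruption is short
        while j + 1 < n_runs and lengths[j] <= rules.nonwear_allowance:
            if rules.strict_flanks and (
                lengths[j - 1] < rules.flank_window or lengths[j + 1] < rules.flank_window
            ):
                break
            zero_total += int(lengths[j + 1])
            last = j + 1
            j += 2
        if zero_total >= rules.nonwear_window:
            stop = starts[last] + lengths[last]
            wear[starts[i]:stop] = False
        i = last + 1
    return wear


def classify_intensity(
    counts: Sequence[int],
    wear: Sequence[bool],
    rules: ProcessingRules | None = None,
) -> np.ndarray:
    """Label each epoch NONWEAR/SB/LIPA/MVPA; non-wear takes precedence."""
    rules = rules or ProcessingRules()
    counts = np.asarray(counts)
    wear = np.asarray(wear, dtype=bool)
    if counts.shape != wear.shape:
        raise ValueError("counts and wear flags must align")
    if (counts < 0).any():
        raise ValueError("negative counts are not valid epoch data")
    out = np.full(counts.shape, NONWEAR, dtype=np.int8)
    out[wear & (counts <= rules.sb_upper)] = SB
    out[wear & (counts > rules.sb_upper) & (counts <= rules.lipa_upper)] = LIPA
    out[wear & (counts >= rules.mvpa_lower)] = MVPA
    return out


def detect_bouts(classes: Sequence[int], target: int, min_length: int) -> list[tuple[int, int]]:
    """Maximal strictly-consecutive runs of ``target`` with length >= min_length.

    Returns 0-based ``(start, length)`` pairs, half-open on the right.
    """
    classes = np.asarray(classes)
    starts, lengths, values = _rle(classes == target)
    return [
        (int(s), int(l))
        for s, l, v in zip(starts, lengths, values)
        if v and l >= min_length
    ]


@dataclass(frozen=True)
class DaySummary:
    wear_minutes: int
    sb_minutes: int
    lipa_minutes: int
    mvpa_minutes: int
    sb_bout_count: int
    sb_bout_minutes: int
    mvpa_bout_count: int
    mvpa_bout_minutes: int
    total_counts: int
    total_steps: int
    valid: bool


def summarise_day(
    counts: Sequence[int],
    steps: Sequence[int] | None = None,
    rules: ProcessingRules | None = None,
) -> DaySummary:
    """Process one day end to end and aggregate to a :class:`DaySummary`.

    Counts/steps totals are over wear epochs only.
    """
    rules = rules or ProcessingRules()
    counts = np.asarray(counts)
    steps = np.zeros_like(counts) if steps is None else np.asarray(steps)
    wear = detect_nonwear(counts, rules)
    classes = classify_intensity(counts, wear, rules)
    sb_bouts = detect_bouts(classes, SB, rules.sb_bout_min)
    mvpa_bouts = detect_bouts(classes, MVPA, rules.mvpa_bout_min)
    wear_minutes = int(wear.sum())
    return DaySummary(
        wear_minutes=wear_minutes,
        sb_minutes=int((classes == SB).sum()),
        lipa_minutes=int((classes == LIPA).sum()),
        mvpa_minutes=int((classes == MVPA).sum()),
        sb_bout_count=len(sb_bouts),
        sb_bout_minutes=int(sum(l for _, l in sb_bouts)),
        mvpa_bout_count=len(mvpa_bouts),
        mvpa_bout_minutes=int(sum(l for _, l in mvpa_bouts)),
        total_counts=int(counts[wear].sum()),
        total_steps=int(steps[wear].sum()),
        valid=wear_minutes >= rules.valid_day_wear,
    )


def process_epochs(epochs: pd.DataFrame, rules: ProcessingRules | None = None) -> pd.DataFrame:
    """Summarise an epoch table (one row per minute) into one row per day.

    Expects columns participant_id, wave_month, day_index, epoch_index,
    counts and (optionally) steps.
    """
    rules = rules or ProcessingRules()
    required = set(DAY_KEY + ["epoch_index", "counts"])
    missing = required - set(epochs.columns)
    if missing:
        raise ValueError(f"epoch table missing columns: {sorted(missing)}")
    has_steps = "steps" in epochs.columns
    rows = []
    for key, grp in epochs.groupby(DAY_KEY, sort=True):
        grp = grp.sort_values("epoch_index")
        summary = summarise_day(
            grp["counts"].to_numpy(),
            grp["steps"].to_numpy() if has_steps else None,
            rules,
        )
        rows.append(dict(zip(DAY_KEY, key)) | summary.__dict__)
    return pd.DataFrame(rows)


def filter_valid_waves(
    days: pd.DataFrame, rules: ProcessingRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the wear-time validity filter.

    Returns ``(retained_days, wave_table, accounting)`` where retained_days
    holds only valid days of retained participant-waves, wave_table has one
    row per input participant-wave with the retention decision, and
    accounting reports exclusion counts (participants with no retained wave
    are excluded from modelling entirely).
    """
    rules = rules or ProcessingRules()
    wave_rows = []
    for (pid, wave), grp in days.groupby(WAVE_KEY, sort=True):
        n_valid = int(grp["valid"].sum())
        wave_rows.append(
            {
                "participant_id": pid,
                "wave_month": wave,
                "n_days": len(grp),
                "n_valid_days": n_valid,
                "retained": n_valid >= rules.valid_file_days,
            }
        )
    waves = pd.DataFrame(wave_rows)
    if waves.empty:
        return days.iloc[0:0], waves, {"participants_in": 0, "participants_retained": 0,
                                       "participants_excluded": 0, "waves_in": 0,
                                       "waves_retained": 0, "waves_dropped": 0}
    retained_keys = waves.loc[waves["retained"], WAVE_KEY]
    retained = days.loc[days["valid"]].merge(retained_keys, on=WAVE_KEY, how="inner")
    participants_in = days["participant_id"].nunique()
    participants_kept = retained["participant_id"].nunique()
    accounting = {
        "participants_in": int(participants_in),
        "participants_retained": int(participants_kept),
        "participants_excluded": int(participants_in - participants_kept),
        "waves_in": int(len(waves)),
        "waves_retained": int(waves["retained"].sum()),
        "waves_dropped": int((~waves["retained"]).sum()),
    }
    return retained, waves, accounting


def weekly_mvpa(
    daily_mvpa_minutes: Iterable[float], rules: ProcessingRules | None = None
) -> tuple[float, bool]:
    """Mean daily moderate-to-vigorous minutes times 7, plus guideline flag."""
    rules = rules or ProcessingRules()
    values = np.asarray(list(daily_mvpa_minutes), dtype=float)
    if values.size == 0:
        raise ValueError("weekly_mvpa needs at least one valid day")
    minutes = float(values.mean() * 7.0)
    return minutes, minutes >= rules.guideline_weekly_mvpa


def wave_guidelines(retained_days: pd.DataFrame, rules: ProcessingRules | None = None) -> pd.DataFrame:
    """Per retained participant-wave: weekly minutes and guideline flag."""
    rules = rules or ProcessingRules()
    rows = []
    for (pid, wave), grp in retained_days.groupby(WAVE_KEY, sort=True):
        minutes, flag = weekly_mvpa(grp["mvpa_minutes"], rules)
        rows.append(
            {
                "participant_id": pid,
                "wave_month": wave,
                "weekly_mvpa_minutes": minutes,
                "meets_guideline": flag,
            }
        )
    return pd.DataFrame(rows)
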