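"""Accelerometer count scoring: MVPA bouts and wear-time validity.

Minute-level vertical-axis counts from a hip-worn device are scored as
MVPA when they fall inside a *bout*: a run of consecutive worn minutes
at or above a count threshold (default 1952 counts/min) lasting at
least a minimum duration (default 10 minutes).  Runs are broken by
non-wear, by below-threshold minutes (unless an interruption allowance
is configured), and by gaps in the minute grid.

A measurement week is valid when the participant wore the device at
least 10 hours on at least 5 days, or accumulated at least 3000 wear
minutes over at least 4 days with any wear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "MVPA_COUNT_THRESHOLD",
    "MIN_BOUT_MINUTES",
    "CountStream",
    "mvpa_minutes",
    "wear_valid",
    "detect_nonwear",
    "score_weekly",
]

#: Vertical-axis counts/min at or above which a minute is MVPA.
MVPA_COUNT_THRESHOLD = 1952

#: Minimum consecutive minutes for a run to count as a bout.
MIN_BOUT_MINUTES = 10


@dataclass(frozen=True)
class CountStream:
    """Minute-level counts for one participant.

    ``data`` needs columns ``timestamp`` (minute resolution), ``counts``
    (nonnegative integers) and ``worn`` (0/1).  Timestamps must be
    strictly increasing; scoring breaks bouts across any gap larger
    than one minute.
    """

    participant_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("timestamp", "counts", "worn"):
            if col not in df.columns:
                raise InvalidParameterError(f"count stream missing column {col!r}")
        ts = pd.to_datetime(df["timestamp"])
        if len(ts) and (ts.dt.second.ne(0).any() or ts.dt.microsecond.ne(0).any()):
            raise InvalidParameterError("timestamps must be at minute resolution")
        deltas = ts.diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            raise InvalidParameterError("timestamps must be strictly increasing")
        if len(deltas) and (deltas.dt.total_seconds() % 60 != 0).any():
            raise InvalidParameterError("timestamps must fall on a one-minute grid")
        if (df["counts"] < 0).any():
            raise InvalidParameterError("counts must be nonnegative")
        object.__setattr__(self, "data", df.assign(timestamp=ts).reset_index(drop=True))

    @property
    def counts(self) -> np.ndarray:
        return self.data["counts"].to_numpy()

    @property
    def worn(self) -> np.ndarray:
        return self.data["worn"].to_numpy().astype(bool)

    def contiguous_blocks(self) -> list[tuple[int, int]]:
        """Index ranges [i, j) of gap-free one-minute runs."""
        ts = self.data["timestamp"]
        if ts.empty:
            return []
        gaps = ts.diff().dt.total_seconds().to_numpy()[1:] != 60.0
        breaks = np.flatnonzero(gaps) + 1
        edges = [0, *breaks.tolist(), len(ts)]
        return list(zip(edges[:-1], edges[1:]))

    def wear_minutes_per_day(self) -> pd.Series:
        return self.data.groupby(self.data["timestamp"].dt.date)["worn"].sum()


def _bout_minutes_in_block(
    above: np.ndarray, worn: np.ndarray, min_bout: int, interruption_allowance: int
) -> int:
    """Count above-threshold minutes lying in qualifying bouts.

    With a nonzero allowance, maximal above-threshold runs separated by
    at most ``interruption_allowance`` worn below-threshold minutes are
    merged; a merged bout qualifies when its above-threshold minutes
    total at least ``min_bout``.  Only above-threshold minutes are
    credited.
    """
    qual = above & worn
    if not qual.any():
        return 0
    # run-length encode qualifying minutes
    padded = np.concatenate(([False], qual, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive

    runs = list(zip(starts, ends))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged:
            ps, pe = merged[-1][0], merged[-1][1]
            gap = slice(pe, s)
            gap_ok = (
                s - pe <= interruption_allowance
                and worn[gap].all()  # non-wear always breaks a bout
            )
            if gap_ok:
                merged[-1][1] = e
                merged[-1][2] += e - s
                continue
        merged.append([s, e, e - s])
    return sum(above_len for _, _, above_len in merged if above_len >= min_bout)


def mvpa_minutes(
    stream: CountStream,
    threshold: float = MVPA_COUNT_THRESHOLD,
    min_bout: int = MIN_BOUT_MINUTES,
    interruption_allowance: int = 0,
) -> int:
    """Total MVPA minutes in a stream under the threshold-and-bout rule."""
    if threshold < 0:
        raise InvalidParameterError(f"threshold must be >= 0, got {threshold}")
    if min_bout < 1:
        raise InvalidParameterError(f"min_bout must be >= 1, got {min_bout}")
    if interruption_allowance < 0:
        raise InvalidParameterError("interruption_allowance must be >= 0")
    total = 0
    counts, worn = stream.counts, stream.worn
    for i, j in stream.contiguous_blocks():
        total += _bout_minutes_in_block(
            counts[i:j] >= threshold, worn[i:j], min_bout, interruption_allowance
        )
    return int(total)


def wear_valid(day_wear_minutes) -> bool:
    """Wear-validity rule for one measurement week.

    True iff at least 5 days have >= 600 wear minutes, or total wear is
    >= 3000 minutes spread over at least 4 days with any wear.
    """
    days = np.asarray(list(day_wear_minutes), dtype=float)
    if days.size == 0 or days.size > 7:
        raise InvalidParameterError(
            f"expected wear minutes for 1-7 days, got {days.size}"
        )
    if ((days < 0) | (days > 1440)).any():
        raise InvalidParameterError("daily wear minutes must lie in [0, 1440]")
    ten_hour_days = int((days >= 600).sum())
    any_wear_days = int((days > 0).sum())
    return bool(ten_hour_days >= 5 or (days.sum() >= 3000 and any_wear_days >= 4))


def detect_nonwear(counts: np.ndarray, min_zero_run: int = 60) -> np.ndarray:
    """Heuristic wear flags: runs of >= ``min_zero_run`` consecutive zero
    counts are marked not worn.  Off by default in scoring — supplied
    wear flags take precedence when available."""
    counts = np.asarray(counts)
    worn = np.ones(counts.shape, dtype=bool)
    zero = counts == 0
    padded = np.concatenate(([False], zero, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        if e - s >= min_zero_run:
            worn[s:e] = False
    return worn


def score_weekly(
    streams: dict[str, CountStream],
    threshold: float = MVPA_COUNT_THRESHOLD,
    min_bout: int = MIN_BOUT_MINUTES,
    interruption_allowance: int = 0,
) -> pd.DataFrame:
    """Score one measurement week per participant.

    Returns a frame with columns participant_id, mvpa_minutes, valid.
    """
    rows = []
    for pid, stream in streams.items():
        rows.append(
            {
                "participant_id": pid,
                "mvpa_minutes": mvpa_minutes(
                    stream, threshold, min_bout, interruption_allowance
                ),
                "valid": wear_valid(stream.wear_minutes_per_day().to_numpy()),
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "mvpa_minutes", "valid"])
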