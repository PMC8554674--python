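"""Epoch-level activity-count I/O, nonwear-day removal, and daily profiles.

The on-disk dialect is a plain UTF-8 CSV with a header row and columns
``subject_id,day_index,epoch_index,count``; ``epoch_index`` runs from 0 to
``epochs_per_day - 1`` within each day.  Counts are nonnegative; each
subject's rows are ordered by ``(day_index, epoch_index)`` and every day must
be complete (exactly ``epochs_per_day`` rows).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, FormatError, ValidationError

SECONDS_PER_DAY = 86400
MINUTES_PER_DAY = 1440

EPOCH_CSV_COLUMNS = ("subject_id", "day_index", "epoch_index", "count")

#: Default fraction of zero-count epochs at or above which a day is nonwear.
DEFAULT_ZERO_FRACTION_THRESHOLD = 0.95

# Stable float formatting used by every CSV writer so that repeated runs are
# byte-identical.
FLOAT_FORMAT = "%.12g"


@dataclasses.dataclass
class EpochSeries:
    """One subject's epoch-level activity counts with whole-day structure.

    ``counts`` holds the retained days back to back; ``day_indices`` maps each
    retained day (in order) to its original ``day_index`` in the source file,
    so nonwear removal keeps an audit trail.
    """

    subject_id: str
    counts: np.ndarray
    epoch_seconds: int = 60
    day_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.epoch_seconds <= 0 or SECONDS_PER_DAY % self.epoch_seconds:
            raise ValidationError(
                f"epoch_seconds={self.epoch_seconds} must divide {SECONDS_PER_DAY}"
            )
        if self.counts.ndim != 1:
            raise ValidationError("counts must be one-dimensional")
        if self.counts.size == 0 or self.counts.size % self.epochs_per_day:
            raise ValidationError(
                f"subject {self.subject_id!r}: counts length {self.counts.size} is "
                f"not a positive multiple of epochs_per_day={self.epochs_per_day}"
            )
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValidationError(
                f"subject {self.subject_id!r}: counts must be finite and >= 0"
            )
        if not self.day_indices:
            self.day_indices = tuple(range(self.n_days))
        elif len(self.day_indices) != self.n_days:
            raise ValidationError(
                f"subject {self.subject_id!r}: {len(self.day_indices)} day indices "
                f"for {self.n_days} days"
            )

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_seconds

    @property
    def n_days(self) -> int:
        return self.counts.size // self.epochs_per_day

    @property
    def day_flags(self) -> tuple[bool, ...]:
        """Wear flags for the days currently held (always True: removed days
        are dropped from ``counts``, not kept)."""
        return (True,) * self.n_days

    def day_matrix(self) -> np.ndarray:
        """Counts reshaped to (n_days, epochs_per_day); a view when possible."""
        return self.counts.reshape(self.n_days, self.epochs_per_day)


def read_epoch_csv(path, epoch_seconds: int = 60) -> list[EpochSeries]:
    """Read an epoch CSV into one :class:`EpochSeries` per subject.

    Subjects appear in order of first appearance.  Raises
    :class:`FormatError` for missing columns and :class:`ValidationError` for
    negative counts or ragged (incomplete) days.
    """
    try:
        frame = pd.read_csv(
            path, dtype={"subject_id": str}, float_precision="round_trip"
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse epoch CSV {path}: {exc}") from exc
    missing = [c for c in EPOCH_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"epoch CSV {path} is missing columns {missing}")
    if len(frame) == 0:
        raise FormatError(f"epoch CSV {path} has no data rows")
    counts = pd.to_numeric(frame["count"], errors="coerce")
    if counts.isna().any():
        bad = frame.loc[counts.isna()].index[0]
        raise ValidationError(f"non-numeric count at row {bad}")
    if (counts < 0).any():
        bad = frame.loc[(counts < 0)].iloc[0]
        raise ValidationError(
            f"negative count for subject {bad['subject_id']!r}, "
            f"day {int(bad['day_index'])}"
        )
    frame = frame.assign(count=counts.astype(float))

    epochs_per_day = SECONDS_PER_DAY // epoch_seconds
    cohort: list[EpochSeries] = []
    for subject_id, sub in frame.groupby("subject_id", sort=False):
        sub = sub.sort_values(["day_index", "epoch_index"], kind="stable")
        day_indices: list[int] = []
        day_blocks: list[np.ndarray] = []
        for day_index, day in sub.groupby("day_index", sort=True):
            if len(day) != epochs_per_day:
                raise ValidationError(
                    f"subject {subject_id!r}, day {int(day_index)}: "
                    f"{len(day)} rows, expected {epochs_per_day}"
                )
            eidx = day["epoch_index"].to_numpy()
            if not np.array_equal(eidx, np.arange(epochs_per_day)):
                raise ValidationError(
                    f"subject {subject_id!r}, day {int(day_index)}: epoch_index "
                    f"must be 0..{epochs_per_day - 1} exactly once each"
                )
            day_indices.append(int(day_index))
            day_blocks.append(day["count"].to_numpy())
        cohort.append(
            EpochSeries(
                subject_id=str(subject_id),
                counts=np.concatenate(day_blocks),
                epoch_seconds=epoch_seconds,
                day_indices=tuple(day_indices),
            )
        )
    return cohort


def write_epoch_csv(cohort: Iterable[EpochSeries], path) -> None:
    """Write a cohort back to the epoch CSV dialect (lossless round trip)."""
    frames = []
    for series in cohort:
        epd = series.epochs_per_day
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": series.subject_id,
                    "day_index": np.repeat(series.day_indices, epd),
                    "epoch_index": np.tile(np.arange(epd), series.n_days),
                    "count": series.counts,
                }
            )
        )
    if not frames:
        raise ValidationError("cannot write an empty cohort")
    # no float_format: repr round-trips counts exactly and is byte-stable
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def clean_nonwear_days(
    series: EpochSeries,
    zero_fraction_threshold: float = DEFAULT_ZERO_FRACTION_THRESHOLD,
) -> EpochSeries:
    """Drop days whose fraction of zero-count epochs is >= the threshold.

    Remaining days are concatenated in their original order and the mapping to
    original day indices is retained in ``day_indices``.  Raises
    :class:`EmptySeriesError` when every day is removed.
    """
    if not 0.0 <= zero_fraction_threshold <= 1.0:
        raise ValidationError("zero_fraction_threshold must be in [0, 1]")
    days = series.day_matrix()
    zero_fraction = (days == 0).mean(axis=1)
    keep = zero_fraction < zero_fraction_threshold
    if not keep.any():
        raise EmptySeriesError(
            f"subject {series.subject_id!r}: all {series.n_days} days flagged nonwear"
        )
    return EpochSeries(
        subject_id=series.subject_id,
        counts=days[keep].reshape(-1),
        epoch_seconds=series.epoch_seconds,
        day_indices=tuple(
            idx for idx, k in zip(series.day_indices, keep) if k
        ),
    )


def clean_cohort(
    cohort: Sequence[EpochSeries],
    zero_fraction_threshold: float = DEFAULT_ZERO_FRACTION_THRESHOLD,
    drop_empty: bool = True,
) -> list[EpochSeries]:
    """Apply :func:`clean_nonwear_days` to every subject.

    With ``drop_empty`` (default) subjects whose days are all nonwear are
    excluded; otherwise the per-subject :class:`EmptySeriesError` propagates.
    """
    cleaned = []
    for series in cohort:
        try:
            cleaned.append(clean_nonwear_days(series, zero_fraction_threshold))
        except EmptySeriesError:
            if not drop_empty:
                raise
    return cleaned


def daily_profile(series: EpochSeries) -> np.ndarray:
    """Mean activity at each within-day epoch across retained days."""
    return series.day_matrix().mean(axis=0)
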