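"""Per-subject periodicity signals on a shared period grid.

For a cohort truncated to a common record length of ``D`` days sampled every
epoch, the one-sided discrete Fourier bins ``k = 1 .. L//2`` (``L`` epochs
total) correspond to periods ``D * 1440 / k`` minutes.  The "periodicity
signal" of subject ``i`` at bin ``k`` is the amplitude-scaled modulus
``(2/L) * |c_k|`` of the DFT of the mean-centered series, so a pure cosine of
amplitude ``a`` at a grid frequency yields a signal of exactly ``a``.  That
scaling makes the signal identical to the least-squares cosine-model amplitude
at the same period (see :func:`cosinor_amplitudes`).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .io import EpochSeries, FLOAT_FORMAT, MINUTES_PER_DAY

#: Relative tolerance when matching a requested period to a grid bin.
_GRID_RTOL = 1e-9


@dataclasses.dataclass
class SpectrumMatrix:
    """n x p matrix of periodicity signals; rows = subjects, columns = periods
    (minutes, strictly decreasing)."""

    subject_ids: tuple[str, ...]
    periods_minutes: np.ndarray
    magnitudes: np.ndarray
    record_days: int
    epochs_per_day: int = 1440

    def __post_init__(self) -> None:
        self.periods_minutes = np.asarray(self.periods_minutes, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 2:
            raise ValidationError("magnitudes must be a 2-D array")
        n, p = self.magnitudes.shape
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length must match magnitude rows")
        if self.periods_minutes.size != p:
            raise ValidationError("periods length must match magnitude columns")
        if p and np.any(np.diff(self.periods_minutes) >= 0):
            raise ValidationError("periods must be strictly decreasing")
        if np.any(self.magnitudes < 0):
            raise ValidationError("magnitudes must be nonnegative")

    @property
    def n(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def p(self) -> int:
        return self.magnitudes.shape[1]

    def column(self, period_minutes: float) -> np.ndarray:
        """The magnitude column for a period on the grid."""
        j = period_index(self.periods_minutes, period_minutes)
        return self.magnitudes[:, j]


def period_grid(record_days: int, epochs_per_day: int = 1440) -> np.ndarray:
    """Periods (minutes) of the one-sided DFT bins for a D-day record.

    Bin ``k`` maps to period ``D * 1440 / k``; ``k`` runs 1..L//2 with
    ``L = record_days * epochs_per_day``, giving strictly decreasing periods.
    """
    if record_days < 1:
        raise ValidationError("record_days must be >= 1")
    total_epochs = record_days * epochs_per_day
    k = np.arange(1, total_epochs // 2 + 1)
    return record_days * MINUTES_PER_DAY / k


def period_index(periods_minutes: np.ndarray, period_minutes: float) -> int:
    """Index of ``period_minutes`` in a grid, matched to relative tolerance."""
    periods_minutes = np.asarray(periods_minutes, dtype=float)
    j = int(np.argmin(np.abs(periods_minutes - period_minutes)))
    if not np.isclose(periods_minutes[j], period_minutes, rtol=_GRID_RTOL, atol=0):
        raise ValidationError(
            f"period {period_minutes} min is not on the frequency grid"
        )
    return j


def compute_spectrum(
    cohort: Sequence[EpochSeries], target_days: int | None = None
) -> SpectrumMatrix:
    """Periodicity-signal matrix of a cohort on one shared period grid.

    Each subject's counts are truncated to the first ``target_days`` retained
    days (default: the cohort minimum so nobody is excluded), mean-centered,
    and transformed; entry ``(i, j)`` is ``(2/L) |c_{k_j}|``.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    epoch_seconds = cohort[0].epoch_seconds
    if any(s.epoch_seconds != epoch_seconds for s in cohort):
        raise ValidationError("all subjects must share one epoch length")
    if target_days is None:
        target_days = min(s.n_days for s in cohort)
    if target_days < 1:
        raise ValidationError("target_days must be >= 1")
    short = [s.subject_id for s in cohort if s.n_days < target_days]
    if short:
        raise ValidationError(
            f"subjects with fewer than {target_days} retained days: {short}"
        )

    epochs_per_day = cohort[0].epochs_per_day
    length = target_days * epochs_per_day
    p = length // 2
    magnitudes = np.empty((len(cohort), p))
    for i, series in enumerate(cohort):
        x = series.counts[:length]
        coeffs = np.fft.rfft(x - x.mean())
        magnitudes[i] = (2.0 / length) * np.abs(coeffs[1 : p + 1])
    return SpectrumMatrix(
        subject_ids=tuple(s.subject_id for s in cohort),
        periods_minutes=period_grid(target_days, epochs_per_day),
        magnitudes=magnitudes,
        record_days=target_days,
        epochs_per_day=epochs_per_day,
    )


def variance_fractions(magnitudes_row: np.ndarray) -> np.ndarray:
    """Squared-magnitude fractions of one spectrum row; sums to 1."""
    row = np.asarray(magnitudes_row, dtype=float)
    if np.any(row < 0):
        raise ValidationError("magnitudes must be nonnegative")
    energy = row**2
    total = energy.sum()
    if total == 0:
        raise ValidationError("variance fractions undefined for an all-zero row")
    return energy / total


def cosinor_amplitudes(
    cohort: Sequence[EpochSeries],
    period_minutes: float,
    target_days: int | None = None,
) -> np.ndarray:
    """Least-squares cosine-model amplitude per subject at one grid period.

    Fits ``counts ~ m + A cos(2 pi t / T) + B sin(2 pi t / T)`` over the
    truncated record and returns ``sqrt(A^2 + B^2)``.  Only periods on the
    shared frequency grid are accepted: at Fourier frequencies the design is
    orthogonal and the amplitude coincides with the spectrum entry.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    if target_days is None:
        target_days = min(s.n_days for s in cohort)
    epochs_per_day = cohort[0].epochs_per_day
    # validates that the period sits on the grid of the truncated record
    period_index(period_grid(target_days, epochs_per_day), period_minutes)

    length = target_days * epochs_per_day
    epoch_minutes = cohort[0].epoch_seconds / 60.0
    t = np.arange(length) * epoch_minutes
    omega = 2.0 * np.pi / period_minutes
    design = np.column_stack(
        [np.ones(length), np.cos(omega * t), np.sin(omega * t)]
    )
    amplitudes = np.empty(len(cohort))
    for i, series in enumerate(cohort):
        if series.n_days < target_days:
            raise ValidationError(
                f"subject {series.subject_id!r} has fewer than {target_days} days"
            )
        beta, *_ = np.linalg.lstsq(design, series.counts[:length], rcond=None)
        amplitudes[i] = float(np.hypot(beta[1], beta[2]))
    return amplitudes


def filter_periods(
    spectrum: SpectrumMatrix,
    min_period_minutes: float | None = None,
    max_period_minutes: float | None = None,
) -> SpectrumMatrix:
    """Restrict columns to min <= period <= max (post-hoc column filter)."""
    keep = np.ones(spectrum.p, dtype=bool)
    if min_period_minutes is not None:
        keep &= spectrum.periods_minutes >= min_period_minutes
    if max_period_minutes is not None:
        keep &= spectrum.periods_minutes <= max_period_minutes
    if not keep.any():
        raise ValidationError("period filter removed every column")
    return SpectrumMatrix(
        subject_ids=spectrum.subject_ids,
        periods_minutes=spectrum.periods_minutes[keep],
        magnitudes=spectrum.magnitudes[:, keep],
        record_days=spectrum.record_days,
        epochs_per_day=spectrum.epochs_per_day,
    )


def write_spectrum_csv(spectrum: SpectrumMatrix, path) -> None:
    """Write the matrix as CSV: a ``#`` metadata line, then subject_id plus one
    column per period (named by period in minutes, 6 decimals)."""
    frame = pd.DataFrame(
        spectrum.magnitudes,
        columns=[f"{p:.6f}" for p in spectrum.periods_minutes],
    )
    frame.insert(0, "subject_id", list(spectrum.subject_ids))
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            f"# record_days={spectrum.record_days},"
            f"epochs_per_day={spectrum.epochs_per_day}\n"
        )
        frame.to_csv(handle, index=False, float_format=FLOAT_FORMAT)


def read_spectrum_csv(path) -> SpectrumMatrix:
    """Read a matrix written by :func:`write_spectrum_csv`."""
    with open(path, "r", encoding="utf-8") as handle:
        meta_line = handle.readline().strip()
        if not meta_line.startswith("#"):
            raise FormatError(f"{path}: missing '# record_days=...' metadata line")
        try:
            meta = dict(
                item.split("=") for item in meta_line.lstrip("# ").split(",")
            )
            record_days = int(meta["record_days"])
            epochs_per_day = int(meta["epochs_per_day"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: malformed metadata line") from exc
        frame = pd.read_csv(handle, dtype={"subject_id": str})
    if "subject_id" not in frame.columns:
        raise FormatError(f"{path}: missing subject_id column")
    period_cols = [c for c in frame.columns if c != "subject_id"]
    try:
        periods = np.array([float(c) for c in period_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric period column name") from exc
    # snap the 6-decimal column names back to exact grid periods D*1440/k
    total_minutes = record_days * MINUTES_PER_DAY
    bins = np.rint(total_minutes / periods)
    exact = total_minutes / bins
    if np.max(np.abs(exact - periods)) > 1e-3:
        raise FormatError(f"{path}: period columns do not sit on the bin grid")
    periods = exact
    return SpectrumMatrix(
        subject_ids=tuple(frame["subject_id"]),
        periods_minutes=periods,
        magnitudes=frame[period_cols].to_numpy(dtype=float),
        record_days=record_days,
        epochs_per_day=epochs_per_day,
    )
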