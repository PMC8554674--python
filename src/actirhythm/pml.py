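"""Penalized diagonal selection of dominant periodicities.

Given the n x p periodicity-signal matrix ``X``, a diagonal matrix ``Theta``
with entries ``theta_j`` in [0, 1] is chosen to minimize

    ||X - X Theta||_F^2 + lambda * (alpha * sum_j theta_j
                                    + (1 - alpha)/2 * sum_j theta_j^2)

The objective separates per coordinate, so the minimizer has the closed form

    theta_j = clip((2 ||x_j||^2 - alpha lambda)
                   / (2 ||x_j||^2 + (1 - alpha) lambda), 0, 1)

and, for alpha > 0, column j becomes active exactly when lambda drops below
``2 ||x_j||^2 / alpha``.  Decreasing lambda therefore admits periodicities in
descending order of spectral energy; the reconstruction error
``||X - X Theta||_F^2 = sum_j (1 - theta_j)^2 ||x_j||^2`` is tracked along the
path and used to pick how many periodicities to keep.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import FLOAT_FORMAT
from .spectrum import SpectrumMatrix


@dataclasses.dataclass(frozen=True)
class PMLConfig:
    """Estimator settings.

    alpha balances the L1 and L2 penalty terms (1 = pure L1, the default).
    lambda_grid, when given, overrides the default knots (the exact entry
    lambdas plus lambda_max and 0).  mse_normalized divides the squared
    Frobenius error by n*p.
    """

    alpha: float = 1.0
    lambda_grid: tuple[float, ...] | None = None
    mse_normalized: bool = True
    max_knots: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.max_knots is not None and self.max_knots < 1:
            raise ValidationError("max_knots must be >= 1")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0 or np.any(grid < 0):
                raise ValidationError("lambda_grid must be nonnegative")
            if np.any(np.diff(grid) >= 0):
                raise ValidationError("lambda_grid must be strictly decreasing")


@dataclasses.dataclass(frozen=True)
class PathKnot:
    lam: float
    theta: np.ndarray
    mse: float
    active_set: frozenset[int]


@dataclasses.dataclass
class PMLPath:
    """Solution path: knots in strictly decreasing lambda, plus the column
    energies and the deterministic entry order of the columns."""

    knots: list[PathKnot]
    column_norms_sq: np.ndarray
    entry_order: tuple[int, ...]
    periods_minutes: np.ndarray
    alpha: float
    mse_normalized: bool

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([k.lam for k in self.knots])

    @property
    def mses(self) -> np.ndarray:
        return np.array([k.mse for k in self.knots])

    @property
    def active_sizes(self) -> np.ndarray:
        return np.array([len(k.active_set) for k in self.knots])


def column_norms_sq(X: SpectrumMatrix | np.ndarray) -> np.ndarray:
    """Per-column squared Euclidean norms (the diagonal of X^T X)."""
    mat = X.magnitudes if isinstance(X, SpectrumMatrix) else np.asarray(X, float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValidationError("X must be a 2-D matrix with at least one row")
    return np.einsum("ij,ij->j", mat, mat)


def theta_solution(
    norms_sq: np.ndarray, lam: float, alpha: float = 1.0
) -> np.ndarray:
    """Closed-form per-coordinate minimizer, clipped to [0, 1].

    Zero-energy columns get theta = 0 for every lambda (including 0), since
    they carry no signal and the stationarity condition is degenerate there.
    """
    norms_sq = np.asarray(norms_sq, dtype=float)
    if np.any(norms_sq < 0):
        raise ValidationError("column norms must be nonnegative")
    if lam < 0:
        raise ValidationError("lambda must be nonnegative")
    numer = 2.0 * norms_sq - alpha * lam
    denom = 2.0 * norms_sq + (1.0 - alpha) * lam
    theta = np.zeros_like(norms_sq)
    ok = denom > 0
    with np.errstate(over="ignore"):  # inf from tiny denominators clips to 1
        theta[ok] = np.clip(numer[ok] / denom[ok], 0.0, 1.0)
    theta[norms_sq == 0] = 0.0
    return theta


def entry_lambda(norm_sq: float, alpha: float) -> float:
    """Largest lambda at which a column's theta becomes positive: 2||x||^2/alpha."""
    if alpha <= 0:
        raise ValidationError(
            "entry lambdas require alpha > 0 (with alpha = 0 every theta is "
            "positive at all finite lambda)"
        )
    if norm_sq < 0:
        raise ValidationError("column norm must be nonnegative")
    return 2.0 * norm_sq / alpha


def mse(
    X: SpectrumMatrix | np.ndarray,
    theta: np.ndarray,
    normalized: bool = True,
) -> float:
    """Reconstruction error ||X - X Theta||_F^2 = sum_j (1-theta_j)^2 ||x_j||^2,
    optionally divided by n*p."""
    mat = X.magnitudes if isinstance(X, SpectrumMatrix) else np.asarray(X, float)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (mat.shape[1],):
        raise ValidationError(
            f"theta has length {theta.size}, expected {mat.shape[1]}"
        )
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValidationError("theta components must be in [0, 1]")
    value = float(np.sum((1.0 - theta) ** 2 * column_norms_sq(mat)))
    if normalized:
        value /= mat.shape[0] * mat.shape[1]
    return value


def _entry_order(norms_sq: np.ndarray, periods_minutes: np.ndarray) -> tuple[int, ...]:
    # Descending energy; ties broken toward the longer period.  The period
    # grid is strictly decreasing, so a smaller column index is a longer
    # period and plain index order settles ties.
    return tuple(sorted(range(norms_sq.size), key=lambda j: (-norms_sq[j], j)))


def solution_path(X: SpectrumMatrix, config: PMLConfig | None = None) -> PMLPath:
    """Trace theta, reconstruction error, and active sets over lambda.

    Default knots are the distinct entry lambdas in decreasing order (the
    largest doubles as lambda_max, where every theta is 0) followed by
    lambda = 0; between consecutive entries the path is smooth, so these are
    the only points where the active set changes.  ``config.max_knots``
    truncates the path after that many entry knots (dropping the final
    lambda = 0 knot); the entry order is unaffected.
    """
    config = config or PMLConfig()
    norms_sq = column_norms_sq(X)
    if norms_sq.size == 0:
        raise ValidationError("X has no columns")
    periods = np.asarray(X.periods_minutes, dtype=float)

    if config.lambda_grid is not None:
        lambdas = [float(l) for l in config.lambda_grid]
    else:
        if config.alpha <= 0:
            raise ValidationError(
                "alpha = 0 has no entry knots; supply an explicit lambda_grid"
            )
        entries = {entry_lambda(ns, config.alpha) for ns in norms_sq if ns > 0}
        if not entries:
            raise ValidationError("every column of X has zero energy")
        lambdas = sorted(entries, reverse=True)
        if config.max_knots is not None and len(lambdas) > config.max_knots:
            # wide period grids make the full path O(p^2); keep the largest
            # entry knots (the dominant periodicities) and stop there
            lambdas = lambdas[: config.max_knots]
        else:
            lambdas = lambdas + [0.0]

    n, p = X.magnitudes.shape
    knots = []
    for lam in lambdas:
        theta = theta_solution(norms_sq, lam, config.alpha)
        knots.append(
            PathKnot(
                lam=lam,
                theta=theta,
                mse=float(np.sum((1.0 - theta) ** 2 * norms_sq))
                / ((n * p) if config.mse_normalized else 1),
                active_set=frozenset(np.flatnonzero(theta > 0).tolist()),
            )
        )
    return PMLPath(
        knots=knots,
        column_norms_sq=norms_sq,
        entry_order=_entry_order(norms_sq, periods),
        periods_minutes=periods,
        alpha=config.alpha,
        mse_normalized=config.mse_normalized,
    )


def select_dominant(path: PMLPath, n_select: int | str) -> list[int]:
    """First periodicities admitted along the path, as column indices.

    ``n_select`` is either a count (the first that many entries, in entry
    order) or the string ``"elbow"``: over the knots where the active-set size
    increases, pick the count m maximizing the error-drop ratio
    ``(MSE_{m-1} - MSE_m) / (MSE_m - MSE_{m+1})`` — an explicit, documented
    stand-in for choosing the dip in the error curve by eye.
    """
    if not path.knots:
        raise ValidationError("path has no knots")
    p = path.column_norms_sq.size
    if n_select == "elbow":
        sizes, errors = _increment_curve(path)
        if len(sizes) < 3:
            return [path.entry_order[0]] if p else []
        tiny = 1e-15 * max(errors[0], 1.0)
        best_m, best_ratio = sizes[1], -np.inf
        for i in range(1, len(sizes) - 1):
            drop = errors[i - 1] - errors[i]
            next_drop = max(errors[i] - errors[i + 1], tiny)
            ratio = drop / next_drop
            if ratio > best_ratio:
                best_ratio, best_m = ratio, sizes[i]
        return list(path.entry_order[:best_m])
    if not isinstance(n_select, (int, np.integer)):
        raise ValidationError("n_select must be a positive integer or 'elbow'")
    if n_select < 1:
        raise ValidationError("n_select must be >= 1")
    if n_select > p:
        raise ValidationError(f"n_select={n_select} exceeds p={p}")
    return list(path.entry_order[:n_select])


def _increment_curve(path: PMLPath) -> tuple[list[int], list[float]]:
    """(active-set size, error) at each knot where the size increases,
    starting from the all-zero knot."""
    sizes: list[int] = []
    errors: list[float] = []
    for knot in path.knots:
        size = len(knot.active_set)
        if not sizes or size > sizes[-1]:
            sizes.append(size)
            errors.append(knot.mse)
    return sizes, errors


def write_path_json(path: PMLPath, file_path) -> None:
    """Export the path as a JSON list of knots."""
    payload = [
        {
            "lambda": knot.lam,
            "mse": knot.mse,
            "active_periods_minutes": sorted(
                (float(path.periods_minutes[j]) for j in knot.active_set),
                reverse=True,
            ),
            "theta": [float(v) for v in knot.theta],
        }
        for knot in path.knots
    ]
    with open(file_path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1)
        handle.write("\n")


def selection_report(path: PMLPath, selected: list[int]) -> pd.DataFrame:
    """Tabular report for selected columns: rank, period, entry lambda,
    energy, and cumulative error drop from the empty model."""
    sizes, errors = _increment_curve(path)
    error_at_size = dict(zip(sizes, errors))
    base = errors[0] if errors else 0.0
    rows = []
    cum_size = 0
    for rank, j in enumerate(selected, start=1):
        cum_size += 1
        drop = base - error_at_size.get(cum_size, np.nan)
        rows.append(
            {
                "rank": rank,
                "period_minutes": float(path.periods_minutes[j]),
                "entry_lambda": entry_lambda(
                    float(path.column_norms_sq[j]), path.alpha
                )
                if path.alpha > 0
                else np.nan,
                "norm_sq": float(path.column_norms_sq[j]),
                "cumulative_mse_drop": drop,
            }
        )
    return pd.DataFrame(rows)


def write_selection_csv(path: PMLPath, selected: list[int], file_path) -> None:
    selection_report(path, selected).to_csv(
        file_path, index=False, float_format=FLOAT_FORMAT
    )
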