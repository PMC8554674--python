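"""Reference methods: sequential Fisher g-test and autocorrelation profiling.

The g-test compares the largest periodogram ordinate to the ordinate sum
under a white-noise null; the exact tail probability is

    P(G > g) = sum_{j=1}^{floor(1/g)} (-1)^(j-1) C(N, j) (1 - j g)^(N-1)

The sequential variant tests the ordered ordinates one at a time at a
Bonferroni-corrected level, removing each significant ordinate and
renormalizing, and stops at the first nonsignificant step.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import ValidationError
from .io import EpochSeries, FLOAT_FORMAT
from .spectrum import SpectrumMatrix


@dataclasses.dataclass(frozen=True)
class FisherStep:
    """One stage of the sequential test."""

    rank: int
    period_minutes: float
    g_statistic: float
    n_remaining: int
    p_value: float
    threshold: float
    significant: bool


@dataclasses.dataclass
class AutocorrelationProfile:
    lags_epochs: np.ndarray
    r: np.ndarray
    peak_lags_epochs: tuple[int, ...] = ()

    def lag_hours(self, epoch_seconds: int = 60) -> np.ndarray:
        return self.lags_epochs * (epoch_seconds / 3600.0)


def _log_series_term(n: int, j: int, g: float) -> float:
    """log of C(n, j) (1 - j g)^(n-1); -inf when 1 - j g <= 0."""
    rest = 1.0 - j * g
    if rest <= 0.0:
        return -math.inf
    return float(
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + (n - 1) * math.log1p(-j * g)
    )


def fisher_g_pvalue(g: float, n_ordinates: int) -> float:
    """Null tail probability P(G > g) of the g statistic for N ordinates.

    The alternating series is evaluated in log space with compensated
    summation whenever its terms decrease from the first one — the series is
    unimodal in j, so this guarantees monotone terms and no catastrophic
    cancellation.  When the terms instead grow (very small g relative to
    ln(N)/N), the partial sums cancel to many orders of magnitude and doubles
    cannot represent the result; there the terms are asymptotically Poisson
    (t_j ~ t_1^j / j!) and the limit ``1 - exp(-t_1)`` with
    ``t_1 = N (1 - g)^(N-1)`` is used instead.  In that regime p > 0.6, far
    from any significance threshold.  The result is clipped to [0, 1].
    """
    n = int(n_ordinates)
    if n < 2:
        raise ValidationError("n_ordinates must be >= 2")
    if not (1.0 / n <= g <= 1.0):
        raise ValidationError(f"g={g} outside [1/{n}, 1]")
    j_max = min(int(math.floor(1.0 / g + 1e-12)), n)
    log_terms = [_log_series_term(n, j, g) for j in range(1, j_max + 1)]
    # fsum returns the correctly rounded sum of its inputs, so the series is
    # reliable while terms stay small; once any term exceeds ~e^15 the
    # cancellation outruns double precision and the Poisson limit takes over
    # (there t_1 >> 1, so p ~ 1 anyway).
    if log_terms and max(log_terms) > 15.0:
        log_t1 = log_terms[0]
        return float(min(-math.expm1(-math.exp(min(log_t1, 700.0))), 1.0))
    terms = []
    for j in range(1, j_max + 1):
        if n <= 60:  # small N: binomials are exact in double precision
            rest = 1.0 - j * g
            term = math.comb(n, j) * rest ** (n - 1) if rest > 0.0 else 0.0
        else:
            log_term = _log_series_term(n, j, g)
            term = math.exp(min(log_term, 700.0)) if log_term > -math.inf else 0.0
        terms.append((-1.0) ** (j - 1) * term)
    return float(min(max(math.fsum(terms), 0.0), 1.0))


def pool_ordinates(X: SpectrumMatrix) -> np.ndarray:
    """Cohort-pooled periodogram: per column, the sum of squared magnitudes
    over subjects.  This is the monotone square of the penalized estimator's
    column energies, so the two methods rank periodicities identically."""
    return np.einsum("ij,ij->j", X.magnitudes, X.magnitudes)


def sequential_fisher(
    ordinates: np.ndarray,
    period_labels: np.ndarray,
    alpha: float = 0.05,
    correction_p: int | None = None,
    max_steps: int | None = None,
) -> list[FisherStep]:
    """Sequential g-test over periodogram ordinates with Bonferroni control.

    At step s the largest remaining ordinate is tested with
    ``g_s = max / sum`` over the ``N_s = p - s + 1`` remaining ordinates and
    declared significant when the p-value is <= alpha / correction_p
    (correction_p defaults to the number of periodicities p).  Significant
    ordinates are removed and testing continues; the first nonsignificant
    step is recorded and the procedure stops.
    """
    ordinates = np.asarray(ordinates, dtype=float)
    period_labels = np.asarray(period_labels, dtype=float)
    if ordinates.ndim != 1 or ordinates.size != period_labels.size:
        raise ValidationError("ordinates and period_labels must match in length")
    if ordinates.size < 2:
        raise ValidationError("need at least two ordinates")
    if np.any(~np.isfinite(ordinates)) or np.any(ordinates <= 0):
        raise ValidationError("ordinates must be finite and positive")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if correction_p is None:
        correction_p = ordinates.size
    if correction_p < 1:
        raise ValidationError("correction_p must be >= 1")
    threshold = alpha / correction_p

    remaining = ordinates.copy()
    labels = period_labels.copy()
    steps: list[FisherStep] = []
    rank = 1
    while remaining.size >= 2:
        if max_steps is not None and rank > max_steps:
            break
        top = int(np.argmax(remaining))  # ties: first index = longest period
        g = float(remaining[top] / remaining.sum())
        n_rem = int(remaining.size)
        p_value = fisher_g_pvalue(min(max(g, 1.0 / n_rem), 1.0), n_rem)
        significant = p_value <= threshold
        steps.append(
            FisherStep(
                rank=rank,
                period_minutes=float(labels[top]),
                g_statistic=g,
                n_remaining=n_rem,
                p_value=p_value,
                threshold=threshold,
                significant=significant,
            )
        )
        if not significant:
            break
        remaining = np.delete(remaining, top)
        labels = np.delete(labels, top)
        rank += 1
    return steps


def significant_periods(steps: Sequence[FisherStep]) -> list[float]:
    """Periods flagged significant, in test order."""
    return [s.period_minutes for s in steps if s.significant]


def autocorrelation(
    series: EpochSeries | np.ndarray, max_lag_epochs: int
) -> AutocorrelationProfile:
    """Sample autocorrelation r_k over lags 0..max_lag_epochs.

    Standard biased estimator with a single global mean:
    ``r_k = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2``,
    guaranteeing r_0 = 1 and |r_k| <= 1.
    """
    x = series.counts if isinstance(series, EpochSeries) else np.asarray(series, float)
    if max_lag_epochs < 1 or max_lag_epochs >= x.size:
        raise ValidationError("max_lag_epochs must be in [1, len(counts) - 1]")
    if np.ptp(x) == 0:
        raise ValidationError("autocorrelation undefined for a constant series")
    r = _sm_acf(x, nlags=max_lag_epochs, fft=True, adjusted=False)
    return AutocorrelationProfile(
        lags_epochs=np.arange(max_lag_epochs + 1), r=np.asarray(r)
    )


def find_local_maxima(
    profile: AutocorrelationProfile, window_epochs: int
) -> list[int]:
    """Lags k >= window that dominate every lag within +/- window, sorted by
    descending r (lag 0 excluded)."""
    if window_epochs < 1:
        raise ValidationError("window_epochs must be >= 1")
    r = profile.r
    n = r.size
    peaks = []
    for k in range(max(1, window_epochs), n):
        lo = max(0, k - window_epochs)
        hi = min(n, k + window_epochs + 1)
        if r[k] >= r[lo:hi].max():
            peaks.append(k)
    peaks.sort(key=lambda k: -r[k])
    profile.peak_lags_epochs = tuple(peaks)
    return peaks


def fisher_report(steps: Sequence[FisherStep]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "period_minutes": s.period_minutes,
                "g": s.g_statistic,
                "N": s.n_remaining,
                "p_value": s.p_value,
                "threshold": s.threshold,
                "significant": s.significant,
            }
            for s in steps
        ]
    )


def write_fisher_csv(steps: Sequence[FisherStep], path) -> None:
    fisher_report(steps).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_acf_csv(
    profile: AutocorrelationProfile, path, epoch_seconds: int = 60
) -> None:
    pd.DataFrame(
        {
            "lag_epochs": profile.lags_epochs,
            "lag_hours": profile.lag_hours(epoch_seconds),
            "r": profile.r,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)
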