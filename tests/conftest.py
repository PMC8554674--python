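import numpy as np
import pytest

from actirhythm import EpochSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_series(day_blocks, subject_id="s1", epoch_seconds=60, day_indices=None):
    """EpochSeries from a list of per-day arrays (each one full day)."""
    counts = np.concatenate([np.asarray(d, dtype=float) for d in day_blocks])
    return EpochSeries(
        subject_id=subject_id,
        counts=counts,
        epoch_seconds=epoch_seconds,
        day_indices=tuple(day_indices) if day_indices else (),
    )


def cosine_series(
    days=7,
    components=((1440.0, 10.0, 0.0),),
    baseline=100.0,
    epochs_per_day=1440,
    noise_sd=0.0,
    seed=0,
    subject_id="s1",
):
    """Deterministic cosine-mixture series for spectrum tests.

    components: iterable of (period_minutes, amplitude, phase).
    """
    epoch_minutes = 1440.0 / epochs_per_day
    t = np.arange(days * epochs_per_day) * epoch_minutes
    x = np.full(t.size, float(baseline))
    for period, amp, phase in components:
        x += amp * np.cos(2 * np.pi * t / period + phase)
    if noise_sd:
        x += np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return EpochSeries(
        subject_id=subject_id,
        counts=np.maximum(x, 0.0),
        epoch_seconds=int(round(60 * epoch_minutes)),
    )
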