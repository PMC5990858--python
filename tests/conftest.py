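"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from diurnalseek import HourlyQuerySeries, SyntheticConfig


@pytest.fixture
def standard_config() -> SyntheticConfig:
    """The standard night-peak study conditions: diurnal amplitude 15 RSV
    units peaking at 2 AM, 20-unit 72 h trend, 3-unit 2 h fast component,
    white noise SD 5, 31 days."""
    return SyntheticConfig(
        n_days=31,
        terms=["masennus"],
        baseline=50.0,
        diurnal_amplitude=15.0,
        acrophase=2.0,
        trend_amplitude=20.0,
        trend_period=72.0,
        noise_hf_amplitude=3.0,
        noise_hf_period=2.0,
        white_sd=5.0,
        seed=0,
    )


def make_series(values, term="q", start="2017-03-01T00") -> HourlyQuerySeries:
    """Series on a contiguous hourly grid starting at the given instant."""
    values = np.asarray(values, dtype=float)
    t0 = np.datetime64(start, "h")
    ts = t0 + np.arange(len(values)) * np.timedelta64(1, "h")
    return HourlyQuerySeries(term, ts, values)


def dft_bandpass(x: np.ndarray, min_period: float, max_period: float) -> np.ndarray:
    """Independent brute-force band-pass: zero every DFT bin whose period
    (1/|f|) falls outside [min_period, max_period], inverse transform."""
    x = np.asarray(x, dtype=float)
    xf = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(len(x), d=1.0)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    keep = (periods >= min_period) & (periods <= max_period)
    return np.fft.irfft(np.where(keep, xf, 0), n=len(x))


def permutation_anova_p(groups, n_perm=10_000, seed=0) -> float:
    """Permutation p-value for the one-way ANOVA F statistic."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(seed)
    obs = f_oneway(*groups).statistic
    pooled = np.concatenate(groups)
    sizes = np.cumsum([len(g) for g in groups])[:-1]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if f_oneway(*np.split(perm, sizes)).statistic >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
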