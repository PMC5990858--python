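"""Synthetic hourly RSV series with known diurnal, trend, and noise structure.

Every downstream stage (band-pass reconstruction, folded profiles, hourly
significance matrices, time-block comparisons) is validated against series
generated here, because real Google Trends exports carry no ground truth.
The generative model per hour t is

    value(t) = baseline
             + A * cos(2*pi*(t - acrophase)/24)          # diurnal component
             + trend_amplitude * cos(2*pi*t/trend_period)  # slow trend, >32 h
             + noise_hf_amplitude * cos(2*pi*t/noise_hf_period + phi)  # <4 h
             + N(0, white_sd**2)                          # observation noise

followed by optional renormalization to max 100 and integer quantization
(round then clip to [0, 100]).  The trend and high-frequency terms sit
deliberately outside the 4-32 h analysis band so band rejection has an
exact known target; the high-frequency term is a fixed-period cosine with
a random phase per term, not broadband noise, for the same reason.

Defaults emulate a month of night-peaking search interest: amplitude 15
RSV units peaking near 2 AM over a baseline of 50, a 20-unit 72 h trend,
a 3-unit 2 h fast component, white noise SD 5, 31 days, 6 query terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .diurnal import DiurnalProfile
from .exceptions import ConfigError
from .io_trends import HOUR, HourlyQuerySeries

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_series",
    "ground_truth_profile",
]

DEFAULT_TERMS = [
    "masennus",
    "masennus oireet",
    "masennustesti",
    "masennus testi",
    "depression",
    "depression test",
]


@dataclass
class SyntheticConfig:
    """Parameters of the generative model; see the module docstring.

    Amplitudes are in RSV units; ``acrophase`` is the peak clock hour in
    [0, 24); ``trend_period`` must exceed 32 h and ``noise_hf_period`` stay
    below 4 h so both fall outside the diurnal analysis band.
    """

    n_days: int = 31
    terms: list[str] = field(default_factory=lambda: list(DEFAULT_TERMS))
    baseline: float = 50.0
    diurnal_amplitude: float = 15.0
    acrophase: float = 2.0
    trend_amplitude: float = 20.0
    trend_period: float = 72.0
    noise_hf_amplitude: float = 3.0
    noise_hf_period: float = 2.0
    white_sd: float = 5.0
    renormalize: bool = False
    quantize: bool = False
    seed: int = 0
    start: str = "2017-03-01T00"

    def validate(self) -> None:
        if self.n_days < 2:
            raise ConfigError(f"n_days must be >= 2, got {self.n_days}")
        if not self.terms:
            raise ConfigError("terms must be non-empty")
        if self.trend_period <= 32:
            raise ConfigError(
                f"trend_period must exceed 32 h (outside the diurnal band), "
                f"got {self.trend_period}"
            )
        if self.noise_hf_period >= 4:
            raise ConfigError(
                f"noise_hf_period must be below 4 h, got {self.noise_hf_period}"
            )
        if self.diurnal_amplitude < 0:
            raise ConfigError("diurnal_amplitude must be >= 0")
        if not 0 <= self.acrophase < 24:
            raise ConfigError(f"acrophase must be in [0, 24), got {self.acrophase}")
        if self.white_sd < 0:
            raise ConfigError("white_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown synthetic config key(s): {sorted(bad)}")
        return cls(**raw)


@dataclass
class GroundTruth:
    """Analytic truth for one generated batch.

    ``diurnal_component`` is the cosine sampled at integer hours 0-23 (zero
    mean); ``true_pp_difference`` is its peak-trough span on that grid
    (exactly 2A for integer acrophase) before any renormalization.  When
    ``renormalize`` is on, the per-term factors in ``scale_by_term`` map it
    onto the 0-100 output scale: truth for a term is
    ``true_pp_difference * scale_by_term[term]``.
    """

    diurnal_component: np.ndarray
    true_peak_hour: int
    true_trough_hour: int
    true_pp_difference: float
    scale_by_term: dict[str, float] = field(default_factory=dict)

    def pp_for(self, term: str) -> float:
        return self.true_pp_difference * self.scale_by_term.get(term, 1.0)


def _diurnal_at(hours: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    return config.diurnal_amplitude * np.cos(
        2 * np.pi * (hours - config.acrophase) / 24.0
    )


def ground_truth_profile(config: SyntheticConfig) -> DiurnalProfile:
    """The 24-point diurnal profile implied by the cosine component alone."""
    config.validate()
    return DiurnalProfile.from_means(_diurnal_at(np.arange(24), config))


def generate_series(
    config: SyntheticConfig,
) -> tuple[list[HourlyQuerySeries], GroundTruth]:
    """Generate one series per term plus the analytic ground truth.

    All terms share the deterministic components; the high-frequency phase
    and the white noise are drawn independently per term from a generator
    seeded by ``config.seed``, so identical config implies bit-identical
    output.
    """
    config.validate()
    n = config.n_days * 24
    t = np.arange(n, dtype=float)
    start = np.datetime64(config.start, "h")
    timestamps = start + np.arange(n) * HOUR

    clock = (timestamps.astype(int) % 24).astype(float)
    diurnal = _diurnal_at(clock, config)
    trend = config.trend_amplitude * np.cos(2 * np.pi * t / config.trend_period)

    rng = np.random.default_rng(config.seed)
    series: list[HourlyQuerySeries] = []
    scale: dict[str, float] = {}
    for term in config.terms:
        phi = rng.uniform(0, 2 * np.pi)
        hf = config.noise_hf_amplitude * np.cos(
            2 * np.pi * t / config.noise_hf_period + phi
        )
        white = rng.normal(0.0, config.white_sd, size=n) if config.white_sd else 0.0
        vals = config.baseline + diurnal + trend + hf + white
        k = 1.0
        if config.renormalize:
            peak = vals.max()
            if peak <= 0:
                raise ConfigError(
                    f"term {term!r}: cannot renormalize, max value {peak} <= 0"
                )
            k = 100.0 / peak
            vals = vals * k
        scale[term] = k
        if config.quantize:
            vals = np.clip(np.rint(vals), 0, 100)
        series.append(HourlyQuerySeries(term, timestamps.copy(), vals))

    base = ground_truth_profile(config)
    truth = GroundTruth(
        diurnal_component=base.mean_by_hour,
        true_peak_hour=base.peak_hour,
        true_trough_hour=base.trough_hour,
        true_pp_difference=base.pp_difference,
        scale_by_term=scale,
    )
    return series, truth
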