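"""Full-pipeline orchestration: read/simulate -> band-pass -> profiles ->
hourly significance -> time blocks, with reproducible file outputs.

Per-term outputs written under the output directory:

* ``reconstructed.csv``    — band-passed series (all terms, one file)
* ``<term>_profile.csv``   — hour, mean_rsv
* ``<term>_summary.json``  — peak/trough hours, pp difference
* ``<term>_sigmatrix.csv`` — 24x24 0/1 directional matrix
* ``<term>_pairs.csv``     — long format hour_i, hour_j, mean_diff, p_adjusted
* ``<term>_blocks.csv``    — block, n, mean, sd
* ``<term>_block_pairs.csv`` — pair, mean_diff, p_raw, p_bonferroni
* ``manifest.json``        — config hash, seed, versions, shapes, timings
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocks import BLOCK_ORDER, BlockSummary, block_anova_posthoc
from .diurnal import DiurnalProfile, fold_days, mean_profile
from .exceptions import ConfigError, DataError
from .hourly_stats import SignificanceMatrix, tukey_kramer
from .io_trends import HourlyQuerySeries, read_trends_csv, write_trends_csv
from .synthetic import SyntheticConfig, generate_series
from .wavelet import BandSpec, reconstruct_series

log = logging.getLogger("diurnalseek")

__all__ = ["PipelineConfig", "TermResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; defaults follow the standard analysis
    (band 4-32 h, alpha 0.05, hourly block observations)."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    band: BandSpec = field(default_factory=BandSpec)
    alpha: float = 0.05
    block_unit: str = "hour"
    raw_stats: bool = False     # hourly stats on raw instead of reconstructed
    out_dir: str = "results"
    seed: int = 0
    wavelet_omega0: float = 6.0
    wavelet_dj: float = 0.125
    wavelet_s0_dt_multiple: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "band" in raw and raw["band"] is not None:
            raw["band"] = BandSpec(**raw["band"])
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown pipeline config key(s): {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_csv / synthetic required")
        if not 0 < self.alpha <= 0.5:
            raise ConfigError(f"alpha must be in (0, 0.5], got {self.alpha}")


@dataclass
class TermResult:
    term: str
    raw: HourlyQuerySeries
    reconstructed: HourlyQuerySeries
    profile: DiurnalProfile
    sig_matrix: SignificanceMatrix
    blocks: BlockSummary


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    d = asdict(config)
    d.pop("out_dir", None)   # hash the scientific settings, not the paths
    blob = json.dumps(d, default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(term: str, stage: str, t0: float, **shapes) -> None:
    log.info(json.dumps({
        "stage": stage, "term": term,
        "elapsed_s": round(time.perf_counter() - t0, 4), **shapes,
    }))


def _slug(term: str) -> str:
    return term.replace(" ", "_")


def run_pipeline(config: PipelineConfig) -> dict[str, TermResult]:
    """Run every stage for every term and write all outputs.

    Identical config + seed produce byte-identical result files.  Stage
    errors propagate annotated with the stage name and term label.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        syn = SyntheticConfig(**{**asdict(config.synthetic), "seed": config.seed})
        series_list, _truth = generate_series(syn)
    else:
        series_list = read_trends_csv(config.input_csv)
        if not series_list:
            raise DataError(f"no series found in {config.input_csv}")

    results: dict[str, TermResult] = {}
    recon_all: list[HourlyQuerySeries] = []
    for s in series_list:
        term = s.term
        try:
            t0 = time.perf_counter()
            rec = reconstruct_series(
                s, config.band,
                omega0=config.wavelet_omega0, dj=config.wavelet_dj,
                s0=config.wavelet_s0_dt_multiple * 1.0,
            )
            _stage(term, "reconstruct", t0, n=len(rec))
            recon_all.append(rec)

            t0 = time.perf_counter()
            folded = fold_days(rec)
            profile = mean_profile(folded)
            _stage(term, "profile", t0, days=folded.n_days)

            t0 = time.perf_counter()
            stats_input = fold_days(s) if config.raw_stats else folded
            sig = tukey_kramer(stats_input, alpha=config.alpha)
            _stage(term, "hourly_stats", t0,
                   significant_pairs=int(sig.greater.sum()))

            t0 = time.perf_counter()
            blocks = block_anova_posthoc(s, alpha=config.alpha,
                                         unit=config.block_unit)
            _stage(term, "blocks", t0)
        except Exception as exc:
            raise type(exc)(f"[term {term!r}] {exc}") from exc

        results[term] = TermResult(term, s, rec, profile, sig, blocks)
        _write_term(out, results[term])

    write_trends_csv(out / "reconstructed.csv", recon_all)
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "numpy_version": np.__version__,
        "n_terms": len(results),
        "n_hours_per_term": len(series_list[0]) if series_list else 0,
        "n_values_total": int(sum(len(s) for s in series_list)),
        "terms": [s.term for s in series_list],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results


def _write_term(out: Path, r: TermResult) -> None:
    slug = _slug(r.term)
    pd.DataFrame(
        {"hour": np.arange(24), "mean_rsv": r.profile.mean_by_hour}
    ).to_csv(out / f"{slug}_profile.csv", index=False, float_format="%.6f")

    (out / f"{slug}_summary.json").write_text(json.dumps({
        "term": r.term,
        "peak_hour": r.profile.peak_hour,
        "trough_hour": r.profile.trough_hour,
        "pp_difference": round(r.profile.pp_difference, 6),
    }, indent=2) + "\n")

    pd.DataFrame(r.sig_matrix.greater.astype(int)).to_csv(
        out / f"{slug}_sigmatrix.csv", index=False, header=False
    )
    ii, jj = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
    mdiff = (r.sig_matrix.mean_by_hour[:, None]
             - r.sig_matrix.mean_by_hour[None, :])
    mask = ii != jj
    pd.DataFrame({
        "hour_i": ii[mask], "hour_j": jj[mask],
        "mean_diff": mdiff[mask].round(6),
        "p_adjusted": r.sig_matrix.p_adjusted[mask].round(8),
    }).to_csv(out / f"{slug}_pairs.csv", index=False)

    pd.DataFrame({
        "block": list(BLOCK_ORDER),
        "n": [r.blocks.n[b] for b in BLOCK_ORDER],
        "mean": [round(r.blocks.mean[b], 6) for b in BLOCK_ORDER],
        "sd": [round(r.blocks.sd[b], 6) for b in BLOCK_ORDER],
    }).to_csv(out / f"{slug}_blocks.csv", index=False)
    pd.DataFrame([{
        "pair": f"{c.block_a}-{c.block_b}",
        "mean_diff": round(c.mean_diff, 6),
        "p_raw": round(c.p_raw, 8),
        "p_bonferroni": round(c.p_bonferroni, 8),
    } for c in r.blocks.comparisons]).to_csv(
        out / f"{slug}_block_pairs.csv", index=False
    )
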