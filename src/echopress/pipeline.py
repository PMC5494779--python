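"""End-to-end orchestration: simulate -> features -> invert -> correlate.

`run_analysis` executes the whole chain in memory and returns every
intermediate table plus the correlation summary; `run_pipeline` wraps it
with file output (A-line dataset + manifest, feature/impedance tables,
JSON summary) so a dataset and all results are regenerable bit for bit
from config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as ep_io
from .analysis import CorrelationResult, PressureSeries, correlate_with_iop
from .config import PipelineConfig, config_hash
from .exceptions import EchopressError
from .features import aggregate_features, build_feature_table
from .impedance import ReflectionSetup, invert_feature_table
from .synthetic import (
    AcquisitionSpec,
    IOPCalibration,
    StackConstants,
    TransducerSpec,
    calibrate_stack_constants,
    simulate_experiment,
)

__all__ = ["PipelineResult", "resolve_constants", "run_analysis", "run_pipeline"]

logger = logging.getLogger("echopress")

# The four quantities correlated with IOP in the summary.
SUMMARY_QUANTITIES = ("Z1", "Z2", "ant_amp", "post_amp")


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    constants: StackConstants
    records: list
    features: pd.DataFrame
    impedances: pd.DataFrame
    aggregated_features: pd.DataFrame
    aggregated_impedances: pd.DataFrame
    correlations: dict[str, CorrelationResult]

    def summary(self) -> dict:
        agg_z = self.aggregated_impedances
        agg_f = self.aggregated_features
        return {
            "config_hash": config_hash(self.config),
            "seed": self.config.seed,
            "iop_levels_mmHg": [float(p) for p in self.config.analysis.iops],
            "constants": {
                "Z0_MRayl": self.constants.Z0,
                "Z3_MRayl": self.constants.Z3,
                "A0": self.constants.A0,
                "posterior_gain": self.constants.posterior_gain,
            },
            "per_level": {
                "Z1_MRayl_mean": agg_z["Z1_mean"].tolist(),
                "Z2_MRayl_mean": agg_z["Z2_mean"].tolist(),
                "ant_amp_mean": agg_f["ant_amp_mean"].tolist(),
                "post_amp_mean": agg_f["post_amp_mean"].tolist(),
                "tof_diff_s_mean": agg_f["tof_diff_mean"].tolist(),
            },
            "correlations": {q: c.as_dict() for q, c in self.correlations.items()},
        }


def resolve_constants(cfg: PipelineConfig) -> tuple[IOPCalibration, StackConstants]:
    """Build the impedance calibration and stack constants from a config.

    Layer constants left null in the config are derived from the endpoint
    amplitude calibration; explicit values take precedence.
    """
    c = cfg.calibration
    cal = IOPCalibration(
        iop_low=c.iop_low, iop_high=c.iop_high,
        Z1_low=c.Z1_low, Z1_high=c.Z1_high,
        Z2_low=c.Z2_low, Z2_high=c.Z2_high,
    )
    layers = cfg.layers
    if None in (layers.Z0, layers.A0, layers.posterior_gain):
        derived = calibrate_stack_constants(
            ant_amp_low=c.ant_amp_low, ant_amp_high=c.ant_amp_high,
            post_amp_low=c.post_amp_low, cal=cal,
        )
    else:
        derived = None
    Z0 = layers.Z0 if layers.Z0 is not None else derived.Z0
    A0 = layers.A0 if layers.A0 is not None else derived.A0
    gain = layers.posterior_gain if layers.posterior_gain is not None else derived.posterior_gain
    Z3 = layers.Z3 if layers.Z3 is not None else Z0
    return cal, StackConstants(Z0=Z0, A0=A0, posterior_gain=gain, Z3=Z3)


def _aggregate_impedances(imp: pd.DataFrame) -> pd.DataFrame:
    per_repeat = imp.groupby(["iop_mmHg", "eye_id", "repeat_id"], as_index=False)[
        ["Z1_MRayl", "Z2_MRayl"]
    ].mean()
    means = per_repeat.groupby("iop_mmHg")[["Z1_MRayl", "Z2_MRayl"]].mean()
    sds = imp.groupby("iop_mmHg")[["Z1_MRayl", "Z2_MRayl"]].std(ddof=1).fillna(0.0)
    out = pd.DataFrame(
        {
            "Z1_mean": means["Z1_MRayl"],
            "Z1_sd": sds["Z1_MRayl"],
            "Z2_mean": means["Z2_MRayl"],
            "Z2_sd": sds["Z2_MRayl"],
        }
    )
    out["n_alines"] = imp.groupby("iop_mmHg").size()
    return out.reset_index()


def _correlate_raw(x, y, quantity: str) -> CorrelationResult:
    """Correlation over unaggregated rows (repeated IOP values allowed)."""
    import numpy as np
    from scipy import stats

    from .analysis import pearson_p_two_sided, pearson_r

    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    r = pearson_r(xa, ya)
    n = xa.size
    res = stats.linregress(xa, ya)
    t = float(r * np.sqrt((n - 2) / (1.0 - r * r))) if abs(r) < 1 else float("inf")
    return CorrelationResult(
        quantity=quantity, r=r, n=n, t_stat=t, df=n - 2,
        p_two_sided=pearson_p_two_sided(r, n),
        slope=float(res.slope), intercept=float(res.intercept),
    )


def run_analysis(cfg: PipelineConfig) -> PipelineResult:
    """Run simulate -> features -> invert -> correlate in memory."""
    t0 = time.perf_counter()
    cal, constants = resolve_constants(cfg)
    tspec = TransducerSpec(
        center_frequency=cfg.transducer.center_frequency,
        fractional_bandwidth=cfg.transducer.fractional_bandwidth,
    )
    aspec = AcquisitionSpec(
        sampling_rate=cfg.acquisition.sampling_rate,
        n_alines=cfg.acquisition.n_alines,
        n_repeats=cfg.acquisition.n_repeats,
        noise_sd=cfg.acquisition.noise_sd,
        record_length=cfg.acquisition.record_length,
        seed=cfg.seed,
    )
    records = simulate_experiment(
        cal, constants, tspec, aspec,
        iops=cfg.analysis.iops,
        cornea_thickness=cfg.layers.cornea_thickness,
        cornea_speed=cfg.layers.cornea_speed,
    )
    t1 = time.perf_counter()

    features = build_feature_table(
        records,
        min_separation=cfg.analysis.min_separation,
        threshold_frac=cfg.analysis.window_frac,
    )
    agg_features = aggregate_features(features)
    t2 = time.perf_counter()

    setup = ReflectionSetup(
        Z0=constants.Z0, A0=constants.A0, Z3=constants.Z3,
        posterior_gain=constants.posterior_gain,
    )
    impedances = invert_feature_table(features, setup)
    agg_imp = _aggregate_impedances(impedances)
    t3 = time.perf_counter()

    per_level = cfg.analysis.per_level
    source = {
        "Z1": (agg_imp["iop_mmHg"], agg_imp["Z1_mean"]) if per_level
        else (impedances["iop_mmHg"], impedances["Z1_MRayl"]),
        "Z2": (agg_imp["iop_mmHg"], agg_imp["Z2_mean"]) if per_level
        else (impedances["iop_mmHg"], impedances["Z2_MRayl"]),
        "ant_amp": (agg_features["iop_mmHg"], agg_features["ant_amp_mean"]) if per_level
        else (features["iop_mmHg"], features["ant_amp"]),
        "post_amp": (agg_features["iop_mmHg"], agg_features["post_amp_mean"]) if per_level
        else (features["iop_mmHg"], features["post_amp"]),
    }
    correlations = {}
    for q, (x, y) in source.items():
        if per_level:
            correlations[q] = correlate_with_iop(PressureSeries(iops=x, values=y, quantity=q))
        else:
            correlations[q] = _correlate_raw(x, y, q)
    t4 = time.perf_counter()

    logger.info(
        "pipeline: config=%s seed=%d | simulate %.2fs, features %.2fs, "
        "invert %.2fs, correlate %.2fs",
        config_hash(cfg), cfg.seed, t1 - t0, t2 - t1, t3 - t2, t4 - t3,
    )
    return PipelineResult(
        config=cfg, constants=constants, records=records,
        features=features, impedances=impedances,
        aggregated_features=agg_features, aggregated_impedances=agg_imp,
        correlations=correlations,
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 write_alines: bool = True) -> PipelineResult:
    """Run the full pipeline and write every intermediate artifact.

    Writes alines/ (CSV per record + manifest), features.csv,
    impedance.csv, aggregated tables and summary.json under ``out_dir``
    (default: the config's output_dir).
    """
    out = Path(out_dir) if out_dir is not None else (
        Path(cfg.output_dir) if cfg.output_dir else None
    )
    if out is None:
        raise EchopressError("no output directory given (config output_dir or out_dir)")
    out.mkdir(parents=True, exist_ok=True)

    result = run_analysis(cfg)
    if write_alines:
        ep_io.write_aline_dataset(result.records, out / "alines")

    ep_io.write_table(result.features, out / "features.csv")
    ep_io.write_table(result.impedances, out / "impedance.csv")
    ep_io.write_table(result.aggregated_features, out / "aggregated_features.csv")
    ep_io.write_table(result.aggregated_impedances, out / "aggregated_impedance.csv")
    (out / "summary.json").write_text(json.dumps(result.summary(), indent=1, sort_keys=True))
    return result
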