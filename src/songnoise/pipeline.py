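"""End-to-end orchestration: simulate/ingest -> metrics -> amplitude ->
min freq -> model selection, with a machine-readable run report.

A run is described by a single declarative :class:`PipelineConfig`
(serialisable to/from JSON); every run writes its resolved config next to
its outputs so results are reproducible from the run directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import models as nm
from .simulate import SimConfig, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # analysis thresholds
    min_snr_margin: float = 0.5
    minfreq_threshold_db: float = -36.0
    presong_window_s: float = 10.0
    # model-set configuration
    amplitude_models: nm.ModelSetConfig = field(
        default_factory=nm.default_amplitude_config
    )
    minfreq_models: nm.ModelSetConfig = field(
        default_factory=nm.default_minfreq_config
    )
    # table-input mode (when simulate is False)
    noise_table: Optional[str] = None
    amplitude_table: Optional[str] = None
    minfreq_table: Optional[str] = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "out_dir" not in d:
            raise ValueError("config missing required field 'out_dir'")
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("distance_range", "noise_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        for key in ("amplitude_models", "minfreq_models"):
            if key in d and isinstance(d[key], dict):
                mc = dict(d[key])
                if "noise_terms" in mc:
                    mc["noise_terms"] = tuple(mc["noise_terms"])
                if mc.get("explicit_models") is not None:
                    mc["explicit_models"] = tuple(tuple(m) for m in mc["explicit_models"])
                d[key] = nm.ModelSetConfig(**mc)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


def _load_tables(config: PipelineConfig):
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        noise_df, amp_df, mf_df, truth = simulate_study(sim)
        return noise_df, amp_df, mf_df, truth
    missing = [
        name
        for name, p in (
            ("noise_table", config.noise_table),
            ("amplitude_table", config.amplitude_table),
            ("minfreq_table", config.minfreq_table),
        )
        if p is None
    ]
    if missing:
        raise ValueError(f"config missing required field(s): {missing}")
    return (
        pd.read_csv(config.noise_table),
        pd.read_csv(config.amplitude_table),
        pd.read_csv(config.minfreq_table),
        None,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write tables, model rankings, and a report.

    Returns the run report (also written to ``report.json``): per-stage
    song counts in/out, the ranked model tables, the covariation test,
    and residual diagnostics for the top models.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "resolved_config.json")
    report: dict = {"stages": {}, "seed": config.seed}

    noise_df, amp_df, mf_df, truth = _load_tables(config)
    noise_df.to_csv(out / "AmbientNoiseMeasures.csv", index=False)
    amp_df.to_csv(out / "SongAmplitude.csv", index=False)
    mf_df.to_csv(out / "MinFreqResults.csv", index=False)
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
    report["stages"]["ingest"] = {
        "songs_in": int(len(mf_df)),
        "songs_amplitude": int(len(amp_df)),
        "birds": int(mf_df["bird_id"].nunique()),
    }

    results: dict[str, nm.ModelSetResult] = {}
    for label, df, mconf in (
        ("amplitude", amp_df, config.amplitude_models),
        ("minfreq", mf_df, config.minfreq_models),
    ):
        usable = df.dropna(subset=[mconf.response])
        n_excluded = len(df) - len(usable)
        if len(usable) == 0:
            logger.warning("%s stage: 0 usable songs, skipping model selection", label)
            report["stages"][label] = {
                "songs_used": 0,
                "songs_excluded": n_excluded,
                "note": "no usable songs",
            }
            continue
        res = nm.fit_model_set(usable, mconf)
        results[label] = res
        res.table.to_csv(out / f"model_ranking_{label}.csv", index=False)
        diag = nm.residual_diagnostics(res.top)
        report["stages"][label] = {
            "songs_used": int(len(usable)),
            "songs_excluded": n_excluded,
            "models_fitted": int(len(res.fits)),
            "models_excluded": int(len(res.excluded)),
            "top_model": res.top.spec.name,
            "top_weight": float(res.weights[0]),
            "null_delta_aicc": float(
                res.table.loc[res.table["model"] == res.null_name, "dAICc"].iloc[0]
            ),
            "diagnostics": {
                "trend_slope": diag.trend_slope,
                "spread_ratio": diag.spread_ratio,
                "normality_p": diag.normality_p,
            },
        }

    if len(mf_df) and amp_df["song_amplitude"].notna().any():
        cov = nm.covariation_test(mf_df, amp_df)
        cov.table.to_csv(out / "covariation_test.csv", index=False)
        report["stages"]["covariation"] = {
            "top_model": cov.top.spec.name,
            "null_aicc": float(
                cov.table.loc[cov.table["model"] == cov.null_name, "AICc"].iloc[0]
            ),
            "amplitude_aicc": float(
                cov.table.loc[cov.table["model"] != cov.null_name, "AICc"].iloc[0]
            ),
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
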