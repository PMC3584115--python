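"""End-to-end pipeline: simulate -> preprocess -> extract -> score -> validate.

All stage parameters live in :class:`PipelineConfig`, which validates each
value against its documented domain and round-trips losslessly through JSON.
Every source of randomness derives from the single top-level seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .errors import ConfigurationError
from .erp import preprocess
from .model import load_published_model, score_table
from .peaks import dichotomize_gating, measure_pair
from .protocol import ClickProtocol, SubjectTruth
from .synth import simulate_cohort, synthesize_eeg
from .validate import ValidationReport, validate_model

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("gate50.pipeline")


@dataclass
class PipelineConfig:
    """Every numeric constant of the processing chain, in one place."""

    seed: int = 0
    n_patients: int = 10
    n_controls: int = 10
    n_pairs: int = 120
    isi_ms: float = 500.0
    inter_pair_s: tuple[float, float] = (8.0, 12.0)
    sampling_rate: float = 1000.0
    noise_sd_uv: float = 5.0
    blink_rate_per_min: float = 2.0
    artifact_rate_per_min: float = 0.5
    online_threshold_uv: float = 100.0
    offline_threshold_uv: float = 50.0
    band_hz: tuple[float, float] = (10.0, 50.0)
    gating_cutoff: float = 0.4
    s1_floor_uv: float = 0.5
    sle: float = 0.15
    sls: float = 0.15
    bootstrap_B: int = 0
    hl_groups: int = 10
    out_dir: str = "gate50_out"

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ConfigurationError(
                f"band_hz: low edge must satisfy 0 < low < high, got {self.band_hz}"
            )
        if self.online_threshold_uv <= 0 or self.offline_threshold_uv <= 0:
            raise ConfigurationError("rejection thresholds must be positive")
        if not 0 <= self.gating_cutoff <= 2:
            raise ConfigurationError("gating_cutoff must lie in [0, 2]")
        for name in ("sle", "sls"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.bootstrap_B < 0 or self.hl_groups < 2:
            raise ConfigurationError("bootstrap_B >= 0 and hl_groups >= 2 required")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ConfigurationError("need at least one subject per group")

    def protocol(self) -> ClickProtocol:
        return ClickProtocol(
            sampling_rate=self.sampling_rate,
            isi_ms=self.isi_ms,
            inter_pair_s=tuple(self.inter_pair_s),
            n_pairs=self.n_pairs,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("inter_pair_s", "band_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> tuple[ValidationReport, dict]:
    """Execute the full chain and write every stage artifact.

    Simulates a cohort, synthesizes one paired-click session per subject,
    runs the preprocessing and peak-scoring chain, replaces the cohort's P50
    columns with the *extracted* values (dropping subjects whose S1 falls
    below the validity floor), scores everyone with the published model and
    reports discrimination and calibration.

    Returns (ValidationReport, artifact-path dict).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.n_patients, config.n_controls,
                             seed=config.seed)
    protocol = config.protocol()
    subject_seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=len(cohort)
    )
    rows = []
    n_invalid = 0
    for i, row in cohort.iterrows():
        truth = SubjectTruth(
            group="patient" if row["group"] == 1 else "control",
            true_s1_amp=float(row["s1_uv"]),
            true_s2_amp=float(row["s2_uv"]),
            true_s1_latency=float(np.clip(row["s1_latency_ms"], 45, 75)),
            noise_sd=config.noise_sd_uv,
            blink_rate=config.blink_rate_per_min,
            artifact_rate=config.artifact_rate_per_min,
        )
        rec = synthesize_eeg(truth, protocol, seed=int(subject_seeds[i]))
        try:
            erp, epochs = preprocess(
                rec,
                online_threshold_uv=config.online_threshold_uv,
                offline_threshold_uv=config.offline_threshold_uv,
                band=config.band_hz,
            )
        except Exception as e:
            raise type(e)(f"subject {i}: preprocess: {e}") from e
        result = measure_pair(erp, 0.0, config.isi_ms)
        log.info(
            "subject %d: %d/%d trials retained, S1=%.2f uV, ratio=%s",
            i, epochs.n_retained, epochs.retained.size, result.s1_uv,
            f"{result.ratio:.2f}" if result.valid else "invalid",
        )
        if not result.valid:
            n_invalid += 1
            continue
        new = row.copy()
        for k, v in result.as_row().items():
            if k in new.index or k in ("valid", "truncated", "s2_zeroed"):
                new[k] = v
        new["gating"] = dichotomize_gating(result.ratio, config.gating_cutoff)
        new["n_trials_used"] = epochs.n_retained
        rows.append(new)
    if n_invalid:
        log.info("removed %d subjects with S1 < %.1f uV",
                 n_invalid, config.s1_floor_uv)
    extracted = pd.DataFrame(rows).reset_index(drop=True)
    coefs = load_published_model()
    probs = score_table(extracted, coefs)
    extracted["predicted_probability"] = probs
    report = validate_model(
        extracted, coefs,
        bootstrap_B=config.bootstrap_B, seed=config.seed,
        hl_groups=min(config.hl_groups, max(2, len(extracted) // 2)),
    )
    artifacts = {
        "config": out / "config.json",
        "cohort": out / "cohort.csv",
        "extracted": out / "extracted_cohort.csv",
        "validation": out / "validation.json",
    }
    config.to_json(artifacts["config"])
    gio.write_cohort(cohort, artifacts["cohort"])
    gio.write_cohort(extracted, artifacts["extracted"])
    report.to_json(artifacts["validation"])
    return report, artifacts
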