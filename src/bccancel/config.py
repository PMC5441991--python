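"""Experiment configuration and frequency plans.

Experiment 1 samples every 50 Hz between 0.25 and 8 kHz, split into 8
one-kilohertz-band sittings (250–1000 Hz, then 1050–2000 Hz, ... up to
7050–8000 Hz), no frequency presented more than once; band order and the
direction of increments within each band are randomized per run.
Experiment 2 repeats the same 8 frequencies (1–8 kHz in 1 kHz steps) in
8 sittings, order randomized within each sitting.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .head_model import SessionJitterScales
from .psychophysics import ObserverParams

__all__ = ["ObserverConfig", "JitterConfig", "ExperimentConfig",
           "exp1_frequency_bands", "exp2_frequencies", "frequency_plan"]

EXP1_GRID_STEP_HZ = 50.0
EXP2_FREQS_HZ = tuple(float(f) for f in range(1000, 9000, 1000))


class ObserverConfig(BaseModel):
    level_step_db: float = 0.2
    phase_step_deg: float = 2.0
    level_noise_db: float = 0.4
    phase_noise_deg: float = 4.0
    n_refinement_iters: int = 2
    grade_thresholds_db: tuple[float, float, float, float] = (3.0, 12.0, 25.0, 40.0)
    lf_noise_factor: float = 5.0
    lf_cutoff_hz: float = 1000.0
    lf_decay_hz: float = 2500.0
    hf_corner_hz: float = 7000.0
    hf_rise_per_khz: float = 0.3

    def to_params(self) -> ObserverParams:
        return ObserverParams(**self.model_dump())


class JitterConfig(BaseModel):
    gain_sd_db: float = Field(1.5, ge=0)
    phase_sd_deg: float = Field(15.0, ge=0)
    contra_slope_sd_deg_per_khz: float = Field(8.0, ge=0)

    def to_scales(self) -> SessionJitterScales:
        return SessionJitterScales(**self.model_dump())


class ExperimentConfig(BaseModel):
    """Full configuration of one simulated participant run."""

    experiment: Literal["exp1", "exp2"]
    model_seed: int = 1
    run_seed: int = 1
    n_sessions: int = 8
    observer: ObserverConfig = ObserverConfig()
    jitter: JitterConfig = JitterConfig()
    anchor_freq_hz: float = 250.0

    @field_validator("n_sessions")
    @classmethod
    def _check_sessions(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_sessions must be >= 1")
        return v


def exp1_frequency_bands() -> list[np.ndarray]:
    """The 8 one-kHz testing bands of the fine-grid experiment."""
    bands = [np.arange(250.0, 1000.0 + 1, EXP1_GRID_STEP_HZ)]
    for lo in range(1000, 8000, 1000):
        bands.append(np.arange(lo + EXP1_GRID_STEP_HZ, lo + 1000.0 + 1,
                               EXP1_GRID_STEP_HZ))
    return bands


def exp2_frequencies() -> np.ndarray:
    return np.asarray(EXP2_FREQS_HZ)


def frequency_plan(config: ExperimentConfig) -> list[tuple[int, np.ndarray]]:
    """Presentation plan: (session_id, frequencies in presentation order).

    All randomization (band order, sweep direction, within-sitting
    shuffles) derives from ``run_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.run_seed, 917]))
    if config.experiment == "exp1":
        bands = exp1_frequency_bands()
        order = rng.permutation(len(bands))
        plan = []
        for sid, band_idx in enumerate(order):
            band = bands[band_idx].copy()
            if rng.random() < 0.5:
                band = band[::-1]
            plan.append((sid, band))
        return plan
    plan = []
    for sid in range(config.n_sessions):
        plan.append((sid, rng.permutation(exp2_frequencies())))
    return plan


def config_json_schema() -> dict:
    """JSON schema of the experiment configuration (also shipped as
    docs/config.schema.json for editor validation of config files)."""
    return ExperimentConfig.model_json_schema()
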