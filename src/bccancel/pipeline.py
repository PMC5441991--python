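"""End-to-end drivers: simulate sessions, analyze records, design cancellers.

These functions are the single computational path shared by the command
line, the numbered analysis scripts and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis as an
from .canceller import BilateralTransferSet, CancellerDesign, design_filter
from .config import ExperimentConfig, frequency_plan
from .head_model import (
    SessionPerturbation,
    TransferModel,
    make_reference_model,
    perturb_for_session,
)
from .psychophysics import run_trial

__all__ = [
    "SimulationResult",
    "Exp1Analysis",
    "simulate_experiment",
    "analyze_exp1",
    "analyze_exp2",
    "boundary_discontinuities",
    "estimate_bc_transfer",
    "design_canceller_from_models",
]


@dataclass
class SimulationResult:
    records: pd.DataFrame
    model: TransferModel
    perturbations: list[SessionPerturbation]
    config: ExperimentConfig


def simulate_experiment(config: ExperimentConfig) -> SimulationResult:
    """Run a full simulated participant through one experiment.

    The truth model is drawn from ``model_seed``; each sitting applies a
    fresh coupling perturbation drawn from ``run_seed`` and the jitter
    scales, then the virtual participant works through that sitting's
    frequency list.  Deterministic: identical config -> identical records.
    """
    model = make_reference_model(config.model_seed)
    params = config.observer.to_params()
    scales = config.jitter.to_scales()
    plan = frequency_plan(config)

    records = []
    perts = []
    for sid, freqs in plan:
        session_model, pert = perturb_for_session(
            model, sid, config.run_seed, scales
        )
        perts.append(pert)
        for f in freqs:
            rec_i, rec_c = run_trial(session_model, float(f), params, sid,
                                     config.run_seed)
            records.extend([rec_i, rec_c])
    return SimulationResult(
        records=an.records_to_frame(records),
        model=model,
        perturbations=perts,
        config=config,
    )


@dataclass
class Exp1Analysis:
    profile: an.IntercochlearProfile
    series: dict  # ear -> stitched UnwrappedSeries
    n_excluded: int
    anchor_fallback: bool = False


def _ear_bands(
    df: pd.DataFrame, ear: str, anchor_freq_hz: float
) -> list[an.UnwrappedSeries]:
    bands = []
    for _, sess in df.loc[df["ear"] == ear].groupby("session_id"):
        sess = sess.sort_values("freq_hz")
        if len(sess) == 0:
            continue
        bands.append(
            an.UnwrappedSeries(
                freqs_hz=sess["freq_hz"].to_numpy(),
                phase_deg=an.unwrap_within_session(
                    sess["cancel_phase_deg"].to_numpy()
                ),
                level_db=sess["cancel_level_db"].to_numpy(),
                anchor_freq_hz=anchor_freq_hz,
            )
        )
    return bands


def analyze_exp1(
    records: pd.DataFrame, anchor_freq_hz: float = 250.0
) -> Exp1Analysis:
    """Exclusion -> within-sitting unwrap -> cross-sitting stitch -> profile."""
    if len(records) == 0:
        raise ValueError("no trial records to analyze")
    kept = an.exclude_grade1(records)
    if len(kept) == 0:
        raise ValueError("all trials excluded (grade 1); nothing to analyze")
    n_excluded = (len(records) - len(kept)) // 2
    series = {}
    for ear in ("ipsi", "contra"):
        bands = _ear_bands(kept, ear, anchor_freq_hz)
        if not bands:
            raise ValueError(f"no retained records for {ear} ear")
        series[ear] = an.stitch_sessions(bands, anchor_freq_hz=anchor_freq_hz)
    profile = an.intercochlear_profile(
        series["ipsi"], series["contra"], n_excluded=n_excluded
    )
    return Exp1Analysis(
        profile=profile,
        series=series,
        n_excluded=n_excluded,
        anchor_fallback=any(s.anchor_fallback for s in series.values()),
    )


def analyze_exp2(records: pd.DataFrame) -> an.VariabilitySummary:
    """Across-sitting variability of the repeated 1-8 kHz frequencies."""
    if len(records) == 0:
        raise ValueError("no trial records to analyze")
    kept = an.exclude_grade1(records)
    return an.session_variability(kept)


def boundary_discontinuities(
    series: an.UnwrappedSeries, band_edges_hz: np.ndarray
) -> pd.DataFrame:
    """Phase and level steps across sitting boundaries of a stitched series.

    For each boundary the step between the nearest retained frequencies on
    either side is reported; session coupling changes show up here while
    they cancel in the inter-cochlear profile.
    """
    rows = []
    for edge in np.asarray(band_edges_hz, dtype=float):
        below = series.freqs_hz <= edge
        above = series.freqs_hz > edge
        if not below.any() or not above.any():
            continue
        i = int(np.where(below)[0][-1])
        j = int(np.where(above)[0][0])
        rows.append(
            {
                "boundary_hz": edge,
                "phase_step_deg": series.phase_deg[j] - series.phase_deg[i],
                "level_step_db": (
                    series.level_db[j] - series.level_db[i]
                    if series.level_db is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def estimate_bc_transfer(
    series: an.UnwrappedSeries, ac_level_db: float = 0.0, ac_phase_deg: float = 0.0
) -> np.ndarray:
    """Complex bone-conduction path implied by cancellation settings.

    At cancellation the earphone drive exactly opposes the BC phasor, so
    the BC path equals the drive level through the (assumed known)
    earphone path with 180 degrees added:  H_bc = 10^(L/20) * H_ac *
    e^{i(psi - 180)}.  The absolute 360-multiple of psi is immaterial.
    """
    if series.level_db is None:
        raise ValueError("series has no levels")
    amp = 10.0 ** ((series.level_db + ac_level_db) / 20.0)
    phase = np.radians(series.phase_deg + ac_phase_deg - 180.0)
    return amp * np.exp(1j * phase)


def design_canceller_from_models(
    left: TransferModel, right: TransferModel, source: int = 0
) -> CancellerDesign:
    """Cross-talk canceller from two single-transducer head models."""
    return design_filter(BilateralTransferSet.from_models(left, right), source)
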