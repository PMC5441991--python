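"""Virtual participant executing the bilateral cancellation procedure.

One trial at one frequency: a fixed-level tone is played through the bone
transducer; the participant first adjusts the level of the ipsilateral
insert earphone to maximise beating against a 1-Hz-detuned probe (maximal
beating = equal levels at the basilar membrane), then scrolls the earphone
phase to the setting that minimises the perceived residual; the same two
steps are repeated at the contralateral ear, followed by two further
refinement iterations of both ears; finally the residual is graded 1-5
against the uncancelled tone.

The human "free scrolling" is modelled as an exhaustive search over the
quantized setting grid (0.2 dB level steps, 2 degree phase steps) with
additive perceptual noise injected once per adjustment.  Insert earphones
are assumed perfectly isolating, so each ear's air-conduction signal
reaches only its own cochlea and the two ears decouple.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

from .head_model import TransferModel

__all__ = [
    "ObserverParams",
    "TrialRecord",
    "CochlearSignal",
    "DegenerateTrialError",
    "superpose",
    "beat_depth",
    "match_level",
    "null_phase",
    "grade_residual",
    "run_trial",
]


class DegenerateTrialError(ValueError):
    """Raised when a trial cannot be performed (no audible BC signal)."""


@dataclass(frozen=True)
class ObserverParams:
    """Quantization steps, perceptual noise and grading thresholds.

    ``level_noise_db`` / ``phase_noise_deg`` are the 1-SD perceptual
    errors of one level-matching / phase-nulling adjustment at mid
    frequencies.  They are scaled by a frequency-dependent multiplier
    (``noise_multiplier``) that models the extra difficulty of the task
    at low frequencies, where near-antiphase temporal-bone motion makes
    beat detection harder: the multiplier equals ``lf_noise_factor`` at
    and below ``lf_cutoff_hz``, decays exponentially above it, and rises
    again slightly above ``hf_corner_hz``.
    """

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
    level_grid_db: tuple[float, float] = (-80.0, 80.0)

    def __post_init__(self) -> None:
        if self.level_step_db <= 0 or self.phase_step_deg <= 0:
            raise ValueError("quantization steps must be positive")
        if self.level_noise_db < 0 or self.phase_noise_deg < 0:
            raise ValueError("noise SDs must be non-negative")
        t = self.grade_thresholds_db
        if len(t) != 4 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("grade thresholds must be 4 strictly ascending values")

    def noise_multiplier(self, freq_hz: float) -> float:
        if freq_hz <= self.lf_cutoff_hz:
            return self.lf_noise_factor
        m = 1.0 + (self.lf_noise_factor - 1.0) * math.exp(
            -(freq_hz - self.lf_cutoff_hz) / self.lf_decay_hz
        )
        if freq_hz > self.hf_corner_hz:
            m += self.hf_rise_per_khz * (freq_hz - self.hf_corner_hz) / 1000.0
        return m


@dataclass(frozen=True)
class TrialRecord:
    """One cancellation attempt at one ear."""

    session_id: int
    freq_hz: float
    ear: str  # "ipsi" or "contra"
    cancel_level_db: float
    cancel_phase_deg: float  # in [0, 360)
    grade: int
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.ear not in ("ipsi", "contra"):
            raise ValueError("ear must be 'ipsi' or 'contra'")
        if not 0.0 <= self.cancel_phase_deg < 360.0:
            raise ValueError("cancel_phase_deg must lie in [0, 360)")
        if self.grade not in (1, 2, 3, 4, 5):
            raise ValueError("grade must be an integer 1-5")


@dataclass(frozen=True)
class CochlearSignal:
    """Phasor of one tone at one cochlea (linear amplitude, degrees)."""

    amplitude: float
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def phasor(self) -> complex:
        return self.amplitude * cmath.exp(1j * math.radians(self.phase_deg))

    @classmethod
    def from_phasor(cls, z: complex) -> "CochlearSignal":
        return cls(abs(z), math.degrees(cmath.phase(z)) % 360.0)


def superpose(a: CochlearSignal, b: CochlearSignal) -> CochlearSignal:
    """Complex sum of two tones of the same frequency at one cochlea."""
    return CochlearSignal.from_phasor(a.phasor + b.phasor)


def beat_depth(a_amp: float, b_amp: float) -> float:
    """Envelope modulation depth of two equal-frequency-offset tones.

    For tones ~1 Hz apart the envelope swings between |A-B| and A+B;
    the min/max amplitude ratio used here is 1 iff the levels match and
    decreases strictly as they diverge.
    """
    if a_amp < 0 or b_amp < 0:
        raise ValueError("amplitudes must be non-negative")
    if a_amp == 0 and b_amp == 0:
        raise ValueError("beat depth undefined for two silent tones")
    return min(a_amp, b_amp) / max(a_amp, b_amp)


def _level_grid(params: ObserverParams) -> np.ndarray:
    lo, hi = params.level_grid_db
    n = int(round((hi - lo) / params.level_step_db))
    return lo + params.level_step_db * np.arange(n + 1)


def match_level(
    bc_at_cochlea: CochlearSignal,
    ac_path_gain: complex,
    params: ObserverParams,
    rng: np.random.Generator | int,
    freq_hz: float | None = None,
) -> float:
    """Level (dB) of the earphone drive that maximises perceived beating.

    The observer scans the whole quantized level grid and picks the drive
    whose air-conducted amplitude at the cochlea best matches the
    (noisily perceived) bone-conducted amplitude.  Ties resolve to the
    lower level.
    """
    if bc_at_cochlea.amplitude <= 0:
        raise DegenerateTrialError("no audible BC signal to match")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mult = params.noise_multiplier(freq_hz) if freq_hz is not None else 1.0
    eps_db = rng.normal(0.0, params.level_noise_db * mult)
    perceived_bc = bc_at_cochlea.amplitude * 10.0 ** (eps_db / 20.0)
    grid = _level_grid(params)
    ac_amp = 10.0 ** (grid / 20.0) * abs(ac_path_gain)
    depths = np.minimum(perceived_bc, ac_amp) / np.maximum(perceived_bc, ac_amp)
    return float(grid[int(np.argmax(depths))])


def null_phase(
    bc_at_cochlea: CochlearSignal,
    ac_drive_level_db: float,
    ac_path_gain: complex,
    params: ObserverParams,
    rng: np.random.Generator | int,
    freq_hz: float | None = None,
) -> float:
    """Drive phase (deg, on the 2-degree grid) minimising the residual.

    The perceptual error enters as a noisy percept of the BC phase, so
    with zero noise the returned grid value is the one nearest the exact
    antiphase solution.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mult = params.noise_multiplier(freq_hz) if freq_hz is not None else 1.0
    eps_deg = rng.normal(0.0, params.phase_noise_deg * mult)
    bc = bc_at_cochlea.amplitude * cmath.exp(
        1j * math.radians(bc_at_cochlea.phase_deg + eps_deg)
    )
    grid = params.phase_step_deg * np.arange(int(round(360.0 / params.phase_step_deg)))
    ac = (
        10.0 ** (ac_drive_level_db / 20.0)
        * ac_path_gain
        * np.exp(1j * np.radians(grid))
    )
    residual = np.abs(bc + ac)
    return float(grid[int(np.argmin(residual))])


def grade_residual(before_amp: float, after_amp: float, params: ObserverParams) -> int:
    """Map achieved attenuation through the verbal 1-5 grading scale.

    Attenuation 20*log10(before/after) below the lowest threshold reads
    "as loud as the start of the task" (grade 1); total cancellation
    (nothing audible) is grade 5.
    """
    if before_amp <= 0:
        raise ValueError("before_amp must be positive")
    if after_amp < 0:
        raise ValueError("after_amp must be non-negative")
    atten_db = math.inf if after_amp == 0 else 20.0 * math.log10(before_amp / after_amp)
    return 1 + sum(atten_db >= t for t in params.grade_thresholds_db)


@dataclass
class _EarState:
    bc: CochlearSignal
    ac_gain: complex
    level_db: float | None = None
    phase_deg: float | None = None

    def residual_amp(self) -> float:
        if self.level_db is None or self.phase_deg is None:
            return self.bc.amplitude
        ac = CochlearSignal.from_phasor(
            10.0 ** (self.level_db / 20.0)
            * self.ac_gain
            * cmath.exp(1j * math.radians(self.phase_deg))
        )
        return superpose(self.bc, ac).amplitude


def run_trial(
    model: TransferModel,
    freq_hz: float,
    params: ObserverParams,
    session_id: int,
    rng_seed: int | np.random.Generator,
) -> tuple[TrialRecord, TrialRecord]:
    """Execute one full bilateral cancellation trial at one frequency.

    Sequence: ipsi level match, ipsi phase null, contra level match (with
    the ipsi canceller playing — inert under the isolating-earphone
    assumption), contra phase null, then ``n_refinement_iters`` further
    alternating refinements.  Both ears receive the grade of the worse
    ear's residual, since the listener rates the overall percept.
    """
    if isinstance(rng_seed, (int, np.integer)):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(rng_seed), int(session_id), int(freq_hz)])
        )
    else:
        rng = rng_seed
    idx = model.index_of(freq_hz)

    ears = {
        "ipsi": _EarState(
            bc=CochlearSignal(
                float(10.0 ** (model.level_bc_ipsi_db[idx] / 20.0)),
                float(model.phase_bc_ipsi_deg[idx] % 360.0),
            ),
            ac_gain=complex(model.H_ac_left[idx]),
        ),
        "contra": _EarState(
            bc=CochlearSignal(
                float(10.0 ** (model.level_bc_contra_db[idx] / 20.0)),
                float(model.phase_bc_contra_deg[idx] % 360.0),
            ),
            ac_gain=complex(model.H_ac_right[idx]),
        ),
    }

    degenerate = any(s.bc.amplitude <= 0 for s in ears.values())
    if not degenerate:
        for _ in range(1 + params.n_refinement_iters):
            for state in ears.values():
                state.level_db = match_level(
                    state.bc, state.ac_gain, params, rng, freq_hz
                )
                state.phase_deg = null_phase(
                    state.bc, state.level_db, state.ac_gain, params, rng, freq_hz
                )
        worse_ratio = max(
            s.residual_amp() / s.bc.amplitude for s in ears.values()
        )
        grade = grade_residual(1.0, worse_ratio, params)
    else:
        grade = 1

    records = []
    for ear, state in ears.items():
        records.append(
            TrialRecord(
                session_id=int(session_id),
                freq_hz=float(freq_hz),
                ear=ear,
                cancel_level_db=float(state.level_db if state.level_db is not None else 0.0),
                cancel_phase_deg=float((state.phase_deg or 0.0) % 360.0),
                grade=int(grade),
                excluded=False,
            )
        )
    return records[0], records[1]
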