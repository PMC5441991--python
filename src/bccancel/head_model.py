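"""Synthetic bilateral bone- and air-conduction transfer functions.

A single mastoid-placed bone transducer (BT) drives both cochleae through
the skull; two insert earphones drive each cochlea through its own ear
canal.  The physics of transcranial transmission is not modelled — the
transfer functions are phenomenological, built to carry the statistical
structure measured psychoacoustically in normal-hearing listeners:

* inter-cochlear phase difference (ICPD) near 180° below ~1 kHz (the two
  temporal bones move roughly in antiphase in the skull's mass-spring
  region), accumulating steeply between 1 and 4 kHz, then rising with an
  approximately constant slope between 4 and 8 kHz;
* inter-cochlear level difference (ICLD, ipsilateral minus contralateral,
  positive = ipsilateral louder) small or slightly negative at low
  frequencies, rising to roughly 10–15 dB above 4 kHz with a mild
  fall-off above 6 kHz;
* narrow anti-resonance notches (>10 dB deep, <500 Hz wide) in the level
  needed for cancellation, one per side, with the rapid local phase
  rotation a near-axis complex zero implies;
* per-session transducer-coupling perturbations that shift both bone
  paths identically (common mode) plus a contralateral-only phase jitter
  that grows linearly with frequency (placement sensitivity).

Phases are stored continuously (unwrapped, degrees); only the simulated
measurement reduces them modulo 360, so ground truth stays unambiguous
for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Notch",
    "TransferModel",
    "SessionPerturbation",
    "SessionJitterScales",
    "make_reference_model",
    "draw_session_perturbation",
    "apply_session_perturbation",
    "perturb_for_session",
]

FREQ_MIN_HZ = 250.0
FREQ_MAX_HZ = 8000.0


@dataclass(frozen=True)
class Notch:
    """Anti-resonance descriptor: a complex zero/pole pair near the axis."""

    center_hz: float
    width_hz: float
    depth_db: float
    side: str  # "ipsi" or "contra"

    def response(self, freqs_hz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Level (dB, <=0) and continuous phase (deg) contribution.

        The notch is the ratio of a high-Q zero to a moderate-Q pole at the
        same centre frequency; depth at centre is q_zero/q_pole and the
        phase transition is continuous because the imaginary parts of
        numerator and denominator never vanish for f > 0.
        """
        q_pole = self.center_hz / self.width_hz
        q_zero = q_pole * 10.0 ** (self.depth_db / 20.0)
        x = np.asarray(freqs_hz, dtype=float) / self.center_hz
        re = 1.0 - x**2
        num = re + 1j * x / q_zero
        den = re + 1j * x / q_pole
        level_db = 20.0 * np.log10(np.abs(num) / np.abs(den))
        # atan2 with strictly positive imaginary part: continuous in f
        phase_deg = np.degrees(
            np.arctan2(x / q_zero, re) - np.arctan2(x / q_pole, re)
        )
        return level_db, phase_deg


@dataclass
class TransferModel:
    """Complex transfer functions from the BT and the two insert earphones.

    Levels are dB re an arbitrary common reference, phases are continuous
    (unwrapped) degrees.  ``ipsi`` is the cochlea on the transducer side.
    """

    freqs_hz: np.ndarray
    level_bc_ipsi_db: np.ndarray
    phase_bc_ipsi_deg: np.ndarray
    level_bc_contra_db: np.ndarray
    phase_bc_contra_deg: np.ndarray
    level_ac_left_db: np.ndarray
    phase_ac_left_deg: np.ndarray
    level_ac_right_db: np.ndarray
    phase_ac_right_deg: np.ndarray
    notches: list[Notch] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        for name in (
            "level_bc_ipsi_db", "phase_bc_ipsi_deg",
            "level_bc_contra_db", "phase_bc_contra_deg",
            "level_ac_left_db", "phase_ac_left_deg",
            "level_ac_right_db", "phase_ac_right_deg",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.freqs_hz.shape:
                raise ValueError(f"{name} shape {arr.shape} != freqs shape")
            setattr(self, name, arr)
        self.validate()

    def validate(self) -> None:
        f = self.freqs_hz
        if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs_hz must be strictly increasing, length >= 2")
        if f[0] < FREQ_MIN_HZ or f[-1] > FREQ_MAX_HZ:
            raise ValueError(f"frequencies must lie in [{FREQ_MIN_HZ}, {FREQ_MAX_HZ}] Hz")
        for name in ("phase_bc_ipsi_deg", "phase_bc_contra_deg",
                     "phase_ac_left_deg", "phase_ac_right_deg"):
            ph = getattr(self, name)
            if np.any(np.abs(np.diff(ph)) >= 180.0):
                raise ValueError(f"{name} not continuous: adjacent step >= 180 deg")
        for name in ("level_bc_ipsi_db", "level_bc_contra_db",
                     "level_ac_left_db", "level_ac_right_db"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    # -- complex accessors -------------------------------------------------
    @staticmethod
    def _to_complex(level_db: np.ndarray, phase_deg: np.ndarray) -> np.ndarray:
        return 10.0 ** (level_db / 20.0) * np.exp(1j * np.radians(phase_deg))

    @property
    def H_bc_ipsi(self) -> np.ndarray:
        return self._to_complex(self.level_bc_ipsi_db, self.phase_bc_ipsi_deg)

    @property
    def H_bc_contra(self) -> np.ndarray:
        return self._to_complex(self.level_bc_contra_db, self.phase_bc_contra_deg)

    @property
    def H_ac_left(self) -> np.ndarray:
        return self._to_complex(self.level_ac_left_db, self.phase_ac_left_deg)

    @property
    def H_ac_right(self) -> np.ndarray:
        return self._to_complex(self.level_ac_right_db, self.phase_ac_right_deg)

    # -- ground truth ------------------------------------------------------
    @property
    def icpd_true_deg(self) -> np.ndarray:
        """True inter-cochlear phase difference (ipsi minus contra), degrees."""
        return self.phase_bc_ipsi_deg - self.phase_bc_contra_deg

    @property
    def icld_true_db(self) -> np.ndarray:
        """True inter-cochlear level difference (ipsi minus contra), dB."""
        return self.level_bc_ipsi_db - self.level_bc_contra_db

    def index_of(self, freq_hz: float) -> int:
        idx = int(np.argmin(np.abs(self.freqs_hz - freq_hz)))
        if abs(self.freqs_hz[idx] - freq_hz) > 1e-6:
            raise ValueError(f"frequency {freq_hz} Hz not on model grid")
        return idx

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "freqs_hz": self.freqs_hz.tolist(),
            "level_bc_ipsi_db": self.level_bc_ipsi_db.tolist(),
            "phase_bc_ipsi_deg": self.phase_bc_ipsi_deg.tolist(),
            "level_bc_contra_db": self.level_bc_contra_db.tolist(),
            "phase_bc_contra_deg": self.phase_bc_contra_deg.tolist(),
            "level_ac_left_db": self.level_ac_left_db.tolist(),
            "phase_ac_left_deg": self.phase_ac_left_deg.tolist(),
            "level_ac_right_db": self.level_ac_right_db.tolist(),
            "phase_ac_right_deg": self.phase_ac_right_deg.tolist(),
            "notches": [
                {"center_hz": n.center_hz, "width_hz": n.width_hz,
                 "depth_db": n.depth_db, "side": n.side}
                for n in self.notches
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "TransferModel":
        notches = [Notch(**n) for n in d.get("notches", [])]
        return cls(
            freqs_hz=np.asarray(d["freqs_hz"]),
            level_bc_ipsi_db=np.asarray(d["level_bc_ipsi_db"]),
            phase_bc_ipsi_deg=np.asarray(d["phase_bc_ipsi_deg"]),
            level_bc_contra_db=np.asarray(d["level_bc_contra_db"]),
            phase_bc_contra_deg=np.asarray(d["phase_bc_contra_deg"]),
            level_ac_left_db=np.asarray(d["level_ac_left_db"]),
            phase_ac_left_deg=np.asarray(d["phase_ac_left_deg"]),
            level_ac_right_db=np.asarray(d["level_ac_right_db"]),
            phase_ac_right_deg=np.asarray(d["phase_ac_right_deg"]),
            notches=notches,
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TransferModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return 3.0 * x**2 - 2.0 * x**3


def make_reference_model(
    seed: int,
    grid_step_hz: float = 50.0,
    *,
    antiphase_spread_deg: float = 30.0,
    ac_mismatch_db: float = 0.0,
    ac_mismatch_deg: float = 0.0,
) -> TransferModel:
    """Draw a random transfer model with the measured qualitative structure.

    Parameters
    ----------
    seed
        Any integer; identical seeds give identical models.
    grid_step_hz
        Frequency grid step; must divide the 250–8000 Hz span.  50 Hz
        reproduces the 156-point measurement grid.
    antiphase_spread_deg
        Half-width of the low-frequency band around 180° within which the
        ipsi/contra phase difference is kept (antiphase temporal-bone
        motion in the 0.3–1 kHz mass-spring region).
    ac_mismatch_db, ac_mismatch_deg
        Optional left/right insert-earphone asymmetry applied to the right
        (contralateral) earphone path.  Defaults off: the subtraction that
        yields inter-cochlear differences attributes all asymmetry to the
        bone paths, which is exact only for matched earphones.
    """
    if not (np.isfinite(grid_step_hz) and grid_step_hz > 0):
        raise ValueError("grid_step_hz must be a positive finite scalar")
    span = FREQ_MAX_HZ - FREQ_MIN_HZ
    n_steps = span / grid_step_hz
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"grid_step_hz={grid_step_hz} does not divide the "
                         f"{FREQ_MIN_HZ}-{FREQ_MAX_HZ} Hz span")
    freqs = FREQ_MIN_HZ + grid_step_hz * np.arange(int(round(n_steps)) + 1)

    rng = np.random.default_rng(seed)
    # ICPD skeleton: near-antiphase floor, steep mid-band accumulation,
    # constant slope above 4 kHz.  All terms monotone non-decreasing.
    low_slope = rng.uniform(4.0, 12.0)          # deg per kHz below the knee
    mid_rise = rng.uniform(500.0, 750.0)        # deg accumulated 1-4 kHz
    high_slope = rng.uniform(120.0, 200.0)      # deg per kHz above 4 kHz
    icpd_smooth = (
        180.0
        + low_slope * (freqs - FREQ_MIN_HZ) / 1000.0
        + mid_rise * _smoothstep((freqs - 1000.0) / 3000.0)
        + high_slope * np.clip(freqs - 4000.0, 0.0, None) / 1000.0
    )

    # ipsilateral bone path: plain propagation delay plus gentle level trend
    delay_ms = rng.uniform(0.25, 0.40)
    phase_base = -360.0 * delay_ms * freqs / 1000.0
    base_level = rng.uniform(-12.0, -6.0)
    trend = np.zeros_like(freqs)
    for k in range(1, 4):
        amp = rng.uniform(0.0, 2.0)
        ph0 = rng.uniform(0.0, 2.0 * np.pi)
        trend += amp * np.cos(2.0 * np.pi * k * (freqs - FREQ_MIN_HZ) / span + ph0)

    # ICLD skeleton: small/negative at low frequencies, 10-15 dB above
    # 4 kHz, mild fall-off above 6 kHz.
    icld_low = rng.uniform(-3.0, 0.0)
    icld_rise = rng.uniform(12.0, 16.0)
    icld_fall = rng.uniform(1.0, 3.0)
    icld_smooth = (
        icld_low
        + icld_rise * _smoothstep((freqs - 1500.0) / 3500.0)
        - icld_fall * np.clip(freqs - 6000.0, 0.0, None) / 2000.0
    )

    notches = [
        Notch(center_hz=float(rng.uniform(1500.0, 3600.0)),
              width_hz=float(rng.uniform(280.0, 400.0)),
              depth_db=float(rng.uniform(12.0, 16.0)), side="ipsi"),
        Notch(center_hz=float(rng.uniform(1500.0, 3800.0)),
              width_hz=float(rng.uniform(280.0, 400.0)),
              depth_db=float(rng.uniform(12.0, 16.0)), side="contra"),
    ]
    level_ipsi = base_level + trend
    phase_ipsi = phase_base.copy()
    level_contra = base_level + trend - icld_smooth
    phase_contra = phase_base - icpd_smooth
    for n in notches:
        lvl, ph = n.response(freqs)
        if n.side == "ipsi":
            level_ipsi = level_ipsi + lvl
            phase_ipsi = phase_ipsi + ph
        else:
            level_contra = level_contra + lvl
            phase_contra = phase_contra + ph

    # keep the low-frequency antiphase band honest for any draw
    low = freqs <= 1000.0
    dev = np.abs((phase_ipsi - phase_contra)[low] - 180.0)
    if np.any(dev > antiphase_spread_deg):  # pragma: no cover - defensive
        raise RuntimeError("antiphase band violated; adjust skeleton ranges")

    zeros = np.zeros_like(freqs)
    return TransferModel(
        freqs_hz=freqs,
        level_bc_ipsi_db=level_ipsi,
        phase_bc_ipsi_deg=phase_ipsi,
        level_bc_contra_db=level_contra,
        phase_bc_contra_deg=phase_contra,
        level_ac_left_db=zeros.copy(),
        phase_ac_left_deg=zeros.copy(),
        level_ac_right_db=zeros + ac_mismatch_db,
        phase_ac_right_deg=zeros + ac_mismatch_deg,
        notches=notches,
        seed=int(seed),
    )


@dataclass(frozen=True)
class SessionPerturbation:
    """Realized coupling change for one experimental sitting.

    Gain and phase offsets are common mode: a change of coupling at the
    transducer alters the drive into the skull and therefore both bone
    paths identically.  Only the contralateral path carries an extra
    placement-sensitivity term, a phase ramp growing with frequency.
    """

    session_id: int
    bc_gain_offset_db: float = 0.0
    bc_phase_offset_deg: float = 0.0
    contra_phase_jitter_slope: float = 0.0  # deg per kHz


@dataclass(frozen=True)
class SessionJitterScales:
    """Standard deviations of the zero-mean session perturbation draws."""

    gain_sd_db: float = 1.5
    phase_sd_deg: float = 15.0
    contra_slope_sd_deg_per_khz: float = 0.0

    def __post_init__(self) -> None:
        if min(self.gain_sd_db, self.phase_sd_deg,
               self.contra_slope_sd_deg_per_khz) < 0:
            raise ValueError("jitter scales must be non-negative")


def draw_session_perturbation(
    session_id: int, seed: int, scales: SessionJitterScales
) -> SessionPerturbation:
    rng = np.random.default_rng(np.random.SeedSequence([seed, session_id]))
    return SessionPerturbation(
        session_id=session_id,
        bc_gain_offset_db=float(rng.normal(0.0, scales.gain_sd_db)),
        bc_phase_offset_deg=float(rng.normal(0.0, scales.phase_sd_deg)),
        contra_phase_jitter_slope=float(
            rng.normal(0.0, scales.contra_slope_sd_deg_per_khz)
        ),
    )


def apply_session_perturbation(
    model: TransferModel, pert: SessionPerturbation
) -> TransferModel:
    """Return a copy of ``model`` with the coupling change applied."""
    return replace(
        model,
        level_bc_ipsi_db=model.level_bc_ipsi_db + pert.bc_gain_offset_db,
        level_bc_contra_db=model.level_bc_contra_db + pert.bc_gain_offset_db,
        phase_bc_ipsi_deg=model.phase_bc_ipsi_deg + pert.bc_phase_offset_deg,
        phase_bc_contra_deg=(
            model.phase_bc_contra_deg
            + pert.bc_phase_offset_deg
            + pert.contra_phase_jitter_slope * model.freqs_hz / 1000.0
        ),
    )


def perturb_for_session(
    model: TransferModel,
    session_id: int,
    seed: int,
    scales: SessionJitterScales,
) -> tuple[TransferModel, SessionPerturbation]:
    """Draw and apply the coupling perturbation for one sitting."""
    pert = draw_session_perturbation(session_id, seed, scales)
    return apply_session_perturbation(model, pert), pert
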