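"""Per-frequency cross-talk cancellation filter for two bone transducers.

With bilateral bone-anchored devices, sound from each transducer reaches
both cochleae.  If the complex transfer from each transducer to each
cochlea is known, the unwanted cross-talk of the source transducer at the
far cochlea can be cancelled by driving the transducer on that side with
a matched-level, opposite-phase copy: per frequency the auxiliary weight
is w = -H[source][off] / H[aux][off].  The design is per-bin only (no
broadband FIR synthesis) and, by default, first order: the cancelling
signal's own cross-talk back to the near cochlea is ignored unless the
exact 2x2 solve is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .head_model import TransferModel

__all__ = [
    "BilateralTransferSet",
    "CancellerDesign",
    "design_filter",
    "design_exact_drives",
    "residual_under_error",
    "evaluate_design",
]

RESIDUAL_FLOOR_DB = -200.0

EARS = ("left", "right")


@dataclass
class BilateralTransferSet:
    """2x2 complex transfer matrix per frequency: H[t][c], transducer t to
    cochlea c, with t, c in {left=0, right=1}."""

    freqs_hz: np.ndarray
    H: np.ndarray  # shape (n, 2, 2), complex

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.H = np.asarray(self.H, dtype=complex)
        if self.H.shape != (self.freqs_hz.size, 2, 2):
            raise ValueError("H must have shape (n_freqs, 2, 2)")
        if not np.all(np.isfinite(self.H.view(float))):
            raise ValueError("transfer matrices must be finite")

    @property
    def singular_mask(self) -> np.ndarray:
        """Frequencies where the 2x2 matrix is (numerically) singular."""
        det = np.abs(np.linalg.det(self.H))
        scale = np.abs(self.H).max(axis=(1, 2)) ** 2
        return det <= 1e-12 * np.maximum(scale, 1e-300)

    @classmethod
    def from_models(
        cls, left: TransferModel, right: TransferModel
    ) -> "BilateralTransferSet":
        """Assemble the matrix set from two single-transducer head models.

        ``left`` is a model measured with the transducer on the left
        mastoid (ipsi = left cochlea); ``right`` mirrors it.
        """
        if left.freqs_hz.shape != right.freqs_hz.shape or np.any(
            left.freqs_hz != right.freqs_hz
        ):
            raise ValueError("models must share a frequency grid")
        n = left.freqs_hz.size
        H = np.empty((n, 2, 2), dtype=complex)
        H[:, 0, 0] = left.H_bc_ipsi
        H[:, 0, 1] = left.H_bc_contra
        H[:, 1, 0] = right.H_bc_contra
        H[:, 1, 1] = right.H_bc_ipsi
        return cls(freqs_hz=left.freqs_hz.copy(), H=H)


@dataclass
class CancellerDesign:
    """Auxiliary-transducer drive weights and predicted residuals."""

    freqs_hz: np.ndarray
    source: int  # transducer index whose cross-talk is cancelled
    gain_db: np.ndarray
    phase_deg: np.ndarray
    predicted_residual_db: np.ndarray  # re uncancelled cross-talk; <= 0 if feasible
    feasible: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return 10.0 ** (self.gain_db / 20.0) * np.exp(1j * np.radians(self.phase_deg))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.freqs_hz,
                "gain_db": self.gain_db,
                "phase_deg": self.phase_deg,
                "predicted_residual_db": self.predicted_residual_db,
                "feasible": self.feasible,
            }
        )


def design_filter(
    H: BilateralTransferSet,
    source: int = 0,
    *,
    tol: float = 1e-12,
    floor_db: float = RESIDUAL_FLOOR_DB,
) -> CancellerDesign:
    """Design the per-frequency cross-talk canceller for one source.

    The off-target cochlea is the one opposite the source transducer; the
    auxiliary transducer is the one on that side.  First-order weight per
    frequency: w = -H[source][off] / H[aux][off], i.e. matched level and
    opposite phase at the off-target cochlea.  The off-cochlea equation is
    linear in w, so with exact transfer data the residual there is zero;
    the auxiliary signal's own contribution to the near cochlea is the
    recursive effect handled by :func:`design_exact_drives`.
    """
    if source not in (0, 1):
        raise ValueError("source must be 0 (left) or 1 (right)")
    off = 1 - source
    aux = 1 - source
    Hs = H.H[:, source, off]
    Ha = H.H[:, aux, off]
    feasible = np.abs(Ha) > tol * np.maximum(np.abs(H.H).max(axis=(1, 2)), 1e-300)
    w = np.where(feasible, -Hs / np.where(feasible, Ha, 1.0), 0.0)
    # no cancellation needed where the source's cross-talk is already zero
    w = np.where(np.abs(Hs) == 0.0, 0.0, w)

    residual = np.abs(Hs + w * Ha)
    ref = np.abs(Hs)
    with np.errstate(divide="ignore", invalid="ignore"):
        res_db = 20.0 * np.log10(residual / np.where(ref > 0, ref, 1.0))
    res_db = np.where(ref > 0, res_db, floor_db)
    res_db = np.maximum(res_db, floor_db)
    res_db = np.where(feasible | (np.abs(Hs) == 0.0), res_db, 0.0)

    amp = np.abs(w)
    with np.errstate(divide="ignore"):
        gain_db = np.where(amp > 0, 20.0 * np.log10(np.where(amp > 0, amp, 1.0)),
                           -np.inf)
    phase_deg = np.degrees(np.angle(w)) % 360.0
    return CancellerDesign(
        freqs_hz=H.freqs_hz.copy(),
        source=source,
        gain_db=gain_db,
        phase_deg=phase_deg,
        predicted_residual_db=res_db,
        feasible=feasible | (np.abs(Hs) == 0.0),
    )


def design_exact_drives(
    H: BilateralTransferSet, source: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2x2 solve: drives [d_source, d_aux] per frequency delivering
    unit signal to the near cochlea and zero to the off-target cochlea,
    compensating the cancelling signal's own cross-talk.  Singular
    frequencies yield NaN drives."""
    if source not in (0, 1):
        raise ValueError("source must be 0 (left) or 1 (right)")
    near, off = source, 1 - source
    target = np.zeros((H.freqs_hz.size, 2), dtype=complex)
    target[:, near] = 1.0
    drives = np.full_like(target, np.nan)
    ok = ~H.singular_mask
    # cochlear signal c = d @ H[f]  (row vector of drives), so solve H^T x = t
    drives[ok] = np.linalg.solve(
        np.transpose(H.H[ok], (0, 2, 1)), target[ok][..., None]
    )[..., 0]
    return drives[:, source], drives[:, 1 - source]


def residual_under_error(
    gain_err_db, phase_err_deg, floor_db: float = RESIDUAL_FLOOR_DB
):
    """Residual cross-talk (dB re uncancelled) under weight errors.

    A canceller whose weight is off by ``gain_err_db`` and
    ``phase_err_deg`` leaves the fraction r = |1 - g e^{i phi}| of the
    original cross-talk amplitude, g = 10^(gain_err_db/20).  Returns
    20 log10(r), floored at ``floor_db``; scalar in, scalar out.
    """
    g = 10.0 ** (np.asarray(gain_err_db, dtype=float) / 20.0)
    phi = np.radians(np.asarray(phase_err_deg, dtype=float))
    r = np.abs(1.0 - g * np.exp(1j * phi))
    with np.errstate(divide="ignore"):
        out = np.where(r > 0, 20.0 * np.log10(np.where(r > 0, r, 1.0)), floor_db)
    out = np.maximum(out, floor_db)
    return float(out) if out.ndim == 0 else out


def evaluate_design(
    design: CancellerDesign,
    H_true: BilateralTransferSet,
    floor_db: float = RESIDUAL_FLOOR_DB,
) -> np.ndarray:
    """Residual cross-talk (dB re uncancelled) of a design against the
    true transfer set — the simulated suppression achieved in situ."""
    off = 1 - design.source
    aux = 1 - design.source
    Hs = H_true.H[:, design.source, off]
    Ha = H_true.H[:, aux, off]
    residual = np.abs(Hs + design.weights * Ha)
    ref = np.abs(Hs)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 20.0 * np.log10(residual / np.where(ref > 0, ref, 1.0))
    db = np.where(ref > 0, db, floor_db)
    return np.maximum(db, floor_db)
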