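"""Turning trial records into unwrapped phase series and inter-cochlear profiles.

Cancellation phases come out of the procedure modulo 360 degrees.  Within
one sitting the frequency grid is fine enough (50 Hz) that the nearest
360-degree-multiple rule restores continuity; between sittings the series
is stitched by comparing the highest frequency of one band with the lowest
of the next and shifting the whole later band by the multiple of 360 that
minimises the boundary step.  The lowest test frequency (250 Hz by
default) anchors the whole series in [0, 360); absolute values remain
arbitrary because they include the transducer coupling of each sitting.

Subtracting the ipsilateral from the contralateral unwrapped phase and
level removes everything common to the two ears — in particular the
session-to-session coupling changes — leaving the inter-cochlear phase
difference (ICPD, degrees) and level difference (ICLD, dB, positive =
ipsilateral greater).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .psychophysics import TrialRecord

__all__ = [
    "UnwrappedSeries",
    "IntercochlearProfile",
    "VariabilitySummary",
    "PairedTTest",
    "records_to_frame",
    "exclude_grade1",
    "unwrap_within_session",
    "stitch_sessions",
    "intercochlear_profile",
    "session_variability",
    "paired_sd_test",
]

RECORD_COLUMNS = [
    "session_id", "freq_hz", "ear", "cancel_level_db",
    "cancel_phase_deg", "grade", "excluded",
]


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the canonical CSV-schema table."""
    return pd.DataFrame(
        [
            {
                "session_id": r.session_id,
                "freq_hz": r.freq_hz,
                "ear": r.ear,
                "cancel_level_db": r.cancel_level_db,
                "cancel_phase_deg": r.cancel_phase_deg,
                "grade": r.grade,
                "excluded": r.excluded,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def exclude_grade1(records: pd.DataFrame) -> pd.DataFrame:
    """Drop trials graded 1 ("as loud as start of task") from analysis.

    A grade belongs to the whole bilateral trial: if either ear of a
    (session, frequency) pair carries grade 1, both ears' results are
    marked excluded and removed, since a poorly cancelled ipsilateral
    tone corrupts the subsequent contralateral adjustment too.
    """
    df = records.copy()
    bad = df.loc[df["grade"] == 1, ["session_id", "freq_hz"]].drop_duplicates()
    key = df.set_index(["session_id", "freq_hz"]).index
    bad_key = bad.set_index(["session_id", "freq_hz"]).index
    df["excluded"] = key.isin(bad_key)
    return df.loc[~df["excluded"]].reset_index(drop=True)


def _nearest_multiple(delta: float) -> int:
    """Multiple k of 360 minimising |delta - 360k|; ties toward smaller |k|."""
    k = math.floor(delta / 360.0 + 0.5)
    if abs(delta - 360.0 * k) == 180.0 and abs(k - 1) < abs(k):
        k -= 1
    return k


@dataclass
class UnwrappedSeries:
    """Continuous cancellation phase (and level) versus frequency, one ear."""

    freqs_hz: np.ndarray
    phase_deg: np.ndarray
    level_db: np.ndarray | None = None
    anchor_freq_hz: float = 250.0
    anchor_fallback: bool = False  # anchor frequency was excluded; nearest used

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if self.level_db is not None:
            self.level_db = np.asarray(self.level_db, dtype=float)
        if self.freqs_hz.shape != self.phase_deg.shape:
            raise ValueError("freqs and phases must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")


def unwrap_within_session(
    phases_deg: np.ndarray, freqs_hz: np.ndarray | None = None
) -> np.ndarray:
    """Unwrap a modulo-360 phase sequence by nearest-multiple continuity.

    The first value is kept as measured; each successive value is shifted
    by the multiple of 360 minimising the step to its predecessor.  An
    exact 180-degree tie resolves toward the smaller absolute unwrapped
    value.  True steps above 180 degrees per grid point are aliased — a
    documented limit of the 50 Hz sampling.
    """
    p = np.asarray(phases_deg, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one phase value")
    out = np.empty_like(p)
    out[0] = p[0]
    for i in range(1, p.size):
        delta = p[i] - out[i - 1]
        k = math.floor(delta / 360.0 + 0.5)
        lo = p[i] - 360.0 * k
        if abs(lo - out[i - 1]) == 180.0:
            alt = lo + 360.0  # the other candidate, 180 deg on the far side
            if abs(alt) < abs(lo):
                lo = alt
        out[i] = lo
    return out


def stitch_sessions(
    bands: list[UnwrappedSeries],
    anchor_freq_hz: float = 250.0,
    max_gap_hz: float = 500.0,
) -> UnwrappedSeries:
    """Join per-sitting unwrapped bands into one continuous series.

    Bands are ordered by frequency; each later band is shifted by the
    multiple of 360 degrees that minimises the step between the highest
    retained frequency of the previous band and the lowest of the next
    (ties broken toward zero shift).  If the nominal boundary frequencies
    were excluded, the nearest retained ones are used and the result is
    flagged.  Finally the whole series is offset by a multiple of 360 so
    the anchor-frequency phase lies in [0, 360).
    """
    if not bands:
        raise ValueError("no bands to stitch")
    bands = sorted(bands, key=lambda b: b.freqs_hz[0])
    freqs = [bands[0].freqs_hz]
    phases = [bands[0].phase_deg.copy()]
    levels = [bands[0].level_db] if bands[0].level_db is not None else None
    for prev, nxt in zip(bands, bands[1:]):
        gap = nxt.freqs_hz[0] - freqs[-1][-1]
        if gap <= 0:
            raise ValueError("bands overlap in frequency")
        if gap > max_gap_hz:
            raise ValueError(
                f"bands not abutting: gap of {gap:g} Hz exceeds {max_gap_hz:g} Hz"
            )
        delta = nxt.phase_deg[0] - phases[-1][-1]
        k = _nearest_multiple(delta)
        freqs.append(nxt.freqs_hz)
        phases.append(nxt.phase_deg - 360.0 * k)
        if levels is not None:
            if nxt.level_db is None:
                raise ValueError("levels present in some bands but not all")
            levels.append(nxt.level_db)

    freq = np.concatenate(freqs)
    phase = np.concatenate(phases)
    level = np.concatenate(levels) if levels is not None else None

    # anchor the series: phase at the anchor frequency into [0, 360)
    fallback = False
    if not np.any(np.isclose(freq, anchor_freq_hz)):
        fallback = True
    anchor_idx = int(np.argmin(np.abs(freq - anchor_freq_hz)))
    shift = 360.0 * math.floor(phase[anchor_idx] / 360.0)
    return UnwrappedSeries(
        freqs_hz=freq,
        phase_deg=phase - shift,
        level_db=level,
        anchor_freq_hz=float(freq[anchor_idx]),
        anchor_fallback=fallback,
    )


@dataclass
class IntercochlearProfile:
    """Unwrapped inter-cochlear differences per retained frequency."""

    freqs_hz: np.ndarray
    icpd_deg: np.ndarray  # ipsi minus contra unwrapped cancellation phase
    icld_db: np.ndarray   # ipsi minus contra cancellation level; positive = ipsi greater
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"freq_hz": self.freqs_hz, "icpd_deg": self.icpd_deg,
             "icld_db": self.icld_db}
        )


def intercochlear_profile(
    ipsi: UnwrappedSeries,
    contra: UnwrappedSeries,
    n_excluded: int = 0,
) -> IntercochlearProfile:
    """Subtract contralateral from ipsilateral unwrapped phase and level."""
    if ipsi.level_db is None or contra.level_db is None:
        raise ValueError("both series need levels to form a profile")
    if ipsi.freqs_hz.shape != contra.freqs_hz.shape or np.any(
        ipsi.freqs_hz != contra.freqs_hz
    ):
        warnings.warn("frequency sets differ between ears; using intersection")
        common, ia, ic = np.intersect1d(
            ipsi.freqs_hz, contra.freqs_hz, return_indices=True
        )
        return IntercochlearProfile(
            freqs_hz=common,
            icpd_deg=ipsi.phase_deg[ia] - contra.phase_deg[ic],
            icld_db=ipsi.level_db[ia] - contra.level_db[ic],
            n_excluded=n_excluded,
        )
    return IntercochlearProfile(
        freqs_hz=ipsi.freqs_hz.copy(),
        icpd_deg=ipsi.phase_deg - contra.phase_deg,
        icld_db=ipsi.level_db - contra.level_db,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class PairedTTest:
    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_sd_test(a: np.ndarray, b: np.ndarray) -> PairedTTest:
    """Two-sided paired Student t-test, t = mean(d) / (sd(d)/sqrt(n)).

    With zero variance of the differences the statistic is undefined; the
    result is flagged degenerate with p = 1 if the mean difference is also
    zero and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need paired 1-d arrays with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        return PairedTTest(
            t=0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean()),
            p=1.0 if d.mean() == 0 else 0.0,
            n=n,
            degenerate=True,
        )
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTTest(t=float(t), p=float(p), n=n)


def _align_to_circular_mean(phases_deg: np.ndarray) -> np.ndarray:
    """Shift each phase by a multiple of 360 onto the branch nearest the
    circular mean, so a linear SD is meaningful for spreads << 360."""
    p = np.asarray(phases_deg, dtype=float)
    mean_angle = math.degrees(
        np.angle(np.mean(np.exp(1j * np.radians(p))))
    )
    return mean_angle + ((p - mean_angle + 180.0) % 360.0 - 180.0)


@dataclass
class VariabilitySummary:
    """Across-sitting mean/SD per frequency and ear, plus paired tests."""

    table: pd.DataFrame  # freq_hz, ear, mean_level_db, sd_level_db,
    #                      mean_phase_deg, sd_phase_deg, n, flagged
    tests: dict = field(default_factory=dict)


def session_variability(records: pd.DataFrame) -> VariabilitySummary:
    """Across-session mean and sample SD of cancellation level and phase.

    Phase SDs are computed after aligning each session's phase onto the
    360-degree branch nearest the cell's circular mean.  Cells with fewer
    than 2 retained sessions are flagged and omitted from the paired
    tests.  The tests compare ipsi vs contra SDs across frequencies
    (phase and level) and ipsi vs contra mean levels.
    """
    rows = []
    for (freq, ear), cell in records.groupby(["freq_hz", "ear"]):
        n = len(cell)
        if n < 2:
            rows.append(
                {"freq_hz": freq, "ear": ear, "mean_level_db": np.nan,
                 "sd_level_db": np.nan, "mean_phase_deg": np.nan,
                 "sd_phase_deg": np.nan, "n": n, "flagged": True}
            )
            continue
        aligned = _align_to_circular_mean(cell["cancel_phase_deg"].to_numpy())
        rows.append(
            {
                "freq_hz": freq,
                "ear": ear,
                "mean_level_db": cell["cancel_level_db"].mean(),
                "sd_level_db": cell["cancel_level_db"].std(ddof=1),
                "mean_phase_deg": aligned.mean(),
                "sd_phase_deg": aligned.std(ddof=1),
                "n": n,
                "flagged": False,
            }
        )
    table = pd.DataFrame(rows).sort_values(["freq_hz", "ear"]).reset_index(drop=True)

    tests: dict = {}
    ok = table.loc[~table["flagged"]]
    wide = ok.pivot(index="freq_hz", columns="ear",
                    values=["sd_phase_deg", "sd_level_db", "mean_level_db"]).dropna()
    if len(wide) >= 2:
        tests["phase_sd_ipsi_vs_contra"] = paired_sd_test(
            wide[("sd_phase_deg", "ipsi")].to_numpy(),
            wide[("sd_phase_deg", "contra")].to_numpy(),
        )
        tests["level_sd_ipsi_vs_contra"] = paired_sd_test(
            wide[("sd_level_db", "ipsi")].to_numpy(),
            wide[("sd_level_db", "contra")].to_numpy(),
        )
        tests["level_mean_ipsi_vs_contra"] = paired_sd_test(
            wide[("mean_level_db", "ipsi")].to_numpy(),
            wide[("mean_level_db", "contra")].to_numpy(),
        )
    return VariabilitySummary(table=table, tests=tests)
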