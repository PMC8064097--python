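"""Breath tracer: CO2-trigger detection, end-tidal extraction, duplicate
pairing, carryover flagging, and Lin's concordance for repeatability.

The sampler raises an electrical trigger when the exhaled CO2
concentration first reaches 4%; the end-tidal fraction is taken as the
ion signal averaged over a fixed window starting a fixed delay after the
trigger (default: 5 s delay, 5 s window, i.e. five 1 Hz spectra).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASES = ("background", "breath", "flush", "unknown")

FLAG_SHORT = "short_exhalation"
FLAG_CARRYOVER = "carryover_suspect"
FLAG_MISSING = "missing_replicate"

#: Channels watched for sampling-line carryover: ethanol and the
#: monoterpene-related exogenous ions.
DEFAULT_CARRYOVER_IONS = ("mz47.05", "mz81.08", "mz137.13")


@dataclass
class RawTraceSession:
    """One participant-timepoint recording at 1 Hz.

    ``cps`` is a ticks x channels frame; ``phase`` labels each tick as
    background (catalyzed air), breath, flush (room air between
    exhalations) or unknown.
    """

    participant_id: str
    timepoint: str
    time_s: np.ndarray
    co2_pct: np.ndarray
    trigger: np.ndarray
    cps: pd.DataFrame
    phase: np.ndarray

    @property
    def session_id(self) -> str:
        return f"{self.participant_id}:{self.timepoint}"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s)
        if len(t) == 0:
            raise ValueError("empty session")
        if not np.all(np.diff(t) == 1):
            raise ValueError("time grid must be strictly increasing at 1 Hz")
        if np.any(np.asarray(self.co2_pct) < 0):
            raise ValueError("CO2 must be non-negative")
        if (self.cps.to_numpy() < 0).any():
            raise ValueError("cps must be non-negative")
        bad = set(np.unique(self.phase)) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    def background_frame(self) -> pd.DataFrame:
        return self.cps.loc[np.asarray(self.phase) == "background"]


@dataclass
class SampleVector:
    """One extracted breath replicate: per-ion mean end-tidal cps."""

    participant_id: str
    timepoint: str
    trigger_time: int
    window: tuple[int, int]              # [start, end)
    mean_cps: pd.Series
    n_spectra: int
    replicate: int | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return FLAG_SHORT not in self.flags


@dataclass
class RcResult:
    """Lin's concordance between the two replicate vectors of a participant."""

    participant_id: str
    rc: float
    s_yx: float
    mean_x: float
    mean_y: float
    s2_x: float
    s2_y: float

    @property
    def band(self) -> str:
        if self.rc > 0.9:
            return "excellent"
        if self.rc >= 0.6:
            return "satisfactory"
        return "unsatisfactory"


def detect_triggers(session: RawTraceSession,
                    threshold: float = 4.0) -> list[int]:
    """Trigger times: first tick of each upward CO2 crossing of threshold.

    The trigger re-arms only once CO2 falls back below the threshold, so a
    noisy plateau cannot fire twice.  Returns sorted times (possibly
    empty).
    """
    co2 = np.asarray(session.co2_pct, dtype=float)
    above = co2 >= threshold
    prev = np.concatenate(([False], above[:-1]))
    idx = np.nonzero(above & ~prev)[0]
    times = [int(session.time_s[i]) for i in idx]
    for t in times:
        logger.info("session %s: CO2 trigger at t=%d s", session.session_id, t)
    return times


def extract_end_tidal(session: RawTraceSession, triggers: list[int],
                      delay_s: int = 5, window_s: int = 5,
                      co2_threshold: float = 4.0) -> list[SampleVector]:
    """Average the ion signal over [t+delay, t+delay+window) per trigger.

    Every retained sample averages exactly ``window_s`` spectra (1 Hz).
    If the exhalation ends inside the window (CO2 drops below threshold)
    or the window overruns the recording, the sample is flagged
    ``short_exhalation`` and excluded from downstream statistics rather
    than truncated, so all samples describe the same breath fraction.
    """
    if delay_s <= 0 or window_s <= 0:
        raise ValueError("delay and window must be positive")
    t0 = int(session.time_s[0])
    n = len(session.time_s)
    out: list[SampleVector] = []
    for trig in triggers:
        start, end = trig + delay_s, trig + delay_s + window_s
        i0, i1 = start - t0, end - t0
        flags: set[str] = set()
        if i1 > n:
            flags.add(FLAG_SHORT)
            i1 = min(i1, n)
            logger.info("session %s: window for trigger t=%d overruns the "
                        "recording; flagged", session.session_id, trig)
        window_co2 = session.co2_pct[i0:i1]
        if FLAG_SHORT not in flags and np.any(window_co2 < co2_threshold):
            flags.add(FLAG_SHORT)
            logger.info("session %s: exhalation too short for trigger t=%d; "
                        "flagged", session.session_id, trig)
        chunk = session.cps.iloc[i0:i1]
        out.append(SampleVector(
            participant_id=session.participant_id,
            timepoint=session.timepoint,
            trigger_time=trig,
            window=(start, end),
            mean_cps=chunk.mean(axis=0),
            n_spectra=len(chunk),
            flags=flags,
        ))
    return out


def pair_duplicates(samples: list[SampleVector]) -> list[SampleVector]:
    """Assign replicate indices 1 and 2 to the first two usable samples.

    Samples flagged ``short_exhalation`` are skipped.  With fewer than two
    usable samples the survivors are flagged ``missing_replicate``; with
    none, the session is excluded (empty return) with a log entry.
    """
    usable = [s for s in samples if s.usable]
    if not usable:
        if samples:
            logger.info("session %s:%s excluded: no usable samples",
                        samples[0].participant_id, samples[0].timepoint)
        return []
    pair = usable[:2]
    for i, s in enumerate(pair, start=1):
        s.replicate = i
    if len(pair) < 2:
        pair[0].flags.add(FLAG_MISSING)
        logger.info("session %s:%s has a single usable sample; flagged "
                    "missing_replicate", pair[0].participant_id,
                    pair[0].timepoint)
    return pair


def flag_carryover(session: RawTraceSession, samples: list[SampleVector],
                   ions: tuple[str, ...] = DEFAULT_CARRYOVER_IONS,
                   factor: float = 3.0, lookback_s: int = 5) -> None:
    """Flag samples whose pre-trigger room-air signal is elevated.

    For each watched ion, the median cps over the ``lookback_s`` room-air
    (non-breath) ticks preceding the trigger is compared with the session
    background median; exceeding ``factor`` times the background marks the
    sample ``carryover_suspect``.  Without a background phase the flags
    are indeterminate and left unset (logged).
    """
    bg = session.background_frame()
    if bg.empty:
        logger.warning("session %s has no background phase; carryover flags "
                       "indeterminate", session.session_id)
        return
    watched = [i for i in ions if i in session.cps.columns]
    if not watched:
        return
    t0 = int(session.time_s[0])
    is_breath = np.asarray(session.phase) == "breath"
    for sample in samples:
        i_trig = sample.trigger_time - t0
        pre = [i for i in range(max(0, i_trig - 3 * lookback_s), i_trig)
               if not is_breath[i]][-lookback_s:]
        if not pre:
            continue
        for ion in watched:
            bg_med = float(bg[ion].median())
            pre_med = float(session.cps[ion].iloc[pre].median())
            if bg_med > 0 and pre_med > factor * bg_med:
                sample.flags.add(FLAG_CARRYOVER)
                logger.info("session %s: carryover suspected on %s "
                            "(pre-trigger %.1f cps vs background %.1f cps)",
                            session.session_id, ion, pre_med, bg_med)
                break


def lin_concordance(x, y, participant_id: str = "") -> RcResult:
    """Lin's concordance correlation coefficient between replicate vectors.

    Rc = 2 S_YX / ((Ybar - Xbar)^2 + S_Y^2 + S_X^2), with covariance and
    variances in population form (divisor n).  Rc = 1 only for identical
    non-constant vectors; two constant vectors are degenerate (raises).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("replicate vectors must be equal-length 1-D, n >= 2")
    mean_x, mean_y = float(x.mean()), float(y.mean())
    s2_x = float(np.mean((x - mean_x) ** 2))
    s2_y = float(np.mean((y - mean_y) ** 2))
    s_yx = float(np.mean((x - mean_x) * (y - mean_y)))
    denom = (mean_y - mean_x) ** 2 + s2_y + s2_x
    if denom == 0:
        raise ValueError("both replicate vectors are constant; Rc undefined")
    return RcResult(participant_id=participant_id, rc=2 * s_yx / denom,
                    s_yx=s_yx, mean_x=mean_x, mean_y=mean_y,
                    s2_x=s2_x, s2_y=s2_y)
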