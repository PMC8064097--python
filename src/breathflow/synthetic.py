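"""Synthetic study generator.

Emulates a three-group (24/17/21 participants), five-timepoint breath
campaign with duplicate CO2-triggered exhalations per session, producing
the raw 1 Hz traces the extraction pipeline consumes together with the
ground truth needed for parameter-recovery tests.

The statistical model, on the natural-log concentration scale::

    ln c[subject, timepoint, ion] = baseline[ion]
                                  + subject_offset[subject, ion]   ~ N(0, subject_sd^2)
                                  + exercise_effect[ion, timepoint]
                                  + group_effect[ion, group, timepoint]
                                  + eps                            ~ N(0, log_sd^2)

Both replicates of a session share the same true concentration; they
differ only through technical noise (per-tick multiplicative lognormal
noise with coefficient of variation ``noise_cv`` plus Poisson counting
noise on the counts themselves).  Setting ``noise_cv = 0`` switches the
whole technical-noise model off, giving exactly reproducible traces.

Each exhalation has a trapezoidal CO2 profile (2 s rise, 16 s plateau in
the 4.6-5.4% range, 2 s fall, ~20 s total); the trigger channel goes high
when CO2 first reaches 4% and re-arms between exhalations.  Ion signal
during the breath phase is proportional to the true concentration (scaled
by the CO2 ramp), so extraction followed by kinetic quantification
inverts the generator exactly up to noise.  Room-air and catalyzed-air
phases revert to instrument-background counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (GROUPS, IonChannel, TIMEPOINTS, default_panel,
                    panel_by_name, primary_channels)
from .quantify import KineticConfig
from .tracer import RawTraceSession

ISOPRENE = "mz69.07"


def _as_ion_map(value, ions: list[str], name: str) -> dict[str, float]:
    if isinstance(value, dict):
        return {i: float(value.get(i, 0.0)) for i in ions}
    return {i: float(value) for i in ions}


@dataclass
class StudyDesignSpec:
    """Sizes, timepoints and channel panel of the simulated campaign."""

    n_per_group: tuple[int, int, int] = (24, 17, 21)
    timepoints: tuple[str, ...] = TIMEPOINTS
    replicates_per_timepoint: int = 2
    ion_channels: list[IonChannel] = field(default_factory=default_panel)
    seed: int = 0
    # session layout, seconds (1 Hz ticks)
    background_s: int = 30
    pre_gap_s: int = 5
    inter_gap_s: int = 10
    tail_s: int = 5
    rise_s: int = 2
    plateau_s: int = 16
    fall_s: int = 2
    plateau_pct: tuple[float, float] = (4.6, 5.4)
    # downstream extraction geometry, used to vet the plateau length
    extraction_delay_s: int = 5
    extraction_window_s: int = 5

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs at least 2 participants")
        if not self.timepoints:
            raise ValueError("timepoints must be nonempty")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be distinct")
        if self.replicates_per_timepoint < 1:
            raise ValueError("need at least one replicate per timepoint")
        primary_channels(self.ion_channels)   # exactly one 21.02 / 39.03
        names = {ch.name for ch in self.ion_channels}
        by_name = panel_by_name(self.ion_channels)
        for ch in self.ion_channels:
            if ch.role == "fragment":
                if ch.parent not in names:
                    raise ValueError(
                        f"fragment {ch.name} references unknown parent "
                        f"{ch.parent}")
                if by_name[ch.parent].role != "endogenous":
                    raise ValueError(
                        f"fragment {ch.name} parent must be endogenous")
        if self.extraction_delay_s + self.extraction_window_s > self.plateau_s:
            raise ValueError(
                "extraction window longer than the CO2 plateau; the "
                "end-tidal algorithm would be undefined")
        if self.plateau_pct[0] < 4.0:
            raise ValueError("plateau must stay at or above the 4% trigger")

    def participants(self) -> pd.DataFrame:
        """Participant table: id and group (St0/St1/St2)."""
        rows = []
        k = 0
        total = sum(self.n_per_group)
        width = max(2, len(str(total)))
        for group, n in zip(GROUPS, self.n_per_group):
            for _ in range(n):
                k += 1
                rows.append({"participant_id": f"S{k:0{width}d}",
                             "group": group})
        return pd.DataFrame(rows)


@dataclass
class EffectSpec:
    """True effect structure on the log-concentration scale."""

    baseline_log_mean: dict[str, float]
    exercise_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    group_effect: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=dict)
    log_sd: float = 0.15
    subject_sd: float = 0.35
    outlier_rate: float = 0.05
    outlier_magnitude: float = 2.5
    outlier_ions: tuple[str, ...] = ("mz47.05", "mz81.08", "mz137.13",
                                     "mz149.10")
    noise_cv: float = 0.02
    background_mean_cps: float | dict = 2.0
    background_sd_cps: float | dict = 0.6
    primary_cps: dict[str, float] = field(default_factory=lambda: {
        "mz21.02": 1.0e4, "mz39.03": 2.0e4})

    def __post_init__(self) -> None:
        if self.log_sd < 0 or self.subject_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.noise_cv < 1):
            raise ValueError("noise_cv must lie in [0, 1)")
        if not (0 <= self.outlier_rate <= 1):
            raise ValueError("outlier_rate must be a probability")
        for ion, per_tp in self.exercise_effect.items():
            for tp, eff in per_tp.items():
                if ion == ISOPRENE and eff > 0:
                    raise ValueError(
                        "isoprene exercise effect must be opposite in sign "
                        "to the (positive) default")
                if ion != ISOPRENE and eff < 0:
                    raise ValueError(
                        f"exercise effect for {ion} at {tp} must be >= 0 "
                        "(isoprene is the only negative channel)")


def default_effects() -> EffectSpec:
    """Campaign defaults: realistic breath baselines (ppbv) and effects.

    Exercise raises most responsive volatiles after each walking day
    (about +0.5 natural-log units on day 1, i.e. ~65% up), with a partial
    recovery at the pre-walking morning sample and an equal plateau on
    days 2 and 3; isoprene mirrors the pattern with negative sign.  The
    short-chain fatty acids additionally carry a group-by-time effect:
    non-statin users (St0) respond more strongly post-walking, while
    statin users stay mildly elevated at the rest sample.
    """
    baseline_ppbv = {
        "mz33.03": 150.0, "mz45.03": 25.0, "mz47.05": 100.0,
        "mz59.05": 500.0, "mz69.07": 100.0, "mz87.09": 5.0,
        "mz61.03": 20.0, "mz75.05": 6.0, "mz89.06": 4.0,
        "mz31.02": 8.0, "mz42.03": 3.0, "mz63.03": 10.0,
        "mz73.06": 2.0, "mz107.09": 1.0,
        "mz81.08": 1.5, "mz137.13": 2.0, "mz149.10": 1.0,
        "mz101.10": 0.02, "mz115.11": 0.02,
    }

    def pattern(day1: float, rest: float, later: float) -> dict[str, float]:
        return {"Day1": day1, "Day2am": rest, "Day2": later, "Day3": later}

    exercise = {
        "mz33.03": pattern(0.45, 0.08, 0.30),
        "mz45.03": pattern(0.40, 0.08, 0.28),
        "mz47.05": pattern(0.50, 0.10, 0.35),
        "mz59.05": pattern(0.55, 0.10, 0.38),
        "mz69.07": pattern(-0.40, -0.06, -0.28),
        "mz87.09": pattern(0.30, 0.05, 0.20),
        "mz61.03": pattern(0.55, 0.10, 0.40),
        "mz75.05": pattern(0.50, 0.08, 0.36),
        "mz89.06": pattern(0.50, 0.08, 0.36),
    }
    scfa_group = {}
    for ion in ("mz61.03", "mz75.05", "mz89.06"):
        scfa_group[ion] = {
            ("St0", "Day1"): 0.45, ("St0", "Day2"): 0.45, ("St0", "Day3"): 0.45,
            ("St1", "Day2am"): 0.22, ("St2", "Day2am"): 0.22,
        }
    return EffectSpec(
        baseline_log_mean={k: math.log(v) for k, v in baseline_ppbv.items()},
        exercise_effect=exercise,
        group_effect=scfa_group,
    )


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery testing."""

    concentrations: pd.DataFrame        # (participant, timepoint) x ion, ppbv
    exercise_responsive: pd.Series      # bool per ion
    group_differential: pd.Series       # bool per ion
    subject_offsets: pd.DataFrame       # participant x ion, log scale
    trigger_times: dict[str, list[int]]  # session id -> trigger seconds
    outliers: pd.DataFrame              # participant, timepoint, ion


def _effect_flags(panel: list[IonChannel], effects: EffectSpec
                  ) -> tuple[pd.Series, pd.Series]:
    by_name = panel_by_name(panel)
    analytes = [ch.name for ch in panel if ch.role != "primary"]

    def has_exercise(name: str) -> bool:
        ch = by_name[name]
        target = ch.parent if ch.role == "fragment" else name
        return any(e != 0 for e in effects.exercise_effect.get(target, {}).values())

    def has_group(name: str) -> bool:
        ch = by_name[name]
        target = ch.parent if ch.role == "fragment" else name
        return any(e != 0 for e in effects.group_effect.get(target, {}).values())

    ex = pd.Series({n: has_exercise(n) for n in analytes})
    gr = pd.Series({n: has_group(n) for n in analytes})
    return ex, gr


def simulate_study(design: StudyDesignSpec, effects: EffectSpec,
                   kinetics: KineticConfig | None = None
                   ) -> tuple[list[RawTraceSession], pd.DataFrame, GroundTruth]:
    """Generate all sessions, the design table and the ground truth.

    One session per participant x timepoint, each with
    ``replicates_per_timepoint`` exhalations.  Deterministic given
    ``design.seed``.
    """
    kinetics = kinetics or KineticConfig()
    panel = design.ion_channels
    by_name = panel_by_name(panel)
    p21, p39 = primary_channels(panel)
    analytes = [ch.name for ch in panel if ch.role != "primary"]
    direct = [n for n in analytes if by_name[n].role != "fragment"]
    fragments = [n for n in analytes if by_name[n].role == "fragment"]
    columns = [p21, p39] + analytes

    participants = design.participants()
    groups = dict(zip(participants.participant_id, participants.group))
    n_subj, n_tp = len(participants), len(design.timepoints)

    bg_mean = _as_ion_map(effects.background_mean_cps, analytes, "background")
    bg_sd = _as_ion_map(effects.background_sd_cps, analytes, "background sd")
    denom = (500.0 * effects.primary_cps[p21]
             + 250.0 * effects.primary_cps[p39])
    cps_per_ncps = denom / kinetics.normalization_target
    sigma = math.sqrt(math.log(1.0 + effects.noise_cv ** 2))

    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(1 + n_subj * n_tp)
    rng0 = np.random.default_rng(children[0])
    offsets = pd.DataFrame(
        rng0.normal(0.0, effects.subject_sd, size=(n_subj, len(analytes))),
        index=participants.participant_id.to_numpy(), columns=analytes)

    sessions: list[RawTraceSession] = []
    truth_rows: list[dict] = []
    trigger_times: dict[str, list[int]] = {}
    outlier_rows: list[dict] = []
    design_rows: list[dict] = []

    for i, prow in participants.iterrows():
        pid, group = prow.participant_id, prow.group
        for j, tp in enumerate(design.timepoints):
            rng = np.random.default_rng(children[1 + i * n_tp + j])
            # --- true concentrations for this sample -------------------
            sample_eps = rng.normal(0.0, effects.log_sd, size=len(direct))
            log_conc = {}
            for eps, ion in zip(sample_eps, direct):
                mu = (effects.baseline_log_mean.get(ion, -math.inf)
                      + offsets.at[pid, ion]
                      + effects.exercise_effect.get(ion, {}).get(tp, 0.0)
                      + effects.group_effect.get(ion, {}).get((group, tp), 0.0)
                      + eps)
                log_conc[ion] = mu
            session_outliers: list[str] = []
            for ion in effects.outlier_ions:
                if ion in log_conc and rng.random() < effects.outlier_rate:
                    log_conc[ion] += effects.outlier_magnitude
                    session_outliers.append(ion)
                    outlier_rows.append({"participant_id": pid,
                                         "timepoint": tp, "ion": ion})
            ppbv = {ion: math.exp(v) for ion, v in log_conc.items()}
            ncps = {ion: ppbv[ion] / kinetics.ppbv_per_ncps(ion)
                    for ion in direct}
            for frag in fragments:
                ch = by_name[frag]
                ncps[frag] = ch.fraction * ncps[ch.parent]
                ppbv[frag] = ncps[frag] * kinetics.ppbv_per_ncps(frag)
            signal_cps = np.array([ncps[ion] * cps_per_ncps
                                   for ion in analytes])

            # --- CO2 / phase skeleton ----------------------------------
            levels = rng.uniform(*design.plateau_pct,
                                 size=design.replicates_per_timepoint)
            co2, phase, ramp = [], [], []

            def _block(n, c, ph, rm=0.0):
                co2.extend([c] * n)
                phase.extend([ph] * n)
                ramp.extend([rm] * n)

            _block(design.background_s, 0.03, "background")
            _block(design.pre_gap_s, 0.5, "flush")
            exhalation_gap_slices = []
            for r, level in enumerate(levels):
                rise_frac = np.linspace(0.3, 0.75, design.rise_s)
                for f in rise_frac:
                    _block(1, f * level, "breath", f)
                _block(design.plateau_s, level, "breath", 1.0)
                fall_frac = np.linspace(0.6, 0.25, design.fall_s)
                for f in fall_frac:
                    _block(1, f * level, "breath", f)
                if r < len(levels) - 1:
                    start = len(co2)
                    _block(design.inter_gap_s, 0.5, "flush")
                    exhalation_gap_slices.append(slice(start, len(co2)))
            _block(design.tail_s, 0.5, "flush")

            co2_arr = np.asarray(co2)
            ramp_arr = np.asarray(ramp)
            phase_arr = np.asarray(phase, dtype=object)
            n_ticks = len(co2_arr)
            breath = phase_arr == "breath"

            # trigger channel: high from the first >=4% tick of each
            # exhalation until CO2 drops below 4% again
            trig_arr = (co2_arr >= 4.0).astype(int)
            above = co2_arr >= 4.0
            prev = np.concatenate(([False], above[:-1]))
            trig_ticks = [int(t) for t in np.nonzero(above & ~prev)[0]]

            # --- counts ------------------------------------------------
            lam = np.where(breath[:, None],
                           ramp_arr[:, None] * signal_cps[None, :],
                           np.array([bg_mean[i_] for i_ in analytes])[None, :])
            if effects.noise_cv > 0:
                factor = rng.lognormal(-0.5 * sigma ** 2, sigma,
                                       size=lam.shape)
                cps = np.where(
                    breath[:, None],
                    rng.poisson(lam * factor).astype(float),
                    np.clip(rng.normal(
                        lam, np.array([bg_sd[i_] for i_ in analytes])[None, :]),
                        0.0, None))
            else:
                cps = lam.copy()
            # sampling-line carryover: an ethanol outlier leaves residue
            # in the flush gap before the next exhalation
            if "mz47.05" in session_outliers:
                k_eth = analytes.index("mz47.05")
                for sl in exhalation_gap_slices:
                    cps[sl, k_eth] = 6.0 * bg_mean["mz47.05"]

            prim = {}
            for name in (p21, p39):
                mean = effects.primary_cps[name]
                if effects.noise_cv > 0:
                    prim[name] = rng.normal(mean, 0.25 * effects.noise_cv * mean,
                                            size=n_ticks)
                else:
                    prim[name] = np.full(n_ticks, mean)

            frame = pd.DataFrame(
                np.column_stack([prim[p21], prim[p39], cps]),
                columns=columns)
            session = RawTraceSession(
                participant_id=pid, timepoint=tp,
                time_s=np.arange(n_ticks), co2_pct=co2_arr,
                trigger=trig_arr, cps=frame, phase=phase_arr)
            sessions.append(session)
            trigger_times[session.session_id] = trig_ticks
            design_rows.append({"participant_id": pid, "group": group,
                                "timepoint": tp})
            truth_rows.append({"participant_id": pid, "timepoint": tp,
                               **{ion: ppbv[ion] for ion in analytes}})

    truth_conc = pd.DataFrame(truth_rows).set_index(
        ["participant_id", "timepoint"])
    ex_flags, gr_flags = _effect_flags(panel, effects)
    truth = GroundTruth(
        concentrations=truth_conc,
        exercise_responsive=ex_flags,
        group_differential=gr_flags,
        subject_offsets=offsets,
        trigger_times=trigger_times,
        outliers=pd.DataFrame(outlier_rows,
                              columns=["participant_id", "timepoint", "ion"]),
    )
    return sessions, pd.DataFrame(design_rows), truth


def write_fixtures(sessions: list[RawTraceSession], design: pd.DataFrame,
                   truth: GroundTruth, directory: str | Path,
                   panel: list[IonChannel] | None = None) -> dict[str, Path]:
    """Write trace/design/ion/ground-truth tables as delimited text.

    Files round-trip losslessly through :mod:`breathflow.io` readers.
    Returns {table name: path}.
    """
    from . import io as bio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel = panel if panel is not None else default_panel()
    paths = {
        "traces": directory / "traces.tsv",
        "design": directory / "design.tsv",
        "ions": directory / "ions.tsv",
        "truth_concentrations": directory / "truth_concentrations.tsv",
        "truth_flags": directory / "truth_flags.tsv",
        "truth_offsets": directory / "truth_offsets.tsv",
        "truth_triggers": directory / "truth_triggers.tsv",
        "truth_outliers": directory / "truth_outliers.tsv",
    }
    try:
        bio.write_trace_table(sessions, paths["traces"])
        design.to_csv(paths["design"], sep="\t", index=False)
        bio.write_ion_table(panel, paths["ions"])
        truth.concentrations.reset_index().to_csv(
            paths["truth_concentrations"], sep="\t", index=False)
        flags = pd.DataFrame({"ion": truth.exercise_responsive.index,
                              "exercise_responsive": truth.exercise_responsive.values,
                              "group_differential": truth.group_differential.values})
        flags.to_csv(paths["truth_flags"], sep="\t", index=False)
        truth.subject_offsets.rename_axis("participant_id").reset_index().to_csv(
            paths["truth_offsets"], sep="\t", index=False)
        trig = pd.DataFrame(
            [{"session_id": sid, "trigger_s": t}
             for sid, times in truth.trigger_times.items() for t in times])
        trig.to_csv(paths["truth_triggers"], sep="\t", index=False)
        truth.outliers.to_csv(paths["truth_outliers"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed to write fixture under {directory}: {exc}") from exc
    return paths
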