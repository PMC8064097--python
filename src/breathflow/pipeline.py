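"""End-to-end orchestration: raw trace sessions -> end-tidal samples ->
concentration matrix -> retained-ion panel, plus the repeatability and
multilevel analyses built on top.

This is thin glue over the module functions; each step can also be run
on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import identify, multilevel, tracer, univariate
from .panel import IonChannel, default_panel, panel_by_name, primary_channels
from .quantify import (ConcentrationMatrix, KineticConfig, apply_lod,
                       compute_lod, filter_ions, normalize_primary_ions)
from .tracer import RawTraceSession, SampleVector

logger = logging.getLogger(__name__)


@dataclass
class ExtractionConfig:
    co2_threshold_pct: float = 4.0
    delay_s: int = 5
    window_s: int = 5
    carryover_factor: float = 3.0
    carryover_ions: tuple[str, ...] = tracer.DEFAULT_CARRYOVER_IONS


def extract_samples(sessions: list[RawTraceSession],
                    config: ExtractionConfig | None = None
                    ) -> list[SampleVector]:
    """Detect triggers, extract end-tidal windows, pair and QC-flag."""
    config = config or ExtractionConfig()
    out: list[SampleVector] = []
    for session in sessions:
        triggers = tracer.detect_triggers(session, config.co2_threshold_pct)
        samples = tracer.extract_end_tidal(
            session, triggers, delay_s=config.delay_s,
            window_s=config.window_s, co2_threshold=config.co2_threshold_pct)
        tracer.flag_carryover(session, samples, ions=config.carryover_ions,
                              factor=config.carryover_factor)
        out.extend(tracer.pair_duplicates(samples))
    return out


def pooled_background(sessions: list[RawTraceSession]) -> pd.DataFrame:
    """Concatenate catalyzed-air background ticks over all sessions."""
    frames = [s.background_frame() for s in sessions]
    frames = [f for f in frames if not f.empty]
    if not frames:
        raise ValueError("no background phase found in any session")
    return pd.concat(frames, ignore_index=True)


def quantify_samples(samples: list[SampleVector],
                     sessions: list[RawTraceSession],
                     design: pd.DataFrame,
                     kinetics: KineticConfig | None = None,
                     panel: list[IonChannel] | None = None
                     ) -> ConcentrationMatrix:
    """Samples -> normalized counts -> ppbv matrix with LoD handling.

    Rows are indexed by (participant_id, timepoint, replicate); primary-
    ion channels are consumed by the normalization and do not appear as
    concentration columns.  The retention filter (above LoD in more than
    half the samples of every group) fills ``matrix.retained``.
    """
    kinetics = kinetics or KineticConfig()
    panel = panel if panel is not None else default_panel()
    first_cols = samples[0].mean_cps.index if samples else []
    p21, p39 = primary_channels(
        [ch for ch in panel if ch.name in set(first_cols)] or panel)
    rows, index = [], []
    for s in samples:
        if s.replicate is None:
            continue
        ncps = normalize_primary_ions(
            s.mean_cps.drop([p21, p39]).to_numpy(),
            s.mean_cps[p21], s.mean_cps[p39],
            target=kinetics.normalization_target)
        ions = [c for c in s.mean_cps.index if c not in (p21, p39)]
        ppbv = [n * kinetics.ppbv_per_ncps(ion)
                for n, ion in zip(ncps, ions)]
        rows.append(pd.Series(ppbv, index=ions))
        index.append((s.participant_id, s.timepoint, s.replicate))
    values = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["participant_id", "timepoint", "replicate"]))
    lods = compute_lod(pooled_background(sessions), kinetics,
                       primary21=p21, primary39=p39)
    matrix = apply_lod(values, lods.reindex(values.columns))
    group_of = design.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    groups = pd.Series(
        [group_of[p] for p, _, _ in matrix.values.index],
        index=matrix.values.index)
    filter_ions(matrix, groups)
    return matrix


def replicate_concordance(matrix: ConcentrationMatrix,
                          log: bool = True) -> pd.DataFrame:
    """Lin's Rc per participant-timepoint duplicate pair.

    Computed across the retained-ion concentration vector of the two
    replicates, on the log scale by default so high-abundance ions do
    not dominate the agreement measure.
    """
    vals = matrix.retained_values()
    if log:
        vals = np.log(vals)
    records = []
    for (pid, tp), chunk in vals.groupby(
            level=["participant_id", "timepoint"], sort=False):
        if len(chunk) < 2:
            continue
        x = chunk.iloc[0].to_numpy()
        y = chunk.iloc[1].to_numpy()
        res = tracer.lin_concordance(x, y, participant_id=pid)
        records.append({"participant_id": pid, "timepoint": tp,
                        "rc": res.rc, "band": res.band})
    return pd.DataFrame.from_records(records)


@dataclass
class StudyAnalysis:
    matrix: ConcentrationMatrix
    annotation: pd.DataFrame
    concordance: pd.DataFrame
    exogenous_ions: list[str]


def analyze_study(sessions: list[RawTraceSession], design: pd.DataFrame,
                  panel: list[IonChannel] | None = None,
                  kinetics: KineticConfig | None = None,
                  extraction: ExtractionConfig | None = None
                  ) -> StudyAnalysis:
    """Run extraction, quantification, filtering and annotation."""
    panel = panel if panel is not None else default_panel()
    samples = extract_samples(sessions, extraction)
    matrix = quantify_samples(samples, sessions, design, kinetics, panel)
    retained_panel = [ch for ch in panel if ch.name in matrix.retained]
    annotation = identify.annotate_channels(
        retained_panel, matrix.retained_values())
    concordance = replicate_concordance(matrix)
    exogenous = [ch.name for ch in retained_panel if ch.role == "exogenous"]
    return StudyAnalysis(matrix=matrix, annotation=annotation,
                         concordance=concordance, exogenous_ions=exogenous)


def timepoint_model(analysis: StudyAnalysis, design: pd.DataFrame,
                    group: str | None = None,
                    timepoints: tuple[str, ...] | None = None,
                    n_components: int = 2
                    ) -> tuple[multilevel.MultilevelModel, pd.Series]:
    """Fit an M-PLS-DA of timepoint classes, excluding exogenous ions.

    Restricted to one statin group (and optionally a timepoint subset,
    e.g. post-walking only); returns (model, VIP scores).  The analysis
    unit is the replicate mean per participant-timepoint.
    """
    values = univariate.replicate_means(analysis.matrix.retained_values())
    frame = values.reset_index()
    group_of = design.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    frame["group"] = frame["participant_id"].map(group_of)
    if group is not None:
        frame = frame[frame["group"] == group]
    if timepoints is not None:
        frame = frame[frame["timepoint"].isin(timepoints)]
    frame = frame.set_index(["participant_id", "timepoint"])
    x = frame[[c for c in values.columns]]
    pm = multilevel.preprocess(
        x,
        pd.Series(x.index.get_level_values("participant_id"), index=x.index),
        pd.Series(x.index.get_level_values("timepoint"), index=x.index),
        drop_ions=analysis.exogenous_ions)
    model = multilevel.mplsda(pm, n_components=n_components)
    return model, multilevel.vip_scores(model)
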