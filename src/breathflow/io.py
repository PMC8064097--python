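"""Readers and writers for the campaign's delimited-text tables.

Trace tables are long-by-tick: one row per second per session with the
CO2 percentage, trigger state, phase label and one ``mz<value>`` column
per ion channel.  Design tables carry one row per participant-timepoint
session.  An HDF5 container with the same schema is supported when
PyTables is available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import IonChannel
from .tracer import RawTraceSession

_META_COLS = ["session_id", "participant_id", "timepoint", "t_s", "co2_pct",
              "trigger", "phase"]


def _sessions_to_frame(sessions: list[RawTraceSession]) -> pd.DataFrame:
    chunks = []
    for s in sessions:
        chunk = pd.DataFrame({
            "session_id": s.session_id,
            "participant_id": s.participant_id,
            "timepoint": s.timepoint,
            "t_s": s.time_s,
            "co2_pct": s.co2_pct,
            "trigger": s.trigger,
            "phase": s.phase,
        })
        chunks.append(pd.concat([chunk, s.cps.reset_index(drop=True)], axis=1))
    if not chunks:
        return pd.DataFrame(columns=_META_COLS)
    return pd.concat(chunks, ignore_index=True)


def _frame_to_sessions(frame: pd.DataFrame) -> list[RawTraceSession]:
    ion_cols = [c for c in frame.columns if c.startswith("mz")]
    sessions = []
    for sid, chunk in frame.groupby("session_id", sort=False):
        chunk = chunk.sort_values("t_s")
        pid = str(chunk["participant_id"].iloc[0])
        tp = str(chunk["timepoint"].iloc[0])
        sessions.append(RawTraceSession(
            participant_id=pid, timepoint=tp,
            time_s=chunk["t_s"].to_numpy(dtype=int),
            co2_pct=chunk["co2_pct"].to_numpy(dtype=float),
            trigger=chunk["trigger"].to_numpy(dtype=int),
            cps=chunk[ion_cols].reset_index(drop=True),
            phase=chunk["phase"].to_numpy(dtype=object)))
    return sessions


def write_trace_table(sessions: list[RawTraceSession],
                      path: str | Path) -> None:
    _sessions_to_frame(sessions).to_csv(path, sep="\t", index=False)


def read_trace_table(path: str | Path) -> list[RawTraceSession]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return _frame_to_sessions(frame)


def write_traces_hdf5(sessions: list[RawTraceSession],
                      path: str | Path) -> None:
    """Same schema as the text table, in one HDF5 dataset (needs PyTables)."""
    _sessions_to_frame(sessions).to_hdf(path, key="traces", mode="w",
                                        format="table")


def read_traces_hdf5(path: str | Path) -> list[RawTraceSession]:
    return _frame_to_sessions(pd.read_hdf(path, key="traces"))


def read_design_table(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    required = {"participant_id", "group", "timepoint"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    return design


def write_ion_table(panel: list[IonChannel], path: str | Path) -> None:
    pd.DataFrame([{
        "ion": ch.name, "mz": ch.mz, "formula": ch.formula,
        "role": ch.role, "compound": ch.compound, "parent": ch.parent,
        "fraction": ch.fraction,
    } for ch in panel]).to_csv(path, sep="\t", index=False)


def read_ion_table(path: str | Path) -> list[IonChannel]:
    frame = pd.read_csv(path, sep="\t")

    def _opt(v):
        return None if pd.isna(v) else v

    return [IonChannel(name=r.ion, mz=float(r.mz), formula=_opt(r.formula),
                       role=r.role, compound=_opt(r.compound),
                       parent=_opt(r.parent),
                       fraction=_opt(r.fraction))
            for r in frame.itertuples()]


def write_sample_table(values: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x ions matrix with its row index as columns."""
    values.reset_index().to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    keys = [c for c in ("participant_id", "timepoint", "replicate")
            if c in frame.columns]
    return frame.set_index(keys)
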