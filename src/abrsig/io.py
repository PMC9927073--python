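"""Readers and writers for the canonical long-format CSV schemas.

Three tidy CSV files carry a cohort: recordings (one waveform sample per
row), peak-latency tables (one peak per row), and subject metadata (one
subject per row).  Comma separated, '.' decimal, header required, UTF-8.
Missing values are empty fields.  Round trips are the identity on valid
data: strings and integers bit-exact, floats to full double precision
(pandas writes shortest-round-trip representations).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ABRRecording,
    FormatError,
    PeakLatencyRow,
    SubjectMetadata,
    ValidationError,
    check_unique_subjects,
    metadata_fields,
)

RECORDING_COLUMNS = [
    "subject_id",
    "trial_index",
    "ear",
    "db_level",
    "sampling_rate_hz",
    "t_ms",
    "amplitude_uv",
]

PEAK_COLUMNS = [
    "subject_id",
    "trial_index",
    "ear",
    "db_level",
    "peak_label",
    "latency_ms",
]

TRIAL_KEY = ["subject_id", "trial_index", "ear", "db_level"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")


def read_recordings(path) -> list[ABRRecording]:
    """Read ABR recordings from a long CSV, one trial per (subject, trial, ear, dB).

    Rows belonging to one trial must appear with strictly increasing
    ``t_ms``; violations raise :class:`ValidationError` naming the trial.
    """
    df = _read_csv(path)
    _require_columns(df, RECORDING_COLUMNS, path)
    records = []
    for (sid, trial, ear, db), g in df.groupby(TRIAL_KEY, sort=True):
        rates = g["sampling_rate_hz"].unique()
        if len(rates) != 1:
            raise ValidationError(
                f"multiple sampling rates in (subject={sid!r}, trial={trial})"
            )
        records.append(
            ABRRecording(
                subject_id=str(sid),
                trial_index=int(trial),
                ear=str(ear),
                db_level=int(db),
                sampling_rate_hz=float(rates[0]),
                t_ms=g["t_ms"].to_numpy(dtype=float),
                amplitude_uv=g["amplitude_uv"].to_numpy(dtype=float),
            )
        )
    return records


def recordings_to_frame(records) -> pd.DataFrame:
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": r.subject_id,
                    "trial_index": r.trial_index,
                    "ear": r.ear,
                    "db_level": r.db_level,
                    "sampling_rate_hz": r.sampling_rate_hz,
                    "t_ms": r.t_ms,
                    "amplitude_uv": r.amplitude_uv,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=RECORDING_COLUMNS)
    return pd.concat(frames, ignore_index=True)[RECORDING_COLUMNS]


def write_recordings(records, path) -> None:
    """Write recordings as long CSV, one sample per row, stable column order."""
    recordings_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_peak_table(path) -> list[PeakLatencyRow]:
    """Read a long peak-latency CSV into one row object per trial."""
    df = _read_csv(path)
    _require_columns(df, PEAK_COLUMNS, path)
    rows = []
    for (sid, trial, ear, db), g in df.groupby(TRIAL_KEY, sort=True):
        latency = {}
        for _, rec in g.iterrows():
            if pd.notna(rec["latency_ms"]):
                latency[str(rec["peak_label"])] = float(rec["latency_ms"])
        rows.append(
            PeakLatencyRow(
                subject_id=str(sid),
                trial_index=int(trial),
                ear=str(ear),
                db_level=int(db),
                latency_ms=latency,
            )
        )
    return rows


def peak_table_to_frame(rows) -> pd.DataFrame:
    out = []
    for r in rows:
        for label, lat in r.latency_ms.items():
            out.append(
                {
                    "subject_id": r.subject_id,
                    "trial_index": r.trial_index,
                    "ear": r.ear,
                    "db_level": r.db_level,
                    "peak_label": label,
                    "latency_ms": lat,
                }
            )
    return pd.DataFrame(out, columns=PEAK_COLUMNS)


def write_peak_table(rows, path) -> None:
    peak_table_to_frame(rows).to_csv(path, index=False, float_format="%.17g")


def read_metadata(path) -> list[SubjectMetadata]:
    """Read subject metadata; enum, range and uniqueness invariants enforced."""
    df = _read_csv(path)
    cols = metadata_fields()
    _require_columns(df, cols, path)
    out = []
    for _, rec in df.iterrows():
        kwargs = {}
        for f in dataclasses.fields(SubjectMetadata):
            v = rec[f.name]
            if pd.isna(v):
                kwargs[f.name] = None
            elif f.name == "subject_id":
                kwargs[f.name] = str(v)
            elif f.name == "postnatal_week":
                kwargs[f.name] = int(v)
            elif f.name in ("birth_weight_g", "ega_weeks", "age_years"):
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = str(v)
        out.append(SubjectMetadata(**kwargs))
    check_unique_subjects(out)
    return out


def metadata_to_frame(metadata) -> pd.DataFrame:
    cols = metadata_fields()
    rows = [dataclasses.asdict(m) for m in metadata]
    df = pd.DataFrame(rows, columns=cols)
    # keep integer column nullable-int so round trips stay bit-exact
    if len(df):
        df["postnatal_week"] = df["postnatal_week"].astype("Int64")
    return df


def write_metadata(metadata, path) -> None:
    check_unique_subjects(metadata)
    metadata_to_frame(metadata).to_csv(path, index=False, float_format="%.17g")


def load_zenodo_deposit(path):  # pragma: no cover - stub
    """Adapter stub for externally deposited clinical ABR data.

    Deposited archives ship in undocumented, study-specific layouts; mapping
    one onto the canonical CSV schemas above is left to the user.  Synthetic
    cohorts (``abrsig.synthetic``) exercise the full pipeline without any
    download.
    """
    raise NotImplementedError(
        "Map the downloaded deposit onto the recordings/peak/metadata CSV "
        "schemas and use read_recordings/read_peak_table/read_metadata."
    )


__all__ = [
    "read_recordings",
    "write_recordings",
    "read_peak_table",
    "write_peak_table",
    "read_metadata",
    "write_metadata",
    "recordings_to_frame",
    "peak_table_to_frame",
    "metadata_to_frame",
    "load_zenodo_deposit",
    "RECORDING_COLUMNS",
    "PEAK_COLUMNS",
]
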