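"""File I/O: delimited recordings, envelopes, labels, and the packaged cohort tables."""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .containers import ChannelMatrix, MotionSignal, RecordingRecord, SleepIndexes, StateLabels
from .errors import IntegrityError, ParseError

__all__ = [
    "read_channel_matrix",
    "write_channel_matrix",
    "read_motion_signal",
    "write_motion_signal",
    "read_labels",
    "write_labels",
    "load_fixture_tables",
]

#: sha256 of the packaged cohort tables, checked on load
FIXTURE_CHECKSUMS = {
    "table1.csv": "96cc2dfb724c7bb5ab0b601e65971830081c93ebd4facbd4d4f005b4a16bd4a2",
    "table2.csv": "9728b58e74bfc7ece9d6853cec733560649aee713895f65c3915fe779d3c24db",
}

PathLike = Union[str, Path]


def read_channel_matrix(path: PathLike, fs: float) -> ChannelMatrix:
    """Read a delimited numeric file (header row = channel ids, one column per channel)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if bad.size:
            # +2: one for the header row, one for 1-based line numbers
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r}, line {bad[0] + 2}"
            )
        if coerced.isna().any():
            raise ParseError(
                f"{path}: missing value in column {col!r}, line "
                f"{int(np.flatnonzero(coerced.isna())[0]) + 2}"
            )
        df[col] = coerced
    return ChannelMatrix(df.to_numpy().T, fs=fs, channel_ids=[str(c) for c in df.columns])


def write_channel_matrix(matrix: ChannelMatrix, path: PathLike) -> None:
    pd.DataFrame(matrix.values.T, columns=list(matrix.channel_ids)).to_csv(path, index=False)


def write_motion_signal(signal: MotionSignal, path: PathLike) -> None:
    """Single-column CSV with a one-line metadata header."""
    norm_max = "" if signal.norm_max is None else repr(signal.norm_max)
    header = f"# fs_hz={signal.fs!r}; normalized={signal.normalized}; norm_max={norm_max}\n"
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("envelope\n")
        np.savetxt(fh, signal.values, fmt="%.12g")


def read_motion_signal(path: PathLike) -> MotionSignal:
    with open(path) as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("#"):
            raise ParseError(f"{path}: missing metadata header line")
        meta: Dict[str, str] = {}
        for part in meta_line.lstrip("#").split(";"):
            key, _, val = part.strip().partition("=")
            meta[key] = val
        try:
            fs = float(meta["fs_hz"])
            normalized = meta.get("normalized", "False") == "True"
            norm_max = float(meta["norm_max"]) if meta.get("norm_max") else None
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: malformed metadata header {meta_line!r}") from exc
        fh.readline()  # column name
        values = np.loadtxt(fh, ndmin=1)
    return MotionSignal(values, fs=fs, normalized=normalized, norm_max=norm_max)


def write_labels(labels: StateLabels, path: PathLike) -> None:
    """Two-column CSV (second_index, state)."""
    pd.DataFrame(
        {"second_index": np.arange(len(labels)), "state": labels.labels}
    ).to_csv(path, index=False)


def read_labels(
    path: PathLike, th_abs: float = np.nan, th_di: float = np.nan, min_qs_s: float = np.nan
) -> StateLabels:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if list(df.columns) != ["second_index", "state"]:
        raise ParseError(f"{path}: expected columns (second_index, state), got {list(df.columns)}")
    order = np.argsort(df["second_index"].to_numpy())
    return StateLabels(
        df["state"].to_numpy()[order], th_abs=th_abs, th_di=th_di, min_qs_s=min_qs_s
    )


def _fixture_frame(name: str) -> pd.DataFrame:
    ref = resources.files("pbsleep") / "fixtures" / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise IntegrityError(
            f"fixture {name} checksum mismatch: expected "
            f"{FIXTURE_CHECKSUMS[name]}, got {digest}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_fixture_tables() -> List[RecordingRecord]:
    """The packaged 44-recording cohort: clinical metrics plus detected state shares.

    22 recordings per dataset; four apnea recordings are flagged uncertain.
    The detected QS/DS/DI percentages are attached as ``record.indexes``
    (ABS was never detected in either cohort, so its share is zero).
    """
    t1 = _fixture_frame("table1.csv")
    t2 = _fixture_frame("table2.csv").set_index("rec")
    records = []
    for row in t1.itertuples(index=False):
        idx = t2.loc[row.rec]
        records.append(
            RecordingRecord(
                rec_id=int(row.rec),
                subject_id=str(row.subject),
                dataset=str(row.dataset),
                st_h=float(row.st_h),
                se=float(row.se),
                tne=None if pd.isna(row.tne) else int(row.tne),
                ahi=None if pd.isna(row.ahi) else float(row.ahi),
                timetable=None if pd.isna(row.timetable) else str(row.timetable),
                uncertain=bool(row.uncertain),
                indexes=SleepIndexes(
                    qs_pct=float(idx.qs_pct),
                    ds_pct=float(idx.ds_pct),
                    di_pct=float(idx.di_pct),
                    abs_pct=0.0,
                ),
            )
        )
    if len(records) != 44:
        raise IntegrityError(f"expected 44 fixture records, found {len(records)}")
    return records
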