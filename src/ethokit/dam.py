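"""Drosophila Activity Monitor (DAM2, Trikinetics) file ingestion.

A DAM2 monitor logs, at a fixed reading interval (typically 60 s), the
number of infrared beam crossings in each of its 32 tubes. Each line of a
monitor text file is one reading: 42 tab-separated fields — a reading
index, the date (``19 Nov 13``), the time (``HH:MM:SS``), a status code,
five unused fields, a light-sensor flag, and the 32 channel counts.

An experiment is described by a metadata CSV with one row per animal:
which monitor ``file``, which tube (``region_id``, 1-32), and the recording
window (``start_datetime``/``stop_datetime``), plus any user columns
(genotype, sex, ...). :func:`link_dam_metadata` resolves those rows to
files on disk and mints each animal's id; :func:`load_dam` then pulls the
activity counts into a :class:`~ethokit.core.LinkedBehaviourTable` with
``t`` in seconds since each animal's own start time.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .core import LinkedBehaviourTable

__all__ = ["Dam2Record", "parse_dam2_file", "link_dam_metadata", "load_dam"]

N_CHANNELS = 32
N_FIELDS = 42  # index, date, time, status, 5 unused, light flag, 32 counts
DATE_FORMAT = "%d %b %y"  # e.g. "19 Nov 13"


@dataclass(frozen=True)
class Dam2Record:
    """One monitor reading: timestamped counts for all 32 channels."""

    reading_index: int
    timestamp: datetime
    status: int
    light: int
    counts: tuple[int, ...]  # 32 entries, channels 1..32

    def count(self, region_id: int) -> int:
        """Beam-crossing count for a 1-based channel number."""
        if not 1 <= region_id <= N_CHANNELS:
            raise ValueError(f"region_id must be in [1, {N_CHANNELS}], got {region_id}")
        return self.counts[region_id - 1]


def _read_dam2_frame(path) -> pd.DataFrame:
    """Parse a DAM2 file into a frame: reading_index, timestamp, status, light, c1..c32."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        cols = ["reading_index", "timestamp", "status", "light"] + [
            f"c{i}" for i in range(1, N_CHANNELS + 1)
        ]
        return pd.DataFrame(columns=cols)
    if raw.shape[1] != N_FIELDS:
        raise ValueError(
            f"{path}: expected {N_FIELDS} tab-separated fields per line, got {raw.shape[1]}"
        )
    out = pd.DataFrame()
    try:
        out["reading_index"] = raw[0].astype(int)
        out["timestamp"] = pd.to_datetime(raw[1] + " " + raw[2], format=f"{DATE_FORMAT} %H:%M:%S")
        out["status"] = raw[3].astype(int)
        out["light"] = raw[9].astype(int)
        counts = raw.iloc[:, 10:].astype(int)
        counts.columns = [f"c{i}" for i in range(1, N_CHANNELS + 1)]
    except (ValueError, TypeError) as exc:
        # re-scan to report the offending line number
        for lineno, row in enumerate(raw.itertuples(index=False), start=1):
            try:
                int(row[0]); int(row[3]); int(row[9])
                datetime.strptime(f"{row[1]} {row[2]}", f"{DATE_FORMAT} %H:%M:%S")
                [int(v) for v in row[10:]]
            except (ValueError, TypeError):
                raise ValueError(f"{path}: malformed line {lineno}: {row!r}") from exc
        raise ValueError(f"{path}: malformed file") from exc
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative activity counts")
    return pd.concat([out, counts], axis=1)


def parse_dam2_file(path) -> list[Dam2Record]:
    """Parse a DAM2 monitor file into records, in file order."""
    frame = _read_dam2_frame(path)
    count_cols = [f"c{i}" for i in range(1, N_CHANNELS + 1)]
    return [
        Dam2Record(
            reading_index=int(row.reading_index),
            timestamp=row.timestamp.to_pydatetime(),
            status=int(row.status),
            light=int(row.light),
            counts=tuple(int(getattr(row, c)) for c in count_cols),
        )
        for row in frame.itertuples(index=False)
    ]


def link_dam_metadata(metadata_csv, result_dir=".") -> pd.DataFrame:
    """Read an experiment metadata CSV and resolve each row to a monitor file.

    Required columns: ``file``, ``start_datetime``, ``stop_datetime``,
    ``region_id``; any further columns are user metavariables and are kept.
    Each animal's id is minted as ``"<start_datetime>|<file basename>|<NN>"``
    with the region zero-padded to two digits, e.g.
    ``"2013-11-19 09:00:00|Monitor36.txt|01"``.

    Returns a metadata frame indexed by id, with a ``path`` column pointing
    at the resolved monitor file.
    """
    meta = pd.read_csv(metadata_csv)
    required = ["file", "start_datetime", "stop_datetime", "region_id"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks required columns: {missing}")

    meta["start_datetime"] = pd.to_datetime(meta["start_datetime"])
    meta["stop_datetime"] = pd.to_datetime(meta["stop_datetime"])
    if meta["start_datetime"].isna().any() or meta["stop_datetime"].isna().any():
        raise ValueError("unparseable start/stop datetimes in metadata")
    bad = meta.index[meta["stop_datetime"] <= meta["start_datetime"]].tolist()
    if bad:
        raise ValueError(f"stop_datetime <= start_datetime on metadata rows {bad}")

    region = pd.to_numeric(meta["region_id"])
    if ((region < 1) | (region > N_CHANNELS) | (region != region.astype(int))).any():
        raise ValueError(f"region_id must be an integer in [1, {N_CHANNELS}]")
    meta["region_id"] = region.astype(int)

    paths = [os.path.join(result_dir, os.path.basename(str(f))) for f in meta["file"]]
    absent = sorted({p for p in paths if not os.path.isfile(p)})
    if absent:
        raise FileNotFoundError(f"monitor files not found: {absent}")
    meta["path"] = paths

    meta["id"] = [
        f"{start:%Y-%m-%d %H:%M:%S}|{os.path.basename(str(f))}|{r:02d}"
        for start, f, r in zip(meta["start_datetime"], meta["file"], meta["region_id"])
    ]
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids (same file/region/start): {dupes}")
    return meta.set_index("id")


def load_dam(meta: pd.DataFrame) -> LinkedBehaviourTable:
    """Load activity counts for every animal in linked metadata.

    For each animal, reads within ``[start_datetime, stop_datetime]`` of its
    monitor file are kept; ``t`` is seconds since that animal's own start
    and ``activity`` is the count in its channel. Readings with a status
    code other than 1 are kept but reported in a warning; an animal whose
    window contains no readings is kept in the metadata with zero reads
    (also warned about).
    """
    if "path" not in meta.columns:
        raise ValueError("metadata not linked; call link_dam_metadata first")
    chunks: list[pd.DataFrame] = []
    n_bad_status = 0
    empty_ids: list[str] = []
    for path, rows in meta.groupby("path", sort=False):
        frame = _read_dam2_frame(path)
        ts = frame["timestamp"].to_numpy()
        n_bad_status += int((frame["status"] != 1).sum())
        for animal_id, row in rows.iterrows():
            lo = np.datetime64(row["start_datetime"])
            hi = np.datetime64(row["stop_datetime"])
            sel = (ts >= lo) & (ts <= hi)
            if not sel.any():
                empty_ids.append(animal_id)
                continue
            t = (ts[sel] - lo) / np.timedelta64(1, "s")
            chunks.append(
                pd.DataFrame(
                    {
                        "id": animal_id,
                        "t": t.astype(float),
                        "activity": frame.loc[sel, f"c{int(row['region_id'])}"].to_numpy(),
                    }
                )
            )
    if n_bad_status:
        warnings.warn(f"{n_bad_status} readings have status != 1 (kept)", stacklevel=2)
    if empty_ids:
        warnings.warn(
            f"no readings in the recording window for ids: {empty_ids}", stacklevel=2
        )
    if chunks:
        data = pd.concat(chunks, ignore_index=True)
    else:
        data = pd.DataFrame({"id": pd.Series(dtype=str), "t": [], "activity": []})
    return LinkedBehaviourTable(data, meta.drop(columns=["path"]))
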