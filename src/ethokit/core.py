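"""Linked behavioural tables.

The central container pairs a long *data* table (one row per read:
``id``, ``t`` in seconds, plus any number of behavioural variables) with a
*metadata* table (one row per individual: experimental descriptors, the
"metavariables"). The two are joined implicitly on the ``id`` key, so a
metavariable such as genotype can be expanded against every read
(:meth:`LinkedBehaviourTable.xmv`), per-individual summaries can be joined
back to their metadata (:func:`rejoin`), and any filtering of the data
restricts the visible metadata to the surviving individuals.

This mirrors how high-throughput behaviour experiments are organised:
hundreds of individuals, days of reads each, and an experimenter-written
table describing treatments. Keeping the two linked prevents the classic
failure mode of summary rows drifting out of register with their
conditions.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinkedBehaviourTable",
    "SummaryCounts",
    "link",
    "rejoin",
    "bin_time",
    "read_metadata_csv",
    "read_data_csv",
]

#: Metadata columns required by activity-monitor experiments; everything else
#: in a metadata table is a free-form user metavariable.
MANDATORY_DAM_METAVARIABLES = ("file", "start_datetime", "stop_datetime", "region_id")


class SummaryCounts(NamedTuple):
    """Sizes of a linked table as reported by :meth:`LinkedBehaviourTable.summary`."""

    n_individuals: int
    n_metavariables: int
    n_variables: int
    n_reads: int


def _normalise_meta(meta: pd.DataFrame, key: str) -> pd.DataFrame:
    if key in meta.columns:
        meta = meta.set_index(key)
    elif meta.index.name != key:
        raise ValueError(f"metadata must carry the key {key!r} as a column or index")
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ids in metadata: {dupes}")
    if (meta.index.astype(str) == "").any():
        raise ValueError("empty id in metadata")
    if "start_datetime" in meta.columns and "stop_datetime" in meta.columns:
        start = pd.to_datetime(meta["start_datetime"])
        stop = pd.to_datetime(meta["stop_datetime"])
        ok = start < stop
        bad = meta.index[~ok & start.notna() & stop.notna()].tolist()
        if bad:
            raise ValueError(f"start_datetime >= stop_datetime for ids: {bad}")
    if "region_id" in meta.columns:
        region = pd.to_numeric(meta["region_id"], errors="coerce")
        bad = meta.index[region.notna() & ~region.between(1, 32)].tolist()
        if bad:
            raise ValueError(f"region_id outside [1, 32] for ids: {bad}")
    return meta


class LinkedBehaviourTable:
    """A long data table of behavioural reads linked to per-individual metadata.

    Parameters
    ----------
    data:
        Long-format table with columns ``id``, ``t`` (seconds, may be negative
        after a baseline shift) and any behavioural variables.
    meta:
        One row per individual; indexed by id (or carrying an ``id`` column).
        May list individuals with no data (e.g. animals that produced no
        reads); data may never reference an id absent from the metadata.
    key:
        Name of the shared key column, ``"id"`` by default.
    """

    def __init__(self, data: pd.DataFrame, meta: pd.DataFrame, key: str = "id") -> None:
        if key not in data.columns:
            raise ValueError(f"data lacks the key column {key!r}")
        if "t" not in data.columns:
            raise ValueError("data lacks the time column 't'")
        meta = _normalise_meta(meta.copy(), key)
        orphans = pd.Index(data[key].unique()).difference(meta.index)
        if len(orphans):
            raise ValueError(f"data ids missing from metadata: {sorted(orphans.tolist())}")
        self.key = key
        self.data = data.reset_index(drop=True)
        self.meta = meta

    # -- introspection ---------------------------------------------------

    @property
    def ids(self) -> list:
        """Ids present in the data, in order of first appearance."""
        return self.data[self.key].unique().tolist()

    @property
    def variables(self) -> list[str]:
        """Behavioural variable names (data columns besides the key and t)."""
        return [c for c in self.data.columns if c not in (self.key, "t")]

    @property
    def metavariables(self) -> list[str]:
        return list(self.meta.columns)

    def summary(self) -> SummaryCounts:
        """Counts of individuals (with data), metavariables, variables, reads."""
        return SummaryCounts(
            n_individuals=int(self.data[self.key].nunique()),
            n_metavariables=len(self.meta.columns),
            n_variables=len(self.variables),
            n_reads=len(self.data),
        )

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        s = self.summary()
        return (
            f"LinkedBehaviourTable: {s.n_individuals} individuals, "
            f"{s.n_metavariables} metavariables, {s.n_variables} variables, "
            f"{s.n_reads} reads"
        )

    def copy(self) -> "LinkedBehaviourTable":
        return LinkedBehaviourTable(self.data.copy(), self.meta.copy(), self.key)

    # -- linking operations ----------------------------------------------

    def xmv(self, metavariable: str) -> pd.Series:
        """Expand a metavariable as a per-read column aligned with the data.

        The value at each data row is the metadata value of that row's id.
        """
        if metavariable not in self.meta.columns:
            raise KeyError(
                f"unknown metavariable {metavariable!r}; have {list(self.meta.columns)}"
            )
        out = self.data[self.key].map(self.meta[metavariable])
        out.name = metavariable
        return out

    def filter_data(
        self, predicate: Callable[[pd.DataFrame], Sequence[bool]] | Sequence[bool]
    ) -> "LinkedBehaviourTable":
        """Keep data rows satisfying *predicate*; restrict metadata to survivors.

        *predicate* is either a boolean mask aligned with the data or a
        callable mapping the data frame to one. The returned table's
        metadata holds exactly the ids still present in the data.
        """
        mask = predicate(self.data) if callable(predicate) else predicate
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self.data),):
            raise ValueError("predicate mask length does not match data")
        new_data = self.data.loc[mask].reset_index(drop=True)
        keep = self.meta.index.intersection(new_data[self.key].unique())
        return LinkedBehaviourTable(new_data, self.meta.loc[keep], self.key)

    def filter_ids(self, ids: Sequence) -> "LinkedBehaviourTable":
        """Keep only reads (and metadata rows) for the given ids."""
        ids = set(ids)
        return self.filter_data(self.data[self.key].isin(ids).to_numpy())

    def rejoin(self, per_id_table: pd.DataFrame) -> pd.DataFrame:
        """Join a one-row-per-id summary back onto all metavariables."""
        return rejoin(per_id_table, self.meta, key=self.key)

    def per_id(self) -> "pd.core.groupby.DataFrameGroupBy":
        """Group the data by individual."""
        return self.data.groupby(self.key, sort=False)


def link(meta: pd.DataFrame, data: pd.DataFrame, key: str = "id") -> LinkedBehaviourTable:
    """Link a metadata table and a long data table on their shared key."""
    return LinkedBehaviourTable(data, meta, key)


def rejoin(per_id_table: pd.DataFrame, meta: pd.DataFrame, key: str = "id") -> pd.DataFrame:
    """Attach every metavariable to a one-row-per-id summary table.

    Raises if the summary references an id absent from the metadata, which
    would silently drop rows in a plain merge.
    """
    meta = _normalise_meta(meta.copy(), key)
    if key in per_id_table.columns:
        ids = per_id_table[key]
        flat = per_id_table.copy()
    else:
        ids = per_id_table.index.to_series()
        flat = per_id_table.reset_index().rename(columns={per_id_table.index.name or "index": key})
    missing = pd.Index(ids.unique()).difference(meta.index)
    if len(missing):
        raise ValueError(f"summary ids missing from metadata: {sorted(missing.tolist())}")
    return flat.merge(meta.reset_index(), on=key, how="left")


_AGGREGATORS = {"mean", "max", "sum"}


def bin_time(
    t: Sequence[float],
    values: Sequence[float],
    bin_width: float,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Aggregate a (t, value) series into fixed-width time bins.

    Bins are half-open ``[k*w, (k+1)*w)`` anchored at t = 0; negative times
    fall into negative-k bins. Output has one row per non-empty bin, indexed
    by the bin's left edge (column ``t``), with the aggregated ``value``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.size == 0:
        return pd.DataFrame({"t": [], "value": []})
    edges = np.floor(t / bin_width) * bin_width
    out = (
        pd.DataFrame({"t": edges, "value": values})
        .groupby("t", sort=True)["value"]
        .agg(aggregator)
        .reset_index()
    )
    return out


# -- generic CSV interfaces ----------------------------------------------


def read_metadata_csv(path, key: str = "id") -> pd.DataFrame:
    """Read a metadata CSV (header row). An id column is generated if absent."""
    meta = pd.read_csv(path)
    if key not in meta.columns:
        meta[key] = [f"row_{i:03d}" for i in range(len(meta))]
    return meta.set_index(key)


def read_data_csv(path, key: str = "id") -> pd.DataFrame:
    """Read a long-format behaviour CSV with columns id, t, <variables>."""
    data = pd.read_csv(path)
    for col in (key, "t"):
        if col not in data.columns:
            raise ValueError(f"long-format data CSV lacks column {col!r}")
    return data
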