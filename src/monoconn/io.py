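"""Readers and writers for spike, session, and result-table files.

Two spike interchange dialects are supported:

* Klusters-style ``.res``/``.clu`` pairs — one integer sample index per
  ``.res`` line; the ``.clu`` file starts with the number of clusters and then
  holds one cluster id per spike. Cluster ids 0 and 1 are skipped as
  noise/artifact clusters (common Klusters convention, configurable).
* A plain comma-delimited table with header
  ``cell_id,animal_id,cell_type,time_s``.

Session tables are ``label,start_s,end_s`` rows; rows labeled ``LIGHT`` add
light-event intervals. Pair-level result tables round-trip losslessly through
CSV with 17-significant-digit floats.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CellType, Interval, SessionSet, SpikeTrain

logger = logging.getLogger(__name__)

DEFAULT_SAMPLING_RATE_HZ = 20_000.0
NOISE_CLUSTERS = (0, 1)

#: Mandatory identity columns of the pair-session result table.
PAIR_TABLE_MANDATORY = ("pair_id", "animal_id", "pre_id", "post_id")


# ---------------------------------------------------------------------------
# Klusters dialect
# ---------------------------------------------------------------------------

def load_klusters(
    res_path: str | Path,
    clu_path: str | Path,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    animal_id: str = "animal0",
    skip_clusters: Sequence[int] = NOISE_CLUSTERS,
    cell_type: CellType = CellType.UNKNOWN,
) -> list[SpikeTrain]:
    """Load spike trains from a Klusters ``.res``/``.clu`` file pair.

    Sample indices are divided by ``sampling_rate_hz`` to give seconds.
    One :class:`SpikeTrain` is returned per cluster id not in
    ``skip_clusters``; ids 0 and 1 are reserved for noise/artifact by default.

    Raises
    ------
    ValueError
        If the two files disagree on the number of spikes.
    """
    res = np.loadtxt(res_path, dtype=np.int64, ndmin=1) if Path(res_path).stat().st_size else np.empty(0, np.int64)
    clu_raw = np.loadtxt(clu_path, dtype=np.int64, ndmin=1) if Path(clu_path).stat().st_size else np.empty(0, np.int64)
    if clu_raw.size == 0:
        if res.size:
            raise ValueError(".clu file empty but .res has spikes")
        return []
    clu = clu_raw[1:]  # first line is the cluster count
    if clu.size != res.size:
        raise ValueError(
            f"spike count mismatch: {res.size} .res lines vs {clu.size} .clu ids"
        )
    trains: list[SpikeTrain] = []
    for cid in np.unique(clu):
        if int(cid) in skip_clusters:
            continue
        times = res[clu == cid] / float(sampling_rate_hz)
        if times.size > 1 and np.any(np.diff(times) <= 0):
            logger.warning("cluster %d: non-monotone spike times; sorting", cid)
            times = np.unique(times)
        trains.append(
            SpikeTrain(
                cell_id=f"{animal_id}_c{int(cid)}",
                animal_id=animal_id,
                cell_type=cell_type,
                spikes=times,
            )
        )
    return trains


def write_klusters(
    trains: Sequence[SpikeTrain],
    res_path: str | Path,
    clu_path: str | Path,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    first_cluster: int = 2,
) -> dict[str, int]:
    """Write trains as a merged, time-sorted ``.res``/``.clu`` pair.

    Returns the cell_id -> cluster id mapping used.
    """
    ids: dict[str, int] = {}
    samples: list[np.ndarray] = []
    clusters: list[np.ndarray] = []
    for k, tr in enumerate(trains):
        cid = first_cluster + k
        ids[tr.cell_id] = cid
        s = np.rint(tr.spikes * sampling_rate_hz).astype(np.int64)
        samples.append(s)
        clusters.append(np.full(s.size, cid, dtype=np.int64))
    if samples:
        all_s = np.concatenate(samples)
        all_c = np.concatenate(clusters)
        order = np.argsort(all_s, kind="stable")
        all_s, all_c = all_s[order], all_c[order]
    else:
        all_s = all_c = np.empty(0, dtype=np.int64)
    n_clusters = len(trains) + first_cluster
    Path(res_path).write_text("".join(f"{v}\n" for v in all_s))
    Path(clu_path).write_text(
        f"{n_clusters}\n" + "".join(f"{v}\n" for v in all_c)
    )
    return ids


# ---------------------------------------------------------------------------
# Tabular spike interchange
# ---------------------------------------------------------------------------

def load_tabular_spikes(path: str | Path) -> list[SpikeTrain]:
    """Load spikes from a CSV with header ``cell_id,animal_id,cell_type,time_s``.

    Rows with negative times are rejected (count logged); times are sorted
    per cell. Unrecognized cell_type strings map to ``unknown``.
    """
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "animal_id": str, "cell_type": str},
        float_precision="round_trip",
    )
    required = {"cell_id", "animal_id", "cell_type", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spike table {path}: missing columns {sorted(missing)}")
    bad = df["time_s"] < 0
    if bad.any():
        logger.warning("%s: rejected %d rows with negative time", path, int(bad.sum()))
        df = df[~bad]
    trains = []
    for cid, grp in df.groupby("cell_id", sort=True):
        try:
            ctype = CellType(grp["cell_type"].iloc[0])
        except ValueError:
            ctype = CellType.UNKNOWN
        times = np.unique(grp["time_s"].to_numpy(dtype=np.float64))
        trains.append(
            SpikeTrain(
                cell_id=str(cid),
                animal_id=str(grp["animal_id"].iloc[0]),
                cell_type=ctype,
                spikes=times,
            )
        )
    return trains


def write_tabular_spikes(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    """Write trains to the CSV spike interchange (inverse of the loader)."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "animal_id": tr.animal_id,
                "cell_type": tr.cell_type.value,
                "time_s": tr.spikes,
            }
        )
        for tr in trains
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell_id", "animal_id", "cell_type", "time_s"])
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Session tables
# ---------------------------------------------------------------------------

def load_session_table(path: str | Path) -> SessionSet:
    """Load a ``label,start_s,end_s`` session table.

    Rows with label ``LIGHT`` become light-event intervals. Sessions given
    out of chronological order are reordered by start time. Overlapping
    sessions, unknown labels, and light intervals outside every session are
    hard errors (raised by :class:`SessionSet` validation).
    """
    df = pd.read_csv(path, dtype={"label": str})
    required = {"label", "start_s", "end_s"}
    if required - set(df.columns):
        raise ValueError(f"session table {path}: expected columns {sorted(required)}")
    sessions, lights = [], []
    for row in df.itertuples(index=False):
        iv = Interval(str(row.label).upper(), float(row.start_s), float(row.end_s))
        (lights if iv.label == "LIGHT" else sessions).append(iv)
    return SessionSet(sessions=sessions, light_intervals=lights)


def write_session_table(sessions: SessionSet, path: str | Path) -> None:
    rows = [(s.label, s.start_s, s.end_s) for s in sessions.sessions]
    rows += [("LIGHT", li.start_s, li.end_s) for li in sessions.light_intervals]
    pd.DataFrame(rows, columns=["label", "start_s", "end_s"]).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Pair-session result tables
# ---------------------------------------------------------------------------

def write_pair_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a pair-session table to CSV, lossless for float64 columns."""
    _check_pair_columns(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read a pair-session table written by :func:`write_pair_table`."""
    table = pd.read_csv(
        path,
        dtype={k: str for k in PAIR_TABLE_MANDATORY},
        float_precision="round_trip",
    )
    _check_pair_columns(table)
    return table


def _check_pair_columns(table: pd.DataFrame) -> None:
    for col in PAIR_TABLE_MANDATORY:
        if col not in table.columns:
            raise ValueError(f"pair table missing mandatory column {col!r}")
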