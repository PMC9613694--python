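"""Panel readers and writers.

Two on-disk layouts are supported:

* ``long`` — a single ``series.csv`` with columns
  ``instance_id, channel_id, time_index, value`` plus ``labels.csv`` with
  ``instance_id, class``.
* ``wide`` — one CSV per instance (rows = time, columns = channels) plus a
  ``manifest.csv`` with ``filename, class``.

Time indices are 1-based in files (matching the convention ``t in 1..k``) and
0-based in memory; this module is the only place that mapping occurs.  The
activity-recognition dialect (``read_arem_folder``) accepts per-session CSVs
with ``#``-prefixed comment lines, a time column and 6 value columns.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .panel import LabeledPanel

__all__ = [
    "read_panel",
    "write_panel",
    "read_arem_folder",
    "write_features",
]


def write_panel(panel: LabeledPanel, path, format: str = "long") -> None:
    """Write a panel to ``path`` (a directory) in the given layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "long":
        rows = []
        for i, chans in enumerate(panel.series):
            iid = panel.instance_ids[i]
            for j, s in enumerate(chans):
                rows.append(
                    pd.DataFrame(
                        {
                            "instance_id": iid,
                            "channel_id": j + 1,
                            "time_index": np.arange(1, s.shape[0] + 1),
                            "value": s,
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(path / "series.csv", index=False)
        pd.DataFrame(
            {"instance_id": panel.instance_ids, "class": panel.labels}
        ).to_csv(path / "labels.csv", index=False)
    elif format == "wide":
        manifest = []
        for i, chans in enumerate(panel.series):
            fname = f"instance_{panel.instance_ids[i]}.csv"
            df = pd.DataFrame(
                {f"channel_{j + 1}": s for j, s in enumerate(chans)},
                index=pd.Index(np.arange(1, chans[0].shape[0] + 1), name="time_index"),
            )
            df.to_csv(path / fname)
            manifest.append({"filename": fname, "class": int(panel.labels[i])})
        pd.DataFrame(manifest).to_csv(path / "manifest.csv", index=False)
    else:
        raise DataError(f"unknown panel format {format!r} (use 'long' or 'wide')")


def _read_long(path: Path) -> LabeledPanel:
    series_file = path / "series.csv"
    labels_file = path / "labels.csv"
    for f in (series_file, labels_file):
        if not f.exists():
            raise DataError(f"missing required file: {f}")
    data = pd.read_csv(series_file)
    labels = pd.read_csv(labels_file)
    required = {"instance_id", "channel_id", "time_index", "value"}
    if not required.issubset(data.columns):
        raise DataError(
            f"{series_file}: expected columns {sorted(required)}, "
            f"got {list(data.columns)}"
        )
    if not {"instance_id", "class"}.issubset(labels.columns):
        raise DataError(f"{labels_file}: expected columns instance_id, class")
    labels["instance_id"] = labels["instance_id"].astype(str)
    label_map = dict(zip(labels["instance_id"], labels["class"].astype(int)))
    if labels["instance_id"].duplicated().any():
        dup = labels.loc[labels["instance_id"].duplicated(), "instance_id"].iloc[0]
        raise DataError(f"{labels_file}: duplicate instance_id {dup!r}")
    data["instance_id"] = data["instance_id"].astype(str)
    if not np.issubdtype(data["value"].dtype, np.number):
        bad = data.loc[pd.to_numeric(data["value"], errors="coerce").isna()].index[0]
        raise DataError(f"{series_file}: non-numeric value at data row {bad + 1}")
    series, lbls, ids = [], [], []
    for iid, grp in data.groupby("instance_id", sort=False):
        if iid not in label_map:
            raise DataError(f"{labels_file}: no class label for instance {iid!r}")
        chans = []
        chan_ids = sorted(grp["channel_id"].unique())
        for j, cid in enumerate(chan_ids, start=1):
            if cid != j:
                raise DataError(
                    f"{series_file}: instance {iid!r} channel ids are not "
                    f"contiguous from 1 (found {chan_ids})"
                )
            sub = grp[grp["channel_id"] == cid].sort_values("time_index")
            t = sub["time_index"].to_numpy()
            if sub["time_index"].duplicated().any():
                raise DataError(
                    f"{series_file}: instance {iid!r} channel {cid} has "
                    f"duplicate time indices"
                )
            if not np.array_equal(t, np.arange(1, t.shape[0] + 1)):
                raise DataError(
                    f"{series_file}: instance {iid!r} channel {cid} time_index "
                    f"must be contiguous from 1"
                )
            chans.append(sub["value"].to_numpy(dtype=float))
        series.append(chans)
        lbls.append(label_map[iid])
        ids.append(iid)
    missing = set(label_map) - set(ids)
    if missing:
        raise DataError(f"labels reference instances absent from series.csv: {sorted(missing)}")
    return LabeledPanel(series=series, labels=np.asarray(lbls), instance_ids=ids)


def _read_wide(path: Path) -> LabeledPanel:
    manifest_file = path / "manifest.csv"
    if not manifest_file.exists():
        raise DataError(f"missing required file: {manifest_file}")
    manifest = pd.read_csv(manifest_file)
    if not {"filename", "class"}.issubset(manifest.columns):
        raise DataError(f"{manifest_file}: expected columns filename, class")
    series, lbls, ids = [], [], []
    for _, row in manifest.iterrows():
        f = path / str(row["filename"])
        if not f.exists():
            raise DataError(f"{manifest_file} references missing file: {f}")
        df = pd.read_csv(f)
        if "time_index" in df.columns:
            df = df.set_index("time_index")
        chans = [df[col].to_numpy(dtype=float) for col in df.columns]
        if not chans:
            raise DataError(f"{f}: no channel columns")
        series.append(chans)
        lbls.append(int(row["class"]))
        ids.append(Path(str(row["filename"])).stem.removeprefix("instance_"))
    return LabeledPanel(series=series, labels=np.asarray(lbls), instance_ids=ids)


def read_panel(path, format: str = "long") -> LabeledPanel:
    """Read a panel directory in ``long`` or ``wide`` layout."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"panel path does not exist: {path}")
    if format == "long":
        return _read_long(path)
    if format == "wide":
        return _read_wide(path)
    raise DataError(f"unknown panel format {format!r} (use 'long' or 'wide')")


def read_arem_folder(path, labels: dict[str, int] | None = None) -> LabeledPanel:
    """Read a folder of per-session activity CSVs (``#`` comments, 6 channels).

    Sessions are expected as ``<activity>/dataset<N>.csv`` or flat files named
    ``<activity>_<N>.csv``; ``labels`` maps activity name to class number
    (defaults to alphabetical order of activities found).  Each file has a
    time column followed by exactly 6 value columns.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"path does not exist: {path}")
    entries: list[tuple[str, int, Path]] = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        for f in sorted(sub.glob("*.csv")):
            num = "".join(ch for ch in f.stem if ch.isdigit()) or "0"
            entries.append((sub.name.lower(), int(num), f))
    if not entries:
        for f in sorted(path.glob("*_*.csv")):
            act, _, num = f.stem.rpartition("_")
            entries.append((act.lower(), int(num), f))
    if not entries:
        raise DataError(f"no activity CSV files found under {path}")
    activities = sorted({a for a, _, _ in entries})
    if labels is None:
        labels = {a: q + 1 for q, a in enumerate(activities)}
    series, lbls, ids = [], [], []
    for act, num, f in sorted(entries, key=lambda e: (labels.get(e[0], 0), e[1])):
        if act not in labels:
            raise DataError(f"no class label for activity {act!r} (file {f})")
        df = pd.read_csv(f, comment="#", header=None)
        df = df.dropna(axis=1, how="all")
        if df.shape[1] != 7:
            raise DataError(
                f"{f}: expected a time column plus 6 value columns, "
                f"got {df.shape[1]} columns"
            )
        t = df.iloc[:, 0].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"{f}: time column is not strictly increasing")
        chans = [df.iloc[:, j].to_numpy(dtype=float) for j in range(1, 7)]
        series.append(chans)
        lbls.append(labels[act])
        ids.append(f"{act}_{num}")
    return LabeledPanel(series=series, labels=np.asarray(lbls), instance_ids=ids)


def write_features(features: pd.DataFrame, path) -> None:
    """Write a feature table (index = instance ids) as CSV."""
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True) if path.parent != Path("") else None
    features.to_csv(path)
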