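"""Readers and writers for the package's delimited-text formats.

* trajectory CSV: header ``time_h,<species...>`` with a JSON metadata
  sidecar (``<path>.meta.json``);
* actogram CSV: ``bin_start_min,count,lights`` with lights coded 0/1;
* verdict / rhythm-summary JSON reports.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .synth import Actogram

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_actogram_csv",
    "read_actogram_csv",
    "write_report_json",
]


def write_trajectory_csv(traj, path, metadata_sidecar=True) -> None:
    df = pd.DataFrame(traj.states, columns=traj.species_names)
    df.insert(0, "time_h", traj.times)
    df.to_csv(path, index=False)
    if metadata_sidecar and traj.metadata:
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(traj.metadata, fh, indent=1)


def read_trajectory_csv(path):
    from .dynamics import Trajectory

    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing time_h column")
    meta = {}
    try:
        with open(f"{path}.meta.json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    names = [c for c in df.columns if c != "time_h"]
    return Trajectory(df["time_h"].to_numpy(), df[names].to_numpy(), names, meta)


def write_actogram_csv(actogram: Actogram, path) -> None:
    bpd = actogram.bins_per_day
    lights = np.zeros(len(actogram.counts), dtype=int)
    for d, lab in enumerate(actogram.schedule):
        if lab == "LD":
            # lights on during the first half of each LD day
            start = d * bpd
            lights[start: start + bpd // 2] = 1
    starts = np.arange(len(actogram.counts)) * actogram.bin_width
    df = pd.DataFrame({
        "bin_start_min": starts.astype(int if actogram.bin_width.is_integer() else float),
        "count": actogram.counts,
        "lights": lights,
    })
    df.to_csv(path, index=False)


def read_actogram_csv(path) -> Actogram:
    df = pd.read_csv(path)
    for col in ("bin_start_min", "count", "lights"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    starts = df["bin_start_min"].to_numpy(float)
    if len(starts) < 2:
        raise ValueError(f"{path}: actogram too short")
    bin_width = float(starts[1] - starts[0])
    counts = df["count"].to_numpy()
    bpd = int(round(24 * 60 / bin_width))
    days = len(counts) // bpd
    lights = df["lights"].to_numpy()
    schedule = ["LD" if lights[d * bpd: (d + 1) * bpd].any() else "DD"
                for d in range(days)]
    return Actogram(bin_width=bin_width, counts=counts[: days * bpd],
                    schedule=schedule)


def write_report_json(obj, path) -> None:
    """Serialize any object exposing ``to_dict`` (or a plain dict)."""
    d = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)
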