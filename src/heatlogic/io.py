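"""Reading and writing the delimited-text interchange formats.

Hourly weather: ``timestamp,dry_bulb_c,dew_point_c[,apparent_c]`` with
ISO-8601 timestamps.  Daily counts:
``date,count[,hosp_*...,holiday_fed,holiday_state]``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .logictree import LogicTree
from .meteorology import validate_hourly

__all__ = [
    "read_hourly_weather",
    "write_hourly_weather",
    "read_daily_counts",
    "write_daily_counts",
    "read_tree",
    "write_tree",
]


def read_hourly_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return validate_hourly(df)


def write_hourly_weather(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.3f")


def read_daily_counts(path) -> tuple[pd.Series, pd.DataFrame | None, pd.DataFrame | None]:
    """Return (counts, holidays, hospitals); the frames are None when absent."""
    df = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    if "count" not in df.columns:
        raise ValueError("daily counts file must have a 'count' column")
    counts = df["count"].astype(float)
    hol_cols = [c for c in df.columns if c.startswith("holiday")]
    hosp_cols = [c for c in df.columns if c.startswith("hosp")]
    holidays = df[hol_cols] if hol_cols else None
    hospitals = df[hosp_cols] if hosp_cols else None
    return counts, holidays, hospitals


def write_daily_counts(counts: pd.Series, path, holidays: pd.DataFrame | None = None,
                       hospitals: pd.DataFrame | None = None) -> None:
    df = pd.DataFrame({"count": counts})
    for extra in (holidays, hospitals):
        if extra is not None:
            df = df.join(extra)
    df.index.name = "date"
    df.reset_index().assign(date=lambda d: d["date"].dt.strftime("%Y-%m-%d")).to_csv(
        path, index=False
    )


def read_tree(path) -> LogicTree:
    return LogicTree.from_json(Path(path).read_text())


def write_tree(tree: LogicTree, path) -> None:
    Path(path).write_text(tree.to_json(indent=2) + "\n")
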