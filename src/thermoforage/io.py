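"""CSV readers/writers and run configuration.

All tables are tidy long-format CSV with ISO-8601 timestamps:

* activity:  nest_id, datetime, surface_temp, worker_count, swarm_speed,
             time_of_day, light, wind, nest_size (exactly one of
             worker_count / swarm_speed per row)
* loggers:   nest_id, timestamp, temp_C (30-min cadence)
* surveys:   nest_id, year, entrance_holes, n_foraging_trails,
             n_tree_trails, n_connection_trails

Readers validate rows and return the accepted table together with a report
of rejected rows and reasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TEMP_BOUNDS = (-10.0, 70.0)


@dataclass
class ValidationReport:
    source: str
    n_rows: int
    n_accepted: int
    rejected: list[tuple[int, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"source": self.source, "n_rows": self.n_rows,
                "n_accepted": self.n_accepted,
                "rejected": [{"row": r, "reason": why} for r, why in self.rejected],
                "notes": list(self.notes)}


def _read_csv(path, required: set[str], source: str) -> tuple[pd.DataFrame, ValidationReport]:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source} file {path} lacks columns {sorted(missing)}")
    report = ValidationReport(source=source, n_rows=len(df), n_accepted=len(df))
    if df.empty:
        report.notes.append("empty input: zero records")
    return df, report


def _drop(df: pd.DataFrame, report: ValidationReport, bad: pd.Series, reason: str):
    for idx in df.index[bad]:
        report.rejected.append((int(idx), reason))
    return df[~bad]


def read_logger_csv(path) -> tuple[pd.DataFrame, ValidationReport]:
    df, report = _read_csv(path, {"nest_id", "timestamp", "temp_C"}, "loggers")
    if df.empty:
        return df, report
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    df = _drop(df, report, ts.isna(), "unparseable timestamp")
    df = df.assign(timestamp=pd.to_datetime(df["timestamp"]))
    temp = pd.to_numeric(df["temp_C"], errors="coerce")
    df = _drop(df, report, ~np.isfinite(temp), "non-numeric temperature")
    dup = df.duplicated(subset=["nest_id", "timestamp"], keep="first")
    df = _drop(df, report, dup, "duplicate (nest_id, timestamp) key")
    df = df.sort_values(["nest_id", "timestamp"]).reset_index(drop=True)
    report.n_accepted = len(df)
    return df, report


def read_activity_csv(path) -> tuple[pd.DataFrame, ValidationReport]:
    df, report = _read_csv(path, {"nest_id", "datetime", "surface_temp"}, "activity")
    if df.empty:
        return df, report
    for col in ("worker_count", "swarm_speed", "time_of_day", "light", "wind",
                "nest_size"):
        if col not in df.columns:
            df[col] = np.nan
    ts = pd.to_datetime(df["datetime"], errors="coerce")
    df = _drop(df, report, ts.isna(), "unparseable datetime")
    df = df.assign(datetime=pd.to_datetime(df["datetime"]))
    temp = pd.to_numeric(df["surface_temp"], errors="coerce")
    out_of_range = ~((temp >= TEMP_BOUNDS[0]) & (temp <= TEMP_BOUNDS[1]))
    df = _drop(df, report, out_of_range.fillna(True),
               f"surface_temp outside {TEMP_BOUNDS}")
    has_count = df["worker_count"].notna()
    has_speed = df["swarm_speed"].notna()
    df = _drop(df, report, ~(has_count ^ has_speed),
               "need exactly one of worker_count / swarm_speed")
    if "time_of_day" in df and df["time_of_day"].isna().all():
        dtx = pd.DatetimeIndex(df["datetime"])
        df = df.assign(time_of_day=dtx.hour + dtx.minute / 60.0)
    df = df.reset_index(drop=True)
    report.n_accepted = len(df)
    return df, report


def read_survey_csv(path) -> tuple[pd.DataFrame, ValidationReport]:
    df, report = _read_csv(path, {"nest_id", "year", "entrance_holes",
                                  "n_foraging_trails", "n_tree_trails",
                                  "n_connection_trails"}, "surveys")
    if df.empty:
        return df, report
    for col in ("entrance_holes", "n_foraging_trails", "n_tree_trails",
                "n_connection_trails"):
        vals = pd.to_numeric(df[col], errors="coerce")
        df = _drop(df, report, (vals < 0) | vals.isna(), f"invalid {col}")
    dup = df.duplicated(subset=["nest_id", "year"], keep="first")
    df = _drop(df, report, dup, "duplicate (nest_id, year) key")
    df = df.reset_index(drop=True)
    report.n_accepted = len(df)
    return df, report


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV output: fixed float format, no index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def series_to_csv(series_list, path) -> None:
    frames = [s.to_frame() for s in series_list]
    write_csv(pd.concat(frames, ignore_index=True), path)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class MCMCSettings:
    iterations: int = 3000
    warmup: int = 1000
    walkers: int = 32


@dataclass
class PipelineConfig:
    """Run configuration: either input paths or a simulate block."""

    activity_path: str | None = None
    loggers_path: str | None = None
    surveys_path: str | None = None
    simulate: dict | None = None
    site_latitude: float = -32.3
    fraction: float = 0.90
    grid_step: float = 0.1
    coverage_threshold: float = 0.9
    n_sim_rlrt: int = 199
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int = 0
    output_dir: str = "thermoforage_out"

    def __post_init__(self) -> None:
        has_paths = any(p is not None for p in
                        (self.activity_path, self.loggers_path, self.surveys_path))
        if has_paths == (self.simulate is not None):
            raise ValueError("config needs exactly one of input paths or a "
                             "simulate block")
        if not (0.0 < self.fraction < 1.0):
            raise ValueError(f"fraction must lie in (0, 1), got {self.fraction}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = MCMCSettings(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)
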