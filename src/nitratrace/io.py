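"""CSV readers/writers and dataset validation.

File dialect: comma-separated, UTF-8, mandatory header row, "." decimal
separator; an empty string means "missing".  ``read_samples`` followed by
``write_samples`` is the identity on the defined schema.

Two source-table layouts are accepted:

* long — columns ``source_id, tracer, mean, sd[, frac_mean, frac_sd]``,
  one row per (source, tracer);
* wide — one row per source with per-tracer columns such as
  ``mean_d15N_NO3, sd_d15N_NO3, ...``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import (
    TRACERS,
    AnalysisConfig,
    MCMCConfig,
    SampleRecord,
    SourceProfile,
)

__all__ = [
    "SchemaError",
    "read_samples",
    "write_samples",
    "read_sources",
    "write_sources",
    "validate_dataset",
    "load_config",
    "dump_config",
]

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "water_type", "d15N_NO3", "d18O_NO3")
OPTIONAL_SAMPLE_COLUMNS = ("region", "no3", "tn", "nh4", "cond", "d18O_H2O")
SAMPLE_COLUMNS = (
    "sample_id",
    "water_type",
    "region",
    "d15N_NO3",
    "d18O_NO3",
    "no3",
    "tn",
    "nh4",
    "cond",
    "d18O_H2O",
)


class SchemaError(ValueError):
    """An input file does not match the documented schema."""


def _parse_float(value, column: str, row: int) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(
            f"non-numeric value {text!r} in column {column!r} at data row {row}"
        ) from None


def read_samples(path: str | Path, schema: dict[str, str] | None = None) -> list[SampleRecord]:
    """Read water samples from CSV, one :class:`SampleRecord` per row.

    Parameters
    ----------
    path:
        CSV file with at least ``sample_id, water_type, d15N_NO3, d18O_NO3``.
    schema:
        Optional map from record field name to the column name used in the
        file, for files with non-default headers.

    Missing optional fields stay absent (``None``) — never zero.
    Row order is preserved.
    """
    schema = schema or {}
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {f: schema.get(f, f) for f in SAMPLE_COLUMNS}
    for f in REQUIRED_SAMPLE_COLUMNS:
        if colmap[f] not in frame.columns:
            raise SchemaError(f"missing required column {colmap[f]!r}")
    records: list[SampleRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))

        def get(fld: str):
            col = colmap[fld]
            return row.get(col) if col in frame.columns else None

        d15 = _parse_float(get("d15N_NO3"), colmap["d15N_NO3"], i)
        if d15 is None:
            raise SchemaError(f"missing d15N_NO3 value at data row {i}")
        records.append(
            SampleRecord(
                sample_id=str(get("sample_id")).strip(),
                water_type=str(get("water_type")).strip(),
                region=str(get("region") or "").strip(),
                d15N_NO3=d15,
                d18O_NO3=_parse_float(get("d18O_NO3"), colmap["d18O_NO3"], i),
                no3=_parse_float(get("no3"), "no3", i),
                tn=_parse_float(get("tn"), "tn", i),
                nh4=_parse_float(get("nh4"), "nh4", i),
                cond=_parse_float(get("cond"), "cond", i),
                d18O_H2O=_parse_float(get("d18O_H2O"), "d18O_H2O", i),
            )
        )
    return records


def samples_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in samples], columns=SAMPLE_COLUMNS)


def write_samples(samples: Sequence[SampleRecord], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def _profiles_from_long(frame: pd.DataFrame) -> list[SourceProfile]:
    if "sd" not in frame.columns:
        raise SchemaError("sources file lacks an 'sd' column (source uncertainty is mandatory)")
    profiles = []
    for sid, grp in frame.groupby("source_id", sort=False):
        mean = dict(zip(grp["tracer"], grp["mean"].astype(float)))
        sd = dict(zip(grp["tracer"], grp["sd"].astype(float)))
        frac_mean = (
            dict(zip(grp["tracer"], grp["frac_mean"].astype(float)))
            if "frac_mean" in grp.columns
            else {}
        )
        frac_sd = (
            dict(zip(grp["tracer"], grp["frac_sd"].astype(float)))
            if "frac_sd" in grp.columns
            else {}
        )
        profiles.append(
            SourceProfile(str(sid), mean=mean, sd=sd, frac_mean=frac_mean, frac_sd=frac_sd)
        )
    return profiles


def _profiles_from_wide(frame: pd.DataFrame) -> list[SourceProfile]:
    mean_cols = [c for c in frame.columns if c.startswith("mean_")]
    tracers = [c[len("mean_"):] for c in mean_cols]
    if not tracers:
        raise SchemaError(
            "sources file is neither long (source_id,tracer,mean,sd) "
            "nor wide (mean_<tracer>, sd_<tracer>) layout"
        )
    for t in tracers:
        if f"sd_{t}" not in frame.columns:
            raise SchemaError(
                f"sources file lacks column 'sd_{t}' (source uncertainty is mandatory)"
            )
    profiles = []
    for _, row in frame.iterrows():
        profiles.append(
            SourceProfile(
                str(row["source_id"]),
                mean={t: float(row[f"mean_{t}"]) for t in tracers},
                sd={t: float(row[f"sd_{t}"]) for t in tracers},
                frac_mean={
                    t: float(row[f"frac_mean_{t}"])
                    for t in tracers
                    if f"frac_mean_{t}" in frame.columns
                },
                frac_sd={
                    t: float(row[f"frac_sd_{t}"])
                    for t in tracers
                    if f"frac_sd_{t}" in frame.columns
                },
            )
        )
    return profiles


def read_sources(path: str | Path) -> list[SourceProfile]:
    """Read nitrate source signatures from CSV (long or wide layout)."""
    frame = pd.read_csv(path)
    if "source_id" not in frame.columns:
        raise SchemaError("sources file lacks a 'source_id' column")
    if "tracer" in frame.columns and "mean" in frame.columns:
        return _profiles_from_long(frame)
    return _profiles_from_wide(frame)


def write_sources(sources: Sequence[SourceProfile], path: str | Path) -> None:
    rows = []
    for s in sources:
        for t in s.tracers:
            rows.append(
                {
                    "source_id": s.source_id,
                    "tracer": t,
                    "mean": s.mean[t],
                    "sd": s.sd[t],
                    "frac_mean": s.frac_mean[t],
                    "frac_sd": s.frac_sd[t],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_dataset(
    samples: Sequence[SampleRecord],
    sources: Sequence[SourceProfile],
    config: AnalysisConfig | None = None,
) -> list[str]:
    """Return a list of violations; an empty list means the dataset is runnable."""
    config = config or AnalysisConfig()
    violations: list[str] = []
    seen: set[str] = set()
    for s in samples:
        if s.sample_id in seen:
            violations.append(f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)
    for src in sources:
        for t in config.tracers:
            if t not in src.mean or t not in src.sd:
                violations.append(f"source {src.source_id!r} missing tracer {t!r}")
            elif src.sd[t] < 0:
                violations.append(f"source {src.source_id!r} has negative sd for {t!r}")
    if len({s.source_id for s in sources}) != len(sources):
        violations.append("duplicate source_id in source set")
    return violations


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a flat JSON config; keys mirror :class:`AnalysisConfig` fields."""
    raw = json.loads(Path(path).read_text())
    mcmc = MCMCConfig(**raw.pop("mcmc", {}))
    if "tracers" in raw:
        raw["tracers"] = tuple(raw["tracers"])
    return AnalysisConfig(mcmc=mcmc, **raw)


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    """Echo the resolved configuration (including seeds) to a JSON file."""
    payload = dataclasses.asdict(config)
    payload["tracers"] = list(config.tracers)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
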