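"""Plain-text file formats and run manifests.

Everything the pipeline writes is diffable text: tidy CSV for rasters,
sweeps, depression curves and metrics; JSON for configuration and the run
manifest.  Reads validate column schemas and fail loudly (with the
offending location) rather than returning partial data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

RASTER_COLUMNS = ["trial", "neuron", "population", "t_ms"]
SWEEP_COLUMNS = ["ga_ratio", "frequency_hz", "n_spikes", "first_latency_ms", "jitter_ms"]
DEPRESSION_COLUMNS = ["frequency_hz", "stimulus_index", "amplitude_norm"]


class FormatError(ValueError):
    """A file did not conform to its documented schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}; found {list(df.columns)}")


def write_raster_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in RASTER_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in RASTER_COLUMNS
    ]
    df[cols].to_csv(path, index=False)


def read_raster_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with location
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    _check_columns(df, RASTER_COLUMNS, path)
    bad = df["t_ms"].isna()
    if bad.any():
        raise FormatError(f"{path}: missing spike times at rows {list(df.index[bad][:5])}")
    return df


def write_depression_csv(curves: dict[float, "pd.Series | list | tuple"], path) -> None:
    rows = []
    for f, amps in sorted(curves.items()):
        for k, a in enumerate(amps):
            rows.append({"frequency_hz": f, "stimulus_index": k, "amplitude_norm": a})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_depression_csv(path) -> dict[float, list[float]]:
    df = pd.read_csv(path)
    _check_columns(df, DEPRESSION_COLUMNS, path)
    out: dict[float, list[float]] = {}
    for f, g in df.groupby("frequency_hz"):
        g = g.sort_values("stimulus_index")
        idx = g["stimulus_index"].to_numpy()
        if not (idx == range(len(idx))).all():
            raise FormatError(f"{path}: non-contiguous stimulus indices for {f} Hz")
        out[float(f)] = g["amplitude_norm"].tolist()
    return out


def config_hash(payload: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written before a pipeline run starts."""

    config: dict
    seeds: dict[str, int]
    package_version: str
    stages: dict[str, str] = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    @property
    def hash(self) -> str:
        return config_hash(self.config)

    def to_json(self) -> dict:
        return {
            "schema_version": 1,
            "config_hash": self.hash,
            "config": self.config,
            "seeds": self.seeds,
            "package_version": self.package_version,
            "stages": self.stages,
            "created": self.created,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2, default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        for key in ("config", "seeds", "package_version"):
            if key not in d:
                raise FormatError(f"{path}: manifest missing required field {key!r}")
        return cls(
            config=d["config"],
            seeds=d["seeds"],
            package_version=d["package_version"],
            stages=d.get("stages", {}),
            created=d.get("created", ""),
        )

    def mark(self, stage: str, status: str, path=None) -> None:
        self.stages[stage] = status
        if path is not None:
            self.save(path)
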