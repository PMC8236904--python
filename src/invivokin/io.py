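"""Readers, writers and reproducibility plumbing.

All on-disk formats are plain text: long-format CSV for metabolomics
tables, two-column CSV for kinetic traces and steady-state curves, JSON
for fit results, model comparisons and run manifests.  Every CLI run
emits a manifest (command, config hash, input hashes, seed, version,
timestamp) sufficient to re-run it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import SteadyStateCurve
from .fractal import KineticTrace

__all__ = [
    "SchemaError",
    "MetabolomicsTable",
    "RunManifest",
    "read_metabolomics_csv",
    "write_metabolomics_csv",
    "read_trace_csv",
    "write_trace_csv",
    "write_curve_csv",
    "write_json",
]

REQUIRED_COLUMNS = [
    "strain",
    "condition",
    "supplement_mM",
    "timepoint_h",
    "replicate",
    "metabolite",
    "relative_abundance",
    "is_censored",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates the value schema."""


@dataclass(frozen=True)
class MetabolomicsTable:
    """Long-format relative metabolite abundances with design keys.

    One row per (strain, condition, supplement dose, timepoint, replicate,
    metabolite).  ``is_censored`` marks values below the detection limit;
    a censored row stores the limit itself.  Unknown extra columns are
    preserved as annotations.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = self.df.copy()
        df["relative_abundance"] = df["relative_abundance"].astype(float)
        df["is_censored"] = df["is_censored"].astype(bool)
        negative = df.index[df["relative_abundance"] < 0]
        if len(negative):
            raise SchemaError(
                f"negative relative_abundance at row index {negative[0]}"
            )
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)


def read_metabolomics_csv(path: str | Path) -> MetabolomicsTable:
    """Read and validate a long-format metabolomics CSV."""
    df = pd.read_csv(path)
    if df.empty and not set(REQUIRED_COLUMNS) <= set(df.columns):
        raise SchemaError(
            f"missing required column(s): "
            f"{', '.join(c for c in REQUIRED_COLUMNS if c not in df.columns)}"
        )
    return MetabolomicsTable(df)


def write_metabolomics_csv(table: MetabolomicsTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> KineticTrace:
    """Read a two-column (time, value) trace CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError("trace CSV needs two columns (time, value)")
    return KineticTrace(
        times=df.iloc[:, 0].to_numpy(float), values=df.iloc[:, 1].to_numpy(float)
    )


def write_trace_csv(trace: KineticTrace, path: str | Path) -> None:
    pd.DataFrame({"time": trace.times, "value": trace.values}).to_csv(path, index=False)


def write_curve_csv(
    curve: SteadyStateCurve, path: str | Path, sidecar_params: dict | None = None
) -> None:
    """Write a steady-state curve as (s1, s2) CSV with a JSON sidecar.

    The sidecar records the generating chain parameters and the unit tag.
    """
    curve.to_frame().to_csv(path, index=False)
    sidecar = {"unit": curve.unit, "params": sidecar_params or {}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    seed: int | None = None
    config_hash: str = ""
    input_hashes: dict[str, str] = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        command: str,
        seed: int | None = None,
        config: dict | None = None,
        inputs: list[str | Path] = (),
    ) -> "RunManifest":
        from . import __version__

        config_hash = (
            hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()
            if config is not None
            else ""
        )
        return cls(
            command=command,
            seed=seed,
            config_hash=config_hash,
            input_hashes={str(p): file_sha256(p) for p in inputs},
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "input_hashes": dict(self.input_hashes),
            "package_version": self.package_version,
            "timestamp": self.timestamp,
        }

    def write(self, out_path: str | Path) -> Path:
        """Write the manifest next to an output file as <out>.manifest.json."""
        path = Path(str(out_path) + ".manifest.json")
        write_json(self.to_dict(), path)
        return path
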