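"""Table I/O, run manifests, and validation.

All tables are tab-separated UTF-8 text with a header row and Unix
newlines; summaries and manifests are JSON.  Readers validate schemas
loudly and name the offending row or column; writers emit a fixed column
order so fixtures are diff-able.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from ecdna_dyn.errors import (
    BadValueError,
    DuplicateIdError,
    EmptyTableError,
    MissingColumnError,
)
from ecdna_dyn.population import CopyNumberDistribution
from ecdna_dyn.scenarios import JunctionFrequencySeries
from ecdna_dyn.synthdata import CellCountTable, DaughterPairTable

__all__ = [
    "RunManifest",
    "read_cell_counts",
    "write_cell_counts",
    "read_daughter_pairs",
    "write_daughter_pairs",
    "write_distribution",
    "read_distribution",
    "expand_distribution",
    "write_junction_series",
]

PathLike = Union[str, Path]


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run's outputs."""

    command: str
    config: dict
    seed: Optional[int]
    outputs: list = field(default_factory=list)
    version: str = ""
    started: str = ""
    finished: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from ecdna_dyn import __version__

            self.version = __version__
        if not self.started:
            self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def finish(self) -> None:
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path: PathLike) -> None:
        self.finish()
        payload = {
            "tool": "ecdna-dyn",
            "version": self.version,
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "outputs": [str(p) for p in self.outputs],
            "started": self.started,
            "finished": self.finished,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _read_tsv(path: PathLike, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        raise MissingColumnError(f"{path}: unknown column(s) {extra} in header")
    if len(df) == 0:
        raise EmptyTableError(f"{path}: header only, no data rows")
    return df


def _parse_count(df: pd.DataFrame, column: str, path: PathLike) -> np.ndarray:
    raw = df[column]
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = parsed.isna() | (parsed != parsed.round()) | (parsed < 0)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise BadValueError(
            f"{path}: column {column!r}, row {row + 1}: value {raw.iloc[row]!r} "
            "is not a non-negative integer"
        )
    return parsed.to_numpy(dtype=np.int64)


def read_cell_counts(path: PathLike) -> CellCountTable:
    """Read a per-cell copy-number TSV with columns ``cell_id``, ``copy_count``."""
    df = _read_tsv(path, ["cell_id", "copy_count"])
    counts = _parse_count(df, "copy_count", path)
    ids = df["cell_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DuplicateIdError(f"{path}: duplicate cell_id {dup!r}")
    table = pd.DataFrame({"cell_id": ids.to_numpy(), "copy_count": counts})
    return CellCountTable(table, {"source": str(path)})


def write_cell_counts(table: CellCountTable, path: PathLike) -> None:
    table.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_daughter_pairs(path: PathLike) -> DaughterPairTable:
    """Read a daughter-pair TSV with columns ``pair_id``, ``n1``, ``n2``.

    Pairs with zero total signal are accepted here; downstream fraction
    analyses exclude them (with a warning) since they carry no information
    about the split.
    """
    df = _read_tsv(path, ["pair_id", "n1", "n2"])
    n1 = _parse_count(df, "n1", path)
    n2 = _parse_count(df, "n2", path)
    ids = df["pair_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DuplicateIdError(f"{path}: duplicate pair_id {dup!r}")
    table = pd.DataFrame({"pair_id": ids.to_numpy(), "n1": n1, "n2": n2})
    return DaughterPairTable(table, {"source": str(path)})


def write_daughter_pairs(table: DaughterPairTable, path: PathLike) -> None:
    table.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_distribution(dist: CopyNumberDistribution, path: PathLike) -> None:
    """Write a copy-number distribution as TSV ``k / count`` rows.

    Counts are the observed cell numbers per class (frequency times sample
    size, rounded), which round-trips exactly for empirical distributions.
    """
    counts = np.rint(dist.frequencies * dist.sample_size).astype(np.int64)
    df = pd.DataFrame({"k": np.arange(counts.size), "count": counts})
    df = df[df["count"] > 0]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_distribution(path: PathLike) -> CopyNumberDistribution:
    """Read a ``k / count`` TSV back into a copy-number distribution."""
    df = _read_tsv(path, ["k", "count"])
    k = _parse_count(df, "k", path)
    count = _parse_count(df, "count", path)
    counts = np.zeros(int(k.max()) + 1, dtype=np.int64)
    np.add.at(counts, k, count)
    return CopyNumberDistribution.from_counts(counts)


def expand_distribution(dist: CopyNumberDistribution) -> np.ndarray:
    """Per-cell count sample implied by an empirical distribution."""
    counts = np.rint(dist.frequencies * dist.sample_size).astype(np.int64)
    return np.repeat(np.arange(counts.size), counts)


def write_junction_series(series: JunctionFrequencySeries, path: PathLike) -> None:
    pd.DataFrame(
        {
            "t": series.times,
            "ecdna_junction_frequency": series.ecdna_junction_frequency,
            "scar_frequency": series.scar_frequency,
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
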