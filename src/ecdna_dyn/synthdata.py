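"""Synthetic stand-ins for the study's measurement modalities.

No sequencing or raw microscopy data accompany the experimental design this
package models, so every pipeline stage is exercised against generated
data:

- daughter-pair tables emulate paired post-mitotic FISH counts
  (~100 pairs per cell line, founders uniform on 20-200 copies);
- per-cell copy-number tables emulate interphase FISH counting, with an
  optional binomial detection-efficiency thinning (probe dropout only, no
  false-positive spots);
- junction-frequency time courses emulate droplet digital PCR, using the
  standard Poisson partition estimator with a single-copy reference
  amplicon.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from ecdna_dyn.errors import ParameterError
from ecdna_dyn.population import CopyNumberDistribution
from ecdna_dyn.scenarios import JunctionFrequencySeries
from ecdna_dyn.segregation import SegregationModel, _division_fractions, uniform_founder_sampler

__all__ = [
    "CellCountTable",
    "DaughterPairTable",
    "make_daughter_pairs",
    "make_fish_table",
    "make_ddpcr_series",
]


@dataclass(frozen=True)
class CellCountTable:
    """Per-cell copy-number counts with generation metadata."""

    table: pd.DataFrame  # columns: cell_id, copy_count
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["cell_id", "copy_count"]:
            raise ParameterError("cell count table needs columns cell_id, copy_count")
        if self.table["cell_id"].duplicated().any():
            raise ParameterError("cell ids must be unique")
        if (self.table["copy_count"] < 0).any():
            raise ParameterError("copy counts must be >= 0")

    @property
    def counts(self) -> np.ndarray:
        return self.table["copy_count"].to_numpy(dtype=np.int64)


@dataclass(frozen=True)
class DaughterPairTable:
    """Paired daughter-cell copy counts with generation metadata."""

    table: pd.DataFrame  # columns: pair_id, n1, n2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["pair_id", "n1", "n2"]:
            raise ParameterError("daughter pair table needs columns pair_id, n1, n2")
        if ((self.table["n1"] < 0) | (self.table["n2"] < 0)).any():
            raise ParameterError("daughter copy counts must be >= 0")


def make_daughter_pairs(
    model: SegregationModel,
    n_pairs: int = 100,
    founder_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: Optional[int] = None,
) -> DaughterPairTable:
    """Simulate a table of post-mitotic daughter pairs under a model.

    Defaults mirror the imaging experiment the table stands in for: about
    100 pairs per cell line with founder copy numbers uniform on [20, 200].
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    if founder_sampler is None:
        founder_sampler = uniform_founder_sampler()
    founders = founder_sampler(rng, n_pairs)
    n1, n2 = _division_fractions(model, founders, rng)
    table = pd.DataFrame(
        {
            "pair_id": [f"pair{i:04d}" for i in range(n_pairs)],
            "n1": np.asarray(n1, dtype=np.int64),
            "n2": np.asarray(n2, dtype=np.int64),
        }
    )
    meta = {"model": model.kind, "seed": seed, "n_pairs": n_pairs}
    if model.kind == "ecdna_binomial":
        meta["p"] = model.p
    else:
        meta["u"] = model.u
    return DaughterPairTable(table, meta)


def make_fish_table(
    source: Union[CopyNumberDistribution, np.ndarray],
    n_cells: int,
    detection_efficiency: float = 1.0,
    seed: Optional[int] = None,
) -> CellCountTable:
    """Emulate an interphase FISH per-cell count table.

    Cells are sampled from ``source`` (a copy-number distribution or a raw
    per-cell count sample) and each true count is thinned binomially with
    the probe detection efficiency: ``observed ~ Binomial(true, eps)``.
    ``eps = 1`` reproduces the source distribution exactly.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    eps = float(detection_efficiency)
    if not (0.0 < eps <= 1.0):
        raise ParameterError(f"detection efficiency {eps} must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(source, CopyNumberDistribution):
        k = np.arange(source.frequencies.size)
        true = rng.choice(k, size=n_cells, p=source.frequencies)
    else:
        source = np.asarray(source, dtype=np.int64)
        if source.ndim != 1 or source.size == 0:
            raise ParameterError("source sample must be a non-empty 1-D array")
        true = rng.choice(source, size=n_cells, replace=True)
    observed = rng.binomial(true, eps) if eps < 1.0 else true
    table = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
            "copy_count": np.asarray(observed, dtype=np.int64),
        }
    )
    return CellCountTable(
        table,
        {"source": "synthetic-fish", "seed": seed, "detection_efficiency": eps},
    )


def make_ddpcr_series(
    truth: JunctionFrequencySeries,
    droplets: int = 20_000,
    copies_per_droplet: float = 0.2,
    seed: Optional[int] = None,
) -> JunctionFrequencySeries:
    """Add droplet-partition counting noise to a junction-frequency series.

    The sample is partitioned into ``droplets`` droplets.  A single-copy
    reference amplicon is loaded at ``copies_per_droplet`` mean copies per
    droplet; each target amplicon is loaded proportionally to its true
    frequency.  Positive-droplet counts are drawn from the Poisson
    partition model and concentrations recovered with the standard
    estimator ``-ln(fraction negative)``; reported frequencies are
    target/reference concentration ratios, so volume constants cancel.
    """
    if droplets < 100:
        raise ParameterError("need at least 100 droplets for a ddPCR estimate")
    if copies_per_droplet <= 0:
        raise ParameterError("copies_per_droplet must be > 0")
    rng = np.random.default_rng(seed)

    def observe(lam: float) -> float:
        """Estimated concentration of one amplicon at mean load ``lam``."""
        p_pos = 1.0 - np.exp(-lam)
        k_pos = rng.binomial(droplets, p_pos)
        if k_pos >= droplets:  # saturated assay: concentration unresolvable
            k_pos = droplets - 1
        return -np.log(1.0 - k_pos / droplets)

    ecdna_obs, scar_obs = [], []
    for ecdna, scar in zip(truth.ecdna_junction_frequency, truth.scar_frequency):
        ref = observe(copies_per_droplet)
        ecdna_obs.append(observe(ecdna * copies_per_droplet) / ref)
        scar_obs.append(observe(scar * copies_per_droplet) / ref)
    return JunctionFrequencySeries(
        np.asarray(truth.times, dtype=float),
        np.asarray(ecdna_obs),
        np.minimum(np.asarray(scar_obs), 1.0),
    )
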