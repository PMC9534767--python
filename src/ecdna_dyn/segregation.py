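"""Single-cell-division models of ecDNA and chromosomal inheritance.

At mitosis a cell with ``n`` ecDNA copies replicates them to ``2n`` and,
because ecDNA lacks centromeres, partitions them between the two daughters
by independent coin flips: daughter 1 receives ``n1 ~ Binomial(2n, p)``
copies and daughter 2 the remaining ``n2 = 2n - n1``.  ``p = 1/2`` is
unbiased random segregation; ``p != 1/2`` models biased segregation.

The chromosomal comparator (an HSR-like amplification) segregates with the
chromosome: daughters each receive ``n`` copies, except that with a small
mis-segregation probability ``u`` one daughter gains a copy at the expense
of the other (``n1 = n +/- 1``).

The inherited fraction per daughter is ``f_i = n_i / (n1 + n2)``.  Repeating
a division over many founder cells yields the expected distribution of
``f`` under each model; comparing it to observed daughter-pair counts with a
two-sample Kolmogorov-Smirnov test distinguishes random from chromosomal
segregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd

from ecdna_dyn.errors import EmptyTableError, ParameterError
from ecdna_dyn.stats import KSResult, ks_two_sample

__all__ = [
    "SegregationModel",
    "DivisionOutcome",
    "FractionDistribution",
    "divide_ecdna",
    "divide_chromosomal",
    "fraction_distribution",
    "sample_fractions",
    "compare_segregation",
    "uniform_founder_sampler",
]

#: Default founder copy-number range: discrete uniform on [20, 200] copies,
#: the span typical of oncogene amplifications observed per cell.
DEFAULT_FOUNDER_RANGE = (20, 200)

#: Default number of simulated divisions for expected-fraction histograms.
DEFAULT_N_DIVISIONS = 100_000


@dataclass(frozen=True)
class SegregationModel:
    """Parametrization of one inheritance model.

    Parameters
    ----------
    kind
        ``"ecdna_binomial"`` for random binomial segregation (parameter
        ``p``), or ``"chromosomal"`` for chromosome-like segregation
        (parameter ``u``).
    p
        Probability that a given replicated copy enters daughter 1.
        Only consulted for the binomial model.  ``p = 1/2`` is unbiased.
    u
        Mis-segregation probability per division: with probability ``u``
        one daughter receives ``n + 1`` copies and the other ``n - 1``.
        Only consulted for the chromosomal model.
    """

    kind: Literal["ecdna_binomial", "chromosomal"]
    p: float = 0.5
    u: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("ecdna_binomial", "chromosomal"):
            raise ParameterError(f"unknown segregation model kind {self.kind!r}")
        if self.kind == "ecdna_binomial" and not (0.0 < self.p < 1.0):
            raise ParameterError(f"segregation probability p={self.p} must lie in (0, 1)")
        if self.kind == "chromosomal" and not (0.0 <= self.u <= 1.0):
            raise ParameterError(f"mis-segregation probability u={self.u} must lie in [0, 1]")


@dataclass(frozen=True)
class DivisionOutcome:
    """Copy counts and inherited fractions of the two daughters of one division."""

    n1: int
    n2: int

    @property
    def f1(self) -> float:
        total = self.n1 + self.n2
        return self.n1 / total if total > 0 else 0.0

    @property
    def f2(self) -> float:
        total = self.n1 + self.n2
        return self.n2 / total if total > 0 else 0.0


@dataclass(frozen=True)
class FractionDistribution:
    """Binned distribution of inherited fractions from simulated divisions."""

    bin_edges: np.ndarray
    bin_masses: np.ndarray
    n_divisions: int
    model: SegregationModel

    def __post_init__(self) -> None:
        total = float(np.sum(self.bin_masses))
        if not np.isclose(total, 1.0):
            raise ParameterError(f"bin masses must sum to 1, got {total}")

    @property
    def mean(self) -> float:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(np.sum(centers * self.bin_masses))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mass": self.bin_masses,
            }
        )


def divide_ecdna(n: int, p: float, rng: np.random.Generator) -> DivisionOutcome:
    """Perform one random-segregation division of a cell with ``n`` ecDNA copies.

    Copies are replicated to ``2n`` and each independently enters daughter 1
    with probability ``p``; a cell with no ecDNA produces two ecDNA-free
    daughters.
    """
    if not (0.0 < p < 1.0):
        raise ParameterError(f"segregation probability p={p} must lie in (0, 1)")
    if n < 0:
        raise ParameterError(f"copy number n={n} must be >= 0")
    if n == 0:
        return DivisionOutcome(0, 0)
    n1 = int(rng.binomial(2 * n, p))
    return DivisionOutcome(n1, 2 * n - n1)


def divide_chromosomal(n: int, u: float, rng: np.random.Generator) -> DivisionOutcome:
    """Perform one chromosomal division: exact 50:50 split, or ``n +/- 1``.

    With probability ``1 - u`` each daughter receives exactly ``n`` copies.
    With probability ``u`` a mis-segregation occurs and daughter 1 receives
    ``n + 1`` or ``n - 1`` copies (each direction equally likely), daughter 2
    the complement ``2n - n1``.
    """
    if not (0.0 <= u <= 1.0):
        raise ParameterError(f"mis-segregation probability u={u} must lie in [0, 1]")
    if n < 1:
        raise ParameterError("chromosomal copy number must be >= 1")
    if rng.random() < u:
        n1 = n + 1 if rng.random() < 0.5 else n - 1
    else:
        n1 = n
    return DivisionOutcome(n1, 2 * n - n1)


def uniform_founder_sampler(
    low: int = DEFAULT_FOUNDER_RANGE[0], high: int = DEFAULT_FOUNDER_RANGE[1]
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Return a sampler of founder copy numbers, discrete uniform on [low, high]."""
    if high < low or low < 0:
        raise ParameterError(f"degenerate founder range [{low}, {high}]")
    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.integers(low, high + 1, size=size)
    return sample


def _division_fractions(
    model: SegregationModel,
    founders: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized divisions for an array of founder copy numbers -> (n1, n2)."""
    founders = np.asarray(founders, dtype=np.int64)
    if model.kind == "ecdna_binomial":
        n1 = rng.binomial(2 * founders, model.p)
    else:
        if np.any(founders < 1):
            raise ParameterError("chromosomal founders must be >= 1")
        mis = rng.random(founders.shape) < model.u
        direction = rng.integers(0, 2, size=founders.shape) * 2 - 1
        n1 = founders + mis * direction
    return n1, 2 * founders - n1


def sample_fractions(
    model: SegregationModel,
    n_divisions: int,
    founder_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate divisions and return the pooled inherited fractions.

    Both daughters of every division contribute, so the returned sample of
    size ``2 * n_divisions`` is symmetric about 1/2 by construction (the
    observed daughter-pair histograms are paired in the same way).
    """
    if n_divisions < 1:
        raise ParameterError("n_divisions must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if founder_sampler is None:
        founder_sampler = uniform_founder_sampler()
    founders = founder_sampler(rng, n_divisions)
    if np.all(founders == founders.flat[0]) and n_divisions > 1 and founders.flat[0] == 0:
        raise ParameterError("founder sampler produced only zero-copy founders")
    n1, n2 = _division_fractions(model, founders, rng)
    total = n1 + n2
    keep = total > 0
    f1 = n1[keep] / total[keep]
    return np.concatenate([f1, 1.0 - f1])


def fraction_distribution(
    model: SegregationModel,
    n_divisions: int = DEFAULT_N_DIVISIONS,
    founder_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: Optional[int] = None,
    n_bins: int = 50,
) -> FractionDistribution:
    """Expected distribution of inherited fractions under a segregation model.

    For each of ``n_divisions`` divisions a founder copy number is sampled
    (default: discrete uniform on [20, 200]), the division is simulated, and
    both daughters' fractions are recorded into ``n_bins`` equal bins on
    [0, 1].
    """
    fractions = sample_fractions(model, n_divisions, founder_sampler, seed=seed)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(fractions, bins=edges)
    masses = counts / counts.sum()
    return FractionDistribution(edges, masses, n_divisions, model)


def observed_fractions(pairs: pd.DataFrame, warn_on_exclusion: bool = True) -> np.ndarray:
    """Pooled inherited fractions from a daughter-pair table (columns n1, n2).

    Pairs with no signal in either daughter (``n1 + n2 == 0``) carry no
    information about the split and are excluded with a warning.
    """
    if len(pairs) == 0:
        raise EmptyTableError("daughter-pair table has no rows")
    n1 = pairs["n1"].to_numpy(dtype=float)
    n2 = pairs["n2"].to_numpy(dtype=float)
    total = n1 + n2
    zero = total == 0
    if zero.any():
        if warn_on_exclusion:
            warnings.warn(
                f"excluding {int(zero.sum())} daughter pair(s) with zero total signal",
                stacklevel=2,
            )
        n1, n2, total = n1[~zero], n2[~zero], total[~zero]
    f1 = n1 / total
    return np.concatenate([f1, n2 / total])


def compare_segregation(
    observed: pd.DataFrame,
    model: SegregationModel,
    n_null: int = 10_000,
    seed: Optional[int] = None,
    founder_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
) -> KSResult:
    """Two-sample KS test of observed daughter-pair fractions against a model.

    ``n_null`` divisions are simulated under ``model`` to build the expected
    fraction sample; the statistic compares its ECDF with the ECDF of the
    pooled observed fractions.
    """
    if len(observed) < 2:
        raise EmptyTableError("need at least 2 daughter pairs to compare")
    obs = observed_fractions(observed)
    null = sample_fractions(model, n_null, founder_sampler, seed=seed)
    return ks_two_sample(obs, null)
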