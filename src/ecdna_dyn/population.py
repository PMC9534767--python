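"""Individual-based stochastic simulation of ecDNA population dynamics.

An exponentially growing population is modelled as a pure birth process.
Each cell carries an integer number ``k`` of ecDNA copies.  Cells without
ecDNA divide at rate ``r- = 1`` (time is measured in generations of
ecDNA-free cells); cells with at least one copy divide at rate ``r+ = s``,
so ``s`` is the selection coefficient (``s = 1`` neutral, ``s > 1`` positive,
``0 < s < 1`` negative selection).  At division the ``k`` copies are
replicated to ``2k`` and partitioned binomially ``Binomial(2k, 1/2)``
between the daughters; a cell with no ecDNA produces two ecDNA-free
daughters.  There is no cell death and no carrying capacity.

Two hallmark behaviours emerge.  Under neutral dynamics the mean copy
number is a martingale (it stays at its founder value in expectation) while
the fraction of ecDNA+ cells decays toward zero like ``~1/t``; under
positive selection the ecDNA+ fraction approaches one and the mean copy
number keeps growing with population size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ecdna_dyn import _core
from ecdna_dyn.errors import NotEstimableError, ParameterError

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "CopyNumberDistribution",
    "MomentSeries",
    "PopulationSummary",
    "CellPopulation",
    "run_gillespie",
    "select_dividing_cell",
    "summarize",
    "tail_exponent",
]

_SEED_MOD = 2**32


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one stochastic growth simulation.

    Parameters
    ----------
    n0
        ecDNA copy number of the single founder cell.
    s
        Selection coefficient: division rate of ecDNA+ cells relative to
        the unit rate of ecDNA-free cells.
    n_target
        Population size at which the simulation terminates.
    seed
        Master seed; replicate ``r`` of a batch derives its stream from
        ``seed + r``.
    snapshot_sizes
        Population sizes at which intermediate states are recorded (the
        final state is always recorded).
    """

    n0: int
    s: float = 1.0
    n_target: int = 10_000
    seed: Optional[int] = None
    snapshot_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ParameterError(f"founder copy number n0={self.n0} must be >= 0")
        if self.s <= 0:
            raise ParameterError(f"selection coefficient s={self.s} must be > 0")
        if self.n_target < 1:
            raise ParameterError(f"n_target={self.n_target} must be >= 1")


@dataclass(frozen=True)
class PopulationState:
    """Snapshot of the population: cells per copy-number class at time ``t``."""

    class_counts: np.ndarray  # class_counts[k] = number of cells with k copies
    t: float

    @classmethod
    def from_cells(cls, cells: np.ndarray, t: float) -> "PopulationState":
        return cls(np.bincount(np.asarray(cells, dtype=np.int64)), float(t))

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    @property
    def n_positive(self) -> int:
        return int(self.class_counts[1:].sum())


@dataclass(frozen=True)
class CopyNumberDistribution:
    """Normalized per-cell copy-number distribution ``q_k``."""

    frequencies: np.ndarray  # frequencies[k] = fraction of cells with k copies
    sample_size: int

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ParameterError("empty population has no copy-number distribution")
        assert np.all(self.frequencies >= 0)
        assert np.isclose(self.frequencies.sum(), 1.0)

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "CopyNumberDistribution":
        counts = np.asarray(counts, dtype=np.int64)
        total = int(counts.sum())
        if total < 1:
            raise ParameterError("empty population has no copy-number distribution")
        return cls(counts / total, total)

    @classmethod
    def from_cells(cls, cells: np.ndarray) -> "CopyNumberDistribution":
        return cls.from_counts(np.bincount(np.asarray(cells, dtype=np.int64)))


@dataclass(frozen=True)
class MomentSeries:
    """Time series of copy-number summary statistics along a trajectory."""

    times: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    variance: np.ndarray
    frac_pos: np.ndarray
    shannon: np.ndarray


@dataclass(frozen=True)
class PopulationSummary:
    """Copy-number distribution and its moment summaries for one state."""

    distribution: CopyNumberDistribution
    m1: float
    m2: float
    variance: float
    frac_pos: float
    shannon: float


class CellPopulation:
    """Mutable simulation engine holding per-cell copy numbers.

    Wraps the compiled event loop with capacity management, a reproducible
    seed stream, and helpers used by the scenario layer (advance to a time
    horizon, dilute back to a smaller size as in cell-culture passaging).
    ``flags`` is a heritable binary marker (both daughters always inherit
    it) used to track the chromosomal scar in CRISPR-C experiments.
    """

    def __init__(
        self,
        cells: Sequence[int],
        s: float = 1.0,
        seed: Optional[int] = None,
        flags: Optional[Sequence[int]] = None,
        capacity: Optional[int] = None,
    ) -> None:
        if s <= 0:
            raise ParameterError(f"selection coefficient s={s} must be > 0")
        start = np.asarray(cells, dtype=np.int64)
        if start.ndim != 1 or start.size == 0:
            raise ParameterError("initial population must be a non-empty 1-D array")
        if np.any(start < 0):
            raise ParameterError("copy numbers must be non-negative")
        self.s = float(s)
        self._rng = np.random.default_rng(seed)
        cap = max(int(capacity or 0), 2 * start.size)
        self._cells = np.zeros(cap, dtype=np.int64)
        self._cells[: start.size] = start
        self._flags = np.zeros(cap, dtype=np.int8)
        if flags is not None:
            fl = np.asarray(flags, dtype=np.int8)
            if fl.shape != start.shape:
                raise ParameterError("flags must match the initial cells in length")
            self._flags[: start.size] = fl
        self.n = int(start.size)
        self.n_pos = int(np.count_nonzero(start))
        self.t = 0.0

    # -- views -------------------------------------------------------------
    @property
    def cells(self) -> np.ndarray:
        return self._cells[: self.n]

    @property
    def flags(self) -> np.ndarray:
        return self._flags[: self.n]

    @property
    def frac_pos(self) -> float:
        return self.n_pos / self.n

    @property
    def flag_frequency(self) -> float:
        return float(np.mean(self._flags[: self.n]))

    def state(self) -> PopulationState:
        return PopulationState.from_cells(self.cells, self.t)

    # -- evolution ---------------------------------------------------------
    def _ensure_capacity(self, needed: int) -> None:
        if needed > self._cells.size:
            new = np.zeros(needed, dtype=np.int64)
            new[: self.n] = self._cells[: self.n]
            self._cells = new
            newf = np.zeros(needed, dtype=np.int8)
            newf[: self.n] = self._flags[: self.n]
            self._flags = newf

    def advance(self, stop_n: Optional[int] = None, stop_t: Optional[float] = None) -> int:
        """Run the birth process until size ``stop_n`` or time ``stop_t``."""
        if stop_n is None and stop_t is None:
            raise ParameterError("need a size or time stopping condition")
        size_cap = int(stop_n) if stop_n is not None else None
        t_cap = float(stop_t) if stop_t is not None else np.inf
        if size_cap is not None and size_cap < self.n:
            raise ParameterError(
                f"stop_n={size_cap} is below the current population size {self.n}"
            )
        if size_cap is None:
            # pure time horizon: grow capacity in chunks as needed
            size_cap = self.n
            while True:
                size_cap = max(size_cap * 4, 1024)
                self._ensure_capacity(size_cap)
                status = self._advance_once(size_cap, t_cap)
                if status == _core.REACHED_TIME:
                    return status
        self._ensure_capacity(size_cap)
        return self._advance_once(size_cap, t_cap)

    def _advance_once(self, stop_n: int, stop_t: float) -> int:
        seed = int(self._rng.integers(0, _SEED_MOD))
        self.n, self.n_pos, self.t, status = _core.advance(
            self._cells, self._flags, self.n, self.n_pos, self.t,
            self.s, stop_n, stop_t, seed,
        )
        return int(status)

    def dilute_to(self, size: int) -> None:
        """Uniformly subsample the population down to ``size`` cells.

        Models culture passaging: a random subset of cells is carried over,
        which preserves all class frequencies in expectation.
        """
        if size < 1 or size > self.n:
            raise ParameterError(f"dilution size {size} not in [1, {self.n}]")
        idx = self._rng.choice(self.n, size=size, replace=False)
        self._cells[:size] = self._cells[idx]
        self._flags[:size] = self._flags[idx]
        self.n = size
        self.n_pos = int(np.count_nonzero(self._cells[:size]))


def run_gillespie(config: SimulationConfig) -> list[PopulationState]:
    """Simulate one trajectory from a single founder cell.

    Returns the recorded states: one per requested snapshot size plus the
    terminal state at ``n_target``.
    """
    if config.n_target < 1:
        raise ParameterError("n_target must be >= 1")
    pop = CellPopulation([config.n0], s=config.s, seed=config.seed,
                         capacity=config.n_target)
    sizes = sorted(set(int(x) for x in config.snapshot_sizes) | {config.n_target})
    if sizes[0] < 1 or sizes[-1] > config.n_target:
        raise ParameterError("snapshot sizes must lie in [1, n_target]")
    out: list[PopulationState] = []
    for size in sizes:
        pop.advance(stop_n=size)
        out.append(pop.state())
    return out


def select_dividing_cell(
    state: PopulationState, s: float, rng: np.random.Generator
) -> int:
    """Draw the copy-number class of the next dividing cell.

    A cell is proposed uniformly at random and accepted with probability
    ``rate(k) / max_rate`` (rejection sampling), which selects cells
    proportional to fitness without enumerating classes.  Returns the copy
    number ``k`` of the accepted cell's class.
    """
    counts = np.asarray(state.class_counts, dtype=np.int64)
    n = int(counts.sum())
    if n < 1:
        raise ParameterError("cannot select from an empty population")
    if s <= 0:
        raise ParameterError("selection coefficient must be > 0")
    max_rate = max(1.0, s)
    cum = np.cumsum(counts)
    while True:
        cell = rng.integers(0, n)
        k = int(np.searchsorted(cum, cell, side="right"))
        rate = s if k > 0 else 1.0
        if rng.random() * max_rate < rate:
            return k


def summarize(state: PopulationState) -> PopulationSummary:
    """Distribution and moment summaries of a population snapshot.

    Reports ``q_k = N_k / N``, the raw moments ``M1 = sum k q_k`` and
    ``M2 = sum k^2 q_k``, the variance, the ecDNA+ fraction ``1 - q_0``,
    and the Shannon diversity index ``-sum q_k ln q_k``.
    """
    dist = CopyNumberDistribution.from_counts(state.class_counts)
    q = dist.frequencies
    k = np.arange(q.size)
    m1 = float(np.sum(k * q))
    m2 = float(np.sum(k * k * q))
    pos = q[q > 0]
    return PopulationSummary(
        distribution=dist,
        m1=m1,
        m2=m2,
        variance=max(m2 - m1 * m1, 0.0),
        frac_pos=float(1.0 - q[0]) if q.size > 0 else 0.0,
        shannon=float(-np.sum(pos * np.log(pos))),
    )


def tail_exponent(
    dist: CopyNumberDistribution,
    tail_fraction: float = 0.1,
    min_exceedances: float = 10.0,
) -> float:
    """Power-law exponent of the distribution's upper tail.

    Fits a least-squares line to ``log CCDF`` vs ``log k`` over the upper
    ``tail_fraction`` of the reliably estimated copy-number range and
    returns the slope.  For an empirical distribution the CCDF is only
    trustworthy where at least ``min_exceedances`` cells are expected above
    ``k``; sparser classes are excluded before the window is chosen, since
    single-cell noise at the extreme tail otherwise dominates the fit.  A
    genuinely power-law tail gives a stable slope; faster-decaying tails
    give increasingly negative slopes as the window shrinks.
    """
    if not (0 < tail_fraction <= 1):
        raise ParameterError("tail_fraction must lie in (0, 1]")
    q = dist.frequencies
    k = np.arange(q.size)
    ccdf = 1.0 - np.cumsum(q)  # P(K > k)
    floor = min_exceedances / dist.sample_size
    reliable = k[(q > 0) & (ccdf >= floor) & (k >= 1)]
    if reliable.size == 0:
        raise NotEstimableError("no reliably estimated tail classes")
    k_hi = reliable[-1]
    k_lo = max(k_hi * (1.0 - tail_fraction), 1.0)
    window = reliable[reliable >= k_lo]
    if window.size < 10:
        raise NotEstimableError(
            "need >= 10 populated copy-number classes in the tail to fit a slope"
        )
    slope = np.polyfit(np.log(window), np.log(ccdf[window]), 1)[0]
    return float(slope)
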