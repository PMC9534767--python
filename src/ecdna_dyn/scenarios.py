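"""End-to-end in-silico experiments built on the stochastic simulator.

Three experiment templates are provided:

- :func:`run_crispr_c` -- CRISPR-C induction of a defined single-copy ecDNA
  in a fraction of founder cells (with an independently inherited
  chromosomal "scar" marker), followed by growth under a piecewise-constant
  selection schedule.  Mirrors a DHFR-ecDNA induction experiment where
  methotrexate turns selection from negative/neutral to strongly positive,
  read out as ddPCR junction frequencies.
- :func:`run_cellline` -- a cell-line stand-in: one founder carrying the
  line's mean copy number grown to a target size; the terminal per-cell
  distribution is what FISH count tables are compared against.
- :func:`run_drug_shift` -- drug adaptation logic: negative selection on
  ecDNA+ cells shifts the copy-number distribution down within a few
  generations, and the shift reverses after drug withdrawal.

Cultures cannot grow unboundedly, so between recording points the
population is passaged: whenever it reaches a cap it is uniformly diluted
back to the founder size, which preserves all class frequencies in
expectation while keeping the simulation at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ecdna_dyn.errors import ParameterError
from ecdna_dyn.population import (
    CellPopulation,
    CopyNumberDistribution,
    MomentSeries,
    SimulationConfig,
    run_gillespie,
    summarize,
)

__all__ = [
    "SelectionSchedule",
    "CrisprCConfig",
    "JunctionFrequencySeries",
    "CrisprCResult",
    "run_crispr_c",
    "run_cellline",
    "run_drug_shift",
]


@dataclass(frozen=True)
class SelectionSchedule:
    """Piecewise-constant selection coefficient ``s(t)``.

    ``segments`` is an ordered tuple of ``(t_start, t_end, s)`` covering
    ``[0, duration]`` without gaps or overlaps.  Time is measured in
    generations of ecDNA-free cells; a day of culture is mapped to one
    generation by convention.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ParameterError("schedule needs at least one segment")
        prev_end = 0.0
        for t0, t1, s in self.segments:
            if not np.isclose(t0, prev_end):
                raise ParameterError(f"segment starting at {t0} leaves a gap/overlap")
            if t1 <= t0:
                raise ParameterError(f"segment ({t0}, {t1}) has non-positive length")
            if s <= 0:
                raise ParameterError(f"selection coefficient s={s} must be > 0")
            prev_end = t1

    @classmethod
    def from_durations(cls, phases: Sequence[tuple[float, float]]) -> "SelectionSchedule":
        """Build a schedule from ``(duration, s)`` phases starting at t=0."""
        segments, t = [], 0.0
        for duration, s in phases:
            segments.append((t, t + float(duration), float(s)))
            t += float(duration)
        return cls(tuple(segments))

    @property
    def duration(self) -> float:
        return self.segments[-1][1]

    def s_at(self, t: float) -> float:
        for t0, t1, s in self.segments:
            if t0 <= t < t1:
                return s
        if np.isclose(t, self.duration):
            return self.segments[-1][2]
        raise ParameterError(f"t={t} outside schedule [0, {self.duration}]")


@dataclass(frozen=True)
class CrisprCConfig:
    """CRISPR-C induction experiment configuration.

    After induction a fraction ``q_ecdna`` of founder cells carries exactly
    one ecDNA copy; an independent fraction ``q_scar`` carries the
    chromosomal scar left at the religated cut site.  The scar segregates
    with the chromosome (both daughters inherit it) and is selectively
    neutral, providing the control readout.
    """

    n0: int = 10_000
    q_ecdna: float = 0.15
    q_scar: float = 0.15
    schedule: SelectionSchedule = field(
        default_factory=lambda: SelectionSchedule.from_durations([(4.0, 0.5), (14.0, 1.0)])
    )
    seed: Optional[int] = None
    dilution_factor: int = 4
    record_dt: float = 0.5

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ParameterError("founder population must have >= 1 cell")
        for name, q in (("q_ecdna", self.q_ecdna), ("q_scar", self.q_scar)):
            if not (0.0 <= q <= 1.0):
                raise ParameterError(f"{name}={q} must lie in [0, 1]")
        if self.dilution_factor < 2:
            raise ParameterError("dilution_factor must be >= 2")
        if self.record_dt <= 0:
            raise ParameterError("record_dt must be > 0")


@dataclass(frozen=True)
class JunctionFrequencySeries:
    """ddPCR-style readout: junction frequencies per genome equivalent.

    ``ecdna_junction_frequency`` is the mean number of ecDNA junctions per
    cell (equal to the mean copy number, since each ecDNA carries one
    junction); ``scar_frequency`` is the fraction of cells carrying the
    chromosomal scar.  Both are concentrations normalized to a single-copy
    reference amplicon.
    """

    times: np.ndarray
    ecdna_junction_frequency: np.ndarray
    scar_frequency: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.ecdna_junction_frequency) == len(self.scar_frequency)):
            raise ParameterError("series arrays must have equal length")
        if np.any(np.asarray(self.ecdna_junction_frequency) < 0):
            raise ParameterError("frequencies must be >= 0")
        if np.any((np.asarray(self.scar_frequency) < 0) | (np.asarray(self.scar_frequency) > 1)):
            raise ParameterError("scar frequency must lie in [0, 1]")


@dataclass(frozen=True)
class CrisprCResult:
    series: JunctionFrequencySeries
    moments: MomentSeries


def _evolve_with_schedule(
    pop: CellPopulation,
    schedule: SelectionSchedule,
    record_dt: float,
    n_floor: int,
    n_cap: int,
) -> list[tuple[float, np.ndarray, float]]:
    """Advance a population through a schedule, passaging at ``n_cap``.

    Returns records ``(t, class_counts, scar_frequency)`` on a regular time
    grid including t=0 and every segment boundary.
    """
    grid = set(np.arange(0.0, schedule.duration + 1e-9, record_dt))
    grid |= {t1 for _t0, t1, _s in schedule.segments}
    records = [(0.0, np.bincount(pop.cells), pop.flag_frequency)]
    for t_rec in sorted(t for t in grid if t > 0):
        pop.s = schedule.s_at(t_rec - 1e-9)
        while pop.t < t_rec - 1e-12:
            status = pop.advance(stop_n=n_cap, stop_t=t_rec)
            if status == 1 and pop.t < t_rec - 1e-12:  # hit the cap: passage
                pop.dilute_to(n_floor)
        records.append((t_rec, np.bincount(pop.cells), pop.flag_frequency))
    return records


def _records_to_result(records: list[tuple[float, np.ndarray, float]]) -> CrisprCResult:
    times = np.array([r[0] for r in records])
    m1, m2, var, frac_pos, shannon, scar = [], [], [], [], [], []
    from ecdna_dyn.population import PopulationState

    for t, counts, scar_freq in records:
        summ = summarize(PopulationState(counts, t))
        m1.append(summ.m1)
        m2.append(summ.m2)
        var.append(summ.variance)
        frac_pos.append(summ.frac_pos)
        shannon.append(summ.shannon)
        scar.append(scar_freq)
    moments = MomentSeries(times, np.array(m1), np.array(m2), np.array(var),
                           np.array(frac_pos), np.array(shannon))
    series = JunctionFrequencySeries(times, np.array(m1), np.array(scar))
    return CrisprCResult(series, moments)


def run_crispr_c(config: CrisprCConfig) -> CrisprCResult:
    """Simulate ecDNA induction and growth under a selection schedule.

    Founders receive ecDNA (exactly one copy) and the scar marker by
    independent Bernoulli draws.  ecDNA+ cells divide at the schedule's
    current ``s``; scar status never affects rates and is inherited by both
    daughters.  Outputs the junction-frequency time course (mean copy
    number and scar fraction) and the moment series.
    """
    rng = np.random.default_rng(config.seed)
    cells = (rng.random(config.n0) < config.q_ecdna).astype(np.int64)
    flags = (rng.random(config.n0) < config.q_scar).astype(np.int8)
    pop = CellPopulation(
        cells,
        s=config.schedule.s_at(0.0),
        seed=int(rng.integers(0, 2**32)),
        flags=flags,
        capacity=config.dilution_factor * config.n0 + 1,
    )
    records = _evolve_with_schedule(
        pop, config.schedule, config.record_dt,
        n_floor=config.n0, n_cap=config.dilution_factor * config.n0,
    )
    return _records_to_result(records)


def run_cellline(
    k_mean: int,
    s: float = 1.0,
    n_target: int = 1_000_000,
    seed: Optional[int] = None,
) -> CopyNumberDistribution:
    """Grow a cell-line stand-in from one founder with ``k_mean`` copies.

    The founder carries the cell line's mean ecDNA copy number; the
    population grows to ``n_target`` cells and the terminal per-cell
    copy-number distribution is returned.  Under neutrality its mean stays
    near ``k_mean`` while the distribution becomes extremely wide: many
    low-copy cells coexist with a few cells carrying hundreds of copies.
    """
    if k_mean < 1:
        raise ParameterError("k_mean must be >= 1")
    states = run_gillespie(
        SimulationConfig(n0=k_mean, s=s, n_target=n_target, seed=seed)
    )
    return CopyNumberDistribution.from_counts(states[-1].class_counts)


def run_drug_shift(
    founder_copies: int = 4,
    n_burn_in: int = 1000,
    s_drug: float = 0.5,
    s_off: float = 2.0,
    t_drug: float = 7.0,
    t_off: float = 7.0,
    seed: Optional[int] = None,
    record_dt: float = 0.5,
    dilution_factor: int = 4,
) -> MomentSeries:
    """Drug challenge followed by withdrawal, tracking copy-number moments.

    A heterogeneous population is first grown neutrally from one founder
    with ``founder_copies`` ecDNA copies to ``n_burn_in`` cells.  During the
    drug phase ecDNA+ cells divide at ``s_drug`` (typically < 1: the drug
    penalizes the amplified oncogene), then at ``s_off`` after withdrawal
    (> 1 when the oncogene is growth-promoting).  Time in the returned
    series is measured from the start of the drug phase.

    Selection acts on ecDNA presence, so the population-level shift is
    carried by the balance between the ecDNA+ and ecDNA-free compartments;
    the default founder copy number is kept low so the neutral burn-in
    leaves an appreciable ecDNA-free reservoir for the drug phase to expand.
    """
    if founder_copies < 1 or n_burn_in < 2:
        raise ParameterError("need founder_copies >= 1 and n_burn_in >= 2")
    rng = np.random.default_rng(seed)
    burn = CellPopulation([founder_copies], s=1.0, seed=int(rng.integers(0, 2**32)),
                          capacity=n_burn_in)
    burn.advance(stop_n=n_burn_in)
    pop = CellPopulation(
        burn.cells.copy(), s=s_drug, seed=int(rng.integers(0, 2**32)),
        capacity=dilution_factor * n_burn_in + 1,
    )
    schedule = SelectionSchedule.from_durations([(t_drug, s_drug), (t_off, s_off)])
    records = _evolve_with_schedule(
        pop, schedule, record_dt, n_floor=n_burn_in, n_cap=dilution_factor * n_burn_in
    )
    return _records_to_result(records).moments
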