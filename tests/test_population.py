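"""Individual-based simulator: bookkeeping, martingale and selection checks."""

import numpy as np
import pytest

from ecdna_dyn import (
    CopyNumberDistribution,
    PopulationState,
    SimulationConfig,
    run_gillespie,
    select_dividing_cell,
    summarize,
    tail_exponent,
)
from ecdna_dyn.errors import NotEstimableError, ParameterError
from ecdna_dyn.population import CellPopulation


class TestRunGillespie:
    def test_no_ecdna_stays_ecdna_free(self):
        states = run_gillespie(SimulationConfig(n0=0, s=3.0, n_target=500, seed=1))
        final = states[-1]
        assert final.n == 500 and final.n_positive == 0

    def test_every_event_adds_one_cell(self):
        states = run_gillespie(
            SimulationConfig(n0=4, s=1.0, n_target=256, seed=2, snapshot_sizes=(2, 16, 64))
        )
        assert [s.n for s in states] == [2, 16, 64, 256]
        assert all(a.t <= b.t for a, b in zip(states, states[1:]))

    def test_neutral_martingale_mean_copy_number(self):
        """E[mean copy number] stays at the founder value under s = 1."""
        means = []
        for r in range(200):
            state = run_gillespie(
                SimulationConfig(n0=1, s=1.0, n_target=2000, seed=1000 + r)
            )[-1]
            means.append(summarize(state).m1)
        means = np.array(means)
        sem = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 1.0) <= 3 * sem

    def test_positive_selection_beats_neutral(self):
        def frac_pos(s, seed):
            state = run_gillespie(
                SimulationConfig(n0=1, s=s, n_target=50_000, seed=seed)
            )[-1]
            return summarize(state).frac_pos

        fp_neutral = np.mean([frac_pos(1.0, 50 + r) for r in range(5)])
        fp_selected = np.mean([frac_pos(2.0, 60 + r) for r in range(5)])
        assert fp_selected > fp_neutral

    def test_mean_copy_number_grows_with_size_under_selection(self):
        m1s = []
        for n_target in (1000, 10_000, 100_000):
            vals = [
                summarize(
                    run_gillespie(
                        SimulationConfig(n0=1, s=2.0, n_target=n_target, seed=70 + r)
                    )[-1]
                ).m1
                for r in range(5)
            ]
            m1s.append(np.mean(vals))
        assert m1s[0] < m1s[1] < m1s[2]

    def test_neutral_extinction_with_population_size(self):
        """The ecDNA+ fraction declines in larger neutral populations."""
        fps = []
        for n_target in (500, 5000, 50_000):
            vals = [
                summarize(
                    run_gillespie(
                        SimulationConfig(n0=1, s=1.0, n_target=n_target, seed=90 + r)
                    )[-1]
                ).frac_pos
                for r in range(30)
            ]
            fps.append(np.mean(vals))
        assert fps[0] > fps[1] > fps[2]

    def test_selection_monotonicity_in_s(self):
        means = []
        for s in (1.0, 1.5, 2.0, 4.0):
            vals = [
                summarize(
                    run_gillespie(
                        SimulationConfig(n0=1, s=s, n_target=100_000, seed=200 + r)
                    )[-1]
                ).m1
                for r in range(3)
            ]
            means.append(np.mean(vals))
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_bad_config_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(n0=-1)
        with pytest.raises(ParameterError):
            SimulationConfig(n0=1, s=0.0)
        with pytest.raises(ParameterError):
            SimulationConfig(n0=1, n_target=0)


class TestSelectDividingCell:
    def test_single_class_always_selected(self, rng):
        state = PopulationState(np.array([0, 0, 0, 7]), 0.0)
        assert all(select_dividing_cell(state, 2.0, rng) == 3 for _ in range(20))

    def test_two_class_fitness_ratio(self, rng):
        """N_0=100, N_5=100 at s=2: the ecDNA+ class divides 2/3 of the time."""
        counts = np.zeros(6, dtype=int)
        counts[0] = 100
        counts[5] = 100
        state = PopulationState(counts, 0.0)
        draws = np.array([select_dividing_cell(state, 2.0, rng) for _ in range(20_000)])
        p5 = np.mean(draws == 5)
        assert abs(p5 - 2 / 3) < 3 * np.sqrt((2 / 3) * (1 / 3) / draws.size)

    def test_neutral_selection_is_uniform(self, rng):
        counts = np.array([300, 100, 0, 100])
        state = PopulationState(counts, 0.0)
        draws = np.array([select_dividing_cell(state, 1.0, rng) for _ in range(30_000)])
        freqs = np.bincount(draws, minlength=4) / draws.size
        assert np.allclose(freqs, counts / counts.sum(), atol=0.015)


class TestSummarize:
    def test_single_class(self):
        state = PopulationState(np.array([0, 0, 0, 10]), 1.0)
        s = summarize(state)
        assert (s.m1, s.m2, s.variance, s.frac_pos, s.shannon) == (3, 9, 0, 1, 0)

    def test_two_equal_classes(self):
        s = summarize(PopulationState(np.array([50, 50]), 0.0))
        assert s.m1 == 0.5 and s.frac_pos == 0.5
        assert s.shannon == pytest.approx(np.log(2))

    def test_empty_state_rejected(self):
        with pytest.raises(ParameterError):
            summarize(PopulationState(np.array([0, 0]), 0.0))

    def test_neutral_variance_tracks_linear_growth(self):
        """Var(k) ~ t * M1 - M1^2 from the deterministic moment law."""
        t_stop = 4.0
        rng = np.random.default_rng(77)
        n_sum = 0
        k_sum = 0.0
        k2_sum = 0.0
        for _ in range(3000):
            pop = CellPopulation([1], s=1.0, seed=int(rng.integers(0, 2**31)))
            pop.advance(stop_t=t_stop)
            cells = pop.cells
            n_sum += cells.size
            k_sum += cells.sum()
            k2_sum += (cells.astype(float) ** 2).sum()
        m1 = k_sum / n_sum
        m2 = k2_sum / n_sum
        # M2(t) = M2(0) + t with M2(0) = 1 for a single-copy founder
        expected_var = 1.0 + t_stop - m1**2
        assert abs((m2 - m1**2) - expected_var) / expected_var < 0.15


class TestTailExponent:
    def test_recovers_power_law_slope(self, rng):
        """Inverse-CDF sampling from CCDF ~ k^-2 is recovered within 5%."""
        k = np.arange(1, 2001)
        ccdf = k**-2.0
        pmf = np.concatenate([[0.0], -np.diff(np.concatenate([[1.0], ccdf]))])
        pmf = np.concatenate([[0.0], pmf[1:] / pmf[1:].sum()])
        draws = rng.choice(np.arange(pmf.size), size=1_000_000, p=pmf)
        dist = CopyNumberDistribution.from_counts(np.bincount(draws))
        slope = tail_exponent(dist, tail_fraction=0.9)
        assert abs(slope - (-2.0)) / 2.0 < 0.05

    def test_geometric_tail_steepens_as_window_shrinks(self):
        k = np.arange(0, 400)
        pmf = 0.97**k
        pmf /= pmf.sum()
        counts = np.rint(pmf * 10_000_000).astype(int)
        dist = CopyNumberDistribution.from_counts(counts)
        wide = tail_exponent(dist, tail_fraction=0.5)
        narrow = tail_exponent(dist, tail_fraction=0.1)
        assert narrow < wide < 0

    def test_single_class_not_estimable(self):
        dist = CopyNumberDistribution.from_counts(np.array([0, 0, 100]))
        with pytest.raises(NotEstimableError):
            tail_exponent(dist)
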