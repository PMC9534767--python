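"""Deterministic description of ecDNA copy-number dynamics.

Let ``rho_k(t)`` be the fraction of cells carrying ``k`` ecDNA copies in an
exponentially growing population with unbiased binomial segregation.  In the
neutral case (all cells divide at rate 1) the density obeys the master
equation::

    d rho_k / dt = -2 rho_k + 2 * sum_{i >= ceil(k/2)} rho_i C(2i, k) 2^(-2i)

The redistribution kernel is the ``Binomial(2i, 1/2)`` mass a daughter
receives from a parent with ``i`` copies.  The dynamics conserve total
density and the first moment (the neutral mean copy number is a martingale),
while the second moment grows linearly: ``dM2/dt = M1``.  All higher
moments scale as ``M^(l)(t) ~ t^(l-1)`` at late times, and the ecDNA+
fraction decays as ``f+(t) = 2 / (2 + t)``.

With selection (ecDNA+ cells divide at rate ``s``, ecDNA-free cells at rate
1) the normalized density picks up bilinear coupling terms::

    d rho_k / dt |_(k>0) = s * (neutral rhs) + (s - 1) rho_0 rho_k
    d rho_0 / dt         = s * (neutral rhs) - (s - 1) rho_0 (1 - rho_0)

(The sign of the ``rho_0`` correction is fixed by density conservation:
summing the right-hand sides must give zero.)  The moment hierarchy then
gives the closed forms ``M1(t) = exp((s-1) * int_0^t rho_0)`` and
``M2(t) = t * M1(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.integrate
import scipy.stats

from ecdna_dyn.errors import NumericalError, ParameterError, TruncationError
from ecdna_dyn.population import MomentSeries

__all__ = [
    "DensityState",
    "TwoPopulationState",
    "DensityIntegration",
    "delta_density",
    "neutral_fraction_positive",
    "density_rhs",
    "integrate_density",
    "selection_m1",
    "selection_m2",
    "two_population_selection",
    "moment_scaling_check",
]

DEFAULT_K_MAX = 512
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12
#: mass allowed to leak past the truncation boundary before k_max is doubled
DEFAULT_LEAK_BOUND = 1e-10


@dataclass(frozen=True)
class DensityState:
    """Copy-number density vector ``rho_k`` (k = 0..k_max) at time ``t``."""

    t: float
    rho: np.ndarray
    leaked_mass: float = 0.0

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 1 or rho.size < 2:
            raise ParameterError("density must be a 1-D vector of length >= 2")
        if np.any(rho < -1e-12):
            raise ParameterError("density values must be non-negative")

    @property
    def k_max(self) -> int:
        return self.rho.size - 1

    @property
    def total(self) -> float:
        return float(self.rho.sum())


@dataclass(frozen=True)
class TwoPopulationState:
    """Coarse two-compartment state: ecDNA+ vs ecDNA-free fractions."""

    t: float
    f_plus: float
    n_plus: Optional[float] = None
    n_minus: Optional[float] = None

    @property
    def f_minus(self) -> float:
        return 1.0 - self.f_plus


def delta_density(k: int, k_max: int = DEFAULT_K_MAX) -> DensityState:
    """All density concentrated in copy-number class ``k`` at ``t = 0``."""
    if not (0 <= k <= k_max):
        raise ParameterError(f"initial class k={k} outside [0, {k_max}]")
    rho = np.zeros(k_max + 1)
    rho[k] = 1.0
    return DensityState(0.0, rho)


def neutral_fraction_positive(t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form ecDNA+ fraction ``f+(t) = 2 / (2 + t)`` under neutrality.

    Derived from the two-population model of an exponentially growing
    population that loses ecDNA+ cells through complete asymmetric
    segregation; the ecDNA+ fraction decays like ``1/t``, so neutral ecDNA
    survives only in a shrinking subpopulation.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("time must be >= 0")
    out = 2.0 / (2.0 + t)
    return float(out) if out.ndim == 0 else out


def _kernel_matrix(k_max: int) -> np.ndarray:
    """Offspring redistribution matrix ``A[k, i] = 2 C(2i, k) 2^(-2i)``.

    Column ``i`` is twice the Binomial(2i, 1/2) pmf truncated to k <= k_max;
    the pmf is evaluated in log space by scipy so large ``i`` do not
    overflow.
    """
    k = np.arange(k_max + 1)
    i = np.arange(k_max + 1)
    return 2.0 * scipy.stats.binom.pmf(k[:, None], 2 * i[None, :], 0.5)


def _neutral_rhs(rho: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return kernel @ rho - 2.0 * rho


def _selection_rhs(rho: np.ndarray, kernel: np.ndarray, s: float) -> np.ndarray:
    base = _neutral_rhs(rho, kernel)
    if s == 1.0:
        return base
    rho0 = rho[0]
    out = s * base + (s - 1.0) * rho0 * rho
    # the k=0 class: correction sign fixed by sum_k d rho_k / dt = 0
    out[0] = s * base[0] - (s - 1.0) * rho0 * (1.0 - rho0)
    return out


def density_rhs(state: DensityState, s: float = 1.0) -> np.ndarray:
    """Right-hand side of the density master equation at one state."""
    if s <= 0:
        raise ParameterError("selection coefficient must be > 0")
    kernel = _kernel_matrix(state.k_max)
    # classes with 2i > k_max put offspring mass beyond the truncation
    colsum = kernel.sum(axis=0)
    leak_rate = float(np.sum(state.rho * (2.0 - colsum)))
    if leak_rate > 1e-6:
        raise TruncationError(
            f"truncation k_max={state.k_max} leaks mass at rate {leak_rate:.2e}; "
            "increase k_max"
        )
    return _selection_rhs(np.asarray(state.rho, dtype=float), kernel, s)


@dataclass(frozen=True)
class DensityIntegration:
    """Result of integrating the density master equation."""

    times: np.ndarray
    rhos: np.ndarray  # shape (n_times, k_max + 1)
    s: float
    leaked_mass: float

    @property
    def k_max(self) -> int:
        return self.rhos.shape[1] - 1

    def state(self, index: int) -> DensityState:
        return DensityState(float(self.times[index]), self.rhos[index], self.leaked_mass)

    def moment(self, l: int) -> np.ndarray:
        """Raw moment series ``M^(l)(t) = sum_k k^l rho_k(t)``."""
        k = np.arange(self.rhos.shape[1], dtype=float)
        return self.rhos @ (k**l)

    @property
    def rho0(self) -> np.ndarray:
        return self.rhos[:, 0]

    @property
    def frac_pos(self) -> np.ndarray:
        return 1.0 - self.rho0

    @property
    def moments(self) -> MomentSeries:
        m1 = self.moment(1)
        m2 = self.moment(2)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(self.rhos > 0, np.log(np.where(self.rhos > 0, self.rhos, 1.0)), 0.0)
        shannon = -np.sum(self.rhos * logs, axis=1)
        return MomentSeries(
            times=self.times,
            m1=m1,
            m2=m2,
            variance=np.maximum(m2 - m1**2, 0.0),
            frac_pos=self.frac_pos,
            shannon=shannon,
        )


def integrate_density(
    initial: DensityState,
    s: float = 1.0,
    t_max: float = 10.0,
    t_eval: Optional[Sequence[float]] = None,
    k_max: Optional[int] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    leak_bound: float = DEFAULT_LEAK_BOUND,
    max_doublings: int = 3,
) -> DensityIntegration:
    """Integrate the copy-number density master equation to ``t_max``.

    Uses an adaptive explicit Runge-Kutta scheme.  If probability mass
    accumulates at the truncation boundary beyond ``leak_bound``, the
    truncation ``k_max`` is doubled and the integration re-run (up to
    ``max_doublings`` times).
    """
    if s <= 0:
        raise ParameterError("selection coefficient must be > 0")
    rho0 = np.asarray(initial.rho, dtype=float)
    if abs(rho0.sum() - 1.0) > 1e-8:
        raise ParameterError(f"initial density must be normalized, sum={rho0.sum()}")
    if t_max < 0:
        raise ParameterError("t_max must be >= 0")
    cur_kmax = int(k_max) if k_max is not None else max(initial.k_max, DEFAULT_K_MAX)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_max, 101)
    t_eval = np.asarray(t_eval, dtype=float)

    for attempt in range(max_doublings + 1):
        rho_init = np.zeros(cur_kmax + 1)
        m = min(rho0.size, cur_kmax + 1)
        rho_init[:m] = rho0[:m]
        kernel = _kernel_matrix(cur_kmax)

        def rhs(_t: float, rho: np.ndarray) -> np.ndarray:
            return _selection_rhs(rho, kernel, s)

        sol = scipy.integrate.solve_ivp(
            rhs,
            (0.0, float(t_max)),
            rho_init,
            method="DOP853",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise NumericalError(f"density integration failed: {sol.message}")
        rhos = sol.y.T
        # mass parked at the truncation boundary signals an under-resolved tail;
        # the total-density defect is reported as the leaked-mass diagnostic
        tail = float(rhos[:, -1].max())
        defect = float(np.abs(1.0 - rhos.sum(axis=1)).max())
        if tail <= leak_bound or attempt == max_doublings:
            if tail > leak_bound:
                raise TruncationError(
                    f"boundary mass {tail:.2e} above bound {leak_bound:.1e} even "
                    f"at k_max={cur_kmax}; raise k_max or leak_bound"
                )
            return DensityIntegration(sol.t, rhos, s, max(defect, tail))
        cur_kmax *= 2
    raise AssertionError("unreachable")


def selection_m1(
    s: float, times: Sequence[float], rho0_path: Sequence[float]
) -> np.ndarray:
    """Mean copy number under selection from the ecDNA-free density path.

    Evaluates the closed form ``M1(t) = exp((s - 1) * int_0^t rho_0(tau)
    d tau)`` by trapezoidal quadrature of the supplied ``rho_0`` series.
    """
    if s <= 0:
        raise ParameterError("selection coefficient must be > 0")
    times = np.asarray(times, dtype=float)
    rho0 = np.asarray(rho0_path, dtype=float)
    if times.shape != rho0.shape:
        raise ParameterError("times and rho0_path must have equal length")
    if np.any((rho0 < -1e-12) | (rho0 > 1 + 1e-12)):
        raise ParameterError("rho_0 values must lie in [0, 1]")
    integral = scipy.integrate.cumulative_trapezoid(rho0, times, initial=0.0)
    return np.exp((s - 1.0) * integral)


def selection_m2(
    m1_series: Sequence[float],
    times: Sequence[float],
    variant: str = "closed_form",
    rho0_path: Optional[Sequence[float]] = None,
    s: Optional[float] = None,
) -> np.ndarray:
    """Second moment under selection.

    ``variant="closed_form"`` evaluates ``M2(t) = t * M1(t)`` pointwise (the
    asymptotic, offset-free solution; exact for ``s = 1`` up to the initial
    offset).  ``variant="general"`` integrates the moment hierarchy
    ``dM2/dt = s * M1 + (s - 1) rho_0 M2`` along a supplied ``rho_0`` path
    -- the form implied by summing ``k^2`` against the density equations,
    which carries a factor ``s`` on the ``M1`` source term that the closed
    form does not.  The two variants coincide at ``s = 1`` and deviate
    increasingly with ``s``.
    """
    m1 = np.asarray(m1_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if m1.shape != times.shape:
        raise ParameterError("m1_series and times must have equal length")
    if variant == "closed_form":
        return times * m1
    if variant != "general":
        raise ParameterError(f"unknown selection_m2 variant {variant!r}")
    if rho0_path is None or s is None:
        raise ParameterError("the general variant needs rho0_path and s")
    rho0 = np.asarray(rho0_path, dtype=float)
    if rho0.shape != times.shape:
        raise ParameterError("rho0_path and times must have equal length")
    # integrating factor: M2(t) = int_0^t s M1(u) exp((s-1) int_u^t rho0) du
    big_i = scipy.integrate.cumulative_trapezoid(rho0, times, initial=0.0)
    inner = s * m1 * np.exp(-(s - 1.0) * big_i)
    outer = scipy.integrate.cumulative_trapezoid(inner, times, initial=0.0)
    return outer * np.exp((s - 1.0) * big_i)


def two_population_selection(
    s: float,
    t_max: float,
    f_minus_path: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    initial: Optional[DensityState] = None,
    n_points: int = 201,
) -> list[TwoPopulationState]:
    """Growth of the ecDNA+ compartment under positive selection.

    Evaluates the closed form ``N+(t) = (1 - f-(0)) * exp(s t - (1 - s) *
    int_0^t f-(tau) d tau)`` along a supplied ``f-`` path, or along the
    ``rho_0`` path of a full density integration (default initial condition:
    all cells with one copy).  Requires ``s > 1``: this solution branch
    describes positive selection, where the ecDNA+ fraction approaches 1.
    """
    if s <= 1:
        raise ParameterError("the positive-selection branch requires s > 1")
    if f_minus_path is None:
        init = initial if initial is not None else delta_density(1)
        res = integrate_density(init, s=s, t_max=t_max,
                                t_eval=np.linspace(0.0, t_max, n_points))
        times, f_minus = res.times, res.rho0
    else:
        times = np.asarray(f_minus_path[0], dtype=float)
        f_minus = np.asarray(f_minus_path[1], dtype=float)
        if times.shape != f_minus.shape:
            raise ParameterError("f_minus_path times and values must align")
        if np.any((f_minus < -1e-12) | (f_minus > 1 + 1e-12)):
            raise ParameterError("f- values must lie in [0, 1]")
    integral = scipy.integrate.cumulative_trapezoid(f_minus, times, initial=0.0)
    n_plus = (1.0 - f_minus[0]) * np.exp(s * times - (1.0 - s) * integral)
    return [
        TwoPopulationState(t=float(t), f_plus=float(1.0 - fm), n_plus=float(npl))
        for t, fm, npl in zip(times, f_minus, n_plus)
    ]


def moment_scaling_check(
    times: Sequence[float],
    moment_values: Sequence[float],
    window_decades: float = 1.0,
) -> float:
    """Late-time log-log scaling exponent of a moment series.

    Fits ``log M`` against ``log t`` over the last ``window_decades``
    decades of the time axis; the neutral hierarchy predicts exponent
    ``l - 1`` for the ``l``-th moment.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(moment_values, dtype=float)
    if times.shape != values.shape:
        raise ParameterError("times and moment_values must have equal length")
    mask = (times > 0) & (values > 0)
    times, values = times[mask], values[mask]
    if times.size < 3 or times[-1] / times[0] < 10**window_decades:
        raise ParameterError(
            "need a positive series spanning at least the requested decades"
        )
    lo = times[-1] / 10**window_decades
    sel = times >= lo
    if np.ptp(values[sel]) == 0:
        return 0.0
    slope = np.polyfit(np.log(times[sel]), np.log(values[sel]), 1)[0]
    return float(slope)
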