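# Methods

## Model

### Segregation at a single division

A cell carrying `n` ecDNA copies replicates them to `2n` and partitions
them between its daughters by independent Bernoulli trials:
`n₁ ~ Binomial(2n, p)`, `n₂ = 2n − n₁`. The per-daughter inherited
fraction is `fᵢ = nᵢ/(n₁+n₂)`. `p` is the probability that a given copy
enters daughter 1; `p = 1/2` (the default everywhere) is unbiased random
segregation, and the package's analytic layer is derived for `p = 1/2`
only. The chromosomal comparator splits `n → (n, n)` exactly, except that
with mis-segregation probability `u` (default 0.05) one daughter receives
`n+1` and the other `n−1`; the gain direction is symmetric (`u/2` each),
which keeps `E[f₁] = 1/2`. Fraction histograms record both daughters of
every division, so they are symmetric about 1/2 by construction — the same
pairing used when daughter cells are imaged in pairs.

Founder copy numbers for expected-fraction distributions are drawn from a
discrete uniform on [20, 200] (inclusive), the span typical of oncogene
amplification per cell. The default number of simulated divisions is 10⁵;
the distribution is identical at larger iteration counts, only smoother.

### Population dynamics

Growth is a pure birth process with no death and no carrying capacity.
ecDNA-free cells divide at rate 1 — time is therefore measured in
generations of ecDNA-free cells — and ecDNA+ cells at rate `s`,
regardless of their exact copy number. This two-level fitness is the
model's central simplification: selection sees only the presence of ecDNA,
not its dose. Consequences that matter for interpreting scenarios are
noted below.

The Gillespie implementation holds per-cell copy numbers in a flat array
and selects the next divider by uniform-proposal rejection sampling
(accept with probability `rate/max_rate`), which is O(1) per event and
exactly equivalent to sampling proportional to fitness. Time advances by
exponential increments at the total rate `N⁺s + N⁻`. The loop is
numba-compiled; 10⁶ birth events take on the order of 0.1 s, so the
package runs cell-line-scale populations (10⁶ cells) on a laptop. Much
larger populations (10⁹–10¹¹) are qualitatively identical but need cluster
time; the exposed `n_target` makes the trade-off explicit.

Reproducibility: every simulation object consumes a single integer seed;
internal segment seeds are drawn from a `numpy` generator derived from it,
and replicate `r` of a batch uses `seed + r` (or an explicit stream).
Identical seeds give identical trajectories.

### Deterministic density equations

The normalized density `ρ_k(t)` of cells with `k` copies obeys

    ∂ρ_k/∂t = −2ρ_k + 2 Σ_{i≥⌈k/2⌉} ρ_i C(2i,k) 2^(−2i)        (neutral)

The lower summation bound is `⌈k/2⌉` (the even-`k` form `i = k/2` is not
integral for odd `k`). Under selection the hierarchy becomes, for `k > 0`,
`∂ρ_k/∂t = s·(neutral rhs) + (s−1)ρ₀ρ_k`, and for the ecDNA-free class
`∂ρ₀/∂t = s·(neutral rhs) − (s−1)ρ₀(1−ρ₀)`. The sign of the `ρ₀`
correction is fixed by total-density conservation (the right-hand sides
must sum to zero); with it the integrator reproduces the closed-form first
moment `M¹(t) = exp((s−1)∫₀ᵗρ₀ dτ)` to 10⁻⁴, and a unit test asserts the
conservation identity directly.

Closed forms exposed alongside the integrator: neutral `M¹` constant,
`dM²/dt = M¹` (stated offset-free as `M²(t) − M²(0) = t`, since a δ-type
initial condition contributes `M²(0) ≠ 0`), the late-time scaling
`M^(l) ~ t^(l−1)`, the neutral ecDNA+ fraction `f⁺(t) = 2/(2+t)`, and the
positive-selection compartment solution
`N⁺(t) = (1−f⁻(0))·exp(st − (1−s)∫f⁻)`. The loss-rate function of the
two-compartment model has no explicit form, so `2/(2+t)` is validated
qualitatively: the log-log slope of `f⁺` from the full density integration
over `t ∈ [10, 50]` is −0.91, consistent with `1/t` decay. The
second-moment solution `M² = t·M¹` under selection corresponds to a moment
equation without a factor `s` on the `M¹` source term; the variant implied
by summing `k²` against the density hierarchy (`dM²/dt = s·M¹ +
(s−1)ρ₀M²`) is available via `selection_m2(..., variant="general")`. The
default matches the closed form; the numeric difference between the two is
documented by a test but not asserted, as the discriminating data do not
exist at this resolution.

### Numerics

- Truncation: densities live on `k = 0..k_max`, default `k_max = 512`.
  If mass at the boundary class exceeds 10⁻¹⁰ the truncation is doubled
  and the integration re-run (up to 3 doublings) before failing loudly.
- Integrator: `scipy.integrate.solve_ivp` with DOP853, `rtol = 1e-8`,
  `atol = 1e-12`. Total density is conserved to better than 10⁻⁸ over the
  tested horizons; the first moment to 10⁻⁶.
- The binomial kernel `C(2i,k)2^(−2i)` is evaluated through scipy's
  log-space binomial pmf, so large `i` do not overflow.
- `tail_exponent` fits log CCDF vs log k by least squares over the upper
  fraction of the *reliably estimated* range: classes where fewer than 10
  cells are expected above `k` are excluded first, because single-cell
  noise at the extreme tail otherwise dominates the slope.
- KS p-values: the two-sample statistic uses scipy's asymptotic
  Kolmogorov form at the effective size `n_x n_y/(n_x+n_y)`; copy-number
  data are discrete, so this p-value is conservative under ties and an
  optional permutation p-value (10⁴ shuffles) is exposed. The subsampling
  trial compares a small subsample against a source ~10³–10⁵ times larger,
  which is effectively a one-sample comparison against a known
  distribution; there the finite-sample Kolmogorov distribution
  (`scipy.stats.kstwo`) is used instead, because the asymptotic form is
  noticeably biased below n ≈ 100 and would distort size-to-size
  comparisons of rejection rates.

## Scenario conventions

- **CRISPR-C induction.** A fraction `q_ecdna` (default 0.15) of founder
  cells receives exactly one ecDNA copy; an independent fraction `q_scar`
  (default 0.15) carries the chromosomal scar. Independence is an
  assumption, made because the scar readout is meant to behave as a
  neutral control; if scar and ecDNA co-occurred in founders, early
  negative selection on ecDNA would drag the scar frequency with it.
  The scar is inherited by both daughters unconditionally and never
  affects rates; across replicates its frequency is a martingale, which a
  test verifies to within 3 standard errors over 200 runs.
- **Day-to-generation mapping.** One schedule time unit is one generation
  of ecDNA-free cells; a treatment day maps 1:1 to a generation. Schedule
  templates follow a 4-unit induction phase at `s = 0.5` and a 14-unit
  treatment phase at configurable `s`.
- **Passaging.** Cultures cannot grow without bound: whenever the
  population reaches `dilution_factor × n0` (default 4×) it is uniformly
  subsampled back to `n0` cells. Uniform subsampling preserves all class
  frequencies in expectation, so moment trajectories are unbiased; it adds
  drift variance, which the replicate-averaged tests absorb.
- **Founder sizes.** Scenario defaults (`n0 = 10⁴` founders, caps at 4×)
  are a stand-in for a culture well; they were chosen once as
  desk-realistic and all directional contracts are asserted on replicate
  means, not single runs.
- **Drug-shift founders.** Because fitness sees only ecDNA presence, a
  population founded at ~100 copies contains essentially no ecDNA-free
  cells and negative selection cannot move its mean. The drug-adaptation
  template therefore defaults to a 4-copy founder, which after neutral
  burn-in leaves an ecDNA-free reservoir of tens of percent; the drug
  phase expands that reservoir (mean and ecDNA+ fraction fall) and the
  withdrawal phase reverses it. A dose-dependent copy-number shift
  *within* the ecDNA+ compartment would require copy-number-dependent
  fitness, which is outside this model (see Limitations).

## Synthetic data

The generators emulate the study designs the pipeline is meant to consume,
not the physics of the instruments:

- **Daughter pairs**: ~100 pairs per "cell line", founders U(20, 200),
  split by the chosen segregation model. Real image-derived pairs carry
  spot-merging and focus artifacts that are not modelled.
- **FISH tables**: cells sampled from a simulated distribution, counts
  thinned binomially by a detection efficiency ε (default 1; probe dropout
  only). There are no false-positive spots, no spatial overlap artifacts,
  and no truncation of high-copy nuclei — passing tests therefore show
  pipeline correctness under idealized counting, not robustness to
  microscopy artifacts.
- **ddPCR series**: droplet partition counts are binomial with the Poisson
  positive-droplet probability `1 − e^(−λ)`; concentrations are recovered
  with the standard `−ln(fraction negative)` estimator and reported as
  ratios to a single-copy reference amplicon, so volume constants cancel.
  Default 2×10⁴ droplets at 0.2 reference copies per droplet. Saturated
  assays (all droplets positive) are clamped rather than diluted, unlike
  real workflows.

Every generator is a pure function of (configuration, seed).

## Test and reference problem sizes

The package's reference computations use sizes chosen to resolve each
effect comfortably on one CPU: 200 replicates of 10⁴-cell neutral
trajectories for the martingale check; 10⁴ replicate ensembles at `t = 3`
against a `k_max = 64` integration (total-variation agreement < 0.02);
a 10⁶-cell population as the subsampling source with 500 resamples at
sizes 25/50/100/500; 10⁵ divisions for segregation histograms. Larger
sizes sharpen nothing qualitative; the originals of these analyses used
populations up to 10¹¹ cells and 10⁷ divisions on comparable mathematics.

## Limitations

- Fitness is presence-based (`s` for any `k ≥ 1`): no copy-number-dosed,
  balancing, or epistatic selection. Consequently the model cannot shift
  the mode of the ecDNA+ compartment per se, only the ± balance and the
  growth-weighted distribution.
- Segregation bias `p ≠ 1/2` is available in the single-division layer but
  the density equations assume `p = 1/2`.
- No cell death, quiescence, cell-cycle structure, spatial structure, or
  multiple coexisting ecDNA species.
- The chromosomal comparator models ±1 mis-segregation only, not
  breakage-fusion-bridge or HSR expansion dynamics.
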