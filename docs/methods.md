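# Methods

## Model

A tissue is a chain of non-stem compartments `i = 1..N`; class `(i, k)`
holds cells in compartment `i` carrying `k` neutral mutations.  One division
of a cell in `(i, k)` resolves to differentiation with probability
`ε_i^k` (two daughters in compartment `i+1`; from the last compartment both
daughters leave the system), mutation with probability `u` (one cell in
`(i, k+1)` — count-conserving), or self-renewal otherwise (one extra cell in
`(i, k)`).  Cells divide at rate `r_i = γ^i r₀`.  Asymmetric divisions are
not modelled separately; at the population level they are absorbed into the
differentiation probability.  Stem cells are not dynamical: the model
follows the clone founded by `n₀` cells placed in the founder compartment
(default 1), with no continuous influx from upstream.  A stem-cell-derived
driver can still be represented by giving the founder clone its own `ε`.

Writing `α = ε + u` (the probability of leaving the current class), the
expected occupancies obey

    dN_i^k/dt = (1 − 2α_i^k) r_i N_i^k + 2 ε_{i−1}^k r_{i−1} N_{i−1}^k
                + u r_i N_i^{k−1}.                                   (1)

`α > ½` yields a transient clonal wave; `α < ½` unbounded accumulation (a
differentiation-block phenotype).  Time is measured in units of `1/r₀` stem
cell generations: with the haematopoietic `r₀ = 1/400` and one stem-cell
division per year, 400 units equal one year (`clonewave.params` provides the
month/year conversions).

### Defaults

| parameter | default | meaning |
|---|---|---|
| `N` | 31 | non-stem compartments needed for a daily mature output of ~3.5e11 cells |
| `ε` | 0.85 | healthy differentiation probability (all compartments, all `k`) |
| `γ` | 1.26 | per-compartment proliferation-rate growth |
| `r₀` | 1/400 | stem-cell division rate per time unit (one per year) |
| `u` | 1e-6 | mutation probability per division |
| `n₀` | 1 | founder cells in compartment 1 |
| `k_max` | 5 | mutation-ladder truncation for the deterministic grids |

The `test-small` preset (5 compartments, `u = 10⁻³`, `r₀ = 1`) keeps the
wave regime but inflates the mutation flux so stochastic tests resolve
mutant statistics with 10³ replicates in seconds.

## Closed forms

System (1) is lower triangular in `(i, k)`, so each class solves a scalar
linear ODE forced by the classes before it.  `ExpPoly` represents every
solution exactly as `Σ_j P_j(t) e^{−λ_j t}` with polynomial `P_j`; solving
`y' = −λy + f` maps polynomials to polynomials (a term with the same decay
rate integrates to one higher degree — the secular case).  This constructs
the Bateman-type closed form for the unmutated cascade and generates the
combinatoric coefficients of the multi-mutant solution for *any* `k` by the
same recursion, rather than hard-coding low-order tables.  Repeated rates
(`γ = 1`) are handled exactly by the secular branch; rate pairs closer than
a relative `1e-9` are merged rather than divided by.

Coefficients are held in extended precision (`long double`).  The
representation cancels almost completely at small `t` when coefficients are
large (large `i`, near-critical `α`); `ExpPoly.noise_floor` bounds that
cancellation error by `machine-ε × Σ_j |P_j|(t) e^{−λ_j t}`, and consumers
(the burden solver) clip values below it to zero.  The adaptive integrator
(`solve_ivp`, LSODA, rtol `1e-10`) is an independent oracle; closed forms
and integrator agree to better than `1e-6` relative error over the test
matrix wherever the occupancy exceeds `1e-7` of its trajectory maximum
(below that the integrator's own absolute tolerance dominates).

In the founder compartment `N_1^k(t) = n₀ (u r₁ t)^k e^{−(2α−1) r₁ t}/k!`,
so the wave maximum sits at `t_peak = k/((2α−1) r₁)` — equally spaced in
`k` — with exact height `n₀ (u k/(2α−1))^k e^{−k}/k!`.  `peak_summary`
reports both this exact value and the Stirling form
`n₀ (u/(2α−1))^k/√(2πk)` (the `n_peak` field), which exposes the `u^k`
suppression; the Stirling approximation overstates the `k = 1` peak by ~8%,
and `peak_numeric` locates the maximum on the closed form for validation.

## Reproductive capacity

`W_i^k` counts the cells of the founder's lineage that ever *depart*
class `(i, k)` (by differentiation or mutation).  A single cell departing
after `l` divisions has probability `α(1−α)^{l−1}` and leaves `2^{l−1}`
same-class cells behind, giving the founder-compartment geometric sum
`W = α/(2α−1)`, finite only for `α > ½`.  Each departure from `(i−1, k)` is
a differentiation with probability `ε/α` (two arrivals) and each departure
from `(i, k−1)` a mutation with probability `u/α` (one arrival); every
arrival founds `α/(2α−1)` departures of its own.  For constant parameters
the recursion closes to

    W_i^k = [α/(2α−1)] · C(i−1+k, k) · a^{i−1} · b^k,
    a = 2ε/(2α−1),  b = u/(2α−1),

evaluated in log space.  The same departure convention is used by the
cumulative production integral `∫ α r_i N_i^k dt` (its `t → ∞` limit *is*
`W_i^k`, verified to `1e-4` by exact integration of the closed form), so the
two conventions never mix.  `capacity_general` runs the recursion with
per-class `ε` tables, `k`-major then `i`-outward so each entry's
dependencies are final; any class with `α ≤ ½` is flagged divergent and the
flag propagates to every class it feeds.  Capacities contain no `r_i`: the
composition of a lineage is independent of how fast it unfolds, which the
tests check by varying `(γ, r₀)`.

## Expected diversity

Under the unique-event (infinite-sites) assumption, the diversity of
`(k+1)`-mutants in compartment `i` grows by new mutation events of
`k`-mutants inside compartment `i` and by differentiation of clones from
compartment `i−1`.  Solving that recursion on the capacity template —
transported diversity amplified by the same per-compartment factor
`2ε/(2α−1)` as the cells that carry it, new events entering with the
self-renewal weight `u W_i^k/(2α−1)` — gives the closed form

    D_i^{k+1} = u W_i^{k+1}/(2α−1)
              = [α/(2α−1)] · C(i−1+k+1, k+1) · a^{i−1} · b^{k+2}.

`D` is a flux-weighted diversity index, not a raw richness: a clone's
contribution downstream carries the amplification its cells undergo.  The
raw expected number of founded `(k+1)`-clones — `u/α · Σ_j W_j^k`
(`u` times the expected division count of the `k`-class) — is exposed as
`expected_founded_clones` and is orders of magnitude larger (≈ 8.8 × 10⁵
vs ≈ 28 for the healthy parametrization), because the vast majority of
clones are founded in the last compartments and never expand.  The Gillespie
clone census estimates exactly this raw count, and the stochastic validation
compares it against `expected_founded_clones`; the index `D` is the quantity
quoted in the worked examples.  Both vanish identically at `u = 0`, and `D`
falls by roughly one decade per 0.033 increase of `ε` near the
haematopoietic point — small changes in self-renewal dominate the expected
mutation landscape.

Compartment exclusions (`diversity_with_exclusions`) zero the new-event term
of the excluded compartments while still transporting upstream clones
through them: the exclusion acts on event origin, not clone presence.

The error budget propagates parameter uncertainties to first order using the
exact log-derivatives of the closed form
(`∂lnD/∂u = 1/α + (k+2)/u − 2(i−1+k+3)/(2α−1)` and the analogous `ε` form);
central finite differences reproduce them to well under 1%.  The two
contributions `|∂D/∂u| Δu` and `|∂D/∂ε| Δε` are combined as a plain sum
(worst-case linear propagation).

## Stochastic engine

The Gillespie implementation keeps every cell: exponential waiting times
with total rate `Σ_i r_i n_i`, a compartment drawn proportionally to its
aggregate rate followed by a uniform cell choice (distributionally identical
to per-cell rates, O(N) per event), and the three outcomes at
`(ε, 1−ε−u, u)`.  A mutation replaces the cell by a single cell with `k+1`
mutations — the count-conserving semantics that matches the deterministic
flux in (1); the division-with-one-mutant-daughter variant is available
behind `mutation_division=True` and is documented as deviating from the
deterministic means.  Each mutation event founds a clone with a unique id
and a parent link; the clone forest exports to newick (labels
`c<id>.i<compartment>`, branch lengths the waiting times between founding
events).  Replicates draw independent streams from a spawned
`SeedSequence`; identical seeds give identical event logs.  Runs hitting the
cell cap are flagged and excluded from ensemble statistics.

What the stochastic tests do and do not show: 10³ replicates of the
`test-small` preset confirm that ensemble means of the unmutated occupancies
track the closed forms within 3 standard errors wherever the expected count
is observable (≥ ~25 observations across the ensemble), that division
outcomes pass a χ² test against `(ε, 1−ε−u, u)`, that essentially all wave
regime runs go extinct, and that the clone census matches its deterministic
expectation.  They exercise a 5-compartment hierarchy with an inflated
mutation rate; they do not probe the 31-compartment amplification range
(covered deterministically), real clinical heterogeneity, selection among
clones, or mutation-rate evolution.

## ALL case study

The inversion treats the leukaemic clone as `N₀ = 100` founder cells in
compartment 1 with an unknown mutant `ε` and unchanged proliferation rates.
The tumour burden at time `t` is `M(t)/(M(t) + R)` with `M` the mutant
mature-compartment occupancy (closed form; total mutant load is `M` up to
O(u)) and `R` a healthy reference pool.  The default
`R = P/((2α−1) r_N) ≈ 1.4 × 10¹¹` is the steady mature pool sustaining the
calibrated daily output `P` of 3.5e11 cells; it is configurable because the
measured burden denominator depends on the assay.  The constraint box
(burden 10–75%, diagnosis 48–77 months) maps to the `ε` interval by
monotonicity — smaller `ε`, larger clone, earlier load:  the lower endpoint
reaches the maximal burden at the window start, the upper endpoint the
minimal burden at the window end (bisection on `ε ∈ [0.55, 1−u]`, tolerance
`1e-4`; nearer the critical point the transit slows and the crossing time is
no longer monotone).  With the default `R` the box yields ≈ [0.775, 0.840]
and the endpoint clones reach their defining loads at ≈ 48 and ≈ 57 months
(the upper endpoint is limited by wave reachability, not by the window).
The diversity predictions for the case study are evaluated per founder
lineage at the fixed differentiation probabilities 0.81 and 0.78 and, for
the detectable-clone variant, with mutation events of compartments 30–31
excluded.

## Numerical choices

* `long double` coefficients in all closed forms; log-space evaluation of
  capacities and diversity (stable to `i = 31` and far beyond).
* Rate-merge tolerance `1e-9` (relative) before dividing by rate gaps;
  merged rates take the exact secular path.
* LSODA with rtol `1e-10`, atol `1e-12·n₀` for the oracle; the linear system
  spans rate ratios of `γ³⁰ ≈ 10³`.
* Cancellation noise floor `1e-17 × Σ|P_j|(t) e^{−λ_j t}` clips closed-form
  evaluations in the burden solver.
* Bisection tolerances: `1e-4` on `ε` (inversion), relative `1e-9` on the
  burden crossing time.
* `k_max = 5` truncates the deterministic ladder (classes above carry
  `u^k`-suppressed mass); the stochastic engine does not truncate and
  reports mutation events beyond `k_max` as truncation leakage.

## Limitations

* Deterministic quantities are expectations; stochastic extinction of small
  clones is absent from the means (the simulator shows ~100% extinction in
  the wave regime while the expected occupancies stay positive).
* No stem-cell influx, no competition for niches or cytokines, no selection:
  all mutations are neutral relative to their founder, and `ε`, `u` are
  constant in time.
* The diversity index weights clones by their downstream amplification;
  counting questions about raw clone numbers must use
  `expected_founded_clones` instead.
* The burden inversion inherits the uncertainty of the reference-pool size
  `R`; its endpoints shift by roughly ±0.02 in `ε` per factor ~4 in `R`.
* Near-critical parametrizations (`α` close to ½) are numerically delicate
  in the closed forms; the integrator remains the fallback there.
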