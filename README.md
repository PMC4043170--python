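# clonewave

Deterministic closed forms and an exact individual-based simulator for the
dynamics of multiple mutations in hierarchically organized tissues, with
human haematopoiesis as the reference system and childhood acute
lymphoblastic leukaemia (ALL) as the worked clinical case.

## The problem

Most tissues are maintained by a differentiation hierarchy: a few slowly
dividing stem cells feed a chain of progenitor compartments whose
proliferation speeds up downstream until the mature cells are produced.
Because a non-stem cell's offspring are progressively pushed out of the
hierarchy, most somatic mutations are transient — yet leukaemia genomes
carry hundreds of passenger mutations.  `clonewave` quantifies exactly how a
hierarchy suppresses cells carrying multiple mutations, and how many
distinct mutations a single (possibly driver-mutated) founder cell is
expected to spawn on its way through the hierarchy.

## The model

Compartments `i = 1..N` hold cells with `k = 0, 1, 2, …` mutations.  A
dividing cell in compartment `i` differentiates with probability `ε` (both
daughters move to `i+1`), mutates with probability `u` (one cell with `k+1`
mutations), or self-renews with probability `1−ε−u`.  Cells divide at rate
`r_i = γ^i r₀`.  The expected occupancies obey the linear system

    dN_i^k/dt = (1 − 2α) r_i N_i^k + 2 ε r_{i−1} N_{i−1}^k + u r_i N_i^{k−1},
    α = ε + u,

with `n₀` founder cells in class `(1, 0)`.  For `α > ½` the solution is a
clonal wave that expands, travels downstream and washes out; for `α < ½`
cells accumulate without bound.  The package provides

* exact Bateman-type closed forms for every `N_i^k(t)` (any `k`, repeated
  rates included), with the adaptive ODE integrator as an independent
  oracle;
* the wave peak in the founder compartment, `t_peak = k/((2α−1) r₁)` and the
  `u^k`-suppressed peak height;
* the reproductive capacity `W_i^k = [α/(2α−1)] C(i−1+k, k) a^{i−1} b^k`
  with `a = 2ε/(2α−1)`, `b = u/(2α−1)` — the expected lifetime output of a
  single founder cell per compartment and mutation class, independent of the
  proliferation rates;
* the expected clonal diversity `D_i^{k+1} = u W_i^{k+1}/(2α−1)` (distinct
  mutations represented in compartment `i`, unique-event assumption), its
  linear error propagation in `u` and `ε`, and the raw count of founded
  clones for comparison with simulations;
* an exact Gillespie engine with per-cell representation, full clone
  genealogy and newick export;
* the ALL pipeline: inversion of the clonal-wave forward map against a
  tumour burden observed in a diagnosis window to estimate the mutant
  differentiation probability, and the resulting diversity predictions.

Haematopoietic defaults: 31 compartments, `ε = 0.85`, `γ = 1.26`,
`u = 10⁻⁶`, `r₀ = 1/400` (one stem-cell division per year; 400 time units
per year).

## Worked example

One healthy founder cell in compartment 1 ultimately sends about
`4.4 × 10¹¹` descendants through the mature compartment — the per-compartment
amplification `2ε/(2α−1) ≈ 2.43` compounded over 30 steps:

```
$ clonewave capacity --preset haematopoiesis | awk -F'\t' '$2==0 && ($1==1||$1==31)'
1	0	1.2142836734752187	0
31	0	441376667712.5178	0
```

The first line is the founder-compartment capacity `α/(2α−1) = 0.85/0.70 ≈
1.214`.  The expected number of *distinct* single mutations represented in
the mature compartment, and its sensitivity to the two parameters:

```
$ clonewave diversity --preset haematopoiesis --i 31 --k 1 --delta-u 1e-7 --delta-eps 0.01
{
  "compartment": 31,
  "k": 1,
  "diversity": 27.92367043407954,
  "founded_clones": 882754.0624000451,
  "error_budget": {
    "delta_total": 21.728504515500056,
    "contribution_u": 5.584474092380733,
    "contribution_eps": 16.14403042311932
  }
}
```

Roughly thirty distinct subclones (`diversity`), even though nearly a
million mutation events are founded along the way (`founded_clones`) — most
clones arise in the last compartments and stay tiny.  Dropping the founder's
differentiation probability to 0.75 (a driver-like change) raises the
diversity a thousand-fold, to ≈ 3.8 × 10⁴: a shift in `ε` that would be hard
to measure in vivo dominates the expected mutation landscape, which is the
central quantitative point of the model.

The ALL case (`clonewave all-case`) infers the mutant `ε` from a tumour
burden of 10–75% at diagnosis 48–77 months after the in-utero founder event
(`N₀ = 100` cells), yielding an interval of ≈ 0.78–0.84 — only slightly
below the healthy 0.85 — and predicts hundreds to thousands of distinct
passenger mutations for it.

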