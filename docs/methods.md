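# Methods

## Scope and model class

`grnforge` simulates perturbation-induced gene expression from a known
gene regulatory network (GRN) so that inference methods can be scored
against an exact ground truth.  The simulator is deterministic — a
two-step ordinary differential equation (ODE) model in mRNA and protein —
with measurement noise applied afterwards.  Keeping stochasticity out of
the dynamics gives full control of the noise level: at σ = 0 the data
are an exact function of the network, so a method's irreducible error
can be separated from its noise sensitivity.

## Network generation

Networks grow by preferential attachment: nodes are added one at a time
and attach to existing nodes with probability proportional to
`(degree + 1)^γ` (γ = 1 by default), which yields a heavy-tailed degree
distribution with a few hubs.  With probability `ffl_weight` an
attachment event instead closes an open two-path through the new or an
existing node into a feed-forward loop (FFL: X→Y, X→Z, Y→Z), the
three-node motif enriched in biological GRNs.  Growth attaches every new
node to the existing component, so the result is weakly connected by
construction; self-loops are never generated (imported networks may
contain them and they are preserved).  The realized edge count equals
`round(sparsity · n_genes)` up to attachment feasibility; a top-up phase
after growth closes the gap, again preferring FFL-closing edges with
probability `ffl_weight`.

Edge weights are drawn `Uniform(0.1, 1.0)` in magnitude with sign
positive (activation) with probability 0.7.  The spread exists so the
strong/weak interaction split below is non-degenerate; the paper-style
median rule needs real-valued weights.

The motif census classifies every unordered gene triad by its induced
subgraph: FFL, 3-cycle, cascade (X→Y→Z only), uplink (fan-in: X→Z, Y→Z),
downlink (fan-out: X→Y, X→Z).  Triads containing mutual edges or extra
edges are counted as none of the five.  The census is validated against
networkx's triadic taxonomy (030T, 030C, 021C, 021U, 021D).

## Kinetics

Each gene obeys

    dx_i/dt = m_i f(y_reg) − λ_i^mRNA x_i
    dy_i/dt = r_i x_i − λ_i^prot y_i

Randomly assigned constants and their ranges:

| parameter | meaning | range / default |
|---|---|---|
| m_i | max transcription rate | 1 for all unperturbed genes |
| λ_i^mRNA | mRNA degradation | Uniform(0.2, 0.7) |
| λ_i^prot | protein degradation | Uniform(0.2, 0.4) — slower than mRNA, mirroring longer protein half-lives |
| r_i | translation rate | Uniform(0.1, 0.3), see below |
| k (per edge) | Hill dissociation constant | Uniform(0.2, 0.6) |
| n (per edge) | Hill coefficient | uniform over {2, 3, 4} |
| α (per edge) | regulatory strength | Uniform(0.6, 1.0) if \|w\| > median(\|w\|) over edges ("strong"), else Uniform(0.4, 0.8) |
| α members / α₃ (combo) | group strengths | Uniform(0.2, 0.4) each, Uniform(0.7, 1.0) joint |

**Translation rate.**  The model is only informative when the Hill
functions operate on their sensitive flank: the unperturbed protein
level y* = r x*/λ^prot (with x* up to m/λ^mRNA ≈ 1.4–5) must land near
the dissociation constants k ∈ [0.2, 0.6].  `r ~ Uniform(0.1, 0.3)`
places the median steady-state protein level around 1, just above k, so
knockdowns move targets measurably.  Larger translation rates (r ≈ 1)
saturate every Hill term — downstream genes then barely respond to
perturbations and all inference collapses to chance — so they are a poor
default for benchmarking data.

**Combinatorial regulation.**  For each target, same-sign regulators are
grouped with probability `combo_probability` (default 0.2).  A group of
occupancies V_i = (y_i/k_i)^{n_i} contributes

    (Σ α_i V_i + α₃ P Π V_i) / (1 + Σ V_i + P Π V_i)

with P = 1 (AND: the product term requires all members) for formed
groups; ungrouped edges are size-one groups with P = 0.  Mixed
activator/repressor groups are never formed.  Upon grouping, member α's
are redrawn from the weak combo range — the solo-edge α is replaced, not
kept.

**Aggregation across groups** (the one-group formula does not fix the
cross-group rule, so this is a package choice): activator groups
contribute their value directly; each repressor group contributes
`1 − (value in activation form)`, i.e. full transcription when the
repressor is absent, reduced by up to α when saturated; the regulation
factor f of a target is the arithmetic mean of its group contributions,
clamped to [0, 1].  The mean keeps f ≤ 1, so m_i remains the true
maximum rate and x_i ≤ m_i/λ_i^mRNA is an invariant.  Genes with no
regulators transcribe at the basal maximum, f = 1, which gives the
unperturbed system a non-trivial steady state.

## Perturbations

A perturbation scales transcription: `m_i = m_i^input (1 + pert)` with
pert ∈ [−1, ∞).  Knockouts (−1) annihilate the rate; overexpression is
uncapped (the CLI warns above pert = 10) — f stays bounded in [0, 1]
regardless, because perturbation scales m, not f.  Strength may be a
scalar or a per-gene map.

Design schemes: **single** (one experiment per gene), **combinatory**
(k genes per experiment, drawn to keep per-gene perturbation counts
balanced, all rows unique), **targeted** (perturbed sets are subsets of
some target's regulator set, falling back to smaller sets when the
requested size is infeasible), **all-genes** (every entry
Uniform(−max, max) \ {0}; rows may repeat), **specific** (explicit gene
sets).  Designs over the same gene list merge row-wise with duplicate
rows dropped.

## Simulation

The control is found by integrating the unperturbed system from a random
start (each concentration Uniform(0, 1)) until the steady-state test
passes: every component of the ODE right-hand side below 1e−5 on two
consecutive accepted solver steps, within a budget of 10 000 steps.  A
converged state is then polished by a direct multidimensional root solve
of RHS = 0 (accepted only if it stays in the same basin and
non-negative), which tightens the endpoint from ~1e−4 to near machine
accuracy.  Systems that oscillate — feedback cycles can yield limit
cycles instead of fixed points — exhaust the budget, are flagged
`converged=False`, and the last computed state stands in for the steady
state.

Each experiment re-integrates from the control state with the perturbed
rates; steady mode returns the endpoint of the same stopping rule,
time-series mode samples a fixed span (default t ∈ [0, 50] model time,
10 points) on a linear grid or a logarithmic grid that concentrates
points early, where the dynamics are.  The integrator is LSODA
(stiffness-switching) at absolute/relative tolerance 1e−8 throughout.
Replicates duplicate the deterministic solution; all replicate variation
comes from the noise model, whose realizations are stored with the data.
Fold changes are `log2(value/control)` with the control (and noisy
values) floored at 1e−9 so knockouts stay finite.

## Noise

- **Gaussian multiplicative** (default): s → s·ε, ε ~ Normal(1, σ).  Not
  clamped at zero by default — with large σ a factor can go negative,
  which is meaningful on fold-change scales; a `clamp0` flag floors
  concentration-scale data.
- **Log-normal multiplicative**: ln ε ~ Normal(−σ²/2, σ²) so E[ε] = 1;
  factors are positive and signs preserved.
- **Single-cell (ZINB)**: expected reads per entry proportional to
  expression × gene length, normalized so the dataset expectation equals
  the requested coverage; counts drawn negative-binomial with dispersion
  d = 1/error_rate − 1 (error_rate → 0 recovers Poisson); zero-inflated
  with probability dropout_rate · exp(−λ), so dropout concentrates in
  low-expression entries.  The mapping from error and dropout rates to
  the ZINB parameters is this package's own construction around the four
  named knobs.
- **Custom**: a user matrix added entry-wise, or a callable
  `(data, seed) → noisy`.

The noise level can be set as a target SNR = s/σ; the dataset-level
signal s is the median absolute value, robust to knockout zeros.

## Benchmarking

Candidates are all ordered gene pairs (optionally excluding the
diagonal, for methods that never predict self-regulation — exclusion
removes exactly n_genes candidates from prediction and truth alike).
Positives are the nonzero truth entries; in signed mode a predicted edge
only counts if its sign matches.  Candidates are ranked by descending
|score|; tied blocks are traversed as units, drawing a straight segment
through the tie so results are order-independent.  Incomplete
predictions are extended: ROC linearly to (1, 1); PR by the
random-guessing construction — the remaining T positives spread
uniformly over the remaining C candidates, so each recovered positive
advances the rank by C/T and precision interpolates as TP/rank.  An
empty prediction therefore scores AUROC exactly 0.5 and AUPR equal to
the positive prevalence.  Areas are trapezoidal; the implementation is
tested to equal a naive per-threshold confusion-matrix recount to
1e−12 and the tie-corrected rank statistic on complete predictions.

The exploratory data report computes: fraction of unique values
(duplicates compared at 6 significant digits), median Pearson
correlation over replicate pairs (replicates = identical design rows)
and over all experiment pairs, the median fractional knockdown rank of
the targeted gene in single-knockdown experiments (1/n_genes = target
most reduced; reported `None` without single knockdowns), and the
singular-value spectrum with log10 condition number (`None` for rank
deficient matrices).

The built-in inference baseline standardizes fold changes per gene
across experiments and scores edge r→t by the mean |z| of t in the
experiments singly perturbing r; regulators never singly perturbed leave
their column unscored, handled by curve extension.  It exists so the
benchmark has an end-to-end consumer, not as a recommended method.

## What the generator does and does not emulate

Synthetic datasets reproduce: bounded sigmoid regulation, mRNA→protein
time lags, motif-enriched scale-free topology, perturbation designs
with per-gene strengths, replicate structure, and three noise families.
They do not emulate: chromatin state or any non-protein regulation,
nonlinear degradation, cell-to-cell heterogeneity within a sample
(noise is applied per measurement, not per cell), batch effects, or
mapping/quantification artifacts of real sequencing pipelines.  Passing
tests therefore demonstrate correctness of the simulator and scorer
under the model's assumptions, not that any inference method will
perform equally on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at 50–100 genes with single-gene
designs and ≤ 3 replicates, where a full pipeline completes in seconds
while exhibiting every code path (hubs, combos, repression, cycles,
extension).  Degenerate inputs are rejected early with typed errors
(infeasible density, empty networks, pert < −1, mismatched gene lists,
all-zero signal for SNR).  Ties in the benchmark are averaged rather
than broken arbitrarily; the steady-state detector is the residual test
(the printed tolerance fully specifies it) rather than a filter-based
variant whose parameters would be free choices.
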