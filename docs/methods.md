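# Methods

This note documents the models, algorithms, numerical choices and
validation-experiment designs implemented in `stratodec`, and what the
passing tests do and do not establish.

## State space and geography

A range is a subset of `n` discrete areas stored as a bitmask (bit *i* =
area *i*). The state space enumerates the null range (index 0) plus every
nonempty subset up to `max_range_size` (default: unlimited, since nothing
in the analysis design requires a cap; capping to 2–3 areas is the standard
way to keep 9-area problems tractable and is exposed everywhere as a flag).
States are ordered by range size then bitmask value, which fixes a
deterministic indexing for all matrices and outputs.

Time strata are intervals `[younger, older)` of Myr before present that
tile `[0, ∞)`; each carries a set of allowed areas and the whole geography
optionally carries an `n × n` dispersal multiplier matrix (default all 1;
the diagonal is unused). A node whose age falls exactly on a boundary is
resolved to the **younger** stratum. Branch segmentation only splits at
boundaries strictly inside a branch, so this convention matters only for
nodes sitting exactly on a boundary.

## Anagenesis

The generator `Q` over the state space has, for an allowed state `R`:
`Q[R, R∪{a}] = d · Σ_{b∈R} m[b,a]` for each addable allowed area `a`
(blocked when `|R| = max_range_size`), `Q[R, R∖{a}] = e` for each `a ∈ R`
(singletons contract to the null range), diagonal = −(row sum). The null
range is absorbing; states disallowed in the stratum have zero rows and
receive no rates. Rates are events per Myr.

## Cladogenesis

Events are enumerated over **ordered** (left, right) daughter pairs, both
orders emitted, matching the convention in which probabilities attach to
labeled daughters:

| family | singleton ancestor | widespread ancestor |
|---|---|---|
| DEC | sympatry (R,R) | subset sympatry (R,{a})/({a},R), vicariance with a singleton part |
| DIVA-like | sympatry (R,R) | all vicariant splits, incl. widespread–widespread |
| BayArea-like | sympatry (R,R) | identical inheritance (R,R) only |

With +*j*, jump events `(R,{a})` and `({a},R)` for each allowed area
`a ∉ R` are added for every ancestor size. Each non-jump event has weight
`(3 − j)/3`, each jump has weight `j`, `j ∈ [0, 3]`; per-ancestor
probabilities are the weights renormalized after removing events whose
daughters are disallowed in the node's stratum. At `j = 0` the jump rows
vanish and every table equals its base-family table entry for entry — the
exact-nesting property the tests assert. At `j = 3` all mass sits on
jumps; an ancestor with no free jump target (e.g. the full range) then has
an empty event set, which is reported as an error rather than silently
renormalized. The null range never speciates.

## Likelihood

Standard pruning over the state space. Tip vectors are indicators of the
coded range (tips must be nonempty, within the range-size cap and allowed
at age 0). Along a branch the conditional-likelihood vector is propagated
by `exp(Q_s Δt_s)` per stratum segment in tipward→rootward order; on entry
into an older stratum the entries of disallowed states are zeroed. At a
node the daughters' transported vectors are combined through the node's
stratum's event table. At the root the likelihood averages the root
partials under a **flat prior over the nonempty states allowed in the
root's stratum** (the null range is excluded: an extinct root cannot be
observed; the prior is exposed as a config option). Each node's vector is
rescaled to sum 1 with the log factor accumulated, which keeps 100-tip ×
512-state problems far from underflow. Impossible data yield −∞ rather
than an exception in `loglik`.

Two consequences of these definitions are worth stating because they are
easy to mis-assume:

- Summed over all nonempty tip patterns, the model's mass is `< 1`
  whenever `e > 0` (the remainder is the probability of null-range
  absorption) and shrinks further under stratum masking.
- Adding a constraint does **not** necessarily lower the prior-averaged
  likelihood: the flat root prior renormalizes over fewer states, and
  masked event tables renormalize per ancestor. What masking does
  guarantee — and what the tests assert — is that zero probability flows
  through disallowed states, and that total tip-pattern mass cannot grow.

Matrix exponentials use scaling-and-squaring (scipy) in the standalone
`expm`; the engine batches all segment durations of a stratum through one
eigendecomposition (`exp(Qt) = V e^{Λt} V⁻¹`) when the decomposition
reconstructs `Q` to 1e-11 relative accuracy, falling back to
scaling-and-squaring otherwise. Eigen-route results are clipped at 0 to
remove negative round-off. Marginal ancestral probabilities combine the
tipward partials with a rootward ("outside") recursion through the event
tables; each node's vector refers to the ancestor state immediately
rootward of its cladogenetic event and is normalized per node, so scaling
factors cancel. Ties for the most probable range break to the lowest state
index.

## Fitting and model comparison

`fit_ml` maximizes the log-likelihood over `log10 d, log10 e ∈ [−12, 1]`
and (for +j) `j ∈ [0, 3]` with bounded Nelder–Mead from a deterministic
grid of start points (default 5; extra starts drawn from the seeded
generator). Derivative-free search is deliberate: the surface can be
multimodal near the `j` bounds and kinked at the `e = 0` boundary, and
evaluations are cheap at these state-space sizes. Evaluation errors
(e.g. the empty-event-set edge at `j = 3`) are treated as −∞. AIC uses
`k = 2` without *j* and `k = 3` with it; the root prior is not counted.
`compare_models` refuses to tabulate fits carrying different dataset
fingerprints.

## Forward simulator

Trees: birth–death conditioned on the number of extant tips via the
general sampling approach (GSA, growing to twice the target and sampling a
moment with exactly *n* extant lineages uniformly), which gives properly
conditioned trees with strictly positive terminal branches; optional
rescaling to a target root age. Ranges: the root state is drawn from the
flat allowed prior (or fixed), branches evolve by Gillespie event-jump
simulation with the generator switching at stratum boundaries, and each
node draws from its stratum's event table. Histories in which any tip is
absorbed into the null range are, by default, rejected and redrawn so tip
data are always valid — the estimators condition on observed,
range-bearing tips — with a flag to keep such histories (null tips
dropped) for studying exactly that conditioning bias.

The songbird-like fixture emulates the structure of a nine-area oscine
analysis: areas lettered A–I (New Guinea, New Zealand, Australia,
Wallacea, S and SE Asia, sub-Saharan Africa, New World, Palaearctic,
Madagascar), two strata with New Guinea disallowed at ages ≥ 15 Myr, a
104-tip GSA tree rescaled to a 33-Myr (Oligocene) crown age, ranges
evolved under DEC+j (d = 0.02, e = 0.005, j = 0.4, ranges capped at 3
areas) from an Australian root, and two terminal codings: the simulated
terminal range ("total clade distribution") and a single area drawn from
it ("inferred clade origin", always a subset). The tree shape, clade sizes
and rates are synthetic; only the area set, the stratum boundary and the
coding structure follow the real study design, so fixture results
demonstrate constraint *semantics*, not any empirical biogeographic claim.

## Validation experiment designs

- **Enumeration oracle.** 2- and 3-tip trees × 1–3 areas × all six model
  variants × 5 seeded parameter draws (180 cases): pruning must match an
  exhaustive sum over joint assignments of cladogenetic events to internal
  nodes to 1e-10. The enumeration reimplements branch transport with
  directly composed exponentials and sums explicit event combinations, so
  it shares no pruning machinery.
- **Worked toys.** The two cherry datasets with `d = e = 0` whose
  likelihoods are 1/3 and 1/18 by hand enumeration, asserted to 1e-12.
- **Nesting.** On 20 simulated 20-tip datasets, `family+j (j = 0)` must
  equal `family` to 1e-12 for all three families.
- **Recovery / selection.** Pure-birth 200-tip trees rescaled to a 5-Myr
  crown, 3 areas. The depth is chosen so that `d = 0.1`/Myr yields a few
  dispersal events per root-tip path while null-range absorption leaves
  rejection-resampling practical. Recovery: 20 replicates under DEC
  (d = 0.1, e = 0.03), refit with 3 starts; the reported quantities are
  the fractions of replicates with d̂ (resp. ê) within ±50% of truth.
  Selection: 20 replicates under DEC+j (j = 1.5), DEC and DEC+j both fit,
  +j counted as selected when its AIC is lower.
- **Constraint contrast.** Ancestral marginals on the songbird-like
  fixture under its generating parameters, constrained vs naive: every
  node older than 15 Myr must carry exactly zero New-Guinea mass when
  constrained, and the naive mass there is never smaller.
- **Simulator fidelity.** 10⁴ cladogenetic draws for a fixed widespread
  ancestor compared to table probabilities within 3 binomial SE per event,
  and 10⁴ singleton sojourn times tested against the exponential with the
  generator's exit rate (KS, p > 0.01), seeded.

## Calibration densities

- `normal_from_ci(mean, lo, hi)`: sd = (hi − mean)/1.959964 (fixed z for
  reproducibility). Printed secondary calibrations are often slightly
  asymmetric because they summarize non-normal posteriors; the upper
  half-width is used and asymmetry tolerated, so for the (21, 17–26)
  calibration the implied lower endpoint is 16.0 Myr, while the symmetric
  (28, 18–38) calibration reproduces both endpoints exactly.
- `truncated_cauchy(t_min, p, c)`: Cauchy with location `t_min(1+p)`,
  scale `c·t_min`, renormalized over the hard support `[t_min, ∞)`; for
  (24, 1.0, 5.0) the mode is 48 Myr. The minimum is hard — no probability
  below the oldest securely assigned fossil; a soft-tailed variant is not
  implemented. Note the heavy tail: ~4e-5 of the mass lies beyond 10⁶ Myr,
  so normalization checks must integrate the full support.
- `max_bound(t_max)`: uniform on `[0, t_max]`, for hard root maxima.

## Known limitations

- **The extinction rate `e` is weakly identified and boundary-biased.**
  Anagenetic range loss is confounded with subset sympatry/vicariance
  (which shrink daughter ranges at no rate cost), and data conditioned on
  surviving, range-bearing tips — whether by rejection-resampling or by
  pruning range-extinct lineages, i.e. any data a real analysis could
  observe — actively penalize `e` through the likelihood's survival
  factor. In the recovery experiment the reproduction script computes this
  directly: d̂ lands within ±50% of truth in essentially all replicates
  while ê collapses to the 0 boundary, mirroring the familiar "e ≈ 0"
  behavior of DEC fits on real data. Point estimates of `e` from this
  class of models should not be interpreted as extinction rates.
- The likelihood does not condition on survival or sampling, and the
  cladogenetic weights are fixed (no per-event free parameters beyond j).
- Strata change *allowed areas* (and, via multipliers, dispersal rates)
  but diversification itself is independent of range (no GeoSSE-style
  feedback), and jump weighting at boundary-spanning nodes uses the
  node's own stratum.
- The simulator's trees are clean birth–death trees: no fossil sampling,
  no rate variation across clades, no topological error — recovery rates
  measured here are therefore best-case relative to empirical data.
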