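# Methods

## Range space

A range is a subset of `n` discrete areas, stored as a bitmask. The state
space contains the null (empty) range plus every non-empty subset of size at
most `max_range_size`, ordered null first, then by size, then by ascending
bitmask. With nine areas and a cap of four this gives
1 + Σ_{k=1..4} C(9,k) = 256 states. The cap is a computational device: matrix
exponentiation is O(S³) in the number of states S, and 2⁹ = 512 uncapped
states would quadruple that cost while ranges of five or more areas are
rarely estimable anyway.

Composite labels classify a range by which supercontinental blocks it
touches: `Laurasia` (Eurasia, North America), `Gondwana` (the remaining
areas, pivoting on Africa), `Northern Pangaea` (Laurasia plus Africa and/or
Arabia only), and `Pangaea` (both blocks more broadly).

## Anagenetic process

Along a branch of length t the range evolves by a CTMC with generator Q:

- expansion: rate `d × (number of occupied areas)` into each currently
  unoccupied area, provided the cap is not exceeded;
- contraction: rate `e` for the loss of each occupied area;
- the null range is absorbing.

Branch transition matrices are `expm(Q t)` (scipy), clipped to [0, 1] and
cached per distinct branch length.

## Cladogenesis

At each internal node the parent range R splits into an ordered daughter
pair. Event weights follow the standard DEC / DIVALIKE / BAYAREALIKE
constructions; the +J variants add founder events `(R, {b})` and `({b}, R)`
for each area b ∉ R with weight `j` per ordered event, while non-jump events
share the remaining weight `ceiling − j` where the ceiling is 3 (DEC),
2 (DIVALIKE) or 1 (BAYAREALIKE) — so the per-event non-jump weight is
(3−j)/3, (2−j)/2 or 1−j respectively. Weights are normalised to a
probability distribution per parent state. At j = 0 each +J model reduces
exactly to its base family (verified to 1e-10 in the tests).

## Likelihood

Felsenstein pruning over the flat post-order node arrays: each child's
conditional vector is propagated through `P(t) = expm(Q t)`, the two
daughter contributions are combined through the cladogenetic event table
(vectorised with `numpy.bincount` over flattened event arrays), constraint
masks are applied, and the vector is rescaled by its maximum with the log
factor accumulated — so likelihoods far below the smallest normal double
remain representable. The root prior is flat over the non-null states;
cladogenesis is applied at the root as at any other node. An unsatisfiable
constraint yields lnL = −inf rather than an exception.

Correctness oracle: an independent brute-force routine enumerates every
joint assignment of internal-node states and sums
`prior × Π (event prob × P[parent-side, child] …)`. Pruning agrees with it
to ~1e-14 on seeded random instances across all six models; a guard refuses
instances beyond 2×10⁶ assignments.

## Node constraints

A constraint names an MRCA by two or more tips and a set of required areas;
the constrained node's state must contain **all** required areas. Masks are
applied after the cladogenetic combination at that node. Constraints can
only lower the likelihood (masking removes probability mass), which the
tests check on random instances.

## ML estimation and model selection

`fit_ml` maximises lnL with L-BFGS-B over `log10 d, log10 e ∈ [−12, log10 5]`
and, for +J models, `j ∈ [0, ceiling − 1e-5]`. The default start is
d = e = 0.01 (and j = 0.01); additional seeded random restarts are optional
and deterministic given the seed, with ties broken toward the lowest start
index. Rates are floored at 1e-12; because the objective is numerically flat
below ~1e-7, a rate that the data drive to zero is typically returned as
~1e-7–1e-8 rather than exactly at the bound — "effectively zero" is the
correct reading.

Model comparison uses AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1) with n = number
of tips and k = 2 (base) or 3 (+J), Akaike weights, and a one-degree
chi-square likelihood-ratio test for nested pairs.

## Ancestral states and summaries

Marginal state probabilities use a standard two-pass (up/down) algorithm on
the split-point (post-cladogenesis) quantity at each internal node; they
equal `exp(lnL with the node forced to state R − lnL)` (verified to 1e-8
element-wise). Summaries: per-area inclusion proportions (probability mass
of states containing the area), most-probable ranges (lowest state index on
exact ties), dispersal counts between parent/child best ranges (a gained
area's credit is split equally over the parent's occupied areas), per-area
loss counts, and composite-label transition counts.

## Forward simulator

`simulate_tree` draws a Yule tree with exactly the requested number of tips
(final segment stretched by an Exp(nλ) draw so the tree stays ultrametric).
`simulate_history` draws the root range from the flat non-null prior (or a
fixed range), samples a cladogenetic event at each node from the event
table, and simulates the anagenetic CTMC exactly along each branch, logging
every event with timestamps and from/to states. A replicate in which **any**
lineage (internal or tip) reaches the null range is rejected wholesale and
re-run with a new sub-seed (stride 1 000 003 from the base seed); the number
of rejections is reported and a budget exhaustion raises a RuntimeError.
`replay_event_log` reconstructs every node state from the log alone and is
checked for exact agreement in the tests.

Two consequences of the rejection step matter for calibration:

- the accepted-data law is the process **conditioned on no lineage dying**,
  so extirpation events out of single-area ranges never appear in accepted
  logs, and other event frequencies are mildly biased relative to the
  unconditioned rates (the calibration test accounts for this);
- rejection cost grows with total tree length × e. Default birth rate 0.1/Myr
  keeps expected tree depth small relative to the ~1/e-scale absorption time
  at the default e = 0.005; the parameter-recovery experiment uses 0.5/Myr
  for its 300-tip trees for the same reason. These are design choices made
  before the recovery results were inspected, not tuned afterwards.

## Scope and limitations

- Trees must be rooted, binary and fully dated; polytomies are rejected
  rather than resolved.
- Constraints are hard masks, not soft priors, and apply to internal nodes
  only; direct fossil tips are not modelled.
- No distance- or time-stratified dispersal multipliers; d and e are global.
- The root prior is flat over non-null states; no alternative priors are
  exposed.
- AICc uses the tip count as the effective sample size, following common
  practice in this model family; it is a convention, not an estimate of
  information content.
- Simulated data are conditioned on survival of every lineage (see above),
  so simulator output is not an unconditioned draw from the model.
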