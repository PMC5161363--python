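# Methods

## The screening problem

`pavnet` searches the space of small transcription-regulation networks for
topologies that robustly perform a Pavlovian-like conditioning function, and
scales the search up by *sub-network combination*: the whole function is
split into a **learning module** (memory switches on only when food and ring
signals co-occur, and persists after they are removed) and a **recall
module** (salivation fires for food alone, or for memory and ring together),
each small enough for exhaustive three-node enumeration.  Robust
sub-networks are then merged pairwise, under logical-consistency rules, into
whole-network candidates that are screened for the combined function.

Robustness of a topology is its **Q-value**: the fraction of parameter sets,
drawn by Latin-hypercube sampling over broad kinetic ranges, under which the
network's dynamics realize the target truth table.

## Dynamics

Each node carries a concentration `A_i(t)`.  Regulation uses Hill kinetics:

* activation `i -> j`:  `V_ij * H(A_i, k_ij, n_ij)` with
  `H(x, T, n) = x^n / (x^n + T^n)`;
* inhibition `i -> j`:  `k_ij * K_ij^n / (K_ij^n + alpha_ij * A_i^n)` — note
  the basal production `k_ij` when the inhibitor is absent;
* degradation: `-eta_j * A_j`.

Activating inputs to one node are **multiplied** (continuous AND) and
inhibiting inputs are **summed** (continuous OR).  A node with no incoming
regulation of any kind has zero production: basal expression only enters
through an inhibition term's `k`.  The empty-product convention (production
1 for unregulated nodes) is deliberately not used — an unregulated,
unsignaled gene has no transcription source.

Sampling ranges (defaults, log-uniform unless noted): `V` in [1e-3, 1e2],
`k` in [1e-6, 1], `K` in [1e-3, 10], `alpha` in [0, 1] (linear), `eta` in
[1e-12, 1], Hill `n` in [1, 3] (linear, continuous; an integer mode is
available through `ParameterRanges(integer_n=True)`).  The Hill coefficient
is sampled continuously because nothing in the model requires integrality
and a log scale over half a decade adds nothing.

## External signals

Signals (food, ring, memory) are clamped species: level `S_on = 1` during a
phase that switches them on, 0 otherwise.  A multiplicative signal acts on
its receptor node in two coupled ways:

1. **drive** — it enters the receptor's activation product through its own
   sampled kinetics `V_s * H(S, k_s, n_s)`, so a signaled receptor is
   produced;
2. **gating** — every regulation *sourced at* the receptor uses the
   effective concentration `A_i * s(t)`.  The signal is the ligand that
   activates the transcription factor, not merely its inducer: without it
   the receptor protein is present but regulatorily silent.

The gating half is essential for the screen to behave sensibly.  Initial
conditions place up to 50 concentration units on input nodes; the sampled
half-max constants (`k <= 1`) sit far below that, so without gating any
leftover receptor protein would saturate its targets and the no-signal
baseline would be indistinguishable from the signaled state — the simplest
conditioning designs, which demonstrably work, would be impossible.  With
gating, the baseline response of every signal path is exactly zero whatever
the initial condition, which is also the biologically standard picture of
signal-dependent transcription-factor activity.

The recall module's food signal is **additive** at the F&S output node (the
OR branch of salivation): an independent production source
`V_s * H(S, k_s, n_s)` that does not gate the node.  The ring and memory
signals are multiplicative.  In a combined network there is no external
memory signal — the learning module's memory output drives the recall
memory input, either as a fused node or through an added activating edge.

## Steady states, on/off calls, and the screening protocol

Simulations run to `t_end = 10000` time units (LSODA, rtol 1e-6, atol 1e-9,
unit-grid sampling; the adaptive integrator replaces a fixed 1e-4 step that
would cost 1e8 steps per run, and agrees on these smooth Hill dynamics).
Output values are judged on the window [9000, 10000]:

* `y0` is the window mean.  **Baseline and expected-off outputs** must
  additionally satisfy the steady band: every window sample within
  `1% * y0` of the mean.  A window lying entirely below 1e-9 (the
  integrator's absolute tolerance) is steady at 0.
* **Expected-on outputs** report `y0` as their plateau without the band.  A
  memory held by very slow dilution is still charging linearly at the end
  of training; demanding a strict plateau there would exclude exactly the
  feed-forward conditioning designs the screen is supposed to find, because
  a plateau by t = 10000 forces `eta >= ~5e-4`, which decays to nothing
  long before the persistence checkpoint.

Every condition is simulated from 10 random initial states (non-output
nodes uniform on [0, 50]; output nodes at 0.1, low by construction), all
integrated as one batched ODE system.  All runs must agree on each judged
output within 1% relative (else the set is rejected as multistable).

On/off calls use the ratio of a condition's output over the no-signal
baseline, with a 1e-12 floor on the denominator: off below 5, on above 15
for sub-modules (5 and 10 for combined networks); a ratio between the
thresholds is not switch-like and fails the parameter set.  All stages
short-circuit on the first failure; the verdict records the failing stage
(`no-steady-state`, `multistable`, `indeterminate-ratio`, `truth-table`,
`persistence`, `sim-failed` — integrator failure counts as a failed set).

**Learning test**: baseline; food only -> off; ring only -> off; food+ring
-> on with plateau `y0`; then, continuing from the trained state with
signals removed, the output must retain at least `0.8 * y0` after 50000
further time units.  **Recall test**: food -> on; memory -> off; ring ->
off; memory+ring -> on (no persistence stage).  **Combined (Pavlovian)
test**: baseline for both outputs; food -> memory off, salivation on;
ring -> both off; food+ring -> memory on; persistence of the memory; and,
continuing from the persistent state, ring alone -> salivation on.
Conditions share one baseline simulation; only the persistence and
post-training stages are continuations, which is the physiologically
literal reading of training followed by a later probe.

## Sampling and reproducibility

One Latin hypercube is drawn per topology per screen: each scalar dimension
(five kinetic fields per edge, one degradation rate per node, five fields
per signal term) is stratified into `n_sets` equal-probability bins hit
exactly once, on the log scale for log-range parameters.  The hypercube
seed is `master_seed XOR canonical_topology_ID` (mod 2^31), so screens over
many topologies are mutually independent but fully determined by one seed;
each parameter set's initial conditions derive from (stream seed, set
index).  Identical inputs give bit-identical results regardless of worker
scheduling, because results are merged in canonical-ID order.

## Combination rules

A merge map fuses 1–3 learning nodes with recall nodes (injective on both
sides; 9 / 18 / 6 maps at arity 1 / 2 / 3 before filtering).  A merge is
rejected when

* a fused pair makes one node both a food receiver (food input or F&S) and
  a ring receiver, or fuses the learning memory output with the recall
  salivation output (role constraints; 6 / 8 / 2 maps survive for the
  canonical role layouts);
* any ordered pair of fused slots carries activation in one module and
  inhibition in the other (self-edges included);
* the added memory link's slot already carries inhibition in the edge
  union.  The link — an activating edge from the learning memory output to
  the recall memory input — is added whenever those two nodes are not fused
  with each other; a slot already unioned to inhibition would contradict
  it.  (This corner only arises when a memory node is fused with some third
  node.)

The combined network keeps the union of both edge sets.  Fused receptor
nodes receive a single signal term per signal.  Combinations are counted
per provenance (learning ID, recall ID, merge map) without deduplicating
identical merged graphs.

## Regulation entropy

For each node with incoming edges, the Shannon entropy (base 2) of the
activation/inhibition split among its in-edges (self-edges included); the
network score is the mean over regulated nodes, 0 for an edgeless network.
This directly measures sign conflict among convergent regulations, which
is what the combination rules suppress: logically valid combined networks
score well below size-matched unconstrained random networks (each ordered
pair uniform over the three states).  The directional ordering, not any
particular numeric value, is the supported claim.

## Problem sizes

The full-scale screen (19683 topologies x 10^4 parameter sets per
module, then ~10^4–10^5 combined candidates) is a multi-core, multi-day
computation; `scripts/full_scale.py` is the one-command driver for it.
The test suite and `scripts/acceptance.py` run scaled-down versions chosen
to resolve the qualitative results on one CPU in minutes: 500-set screens
establish the zero Q-values of empty topologies, 1000–2000-set screens
resolve the positive Q-values of the canonical designs (the whole-function
pass rate is roughly an order of magnitude below the sub-function rates,
hence the larger draw there), and combination logic is verified exhaustively
on small random pools against a brute-force oracle.

## Known limitations

* The gating signal model and the on-state plateau policy are this
  package's resolutions of genuinely underdetermined protocol details; both
  are chosen to make the canonical feed-forward conditioning designs
  feasible, as they must be, and are documented above rather than hidden.
* Q-values under these conventions are internally consistent but their
  absolute scale should not be compared against other implementations of
  similar screens without aligning the signal and steadiness conventions.
* Only transcription-style noncompetitive activation/inhibition kinetics
  are implemented; protein–protein interaction variants, stochastic
  dynamics, and combinations of more than two sub-networks are out of
  scope.
* A salivation output with near-zero degradation can carry a stale high
  value from the training phase into the post-training probe under the
  continuation protocol; the screen accepts this as written.
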