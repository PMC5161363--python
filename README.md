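# pavnet

Enumerating and combining regulatory sub-networks that perform a
Pavlovian-like conditioning function.

## The problem

Given a biological function, which network topologies can perform it
robustly?  Exhaustive enumeration answers this for three-node
transcription networks — all 19683 (3^9) signed directed topologies — but
becomes hopeless beyond that (3^16 ≈ 4.3·10^7 four-node candidates).
`pavnet` implements the *sub-network combination* strategy: split a complex
function into sub-functions small enough for three-node enumeration, screen
each sub-space for robust sub-networks, then merge pairs of robust
sub-networks under logical-consistency rules into whole-network candidates
and screen those for the combined function.

The instantiated function is classical conditioning.  A **learning module**
turns a persistent memory on only when the food and ring signals co-occur;
a **recall module** drives salivation for food alone or for memory+ring
together (its food receiver and salivation output share one node, F&S).
Merged networks must reproduce the whole behavior: food always salivates,
and ring alone salivates only after food+ring training has latched the
memory.

## The statistic

Each topology's dynamics follow Hill-function ODEs

    dA_j/dt = [ ∏ activators  V·H(A_i, k, n) ] + [ Σ inhibitors  k·K^n/(K^n + α·A_i^n) ] − η_j·A_j,
    H(x, T, n) = x^n / (x^n + T^n),

with activating inputs multiplied (AND-like) and inhibiting inputs summed
(OR-like).  A topology's robustness is its **Q-value**: the fraction of
Latin-hypercube parameter sets (log-scale over broad kinetic ranges) whose
dynamics pass the function's truth-table protocol — unique steady outputs
over 10 random initial conditions, on/off output ratios of 15/5 (10/5 for
combined networks) against the no-signal baseline, and 80% memory retention
50000 time units after the training signals are removed.  Pools of robust
sub-networks (Q > 0.007 learning, Q > 0.008 recall) feed the combination
stage.  See `docs/methods.md` for the full model, the signal conventions,
and every threshold.

## Worked example

```python
from pavnet import compute_q, test_learning
from pavnet.cli_io import simplest_learning_topology
from pavnet.topology import encode_id

t = simplest_learning_topology()          # R->M and F->M activation
print("canonical ID:", encode_id(t))
r = compute_q(t, test_learning, n_sets=200, seed=1)
print(f"learning Q-value: {r.q:.3f}  ({r.n_pass}/{r.n_sets} parameter sets)")
```

prints

```
canonical ID: 756
learning Q-value: 0.510  (102/200 parameter sets)
```

Topology 756 is the simplest learning design — each input node activates
the memory node — and about half of the sampled kinetics realize the
conditioning truth table with it, most passes holding the memory through
slow dilution of the output after the gated inputs shut off.  An empty
topology under the same screen scores exactly 0.

The same machinery runs from the shell:

```
pavnet enumerate-module --function learning --n-sets 10000 --out results/learning
pavnet enumerate-module --function recall   --n-sets 10000 --out results/recall
pavnet combine --learning-pool results/learning.pool.json \
               --recall-pool results/recall.pool.json --arity 1 --out results/arity1.tsv
pavnet test-pavlovian --learning-pool results/learning.pool.json \
               --recall-pool results/recall.pool.json --arity 1 \
               --out results/arity1.screened.tsv
pavnet report --pool results/learning.pool.json --out results/learning.report.json
```

`scripts/full_scale.py --out results/full --workers N` is the one-command
driver for the complete full-scale pipeline (all 19683 topologies per
module at 10^4 parameter sets, then every logically possible one-, two- and
three-node combination); at full scale it is a multi-core, multi-day run,
and `--limit/--n-sets` scale it down for smoke testing.

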