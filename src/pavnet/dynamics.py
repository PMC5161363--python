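"""Transcription-regulation ODE dynamics for signed network topologies.

Each node *i* carries a concentration ``A_i``.  Regulation follows standard
Hill kinetics:

* activation of *j* by *i* contributes ``V * H(A_i, k, n)`` with the Hill
  function ``H(x, T, n) = x^n / (x^n + T^n)``;
* inhibition contributes ``k * K^n / (K^n + alpha * A_i^n)`` — note the basal
  production ``k`` when the inhibitor is absent;
* every node degrades as ``-eta_i * A_i``.

Composition implements continuous logic: activating inputs to one node (and
multiplicative external-signal terms) are **multiplied** (AND-like), while
inhibiting inputs (and additive signal terms) are **summed** (OR-like).  A
node with no activating input, no multiplicative signal, no inhibitor and no
additive signal has zero production: an unregulated gene has no transcription
source here, basal expression only ever enters through the inhibition term's
``k``.

External signals (food / ring / memory) are clamped species, level
``S_on`` while a phase switches them on and 0 otherwise.  A multiplicative
signal acts on its receptor node in two ways: it drives the node's
production through its own kinetic parameters as an activation term in the
node's product, and it gates the node's regulatory *activity* — every
regulation sourced at the receptor uses the effective concentration
``A_i * s(t)`` instead of ``A_i``.  A receptor whose signal is absent
therefore transmits nothing downstream, whatever protein is left over from
the initial condition: the signal is the ligand that activates the
transcription factor, not just its inducer.  An additive signal (the recall
food input at the salivation node) is an independent production source and
does not gate its node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .topology import NodeRole, Topology, RegulationSign

__all__ = [
    "SIGNALS",
    "EdgeParams",
    "NodeParams",
    "ParameterSet",
    "SignalEdge",
    "InputSchedule",
    "Trajectory",
    "SimulationError",
    "derive_signal_edges",
    "hill",
    "activation_term",
    "inhibition_term",
    "build_production",
    "simulate",
    "CompiledSystem",
    "RTOL",
    "ATOL",
    "S_ON",
]

#: External signal names recognized by schedules and signal wirings.
SIGNALS = ("food", "ring", "memory")

#: Integrator tolerances (adaptive stiff-capable LSODA with unit-grid output).
RTOL = 1e-6
ATOL = 1e-9

#: Clamped level of an external signal while switched on.
S_ON = 1.0


class SimulationError(RuntimeError):
    """Integration failed (stiffness breakdown or non-finite state)."""


@dataclass(frozen=True)
class EdgeParams:
    """Kinetic parameters of one regulation edge (or signal term).

    ``V``: maximal production rate; ``k``: activation half-max *or* inhibition
    production scale depending on the edge sign; ``K``: inhibition
    coefficient; ``alpha``: inhibition weight in [0, 1]; ``n``: Hill
    coefficient.  Activation uses (V, k, n); inhibition uses (k, K, alpha, n).
    """

    V: float
    k: float
    K: float
    alpha: float
    n: float


@dataclass(frozen=True)
class NodeParams:
    """Per-node first-order degradation rate ``eta``."""

    eta: float


@dataclass
class ParameterSet:
    """One draw of the parameter hypercube for a given topology.

    ``edge_params`` maps each non-none adjacency entry ``(i, j)`` to its
    :class:`EdgeParams`; ``node_params`` maps every node to its degradation;
    ``signal_params`` maps ``(signal name, receiving node)`` to the kinetics
    of that external-signal activation term.
    """

    edge_params: dict[tuple[int, int], EdgeParams]
    node_params: dict[int, NodeParams]
    signal_params: dict[tuple[str, int], EdgeParams] = field(default_factory=dict)


@dataclass(frozen=True)
class SignalEdge:
    """Wiring of one external signal onto one node.

    ``additive=False`` composes the signal term into the node's activation
    product (AND-like); ``additive=True`` adds it as an independent source
    (the recall food signal at the salivation output).
    """

    signal: str
    node: int
    additive: bool = False


@dataclass
class InputSchedule:
    """Piecewise-constant signal protocol: list of ``(duration, levels)``."""

    phases: list[tuple[float, dict[str, float]]]

    def __post_init__(self) -> None:
        for dur, _levels in self.phases:
            if dur <= 0:
                raise ValueError("phase durations must be positive")

    @property
    def t_end(self) -> float:
        return float(sum(d for d, _ in self.phases))


@dataclass
class Trajectory:
    """Sampled solution: ``times`` (T,) and ``states`` (T, n_nodes)."""

    times: np.ndarray
    states: np.ndarray


def derive_signal_edges(t: Topology) -> list[SignalEdge]:
    """Default external-signal wiring implied by a topology's node roles.

    Ring and food inputs receive their signals multiplicatively; the recall
    F&S node additionally receives the food signal additively.  An external
    memory signal is wired to a ``memory_input`` node only when the topology
    has no ``memory_output`` node of its own (i.e. a standalone recall
    module); in a combined network the learning module supplies the memory.
    """
    has_memory_source = any(r is NodeRole.MEMORY_OUTPUT for r in t.roles.values())
    edges: list[SignalEdge] = []
    for i in sorted(t.roles):
        role = t.roles[i]
        if role is NodeRole.RING_INPUT:
            edges.append(SignalEdge("ring", i, additive=False))
        elif role is NodeRole.FOOD_INPUT:
            edges.append(SignalEdge("food", i, additive=False))
        elif role is NodeRole.OUTPUT_FS:
            edges.append(SignalEdge("food", i, additive=True))
        elif role is NodeRole.MEMORY_INPUT and not has_memory_source:
            edges.append(SignalEdge("memory", i, additive=False))
    return edges


# ----------------------------------------------------------------------
# Closed-form regulation terms


def hill(x: float, T: float, n: float) -> float:
    """Hill function ``x^n / (x^n + T^n)``; half-max at ``x = T``."""
    if T <= 0:
        raise ValueError("Hill half-max T must be positive")
    if x < 0:
        raise ValueError("concentration must be nonnegative")
    if x == 0.0:
        return 0.0
    xn = x**n
    return xn / (xn + T**n)


def activation_term(A_i: float, p: EdgeParams) -> float:
    """Production from a positive regulation: ``V * H(A_i, k, n)``."""
    return p.V * hill(A_i, p.k, p.n)


def inhibition_term(A_i: float, p: EdgeParams) -> float:
    """Production under a negative regulation: ``k * K^n / (K^n + alpha * A_i^n)``.

    Equals the basal rate ``k`` when the inhibitor is absent (``A_i = 0``) or
    unweighted (``alpha = 0``); decreases toward 0 as ``A_i`` grows.
    """
    Kn = p.K**p.n
    return p.k * Kn / (Kn + p.alpha * max(A_i, 0.0) ** p.n)


def build_production(
    t: Topology,
    params: ParameterSet,
    node: int,
    state: Sequence[float],
    signals: Mapping[str, float] | None = None,
    additive_signals: Iterable[tuple[str, int]] = (),
    gates: Mapping[int, float] | None = None,
) -> float:
    """Total production rate of *node* at the given state and signal levels.

    Activating edges and multiplicative signal terms multiply together;
    inhibiting edges and additive signal terms sum.  With no incoming
    regulation of any kind the production is zero.  ``gates`` maps a source
    node to its activity factor (the level of the signal gating it); absent
    entries default to 1.
    """
    signals = dict(signals or {})
    additive = set(additive_signals)
    gates = dict(gates or {})
    factors: list[float] = []
    total = 0.0
    for i in range(t.n_nodes):
        s = t.sign(i, node)
        x = float(state[i]) * float(gates.get(i, 1.0))
        if s is RegulationSign.ACTIVATION:
            factors.append(activation_term(x, params.edge_params[(i, node)]))
        elif s is RegulationSign.INHIBITION:
            total += inhibition_term(x, params.edge_params[(i, node)])
    for (sig, nd), p in sorted(params.signal_params.items()):
        if nd != node:
            continue
        level = float(signals.get(sig, 0.0))
        term = activation_term(level, p)
        if (sig, nd) in additive:
            total += term
        else:
            factors.append(term)
    if factors:
        total += float(np.prod(factors))
    return total


# ----------------------------------------------------------------------
# Compiled right-hand side for fast (batched) integration


class CompiledSystem:
    """Pre-compiled ODE right-hand side for one (topology, parameter set).

    Flattens the regulation structure into term arrays so the RHS costs a
    handful of vectorized operations, and supports integrating a *batch* of
    initial conditions as independent copies of the same vector field (used
    for the multi-initial-condition convergence test).
    """

    def __init__(
        self,
        t: Topology,
        params: ParameterSet,
        signal_edges: Sequence[SignalEdge] = (),
    ) -> None:
        n = t.n_nodes
        self.n_nodes = n
        self.eta = np.array(
            [params.node_params[i].eta for i in range(n)], dtype=float
        )
        # per node: activation terms (src, V, k^n, n) and inhibition terms
        self.act: list[np.ndarray] = []
        self.inh: list[np.ndarray] = []
        for j in range(n):
            a_rows, i_rows = [], []
            for i in range(n):
                s = int(t.adjacency[i, j])
                if s == RegulationSign.ACTIVATION:
                    p = params.edge_params[(i, j)]
                    a_rows.append((i, p.V, p.k**p.n, p.n))
                elif s == RegulationSign.INHIBITION:
                    p = params.edge_params[(i, j)]
                    i_rows.append((i, p.k, p.K**p.n, p.alpha, p.n))
            self.act.append(np.array(a_rows, dtype=float).reshape(-1, 4))
            self.inh.append(np.array(i_rows, dtype=float).reshape(-1, 5))
        # signal wiring: constants recomputed per phase from the levels
        self.signal_edges = list(signal_edges)
        for e in self.signal_edges:
            if (e.signal, e.node) not in params.signal_params:
                raise KeyError(f"missing signal params for {(e.signal, e.node)}")
        self.params = params
        # nodes with a multiplicative production part (activation edges and/or
        # multiplicative signal terms); all others have product part 0
        self.has_product = np.array(
            [
                self.act[j].shape[0] > 0
                or any(e.node == j and not e.additive for e in self.signal_edges)
                for j in range(n)
            ]
        )

    # -- phase constants -----------------------------------------------
    def _phase_constants(
        self, levels: Mapping[str, float]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-node (signal production factor, additive source, activity gate).

        The gate of a receptor node is the level of its multiplicative
        signal(s); nodes without a multiplicative signal are ungated (1).
        """
        n = self.n_nodes
        mult = np.ones(n)
        add = np.zeros(n)
        gate = np.ones(n)
        for e in self.signal_edges:
            p = self.params.signal_params[(e.signal, e.node)]
            level = float(levels.get(e.signal, 0.0))
            term = activation_term(level, p)
            if e.additive:
                add[e.node] += term
            else:
                mult[e.node] *= term
                gate[e.node] *= level
        return mult, add, gate

    def rhs(self, levels: Mapping[str, float], batch: int):
        """Vector field for *batch* independent copies under constant levels."""
        n = self.n_nodes
        mult, add, gate = self._phase_constants(levels)
        eta = self.eta
        act, inh = self.act, self.inh
        has_prod = self.has_product

        def f(_t: float, y: np.ndarray) -> np.ndarray:
            A = y.reshape(batch, n)
            A = np.where(A > 0.0, A, 0.0)
            dA = -(A * eta)
            Aeff = A * gate
            for j in range(n):
                if has_prod[j] and mult[j] > 0.0:
                    p = np.full(batch, mult[j])
                    for i, V, kn, hn in act[j]:
                        x = Aeff[:, int(i)] ** hn
                        p *= V * x / (x + kn)
                    dA[:, j] += p
                terms = inh[j]
                for i, k, Kn, alpha, hn in terms:
                    x = Aeff[:, int(i)] ** hn
                    dA[:, j] += k * Kn / (Kn + alpha * x)
                if add[j]:
                    dA[:, j] += add[j]
            return dA.ravel()

        return f

    # -- integration -----------------------------------------------------
    def integrate(
        self,
        levels: Mapping[str, float],
        inits: np.ndarray,
        t_eval: np.ndarray,
        t_span: tuple[float, float] | None = None,
    ) -> np.ndarray:
        """Integrate a batch of initial conditions under constant signals.

        Parameters
        ----------
        inits
            ``(batch, n_nodes)`` initial concentrations.
        t_eval
            Sample times (relative to the phase start at 0).

        Returns
        -------
        ``(batch, len(t_eval), n_nodes)`` states, clamped at 0 from below.
        """
        inits = np.atleast_2d(np.asarray(inits, dtype=float))
        batch = inits.shape[0]
        t_eval = np.asarray(t_eval, dtype=float)
        if t_span is None:
            t_span = (0.0, float(t_eval[-1]))
        sol = solve_ivp(
            self.rhs(levels, batch),
            t_span,
            inits.ravel(),
            method="LSODA",
            t_eval=t_eval,
            rtol=RTOL,
            atol=ATOL,
        )
        if not sol.success or not np.isfinite(sol.y).all():
            raise SimulationError(sol.message)
        out = sol.y.T.reshape(len(t_eval), batch, self.n_nodes).transpose(1, 0, 2)
        return np.maximum(out, 0.0)


# ----------------------------------------------------------------------
# Public phase-by-phase simulation


def simulate(
    t: Topology,
    params: ParameterSet,
    schedule: InputSchedule,
    init: Sequence[float],
    t_end: float | None = None,
    signal_edges: Sequence[SignalEdge] | None = None,
) -> Trajectory:
    """Integrate one topology/parameter set through a signal schedule.

    The state is continuous across phase boundaries; the trajectory is
    sampled on the unit time grid from 0 to ``t_end`` (default: the schedule
    length).  Integration failure raises :class:`SimulationError`, which
    screening callers treat as a failed parameter set.
    """
    init = np.asarray(init, dtype=float)
    if (init < 0).any():
        raise ValueError("initial concentrations must be nonnegative")
    if t_end is None:
        t_end = schedule.t_end
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if signal_edges is None:
        signal_edges = derive_signal_edges(t)
    system = CompiledSystem(t, params, signal_edges)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    t0 = 0.0
    state = init.copy()
    for phase_idx, (dur, levels) in enumerate(schedule.phases):
        if t0 >= t_end:
            break
        dur = min(dur, t_end - t0)
        # unit grid within the phase, including both endpoints
        rel = np.arange(0.0, dur + 0.5, 1.0)
        if rel[-1] < dur:
            rel = np.append(rel, dur)
        states = system.integrate(levels, state[None, :], rel, t_span=(0.0, dur))[0]
        state = states[-1].copy()
        keep = slice(0, None) if phase_idx == 0 else slice(1, None)
        times_out.append(rel[keep] + t0)
        states_out.append(states[keep])
        t0 += dur
    return Trajectory(np.concatenate(times_out), np.concatenate(states_out))
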