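"""Functional screening: does a (topology, parameter set) realize the
learning or recall behavior, and how robustly (Q-value)?

A parameter set passes a function test when, for every input condition, the
output settles to a unique steady state across random initial conditions and
the on/off pattern of output ratios matches the module's truth table.  The
Q-value of a topology is the fraction of Latin-hypercube parameter sets that
pass — the robustness statistic of the screen.

Protocol details (defaults):

* simulations run to ``t_end = 10000`` time units; outputs are judged on
  the window [9000, 10000] at unit sampling.  Baseline and expected-off
  outputs must hold a steady band: every sample within 1% of the window
  mean (values below an absolute floor of 1e-9 count as zero, steady at 0).
  Expected-on outputs take the window mean as their plateau value ``y0``
  without the band — a memory held by very slow degradation is still
  charging at the end of the training phase, and the screen accepts it as
  long as all initial conditions agree;
* each condition starts from 10 random initial states, non-output nodes
  uniform on [0, 50] and output nodes at 0.1; all runs must converge to the
  same steady output (1% relative agreement);
* output state is the ratio of the condition's steady output over the
  no-signal baseline: off below 5, on above 15 for sub-modules (5/10 for
  combined networks), in between the set is excluded as not switch-like;
* learning only: after the food+ring plateau, signals are removed and the
  output must retain at least 80% of the plateau after 50000 further time
  units (memory persistence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .dynamics import (
    CompiledSystem,
    ParameterSet,
    S_ON,
    SignalEdge,
    SimulationError,
    Trajectory,
)
from .sampling import (
    DEFAULT_RANGES,
    ParameterRanges,
    derive_signal_edges,
    sample_parameters,
    topology_seed,
)
from .topology import NodeRole, Topology, encode_id

__all__ = [
    "SteadyStateCriterion",
    "RatioThresholds",
    "PersistenceRule",
    "EvalSettings",
    "Verdict",
    "QResult",
    "detect_steady_state",
    "converged_unique_state",
    "output_state",
    "test_learning",
    "test_recall",
    "compute_q",
    "select_pool",
    "draw_inits",
    "unique_steady_outputs",
    "StageFailure",
]


# ----------------------------------------------------------------------
# Criteria and configuration


@dataclass(frozen=True)
class SteadyStateCriterion:
    """Window-based steadiness: all samples within ``rel_tol`` of the mean."""

    window: tuple[float, float] = (9000.0, 10000.0)
    rel_tol: float = 0.01
    zero_floor: float = 1e-9

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


@dataclass(frozen=True)
class RatioThresholds:
    """On/off classification of the output ratio; between them is excluded."""

    off_max: float = 5.0
    on_min: float = 15.0

    def __post_init__(self) -> None:
        if self.off_max > self.on_min:
            raise ValueError("off_max must not exceed on_min")


@dataclass(frozen=True)
class PersistenceRule:
    """Memory retention after signal removal."""

    t_check: float = 50000.0
    retain_frac: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.retain_frac <= 1:
            raise ValueError("retain_frac must be in (0, 1]")


@dataclass(frozen=True)
class EvalSettings:
    """All knobs of the functional screen (defaults = sub-module settings)."""

    t_end: float = 10000.0
    steady: SteadyStateCriterion = field(default_factory=SteadyStateCriterion)
    ratios: RatioThresholds = field(default_factory=RatioThresholds)
    persistence: PersistenceRule = field(default_factory=PersistenceRule)
    n_inits: int = 10
    init_high: float = 50.0
    output_init: float = 0.1
    s_on: float = S_ON
    agree_tol: float = 0.01
    ratio_eps: float = 1e-12

    def for_combined(self) -> "EvalSettings":
        """Combined-network variant: on/off thresholds 5 and 10."""
        return replace(self, ratios=RatioThresholds(off_max=5.0, on_min=10.0))


DEFAULT_SETTINGS = EvalSettings()


@dataclass(frozen=True)
class Verdict:
    """Pass/fail of one parameter set, with the stage that rejected it."""

    passed: bool
    failure_stage: str = "none"

    def __post_init__(self) -> None:
        if self.passed and self.failure_stage != "none":
            raise ValueError("a passing verdict has no failure stage")


@dataclass(frozen=True)
class QResult:
    """Aggregated robustness of one topology under one function test."""

    topology_id: int
    n_sets: int
    n_pass: int

    @property
    def q(self) -> float:
        return self.n_pass / self.n_sets


class StageFailure(Exception):
    """Internal control flow: a screening stage rejected the parameter set."""

    def __init__(self, stage: str):
        super().__init__(stage)
        self.stage = stage


# ----------------------------------------------------------------------
# Steady-state machinery


def _steady_value(
    ys: np.ndarray, crit: SteadyStateCriterion, require_band: bool = True
) -> float | None:
    """Steady value of a sampled window, or None if not steady.

    With ``require_band`` every sample must lie within ``rel_tol`` of the
    window mean; without it the window mean itself is returned (the plateau
    value ``y0`` of a switched-on output, which may still be charging when
    its degradation is slow).
    """
    if np.all(np.abs(ys) <= crit.zero_floor):
        return 0.0
    y0 = float(ys.mean())
    if y0 <= 0:
        return None
    if not require_band:
        return y0
    if np.all(np.abs(ys - y0) < crit.rel_tol * y0):
        return y0
    return None


def detect_steady_state(
    traj: Trajectory, node: int, crit: SteadyStateCriterion = SteadyStateCriterion()
) -> float | None:
    """Steady value of one node over the criterion window, or None.

    The window mean is ``y0``; the node is steady iff every unit-grid sample
    in the window lies within ``rel_tol * y0`` of it.  A window that sits
    entirely below the absolute zero floor is steady at 0.
    """
    w0, w1 = crit.window
    mask = (traj.times >= w0) & (traj.times <= w1)
    if not mask.any():
        raise ValueError("trajectory does not span the steady-state window")
    return _steady_value(traj.states[mask, node], crit)


def _window_grid(settings: EvalSettings) -> np.ndarray:
    w0, w1 = settings.steady.window
    grid = np.arange(w0, w1 + 0.5, 1.0)
    if grid[-1] < settings.t_end:
        grid = np.append(grid, settings.t_end)
    return grid


def draw_inits(
    n_nodes: int,
    output_nodes: Iterable[int],
    n_inits: int,
    rng: np.random.Generator,
    high: float = 50.0,
    output_init: float = 0.1,
) -> np.ndarray:
    """Random initial conditions: outputs fixed low, other nodes on [0, high]."""
    inits = rng.uniform(0.0, high, size=(n_inits, n_nodes))
    for j in output_nodes:
        inits[:, j] = output_init
    return inits


def unique_steady_outputs(
    system: CompiledSystem,
    levels: dict[str, float],
    inits: np.ndarray,
    output_nodes: Sequence[int],
    settings: EvalSettings,
    band_nodes: Sequence[int] | None = None,
) -> tuple[dict[int, float], np.ndarray]:
    """Steady output values common to all initial conditions.

    Output nodes listed in ``band_nodes`` (default: all) must satisfy the
    full 1% window band; the others — outputs expected to have switched on,
    which may still be charging toward a distant fixed point — report the
    window mean as their plateau value.  Raises :class:`StageFailure` with
    stage ``no-steady-state`` when a banded node drifts, or ``multistable``
    when runs disagree (beyond 1% relative) on a value.  Returns the common
    values and the final full state of the first run (used to continue the
    persistence phase from the trained plateau).
    """
    grid = _window_grid(settings)
    banded = set(output_nodes if band_nodes is None else band_nodes)
    try:
        states = system.integrate(levels, inits, grid, t_span=(0.0, settings.t_end))
    except SimulationError as exc:
        raise StageFailure("sim-failed") from exc
    w_mask = grid <= settings.steady.window[1]
    values: dict[int, float] = {}
    for node in output_nodes:
        vals = []
        for b in range(states.shape[0]):
            v = _steady_value(
                states[b, w_mask, node], settings.steady, require_band=node in banded
            )
            if v is None:
                raise StageFailure("no-steady-state")
            vals.append(v)
        arr = np.array(vals)
        if np.all(arr <= settings.steady.zero_floor):
            values[node] = 0.0
            continue
        mean = float(arr.mean())
        if mean <= 0 or np.any(np.abs(arr - mean) >= settings.agree_tol * mean):
            raise StageFailure("multistable")
        values[node] = mean
    return values, states[:, -1, :][0].copy()


def converged_unique_state(
    t: Topology,
    params: ParameterSet,
    levels: dict[str, float],
    n_inits: int = 10,
    seed: int = 0,
    settings: EvalSettings = DEFAULT_SETTINGS,
    signal_edges: Sequence[SignalEdge] | None = None,
) -> float:
    """Common steady output over random initial conditions, for one condition.

    Convenience wrapper over the batched machinery; raises
    :class:`StageFailure` on non-convergence or multistability.
    """
    if signal_edges is None:
        signal_edges = derive_signal_edges(t)
    out = _output_node(t)
    system = CompiledSystem(t, params, signal_edges)
    rng = np.random.default_rng(seed)
    inits = draw_inits(
        t.n_nodes, [out], n_inits, rng, settings.init_high, settings.output_init
    )
    values, _final = unique_steady_outputs(system, levels, inits, [out], settings)
    return values[out]


# ----------------------------------------------------------------------
# Output classification


def output_state(y_on: float, y_off: float, thr: RatioThresholds) -> str:
    """Classify an output as 'on', 'off' or 'indeterminate' by its ratio.

    The ratio is ``y_on / max(y_off, eps)`` with a 1e-12 floor so a baseline
    at numerical zero does not divide out.
    """
    ratio = y_on / max(y_off, 1e-12)
    if ratio < thr.off_max:
        return "off"
    if ratio > thr.on_min:
        return "on"
    return "indeterminate"


def _require_state(y_on: float, y_off: float, thr: RatioThresholds, want: str) -> None:
    got = output_state(y_on, y_off, thr)
    if got == want:
        return
    raise StageFailure("indeterminate-ratio" if got == "indeterminate" else "truth-table")


def _output_node(t: Topology) -> int:
    for role in (NodeRole.MEMORY_OUTPUT, NodeRole.OUTPUT_FS):
        try:
            return t.node_with_role(role)
        except KeyError:
            continue
    raise KeyError("topology has no output role")


# ----------------------------------------------------------------------
# Function tests


def test_learning(
    t: Topology,
    params: ParameterSet,
    settings: EvalSettings = DEFAULT_SETTINGS,
    init_rng: np.random.Generator | None = None,
) -> Verdict:
    """Learning-module truth table plus memory persistence.

    Stages, with early exit: (1) no-signal baseline converges to a unique
    steady output; (2) food alone → off; (3) ring alone → off; (4) food and
    ring together → on, with a steady plateau; (5) signals removed from the
    plateau → output retains >= 80% of it at the checkpoint time.
    """
    rng = init_rng if init_rng is not None else np.random.default_rng(0)
    on = settings.s_on
    conditions = [
        ({"food": on}, "off"),
        ({"ring": on}, "off"),
        ({"food": on, "ring": on}, "on"),
    ]
    try:
        out = t.node_with_role(NodeRole.MEMORY_OUTPUT)
        system = CompiledSystem(t, params, derive_signal_edges(t))
        inits = draw_inits(
            t.n_nodes, [out], settings.n_inits, rng,
            settings.init_high, settings.output_init,
        )
        baseline, _ = unique_steady_outputs(system, {}, inits, [out], settings)
        y_off = baseline[out]
        plateau = None
        plateau_state = None
        for levels, want in conditions:
            band = [out] if want == "off" else []
            values, final = unique_steady_outputs(
                system, levels, inits, [out], settings, band_nodes=band
            )
            _require_state(values[out], y_off, settings.ratios, want)
            if want == "on":
                plateau, plateau_state = values[out], final
        # persistence: continue from the trained plateau with signals removed
        rule = settings.persistence
        try:
            tail = system.integrate(
                {}, plateau_state[None, :], np.array([rule.t_check]),
                t_span=(0.0, rule.t_check),
            )
        except SimulationError as exc:
            raise StageFailure("sim-failed") from exc
        if tail[0, -1, out] < rule.retain_frac * plateau:
            raise StageFailure("persistence")
    except StageFailure as f:
        return Verdict(False, f.stage)
    return Verdict(True)


def test_recall(
    t: Topology,
    params: ParameterSet,
    settings: EvalSettings = DEFAULT_SETTINGS,
    init_rng: np.random.Generator | None = None,
) -> Verdict:
    """Recall-module truth table (no persistence requirement).

    Against the no-signal baseline: food alone → on; memory alone → off;
    ring alone → off; memory and ring together → on.  The food signal acts
    additively on the F&S output node; memory and ring act multiplicatively.
    """
    rng = init_rng if init_rng is not None else np.random.default_rng(0)
    on = settings.s_on
    conditions = [
        ({"food": on}, "on"),
        ({"memory": on}, "off"),
        ({"ring": on}, "off"),
        ({"memory": on, "ring": on}, "on"),
    ]
    try:
        out = t.node_with_role(NodeRole.OUTPUT_FS)
        system = CompiledSystem(t, params, derive_signal_edges(t))
        inits = draw_inits(
            t.n_nodes, [out], settings.n_inits, rng,
            settings.init_high, settings.output_init,
        )
        baseline, _ = unique_steady_outputs(system, {}, inits, [out], settings)
        y_off = baseline[out]
        for levels, want in conditions:
            band = [out] if want == "off" else []
            values, _ = unique_steady_outputs(
                system, levels, inits, [out], settings, band_nodes=band
            )
            _require_state(values[out], y_off, settings.ratios, want)
    except StageFailure as f:
        return Verdict(False, f.stage)
    return Verdict(True)


# ----------------------------------------------------------------------
# Q-value aggregation


TestFunction = Callable[[Topology, ParameterSet, EvalSettings, np.random.Generator], Verdict]


def compute_q(
    t: Topology,
    test: TestFunction,
    n_sets: int,
    seed: int,
    settings: EvalSettings = DEFAULT_SETTINGS,
    ranges: ParameterRanges = DEFAULT_RANGES,
    signal_edges: Sequence[SignalEdge] | None = None,
) -> QResult:
    """Fraction of Latin-hypercube parameter sets passing a function test.

    Deterministic given (topology, seed, n_sets, settings): parameters come
    from the per-topology hypercube stream and each set's random initial
    conditions are seeded by (topology stream seed, set index).
    """
    param_sets = sample_parameters(
        t, n_sets, seed, ranges,
        signal_edges=list(signal_edges) if signal_edges is not None else None,
    )
    base = topology_seed(seed, t)
    n_pass = 0
    for idx, params in enumerate(param_sets):
        rng = np.random.default_rng([base, idx])
        if test(t, params, settings, rng).passed:
            n_pass += 1
    return QResult(encode_id(t), n_sets, n_pass)


def select_pool(
    results: Iterable[QResult], q_threshold: float
) -> list[tuple[int, float]]:
    """Robust topologies: q strictly above threshold, ranked by q then ID."""
    kept = [(r.topology_id, r.q) for r in results if r.q > q_threshold]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return kept
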