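"""Latin-hypercube parameter sampling over log-scale kinetic ranges.

Each scalar dimension of a topology's parameter space (edge kinetics, node
degradation rates, external-signal kinetics) is stratified into ``n_sets``
equal-probability bins, each hit exactly once across the draw.  Stratification
happens on the log10 scale for parameters spanning decades and on the linear
scale for ``alpha`` and the Hill coefficient ``n``.

Default ranges: V in [1e-3, 1e2], k in [1e-6, 1], K in [1e-3, 10] (all log),
alpha in [0, 1] linear, eta in [1e-12, 1] log, n in [1, 3] linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

from .dynamics import (
    EdgeParams,
    NodeParams,
    ParameterSet,
    SignalEdge,
    derive_signal_edges,
)
from .topology import Topology, encode_id

__all__ = [
    "ParameterRanges",
    "DEFAULT_RANGES",
    "EDGE_FIELDS",
    "derive_signal_edges",
    "parameter_dimensions",
    "sample_parameters",
    "topology_seed",
]

#: EdgeParams fields, in sampling order.
EDGE_FIELDS = ("V", "k", "K", "alpha", "n")


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter (low, high, scale) with scale in {"log", "linear"}.

    ``integer_n`` switches the Hill coefficient to stratified draws over the
    integers {1, 2, 3} instead of the continuous interval [1, 3].
    """

    ranges: dict[str, tuple[float, float, str]] = field(
        default_factory=lambda: {
            "V": (1e-3, 1e2, "log"),
            "k": (1e-6, 1.0, "log"),
            "K": (1e-3, 10.0, "log"),
            "alpha": (0.0, 1.0, "linear"),
            "eta": (1e-12, 1.0, "log"),
            "n": (1.0, 3.0, "linear"),
        }
    )
    integer_n: bool = False

    def __post_init__(self) -> None:
        for name, (low, high, scale) in self.ranges.items():
            if not low < high:
                raise ValueError(f"range for {name!r} must have low < high")
            if scale not in ("log", "linear"):
                raise ValueError(f"unknown scale {scale!r} for {name!r}")
            if scale == "log" and low <= 0:
                raise ValueError(f"log-scale range for {name!r} needs low > 0")

    def with_overrides(self, **kwargs: tuple[float, float, str]) -> "ParameterRanges":
        merged = dict(self.ranges)
        merged.update(kwargs)
        return replace(self, ranges=merged)

    def transform(self, name: str, u: np.ndarray) -> np.ndarray:
        """Map uniform-[0,1) strata values onto the parameter's scale."""
        low, high, scale = self.ranges[name]
        if name == "n" and self.integer_n:
            k = int(round(high - low)) + 1
            return low + np.floor(u * k).clip(max=k - 1)
        if scale == "log":
            return low * (high / low) ** u
        return low + u * (high - low)


DEFAULT_RANGES = ParameterRanges()


def parameter_dimensions(
    t: Topology, signal_edges: list[SignalEdge]
) -> list[tuple[str, object]]:
    """Ordered scalar dimensions: (parameter name, owner key) pairs.

    Edge dimensions come first in row-major edge order, then per-node ``eta``,
    then signal-edge dimensions sorted by (signal, node).
    """
    dims: list[tuple[str, object]] = []
    for i, j, _sign in t.edges():
        for f in EDGE_FIELDS:
            dims.append((f, ("edge", i, j)))
    for i in range(t.n_nodes):
        dims.append(("eta", ("node", i)))
    for e in sorted(signal_edges, key=lambda e: (e.signal, e.node, e.additive)):
        for f in EDGE_FIELDS:
            dims.append((f, ("signal", e.signal, e.node)))
    return dims


def topology_seed(seed: int, t: Topology) -> int:
    """Per-topology stream seed: ``seed XOR canonical ID`` (mod 2^31)."""
    return (int(seed) ^ encode_id(t)) % (2**31)


def sample_parameters(
    t: Topology,
    n_sets: int,
    seed: int,
    ranges: ParameterRanges = DEFAULT_RANGES,
    signal_edges: list[SignalEdge] | None = None,
) -> list[ParameterSet]:
    """Draw ``n_sets`` Latin-hypercube parameter sets for one topology.

    Every non-none edge contributes its kinetic fields as dimensions, every
    node its degradation rate, and every external-signal term its own
    kinetics.  Reproducible: the hypercube is seeded from ``seed`` XOR the
    topology's canonical ID, so screens over many topologies are independent
    yet fully determined by one master seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if signal_edges is None:
        signal_edges = derive_signal_edges(t)
    dims = parameter_dimensions(t, signal_edges)
    sampler = qmc.LatinHypercube(d=len(dims), seed=topology_seed(seed, t))
    unit = sampler.random(n=n_sets)  # (n_sets, n_dims) in [0, 1)
    cols = {
        (name, key): ranges.transform(name, unit[:, idx])
        for idx, (name, key) in enumerate(dims)
    }

    out: list[ParameterSet] = []
    for s in range(n_sets):
        edge_params: dict[tuple[int, int], EdgeParams] = {}
        for i, j, _sign in t.edges():
            key = ("edge", i, j)
            edge_params[(i, j)] = EdgeParams(
                **{f: float(cols[(f, key)][s]) for f in EDGE_FIELDS}
            )
        node_params = {
            i: NodeParams(eta=float(cols[("eta", ("node", i))][s]))
            for i in range(t.n_nodes)
        }
        signal_params = {
            (e.signal, e.node): EdgeParams(
                **{
                    f: float(cols[(f, ("signal", e.signal, e.node))][s])
                    for f in EDGE_FIELDS
                }
            )
            for e in signal_edges
        }
        out.append(ParameterSet(edge_params, node_params, signal_params))
    return out
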