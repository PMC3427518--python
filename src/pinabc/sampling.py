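"""Uniform node-subsampling model for incomplete interactome data.

Interaction datasets cover only a fraction of an organism's proteins. To
compare a growth model with such data without bias, networks are grown to
the organism's full gene count ``n_total`` and then reduced to the data's
size ``n_sampled`` by sampling nodes uniformly without replacement and
taking the induced subgraph. Induced subsamples may contain degree-zero
nodes, which real interactome data never do; that mismatch is kept here (as
the parsimonious choice) and corrected only when inferring degree
distributions (see :mod:`pinabc.model_averaging`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import UndirectedGraph
from .growth_models import ModelId, ParameterVector, simulate

__all__ = [
    "SamplingConfig",
    "induced_subsample",
    "simulate_with_sampling",
    "sampling_fraction",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Genome size ``n_total`` (proteins in the organism) and observed size
    ``n_sampled`` (proteins in the interaction dataset)."""

    n_total: int
    n_sampled: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_sampled <= self.n_total:
            raise ValueError(
                f"need 1 <= n_sampled <= n_total, got n_sampled={self.n_sampled}, "
                f"n_total={self.n_total}"
            )


def induced_subsample(
    g: UndirectedGraph, n_sampled: int, rng: np.random.Generator
) -> UndirectedGraph:
    """Induced subgraph on ``n_sampled`` nodes chosen uniformly without
    replacement.

    An edge survives iff both endpoints were sampled; nodes isolated by the
    sampling are retained. Sampled nodes are renumbered ``0..n_sampled-1``
    in the order drawn.
    """
    if n_sampled > g.node_count:
        raise ValueError(
            f"cannot sample {n_sampled} nodes from a graph with {g.node_count}"
        )
    keep = rng.choice(g.node_count, size=n_sampled, replace=False)
    index = {int(old): new for new, old in enumerate(keep)}
    edges = frozenset(
        (min(index[u], index[v]), max(index[u], index[v]))
        for u, v in g.edges
        if u in index and v in index
    )
    return UndirectedGraph(n_sampled, edges)


def simulate_with_sampling(
    model: ModelId,
    params: ParameterVector,
    config: SamplingConfig,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """Grow to ``n_total`` nodes, then subsample down to ``n_sampled``.

    This is the simulation route used inside ABC whenever a sampling model
    is configured: parameters describe the full network, while the output
    matches the observed data's size exactly.
    """
    full = simulate(model, params, config.n_total, rng, seed)
    if config.n_sampled == config.n_total:
        return full
    return induced_subsample(full, config.n_sampled, rng)


def sampling_fraction(n_sampled: int, n_total: int) -> float:
    """Fraction of the organism's proteins present in the data."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 1 <= n_sampled <= n_total:
        raise ValueError(f"need 1 <= n_sampled <= n_total, got {n_sampled}/{n_total}")
    return n_sampled / n_total
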