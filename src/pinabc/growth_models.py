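"""Stochastic simulators for protein-interaction-network growth models.

Six models grow a simple undirected graph node by node to a target size:

``DA``
    Duplication-attachment: a uniformly chosen node is duplicated; each of
    its edges is inherited by the copy with probability ``1 - delta``
    (divergence loses it with probability ``delta``; the original's edges
    are never touched), and a heterodimerization edge between original and
    copy is added with probability ``alpha``.
``DAC``
    Duplication-attachment with complementarity: as DA, but divergence acts
    on each original/copy edge pair — with probability ``1 - delta`` both
    are kept, otherwise one of the two is deleted uniformly at random, so at
    least one always survives.
``LPA``
    Linear preferential attachment: each step adds one node and attaches
    ``Poisson(m)`` edges to existing nodes with probability proportional to
    degree (``k / 2M``).
``GSF``
    Generalized scale-free growth: edges carry weights (initially 1); each
    attachment selects an edge with probability proportional to its weight,
    connects the new node to a uniformly chosen endpoint, and increments the
    selected edge's weight by ``omega``. The limiting degree exponent is
    ``2 + 1/(1 + 2*omega)``.
``DACR`` / ``DACL``
    Mixtures: with probability ``p`` a DAC duplication step, otherwise a new
    node plus ``Poisson(m)`` random edges — placed between uniformly chosen
    node pairs (DACR) or attached preferentially from the new node (DACL).

All simulators are driven by a single ``numpy.random.Generator`` threaded
through every stochastic choice in a fixed documented order, so a fixed seed
reproduces the grown graph exactly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .graph_core import UndirectedGraph

__all__ = [
    "ModelId",
    "ParameterVector",
    "PriorSpec",
    "ACTIVE_PARAMS",
    "PARAM_ORDER",
    "default_prior",
    "seed_graph",
    "grow_da",
    "grow_dac",
    "grow_lpa",
    "grow_gsf",
    "grow_dacr",
    "grow_dacl",
    "simulate",
]


class ModelId(enum.IntEnum):
    """Closed enumeration of growth models, with stable ordinals so the
    model choice can itself be a discrete particle coordinate."""

    DA = 0
    DAC = 1
    LPA = 2
    GSF = 3
    DACR = 4
    DACL = 5


PARAM_ORDER: tuple[str, ...] = ("delta", "alpha", "p", "m", "omega")

ACTIVE_PARAMS: dict[ModelId, tuple[str, ...]] = {
    ModelId.DA: ("delta", "alpha"),
    ModelId.DAC: ("delta", "alpha"),
    ModelId.LPA: ("m",),
    ModelId.GSF: ("m", "omega"),
    ModelId.DACR: ("delta", "alpha", "p", "m"),
    ModelId.DACL: ("delta", "alpha", "p", "m"),
}

#: legal domain of each parameter as (low, high, low_open)
_PARAM_DOMAIN: dict[str, tuple[float, float, bool]] = {
    "delta": (0.0, 1.0, False),
    "alpha": (0.0, 1.0, False),
    "p": (0.0, 1.0, False),
    "m": (0.0, np.inf, True),
    "omega": (0.0, np.inf, False),
}


@dataclass(frozen=True)
class ParameterVector:
    """Named growth-model parameters; inactive entries stay ``None``.

    delta : probability that a duplicated edge diverges (is lost)
    alpha : probability of the original-copy heterodimerization edge
    p     : probability of a duplication move (vs an edge-addition move)
    m     : Poisson mean of edges added per edge-addition step
    omega : GSF edge-weight increment per attachment
    """

    delta: float | None = None
    alpha: float | None = None
    p: float | None = None
    m: float | None = None
    omega: float | None = None

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def active(self, model: ModelId) -> dict[str, float]:
        """The parameters the model uses, validated for presence and range."""
        out = {}
        for name in ACTIVE_PARAMS[model]:
            value = self.get(name)
            if value is None:
                raise ValueError(f"model {model.name} requires parameter '{name}'")
            lo, hi, lo_open = _PARAM_DOMAIN[name]
            if not (lo <= value <= hi) or (lo_open and value <= lo):
                raise ValueError(
                    f"parameter '{name}'={value} outside its legal domain for {model.name}"
                )
            out[name] = float(value)
        for name in PARAM_ORDER:
            if name not in ACTIVE_PARAMS[model] and self.get(name) is not None:
                warnings.warn(
                    f"parameter '{name}' is inactive for model {model.name} and ignored",
                    stacklevel=3,
                )
        return out

    def replace(self, **updates: float) -> "ParameterVector":
        values = {name: self.get(name) for name in PARAM_ORDER}
        values.update(updates)
        return ParameterVector(**values)

    def as_array(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.get(n) for n in names], dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one ``(lower, upper)`` range per parameter."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if name not in _PARAM_DOMAIN:
                raise ValueError(f"unknown parameter '{name}'")
            dlo, dhi, lo_open = _PARAM_DOMAIN[name]
            if not lo < hi:
                raise ValueError(f"prior for '{name}' needs lower < upper, got ({lo}, {hi})")
            if lo < dlo or hi > dhi or (lo_open and lo <= dlo):
                raise ValueError(
                    f"prior range ({lo}, {hi}) for '{name}' leaves its legal domain"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_ORDER if n in self.ranges)

    def sample(self, rng: np.random.Generator) -> ParameterVector:
        values = {n: float(rng.uniform(*self.ranges[n])) for n in self.names}
        return ParameterVector(**values)

    def contains(self, params: ParameterVector) -> bool:
        for n in self.names:
            v = params.get(n)
            if v is None or not (self.ranges[n][0] <= v <= self.ranges[n][1]):
                return False
        return True

    def density(self, params: ParameterVector) -> float:
        if not self.contains(params):
            return 0.0
        vol = 1.0
        for lo, hi in self.ranges.values():
            vol *= hi - lo
        return 1.0 / vol


def default_prior(model: ModelId) -> PriorSpec:
    """Uniform priors over each active parameter's natural range.

    Probabilities get U(0, 1); the Poisson mean m gets U(0.1, 8), wide
    enough to cover node:edge ratios seen in interactome data; omega gets
    U(0, 2), spanning limiting exponents from 3 down to 2.2.
    """
    defaults = {"delta": (0.0, 1.0), "alpha": (0.0, 1.0), "p": (0.0, 1.0),
                "m": (0.1, 8.0), "omega": (0.0, 2.0)}
    return PriorSpec({n: defaults[n] for n in ACTIVE_PARAMS[model]})


# ---------------------------------------------------------------------------
# growth machinery

class _GrowState:
    """Mutable adjacency structure with O(1) edge updates and an
    incrementally maintained degree array."""

    def __init__(self, seed: UndirectedGraph):
        self.adj: list[set[int]] = [set() for _ in range(seed.node_count)]
        self.edge_set: set[tuple[int, int]] = set()
        self._deg = np.zeros(max(16, 2 * seed.node_count), dtype=np.int64)
        for u, v in sorted(seed.edges):
            self._link(u, v)

    @property
    def n(self) -> int:
        return len(self.adj)

    def degrees(self) -> np.ndarray:
        return self._deg[: self.n]

    def add_node(self) -> int:
        self.adj.append(set())
        if self.n > len(self._deg):
            self._deg = np.concatenate([self._deg, np.zeros(len(self._deg), dtype=np.int64)])
        self._deg[self.n - 1] = 0
        return self.n - 1

    def _link(self, u: int, v: int) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.edge_set.add((u, v) if u < v else (v, u))
        self._deg[u] += 1
        self._deg[v] += 1

    def try_add_edge(self, u: int, v: int) -> bool:
        """Add {u, v}; silently discard self-loops and existing edges."""
        if u == v:
            return False
        key = (u, v) if u < v else (v, u)
        if key in self.edge_set:
            return False
        self._link(u, v)
        return True

    def remove_edge(self, u: int, v: int) -> None:
        key = (u, v) if u < v else (v, u)
        self.edge_set.remove(key)
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self._deg[u] -= 1
        self._deg[v] -= 1

    def to_graph(self) -> UndirectedGraph:
        return UndirectedGraph(self.n, frozenset(self.edge_set))


def seed_graph(size: int = 2, shape: str = "path", target: int | None = None) -> UndirectedGraph:
    """Initial network for the simulators.

    The default — two nodes joined by one edge — is the smallest graph on
    which every growth move is defined. ``shape`` may be ``"path"`` or
    ``"ring"``; ``target`` (the eventual grown size), when given, is checked
    against the seed size.
    """
    if size < 2:
        raise ValueError("seed graphs need at least 2 nodes")
    if target is not None and size > target:
        raise ValueError(f"seed size {size} exceeds the target size {target}")
    if shape == "path":
        edges = frozenset((i, i + 1) for i in range(size - 1))
    elif shape == "ring":
        edges = frozenset((i, (i + 1) % size) for i in range(size))
    else:
        raise ValueError(f"unknown seed shape {shape!r} (use 'path' or 'ring')")
    return UndirectedGraph(size, edges)


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} is not a probability")
    return float(value)


def _duplication_step(
    state: _GrowState,
    delta: float,
    alpha: float,
    rng: np.random.Generator,
    complementary: bool,
) -> None:
    """One duplication-divergence move.

    RNG draw order: parent choice; per inherited edge (neighbours in sorted
    order) a divergence draw, plus — in the complementary variant, on
    divergence — a uniform pick of which edge of the pair survives; finally
    the heterodimerization draw.
    """
    parent = int(rng.integers(state.n))
    child = state.add_node()
    for nb in sorted(state.adj[parent]):
        if rng.random() < 1.0 - delta:
            state.try_add_edge(child, nb)
        elif complementary:
            if rng.random() < 0.5:
                # the original's edge is the one deleted; the copy's survives
                state.remove_edge(parent, nb)
                state.try_add_edge(child, nb)
    if rng.random() < alpha:
        state.try_add_edge(parent, child)


def _preferential_pick(
    state: _GrowState, excluded: set[int], rng: np.random.Generator
) -> int | None:
    """One target with probability degree/2M among non-excluded nodes;
    uniform fallback when no edges are available."""
    w = state.degrees().astype(float)
    if excluded:
        w[list(excluded)] = 0.0
    total = w.sum()
    if total > 0.0:
        u = rng.random() * total
        return int(np.searchsorted(np.cumsum(w), u, side="right"))
    candidates = [i for i in range(state.n) if i not in excluded]
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def _lpa_step(state: _GrowState, m: float, rng: np.random.Generator) -> None:
    """Add one node and Poisson(m) preferential edges from it, targets drawn
    without replacement (the Poisson draw is capped at the number of
    existing nodes)."""
    n_existing = state.n
    new = state.add_node()
    k = min(int(rng.poisson(m)), n_existing)
    chosen: set[int] = {new}
    for _ in range(k):
        target = _preferential_pick(state, chosen, rng)
        if target is None:
            break
        state.try_add_edge(new, target)
        chosen.add(target)


def _uniform_edge_step(state: _GrowState, m: float, rng: np.random.Generator) -> None:
    """Add one node and Poisson(m) edges between uniformly chosen node
    pairs (the new node included); colliding or self-pair proposals are
    discarded without retry."""
    n_existing = state.n
    state.add_node()
    k = min(int(rng.poisson(m)), n_existing)
    for _ in range(k):
        u = int(rng.integers(state.n))
        v = int(rng.integers(state.n))
        state.try_add_edge(u, v)


def _select_weighted_edge(
    weights: list[float], max_w: float, rng: np.random.Generator
) -> int:
    """Index drawn with probability proportional to weight, by rejection
    sampling against the running maximum weight."""
    while True:
        idx = int(rng.integers(len(weights)))
        if rng.random() * max_w <= weights[idx]:
            return idx


def _resolve_seed(seed: UndirectedGraph | None, n: int) -> UndirectedGraph:
    s = seed if seed is not None else seed_graph(2)
    if s.node_count > n:
        raise ValueError(f"seed has {s.node_count} nodes, more than the target {n}")
    return s


def grow_da(
    n: int,
    delta: float,
    alpha: float,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """Duplication-attachment growth to ``n`` nodes."""
    _check_prob("delta", delta)
    _check_prob("alpha", alpha)
    state = _GrowState(_resolve_seed(seed, n))
    while state.n < n:
        _duplication_step(state, delta, alpha, rng, complementary=False)
    return state.to_graph()


def grow_dac(
    n: int,
    delta: float,
    alpha: float,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """Duplication-attachment with complementarity: at least one edge of
    each original/copy pair survives divergence."""
    _check_prob("delta", delta)
    _check_prob("alpha", alpha)
    state = _GrowState(_resolve_seed(seed, n))
    while state.n < n:
        _duplication_step(state, delta, alpha, rng, complementary=True)
    return state.to_graph()


def grow_lpa(
    n: int,
    m: float,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """Linear preferential attachment with Poisson(m) edges per step."""
    if m <= 0:
        raise ValueError(f"m={m} must be positive")
    state = _GrowState(_resolve_seed(seed, n))
    while state.n < n:
        _lpa_step(state, m, rng)
    return state.to_graph()


def grow_gsf(
    n: int,
    m: float,
    omega: float,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """Generalized scale-free growth via weighted edge selection.

    Per attachment: an edge is selected with probability proportional to its
    weight (rejection sampling against the running maximum weight), the new
    node is linked to a uniformly chosen endpoint of it, and the selected
    edge's weight grows by ``omega``. Newly created edges enter at weight 1
    and are immediately eligible for selection.
    """
    if m <= 0:
        raise ValueError(f"m={m} must be positive")
    if omega < 0:
        raise ValueError(f"omega={omega} must be nonnegative")
    seed_g = _resolve_seed(seed, n)
    if seed_g.edge_count == 0:
        raise ValueError("GSF needs a seed with at least one edge (weighted edge selection)")
    state = _GrowState(seed_g)
    edge_list: list[tuple[int, int]] = sorted(seed_g.edges)
    weights: list[float] = [1.0] * len(edge_list)
    max_w = 1.0
    while state.n < n:
        n_existing = state.n
        new = state.add_node()
        k = min(int(rng.poisson(m)), n_existing)
        for _ in range(k):
            idx = _select_weighted_edge(weights, max_w, rng)
            a, b = edge_list[idx]
            endpoint = a if rng.random() < 0.5 else b
            if state.try_add_edge(new, endpoint):
                edge_list.append((new, endpoint))
                weights.append(1.0)
            weights[idx] += omega
            if weights[idx] > max_w:
                max_w = weights[idx]
    return state.to_graph()


def _grow_mixture(
    n: int,
    delta: float,
    alpha: float,
    p: float,
    m: float,
    rng: np.random.Generator,
    seed: UndirectedGraph | None,
    preferential: bool,
) -> UndirectedGraph:
    _check_prob("delta", delta)
    _check_prob("alpha", alpha)
    _check_prob("p", p)
    if m <= 0:
        raise ValueError(f"m={m} must be positive")
    state = _GrowState(_resolve_seed(seed, n))
    while state.n < n:
        # p exactly 0 or 1 skips the move-choice draw, so those degenerate
        # mixtures consume the RNG stream identically to the pure models
        if p == 1.0:
            duplicate = True
        elif p == 0.0:
            duplicate = False
        else:
            duplicate = rng.random() < p
        if duplicate:
            _duplication_step(state, delta, alpha, rng, complementary=True)
        elif preferential:
            _lpa_step(state, m, rng)
        else:
            _uniform_edge_step(state, m, rng)
    return state.to_graph()


def grow_dacr(
    n: int,
    delta: float,
    alpha: float,
    p: float,
    m: float,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """DAC duplication with probability p, uniform random edge addition
    otherwise."""
    return _grow_mixture(n, delta, alpha, p, m, rng, seed, preferential=False)


def grow_dacl(
    n: int,
    delta: float,
    alpha: float,
    p: float,
    m: float,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """DAC duplication with probability p, preferential edge addition
    otherwise."""
    return _grow_mixture(n, delta, alpha, p, m, rng, seed, preferential=True)


def simulate(
    model: ModelId,
    params: ParameterVector,
    n: int,
    rng: np.random.Generator,
    seed: UndirectedGraph | None = None,
) -> UndirectedGraph:
    """Grow one network from ``model`` with ``params`` to ``n`` nodes.

    Validates that every active parameter is present and in range (missing
    ones raise; supplied inactive ones only warn), then dispatches to the
    matching ``grow_*`` simulator. Identical RNG state yields an identical
    graph.
    """
    a = params.active(model)
    if model is ModelId.DA:
        return grow_da(n, a["delta"], a["alpha"], rng, seed)
    if model is ModelId.DAC:
        return grow_dac(n, a["delta"], a["alpha"], rng, seed)
    if model is ModelId.LPA:
        return grow_lpa(n, a["m"], rng, seed)
    if model is ModelId.GSF:
        return grow_gsf(n, a["m"], a["omega"], rng, seed)
    if model is ModelId.DACR:
        return grow_dacr(n, a["delta"], a["alpha"], a["p"], a["m"], rng, seed)
    if model is ModelId.DACL:
        return grow_dacl(n, a["delta"], a["alpha"], a["p"], a["m"], rng, seed)
    raise ValueError(f"unknown model {model!r}")
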