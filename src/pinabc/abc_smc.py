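"""ABC sequential Monte Carlo for a single network growth model.

Likelihoods of network growth models are intractable, so the posterior is
approximated by simulation: a parameter proposal ``theta`` is simulated
``R`` times, each simulated network is compared to the data through the
spectral edit-distance bound, and the number ``s`` of simulations landing
within the current tolerance ``epsilon`` acts as an (unnormalized)
likelihood estimate. A population of ``N`` weighted particles is evolved
through a decreasing tolerance schedule: particles are resampled by weight,
perturbed with a zero-mean Gaussian kernel (diagonal bandwidth), re-simulated,
accepted iff ``s > 0``, and reweighted with the sequential importance
weight

    w  ∝  prior(theta) * s / sum_j w_j K(theta | theta_j),

with ``w ← s`` in the first generation (a draw straight from the prior).
The weighted particles of the final population form the empirical ABC
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph_core import UndirectedGraph, spectral_distance
from .growth_models import (
    PARAM_ORDER,
    ModelId,
    ParameterVector,
    PriorSpec,
    simulate,
)
from .sampling import SamplingConfig, simulate_with_sampling

__all__ = [
    "Particle",
    "Population",
    "ABCConfig",
    "KernelConfig",
    "approximate_likelihood",
    "perturb_parameters",
    "compute_weight",
    "adaptive_epsilon",
    "run_abc_smc",
    "populations_to_table",
    "table_to_populations",
    "weighted_quantile",
    "marginal_interval",
]


@dataclass(frozen=True)
class KernelConfig:
    """Perturbation kernel settings.

    ``bandwidths`` — fixed per-parameter Gaussian standard deviations; when
    None (default) the bandwidth for each parameter is recomputed every
    generation as sqrt(2 × weighted sample variance) of the previous
    population, the standard adaptive choice. ``model_switch_prob`` is the
    probability, in joint model/parameter runs, of proposing a uniformly
    chosen different model.
    """

    bandwidths: dict[str, float] | None = None
    model_switch_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.bandwidths is not None:
            for name, bw in self.bandwidths.items():
                if bw <= 0:
                    raise ValueError(f"kernel bandwidth for '{name}' must be > 0, got {bw}")
        if not 0.0 <= self.model_switch_prob <= 1.0:
            raise ValueError("model_switch_prob must be a probability")


@dataclass(frozen=True)
class ABCConfig:
    """Run settings for ABC-SMC.

    n_particles
        Population size N.
    n_populations
        Number of tolerance levels T.
    n_repeats
        Simulations R per proposal; ``s`` counts how many fall within
        tolerance.
    epsilon_schedule
        Explicit strictly decreasing tolerances; None (default) selects the
        adaptive rule: the first generation accepts everything and each
        later tolerance is the ``epsilon_quantile`` of the previous
        generation's accepted distances.
    sampling
        Optional node-sampling model; when set, every simulation grows to
        ``n_total`` nodes and is subsampled to the data's size.
    max_attempts_factor
        Abort threshold: a generation may use at most
        ``max_attempts_factor × n_particles`` proposals.
    """

    n_particles: int = 1000
    n_populations: int = 8
    n_repeats: int = 1
    epsilon_schedule: tuple[float, ...] | None = None
    epsilon_quantile: float = 0.5
    kernel: KernelConfig = field(default_factory=KernelConfig)
    sampling: SamplingConfig | None = None
    max_attempts_factor: int = 500

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.n_populations < 1:
            raise ValueError("need at least 1 population")
        if self.n_repeats < 1:
            raise ValueError("need at least 1 repeat")
        if not 0.0 < self.epsilon_quantile < 1.0:
            raise ValueError("epsilon_quantile must lie in (0, 1)")
        if self.epsilon_schedule is not None:
            sched = tuple(float(e) for e in self.epsilon_schedule)
            if len(sched) != self.n_populations:
                raise ValueError(
                    f"epsilon schedule has {len(sched)} entries for "
                    f"{self.n_populations} populations"
                )
            if any(b >= a for a, b in zip(sched, sched[1:])):
                raise ValueError("explicit epsilon schedule must be strictly decreasing")
            object.__setattr__(self, "epsilon_schedule", sched)


@dataclass(frozen=True)
class Particle:
    """One weighted (model, parameter) draw.

    ``accepted_count`` is the likelihood estimate ``s`` (simulations within
    tolerance out of R); ``min_distance`` the smallest realized distance,
    kept to drive the adaptive tolerance schedule.
    """

    model: ModelId
    params: ParameterVector
    weight: float
    accepted_count: int
    min_distance: float


@dataclass(frozen=True)
class Population:
    """Weighted particle population at one tolerance level ``epsilon``."""

    particles: tuple[Particle, ...]
    epsilon: float
    t: int

    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.particles])

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return abs(self.weights().sum() - 1.0) <= tol

    def normalized(self) -> "Population":
        w = self.weights()
        total = w.sum()
        if total <= 0:
            raise ValueError("population has no positive weight")
        return Population(
            tuple(replace(p, weight=p.weight / total) for p in self.particles),
            self.epsilon,
            self.t,
        )


# ---------------------------------------------------------------------------
# building blocks


def _simulate_distances(
    model: ModelId,
    params: ParameterVector,
    data: UndirectedGraph,
    config: ABCConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spectral distances between R fresh simulations and the data."""
    out = np.empty(config.n_repeats)
    for r in range(config.n_repeats):
        if config.sampling is not None:
            g = simulate_with_sampling(model, params, config.sampling, rng)
        else:
            g = simulate(model, params, data.node_count, rng)
        out[r] = spectral_distance(g, data)
    return out


def approximate_likelihood(
    model: ModelId,
    params: ParameterVector,
    data: UndirectedGraph,
    epsilon: float,
    config: ABCConfig,
    rng: np.random.Generator,
) -> int:
    """Number of R simulations whose distance to the data is <= epsilon."""
    dists = _simulate_distances(model, params, data, config, rng)
    return int(np.sum(dists <= epsilon))


def perturb_parameters(
    params: ParameterVector,
    bandwidths: dict[str, float],
    prior: PriorSpec,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> ParameterVector | None:
    """Gaussian-perturb each active parameter; redraw until inside the prior.

    Returns None after ``max_retries`` failed draws, signalling the caller
    to resample a new source particle (the effective kernel is a truncated
    Gaussian; the retry cap guards against particles pinned in a corner of
    the prior box with a huge bandwidth).
    """
    for _ in range(max_retries):
        updates = {
            name: params.get(name) + rng.normal(0.0, bandwidths[name])
            for name in prior.names
        }
        proposal = params.replace(**updates)
        if prior.contains(proposal):
            return proposal
    return None


def _kernel_density(
    x: np.ndarray,
    source_matrix: np.ndarray,
    bandwidths: np.ndarray,
) -> np.ndarray:
    """Gaussian product-kernel density of the point ``x`` around each row
    of ``source_matrix`` (columns ordered as the prior's names)."""
    z = (source_matrix - x) / bandwidths
    log_norm = np.sum(np.log(bandwidths * np.sqrt(2.0 * np.pi)))
    return np.exp(-0.5 * np.sum(z * z, axis=1) - log_norm)


def compute_weight(
    proposal: ParameterVector,
    s: int,
    prev: Population,
    bandwidths: dict[str, float],
    prior: PriorSpec,
) -> float:
    """Importance weight  prior × s / (kernel mixture over the previous
    population).  Only meaningful for accepted proposals (s > 0)."""
    if s <= 0:
        raise ValueError("weights are computed only for accepted particles (s > 0)")
    if not prev.particles:
        raise ValueError("previous population is empty")
    names = prior.names
    src = np.array([[q.params.get(n) for n in names] for q in prev.particles])
    bw = np.array([bandwidths[n] for n in names])
    dens = _kernel_density(proposal.as_array(names), src, bw)
    mixture = float(np.dot(prev.weights(), dens))
    if mixture <= 0.0:
        # all sources numerically unreachable; weight dominated by the prior
        mixture = np.finfo(float).tiny
    return prior.density(proposal) * s / mixture


def adaptive_epsilon(prev: Population, quantile: float = 0.5) -> float:
    """Next tolerance: a quantile (midpoint convention, default the median)
    of the previous population's accepted distances, clamped strictly below
    the previous epsilon."""
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    dists = np.array([p.min_distance for p in prev.particles])
    eps = float(np.quantile(dists, quantile, method="midpoint"))
    if eps >= prev.epsilon:
        eps = float(np.nextafter(prev.epsilon, -np.inf))
    return eps


def run_abc_smc(
    data: UndirectedGraph,
    model: ModelId,
    prior: PriorSpec,
    config: ABCConfig,
    rng: np.random.Generator,
) -> list[Population]:
    """Fit a single model's ABC posterior (the one-model case of the joint
    model/parameter sampler; both share one engine, so traces coincide
    exactly when only one model is configured)."""
    from .model_selection import _run_joint_smc  # shared engine; avoids a cycle

    return _run_joint_smc(data, {model: prior}, config, rng)


# ---------------------------------------------------------------------------
# trace tables and posterior summaries

_TRACE_COLUMNS = ["generation", "epsilon", "model", *PARAM_ORDER,
                  "weight", "accepted_count", "min_distance"]


def populations_to_table(populations: list[Population]) -> pd.DataFrame:
    """Flat trace: one row per particle, columns (generation, epsilon,
    model, delta, alpha, p, m, omega, weight, accepted_count,
    min_distance); inactive parameters are NaN."""
    rows = []
    for pop in populations:
        for part in pop.particles:
            row = {
                "generation": pop.t,
                "epsilon": pop.epsilon,
                "model": part.model.name,
                "weight": part.weight,
                "accepted_count": part.accepted_count,
                "min_distance": part.min_distance,
            }
            for name in PARAM_ORDER:
                v = part.params.get(name)
                row[name] = np.nan if v is None else v
            rows.append(row)
    return pd.DataFrame(rows, columns=_TRACE_COLUMNS)


def table_to_populations(df: pd.DataFrame) -> list[Population]:
    """Inverse of :func:`populations_to_table`."""
    pops = []
    for t, group in df.groupby("generation", sort=True):
        particles = []
        for _, row in group.iterrows():
            model = ModelId[row["model"]]
            values = {
                n: (None if pd.isna(row[n]) else float(row[n]))
                for n in PARAM_ORDER
            }
            particles.append(
                Particle(
                    model=model,
                    params=ParameterVector(**values),
                    weight=float(row["weight"]),
                    accepted_count=int(row["accepted_count"]),
                    min_distance=float(row["min_distance"]),
                )
            )
        pops.append(Population(tuple(particles), float(group["epsilon"].iloc[0]), int(t)))
    return pops


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Quantile of a weighted sample (inverse of the weighted ECDF)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, q, side="left").clip(0, len(v) - 1)])


def marginal_interval(
    pop: Population, name: str, level: float = 0.9
) -> tuple[float, float]:
    """Weighted central credible interval for one parameter of a
    normalized population."""
    values = np.array([p.params.get(name) for p in pop.particles], dtype=float)
    w = pop.weights()
    lo = (1.0 - level) / 2.0
    return weighted_quantile(values, w, lo), weighted_quantile(values, w, 1.0 - lo)
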