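"""Bayesian model averaging of network statistics.

When no single growth model dominates the posterior, predictions should be
pooled: a statistic ``t_m`` computed under each model ``m`` is averaged with
the posterior model probabilities,

    E[t] = sum_m P(m | D) * t_m.

The main predictive statistic implemented here is the degree distribution
of the (full or observed) network, reconstructed by simulating
posterior-resampled particles through the growth-plus-sampling pipeline.
Because real interactome data never contain degree-zero proteins while
induced subsamples do, the pooled predictive distribution is truncated to
degrees k >= 1 and renormalized before being compared with data.
"""

from __future__ import annotations

import numpy as np

from .abc_smc import Population
from .graph_core import degree_distribution
from .growth_models import ModelId
from .model_selection import ModelPosterior, marginal_model_posterior
from .sampling import SamplingConfig, simulate_with_sampling

__all__ = [
    "model_averaged_statistic",
    "posterior_predictive_degree_distribution",
]


def _pad(vectors: list[np.ndarray]) -> np.ndarray:
    n = max(len(v) for v in vectors)
    return np.stack([np.pad(v, (0, n - len(v))) for v in vectors])


def model_averaged_statistic(
    posterior: ModelPosterior,
    per_model_values: dict[ModelId, float | np.ndarray],
):
    """Posterior-probability-weighted average of a per-model statistic.

    Accepts scalars or vectors (vectors of unequal length are zero-padded
    on the right, which preserves probability-vector normalization). Models
    with posterior probability zero may be missing from
    ``per_model_values``; a model with positive probability must not be.
    """
    missing = [m for m, p in posterior.items() if p > 0 and m not in per_model_values]
    if missing:
        raise ValueError(
            "no statistic supplied for models with positive posterior: "
            + ", ".join(m.name for m in missing)
        )
    used = [m for m, p in posterior.items() if p > 0]
    values = [np.asarray(per_model_values[m], dtype=float) for m in used]
    probs = np.array([posterior[m] for m in used])
    if values and values[0].ndim > 0:
        return probs @ _pad(values)
    return float(np.dot(probs, [float(v) for v in values]))


def posterior_predictive_degree_distribution(
    populations: list[Population],
    sampling: SamplingConfig,
    rng: np.random.Generator,
    n_draws: int | None = None,
) -> np.ndarray:
    """Model-averaged posterior-predictive degree distribution over k >= 1.

    Particles are resampled by weight from the final population and each
    draw is simulated through the growth(-plus-sampling) pipeline. The
    simulated degree distributions are averaged within each model and then
    pooled with the marginal model posterior; finally the degree-zero mass
    is dropped and the vector renormalized, matching the fact that observed
    interactome data contain no isolated proteins. Entry ``k-1`` of the
    returned vector is the predictive probability of degree ``k``.

    ``n_draws`` defaults to the particle count (one simulation per
    resampled particle). The marginal posterior of models that happen to
    receive no draws is renormalized away.
    """
    if not populations:
        raise ValueError("no populations supplied")
    final = populations[-1]
    if n_draws is None:
        n_draws = len(final.particles)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")

    posterior = marginal_model_posterior(final)
    weights = final.weights()
    idx = rng.choice(len(final.particles), size=n_draws, replace=True, p=weights)

    per_model: dict[ModelId, list[np.ndarray]] = {}
    for i in idx:
        part = final.particles[int(i)]
        g = simulate_with_sampling(part.model, part.params, sampling, rng)
        per_model.setdefault(part.model, []).append(degree_distribution(g))

    means = {m: np.mean(_pad(v), axis=0) for m, v in per_model.items()}
    mass = sum(posterior[m] for m in means)
    pooled = model_averaged_statistic(
        {m: posterior[m] / mass for m in means}, means
    )
    tail = np.asarray(pooled)[1:]
    total = tail.sum()
    if total <= 0:
        raise ValueError(
            "every predictive draw was an empty graph; nothing remains after "
            "the degree-zero correction"
        )
    return tail / total
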