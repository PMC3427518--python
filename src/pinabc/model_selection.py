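"""Joint model + parameter ABC-SMC and marginal model posteriors.

Model choice is treated as one more (discrete) particle coordinate: a
proposal first draws a model from the previous generation's marginal model
probabilities, resamples a parameter particle of that model, perturbs the
model with a switch kernel (stay with probability ``1 - p``, otherwise move
to a uniformly chosen other model) and the parameters with the Gaussian
kernel, and is accepted iff at least one of its R simulations falls within
tolerance. The joint importance weight divides the (model prior × parameter
prior × s) numerator by the full proposal mass — the model-kernel mixture
over the previous marginals times the parameter-kernel mixture over the
previous particles of the proposed model. Marginalizing the final
population's weights over parameters yields the posterior model
probabilities.

Parameters of different models are not commensurable, so a particle that
switches to model ``m'`` re-proposes its parameters by perturbing a
resampled particle *of* ``m'`` (or drawing fresh from ``m'``'s prior if the
model currently has no particles); inactive parameters are dropped rather
than carried silently.
"""

from __future__ import annotations

import logging

import numpy as np

from .abc_smc import (
    ABCConfig,
    Particle,
    Population,
    PriorSpec,
    _kernel_density,
    _simulate_distances,
    adaptive_epsilon,
    perturb_parameters,
)
from .graph_core import UndirectedGraph
from .growth_models import ModelId, ParameterVector

__all__ = [
    "ModelPosterior",
    "perturb_model",
    "marginal_model_posterior",
    "compute_weight_joint",
    "run_abc_smc_model_selection",
]

logger = logging.getLogger(__name__)

#: mapping ModelId -> posterior probability (sums to one)
ModelPosterior = dict[ModelId, float]

_SINGLETON_WARNED = False


def perturb_model(
    current: ModelId,
    model_set: list[ModelId],
    switch_prob: float,
    rng: np.random.Generator,
) -> ModelId:
    """Model kernel: keep ``current`` with probability ``1 - switch_prob``,
    otherwise move to a uniform draw over the other models."""
    global _SINGLETON_WARNED
    if not model_set:
        raise ValueError("model_set must be nonempty")
    if current not in model_set:
        raise ValueError(f"{current!r} is not in the configured model set")
    others = [m for m in model_set if m is not current]
    if not others:
        if switch_prob > 0 and not _SINGLETON_WARNED:
            logger.info("single-model set: model kernel has nowhere to switch to")
            _SINGLETON_WARNED = True
        return current
    if rng.random() < switch_prob:
        return others[int(rng.integers(len(others)))]
    return current


def _model_kernel_prob(
    target: ModelId, source: ModelId, model_set: list[ModelId], switch_prob: float
) -> float:
    if len(model_set) == 1:
        return 1.0
    if target is source:
        return 1.0 - switch_prob
    return switch_prob / (len(model_set) - 1)


def marginal_model_posterior(
    pop: Population, model_set: list[ModelId] | None = None
) -> ModelPosterior:
    """Posterior probability of each model: the summed weights of its
    particles. Requires a normalized population."""
    if not pop.is_normalized():
        raise ValueError("population must be normalized before marginalizing")
    models = model_set if model_set is not None else sorted({p.model for p in pop.particles})
    posterior = {m: 0.0 for m in models}
    for part in pop.particles:
        if part.model not in posterior:
            raise ValueError(f"particle carries model {part.model.name} outside the model set")
        posterior[part.model] += part.weight
    return posterior


def compute_weight_joint(
    model: ModelId,
    params: ParameterVector,
    s: int,
    prev: Population,
    bandwidths: dict[ModelId, dict[str, float]],
    model_priors: dict[ModelId, PriorSpec],
    switch_prob: float,
    model_prior_probs: dict[ModelId, float] | None = None,
) -> float:
    """Joint importance weight for an accepted (model, parameters) proposal.

    numerator   P0(model) × prior(params | model) × s
    denominator [Σ_m' P_{t-1}(m') K_M(model | m')] ×
                [Σ_{j : m_j = model} w̄_j K_θ(params | θ_j)]

    where w̄ are the previous weights renormalized within the proposed
    model; if that model had no particles, its parameters were drawn fresh
    from the prior and the second factor is the prior density.
    """
    if s <= 0:
        raise ValueError("weights are computed only for accepted particles (s > 0)")
    if not prev.particles:
        raise ValueError("previous population is empty")
    model_set = list(model_priors)
    if model_prior_probs is None:
        model_prior_probs = {m: 1.0 / len(model_set) for m in model_set}
    marginal = marginal_model_posterior(prev, model_set)

    q_model = sum(
        marginal[src] * _model_kernel_prob(model, src, model_set, switch_prob)
        for src in model_set
    )
    if q_model <= 0.0:
        raise ValueError(
            f"model {model.name} cannot be proposed from the previous population "
            f"(zero marginal everywhere and switch_prob={switch_prob})"
        )

    prior = model_priors[model]
    names = prior.names
    same = [p for p in prev.particles if p.model is model]
    if same:
        w = np.array([p.weight for p in same])
        w = w / w.sum()
        src = np.array([[p.params.get(n) for n in names] for p in same])
        bw = np.array([bandwidths[model][n] for n in names])
        q_theta = float(np.dot(w, _kernel_density(params.as_array(names), src, bw)))
        if q_theta <= 0.0:
            q_theta = np.finfo(float).tiny
    else:
        q_theta = prior.density(params)
    return model_prior_probs[model] * prior.density(params) * s / (q_model * q_theta)


# ---------------------------------------------------------------------------
# the shared SMC engine


def _categorical(probs: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(probs), rng.random() * probs.sum(), side="right"))


def _adaptive_bandwidths(
    pop: Population, model_priors: dict[ModelId, PriorSpec]
) -> dict[ModelId, dict[str, float]]:
    """Per-model, per-parameter kernel bandwidth sqrt(2 × weighted variance)
    of the population, floored at 1e-3 of the prior range so the kernel
    never degenerates when a marginal collapses."""
    out: dict[ModelId, dict[str, float]] = {}
    for model, prior in model_priors.items():
        same = [p for p in pop.particles if p.model is model]
        bws = {}
        for name in prior.names:
            lo, hi = prior.ranges[name]
            floor = 1e-3 * (hi - lo)
            if same:
                w = np.array([p.weight for p in same])
                w = w / w.sum()
                x = np.array([p.params.get(name) for p in same], dtype=float)
                mean = float(np.dot(w, x))
                var = float(np.dot(w, (x - mean) ** 2))
                bws[name] = max(np.sqrt(2.0 * var), floor)
            else:
                # fresh prior draws need no perturbation; keep a sane value
                # for density bookkeeping if the model reappears
                bws[name] = 0.5 * (hi - lo)
        out[model] = bws
    return out


def _run_joint_smc(
    data: UndirectedGraph,
    model_priors: dict[ModelId, PriorSpec],
    config: ABCConfig,
    rng: np.random.Generator,
    model_prior_probs: dict[ModelId, float] | None = None,
) -> list[Population]:
    """Sequential importance sampler over (model, parameters) particles.

    With a single configured model no RNG draws are spent on model choice
    or the model kernel, so the trace is identical to the plain
    single-model sampler's.
    """
    models = list(model_priors)
    multi = len(models) > 1
    if model_prior_probs is None:
        model_prior_probs = {m: 1.0 / len(models) for m in models}
    if config.sampling is not None and config.sampling.n_sampled != data.node_count:
        raise ValueError(
            f"sampling config expects data with {config.sampling.n_sampled} nodes, "
            f"got {data.node_count}"
        )
    switch_prob = config.kernel.model_switch_prob
    fixed_bw = config.kernel.bandwidths

    populations: list[Population] = []
    bandwidths: dict[ModelId, dict[str, float]] = {}
    max_attempts = config.max_attempts_factor * config.n_particles

    for t in range(1, config.n_populations + 1):
        if config.epsilon_schedule is not None:
            eps = config.epsilon_schedule[t - 1]
        elif t == 1:
            eps = np.inf
        else:
            eps = adaptive_epsilon(populations[-1], config.epsilon_quantile)

        prev = populations[-1] if populations else None
        if prev is not None:
            prev_marginal = marginal_model_posterior(prev, models)
            by_model = {
                m: [p for p in prev.particles if p.model is m] for m in models
            }
            by_model_w = {
                m: (np.array([p.weight for p in parts]) if parts else None)
                for m, parts in by_model.items()
            }

        particles: list[Particle] = []
        attempts = 0
        while len(particles) < config.n_particles:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"generation {t}: acceptance stalled at tolerance {eps:.6g} "
                    f"after {attempts - 1} proposals for "
                    f"{config.n_particles} particles; relax the schedule or "
                    f"raise max_attempts_factor"
                )
            if t == 1:
                model = (
                    models[_categorical(
                        np.array([model_prior_probs[m] for m in models]), rng)]
                    if multi
                    else models[0]
                )
                theta = model_priors[model].sample(rng)
            else:
                if multi:
                    src_model = models[_categorical(
                        np.array([prev_marginal[m] for m in models]), rng)]
                    model = perturb_model(src_model, models, switch_prob, rng)
                else:
                    model = models[0]
                sources = by_model[model]
                if not sources:
                    theta = model_priors[model].sample(rng)
                else:
                    w = by_model_w[model]
                    src = sources[_categorical(w, rng)]
                    theta = perturb_parameters(
                        src.params, bandwidths[model], model_priors[model], rng
                    )
                    if theta is None:
                        continue  # retry with a freshly resampled source
            dists = _simulate_distances(model, theta, data, config, rng)
            s = int(np.sum(dists <= eps))
            if s == 0:
                continue
            if t == 1:
                weight = float(s)
            else:
                weight = compute_weight_joint(
                    model, theta, s, prev, bandwidths, model_priors,
                    switch_prob if multi else 0.0, model_prior_probs,
                )
            particles.append(
                Particle(model, theta, weight, s, float(dists.min()))
            )
        pop = Population(tuple(particles), float(eps), t).normalized()
        populations.append(pop)
        bandwidths = (
            {m: dict(fixed_bw) for m in models}
            if fixed_bw is not None
            else _adaptive_bandwidths(pop, model_priors)
        )
    return populations


def run_abc_smc_model_selection(
    data: UndirectedGraph,
    model_priors: dict[ModelId, PriorSpec],
    config: ABCConfig,
    rng: np.random.Generator,
    model_prior_probs: dict[ModelId, float] | None = None,
) -> tuple[list[Population], ModelPosterior]:
    """Joint model/parameter ABC-SMC; returns the population trace and the
    final marginal model posterior. The model prior is uniform unless
    ``model_prior_probs`` says otherwise."""
    if len(model_priors) < 2:
        raise ValueError("model selection needs at least two candidate models")
    populations = _run_joint_smc(data, model_priors, config, rng, model_prior_probs)
    posterior = marginal_model_posterior(populations[-1], list(model_priors))
    return populations, posterior
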