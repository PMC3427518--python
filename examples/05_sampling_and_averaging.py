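"""Infer full-network properties from an incomplete interactome sample.

A DACR "truth" network stands in for the full proteome; only half of its
nodes are observed. Inference runs with the node-sampling model switched on
(every simulation is grown to the full size and subsampled to the data's
size), and the fitted posterior is then used to reconstruct the degree
distribution of the *full* network, with the degree-zero correction
applied.
"""

import numpy as np

from pinabc import (
    ABCConfig,
    ModelId,
    PriorSpec,
    SamplingConfig,
    degree_distribution,
    grow_dacr,
    induced_subsample,
    posterior_predictive_degree_distribution,
    run_abc_smc,
    sampling_fraction,
)

N_TOTAL, N_SAMPLED = 600, 300
truth = grow_dacr(N_TOTAL, 0.4, 0.25, 0.7, 3.0, np.random.default_rng(2012))
rng = np.random.default_rng(1)
data = induced_subsample(truth, N_SAMPLED, rng)
print(f"full network: {truth.node_count} nodes, {truth.edge_count} edges")
print(f"observed sample: {data.node_count} nodes, {data.edge_count} edges "
      f"(sampling fraction {sampling_fraction(N_SAMPLED, N_TOTAL):.2f})")

prior = PriorSpec({"delta": (0.0, 1.0), "alpha": (0.0, 1.0),
                   "p": (0.0, 1.0), "m": (0.1, 8.0)})
config = ABCConfig(n_particles=80, n_populations=4,
                   sampling=SamplingConfig(N_TOTAL, N_SAMPLED))
populations = run_abc_smc(data, ModelId.DACR, prior, config, rng)

predicted = posterior_predictive_degree_distribution(
    populations, SamplingConfig(N_TOTAL, N_TOTAL), rng, n_draws=400
)
observed = degree_distribution(truth)[1:]
observed = observed / observed.sum()

n = max(len(predicted), len(observed))
pred = np.pad(predicted, (0, n - len(predicted)))
obs = np.pad(observed, (0, n - len(observed)))
print(f"total-variation distance, predicted vs true degree distribution: "
      f"{0.5 * np.abs(pred - obs).sum():.4f}")
print("degree  predicted  true")
for k in range(min(8, n)):
    print(f"{k + 1:6d}  {pred[k]:9.4f}  {obs[k]:6.4f}")

# Despite seeing only half of the nodes, the posterior-predictive degree
# distribution of the full 600-node network tracks the truth closely; the
# same pipeline run on a 25% sample gives a visibly larger TV distance.
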