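"""Simulate a labeling experiment and recover the rate constants.

Generates 80 genes at the study design (6 time points, 2 fractions,
2 replicates, mean-dependent replicate noise), fits the replicate-noise
model and then each gene's (kE, kD, kT) by weighted Levenberg-Marquardt,
and compares the estimates with the simulation ground truth.
"""

import numpy as np
from scipy.stats import spearmanr

from nucflux import FitConfig, fit_dataset, fit_noise_model
from nucflux.simulate import sample_gene_parameters, simulate_experiment
from nucflux.studies import noise_only_config

config = noise_only_config(n_genes=80, seed=4)
rng = config.rng()
truth = sample_gene_parameters(config, rng)
experiment = simulate_experiment(truth, config, rng)

noise = fit_noise_model(experiment.expression, min_points=80)
print(f"replicate CV at FPKM 10: {float(noise(10.0)):.3f}")

results, report = fit_dataset(
    experiment.expression.rename(columns={"fpkm_spikenorm": "abundance"}),
    config.cell_cycle,
    noise,
    FitConfig(),
)
print(f"fitted {report['n_fitted']} gene x replicate series, "
      f"{report['n_retained']} genes retained at r^2 > 0.8")

merged = results[results.converged].merge(truth, on="gene_id")
for est, tru, label in [
    ("transcription_rate_fpkm_per_min", "kS", "transcription"),
    ("export_rate_per_min", "kE", "export"),
    ("decay_rate_per_min", "kD", "decay"),
]:
    rho = spearmanr(merged[est], merged[tru]).statistic
    err = np.median(np.abs(np.log2(merged[est] / merged[tru])))
    print(f"{label:14s} Spearman(true, est) = {rho:.3f}, "
          f"median |log2 error| = {err:.3f}")

print(
    "\nTranscription is pinned by the t=0 abundances and recovered almost "
    "perfectly; export and decay come from the curve shapes and carry the "
    "replicate noise, hence the lower but still strong rank correlation."
)
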