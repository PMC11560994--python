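"""Synthetic RCBD trials with planted AMMI structure, and recovery.

Generates a trial shaped like the maize study (the generator defaults),
shows that a noise-free fit returns the planted interaction exactly, and
then runs a small seeded recovery study under plot noise.
"""

import numpy as np

from ammistab import cell_means, fit_ammi, generate_met, recovery_study

# noise-free: the fit must return the planted singular values exactly
trial, truth = generate_met(
    G=20, E=5, r=3, singular_values=(6.0, 3.0), block_sd=0.0, error_sd=0.0, seed=1
)
fit = fit_ammi(cell_means(trial), n_axes="all")
print("planted singular values:", truth.singular_values)
print("recovered (noise-free):  ", np.round(fit.singular_values[:2], 10))
print("-> exact recovery in the noiseless limit.\n")

# noisy: 50 genotypes, 5 sites, 3 blocks, plot error sd 0.3 t/ha
res = recovery_study(
    n_reps=50, seed=11, G=50, E=5, r=3, singular_values=(6.0, 3.0),
    block_sd=0.1, error_sd=0.3,
)
print("recovery under noise (50 replicates):")
print(res["summary"].round(4).to_string())
print(f"mean Spearman agreement of true vs fitted ASV ranks: "
      f"{res['mean_asv_spearman']:.3f}")
print("\nThe leading singular value is recovered with a relative RMSE of a",
      "couple of percent (noise inflates it slightly, hence the small",
      "positive bias), and stability rankings are essentially preserved.")
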