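"""Inferring replication origins from a noisy abundance track.

Generates a 300 kb chromosome with four origins of known position and
firing intensity, simulates a sequencing track with multiplicative Gamma
noise (CV 4%), and runs the simulated-annealing/AIC inference to recover
origin number, positions, intensities and Lambda/v.
"""

import numpy as np

import repliprog as rp

true = rp.YeastModelParams(
    origins=rp.PointOriginSet.single_chrom(
        [40e3, 110e3, 180e3, 260e3], [2e-5, 4e-5, 8e-5, 1.5e-4]
    ),
    lam_hat=1e-5,  # Lambda/v per bp
)
observed = rp.simulate_yeast_abundance(
    true, chrom_length=300e3, bin_bp=1000, noise=rp.NoiseConfig(cv=0.04, seed=0)
)

model = rp.anneal_fit(observed, rp.InferenceConfig(seed=0))
inferred = model.params.origins

print(f"inferred K = {model.n_origins} origins (truth: 4); "
      f"Lambda/v = {model.params.lam_hat:.2e} /bp (truth 1.0e-05)")
print(f"{'true pos':>10} {'inferred':>10} {'dist bp':>8} {'true iota':>10} {'inferred':>10}")
for pos, iota in zip(true.origins.position, true.origins.intensity):
    j = int(np.argmin(np.abs(inferred.position - pos)))
    print(f"{pos:10.0f} {inferred.position[j]:10.0f} "
          f"{abs(inferred.position[j] - pos):8.0f} {iota:10.1e} {inferred.intensity[j]:10.1e}")
print("positions land within ~1 bin; intensities are identifiable because")
print("the firing rates are comparable to the growth rate (I*/Lambda ~ 2-15)")
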