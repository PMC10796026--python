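"""Validating an inferred origin set against a reference annotation.

Compares two origin sets by kernel-density correlation across smoothing
scales, nearest-neighbour distances, and rank tests against two null
models: random shifts of each origin and a chromosome-label shuffle.
"""

import numpy as np

import repliprog as rp

rng = np.random.default_rng(0)
chroms = [f"chr{i + 1}" for i in range(8)]
lengths = {c: 1.2e6 for c in chroms}

# "known" annotation: ~20 origins per chromosome
cs, ps = [], []
for c in chroms:
    pos = np.sort(rng.uniform(0, lengths[c], 20))
    cs.extend([c] * 20)
    ps.extend(pos)
known = rp.PointOriginSet(cs, ps, [1e-4] * len(ps))

# "inferred" set: the same origins located with ~3 kb error
inferred = rp.null_shift(known, max_shift=3e3, seed=1, chrom_lengths=lengths)

report = rp.validate_origins(inferred, known, seed=2, chrom_lengths=lengths)
print("Pearson correlation of origin densities (observed vs nulls):")
print(f"{'scale kb':>9} {'observed':>9} {'shifted':>9} {'shuffled':>9}")
for s in report.correlation_observed:
    print(f"{s / 1e3:9.0f} {report.correlation_observed[s]:9.3f} "
          f"{report.correlation_shift_null[s]:9.3f} "
          f"{report.correlation_shuffle_null[s]:9.3f}")
print(f"median distance inferred->known: {report.median_inferred_to_known:.0f} bp")
print(f"median distance known->inferred: {report.median_known_to_inferred:.0f} bp")
print(f"rank-test p (observed vs shift null):   {report.p_shift:.2e}")
print(f"rank-test p (observed vs shuffle null): {report.p_shuffle:.2e}")
print("small observed distances and a correlation peak at small scales that")
print("vanishes under both nulls indicate genuine positional agreement")
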