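"""From a replication program to sequencing abundance, and back to speed.

In an asynchronous exponential culture, genome ages are exponentially
distributed, so any replication program f(x, tau) maps to a DNA abundance
P(x) = E[exp(-Lambda * tau_rep(x))].  This script builds a deterministic
single-fork program, computes its abundance, and then inverts the
abundance track back into the local fork speed.
"""

import numpy as np

import repliprog as rp

growth = rp.GrowthRate.from_doubling_time(7200.0)  # 2 h doubling
print(f"growth rate Lambda = {growth.lam:.3e} /s")

# a fork leaving an origin at x = 0 and accelerating along the chromosome
speed = lambda x: 20.0 + 2e-5 * x  # bp/s  # noqa: E731
edges = np.arange(0, 300_001, 1000.0)
mid = 0.5 * (edges[:-1] + edges[1:])
values = rp.deterministic_abundance(0.0, 0.0, speed, growth, mid)
profile = rp.AbundanceProfile.from_arrays("chr", edges[:-1], edges[1:], values)

print(f"abundance at origin  : {values[0]:.4f}  (origin present in every genome)")
print(f"abundance at 300 kb  : {values[-1]:.4f}  (late regions are rarer)")

recovered = rp.speed_from_abundance(profile, growth)
ok = ~recovered.flagged
err = np.abs(recovered.speed[ok] - speed(recovered.position[ok])) / speed(recovered.position[ok])
print(f"speed inverted from the track: max relative error {100 * err.max():.3f}% "
      f"over {ok.sum()} interior bins")
print("the log-slope of the abundance is -Lambda/v(x): steeper decay = slower fork")
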