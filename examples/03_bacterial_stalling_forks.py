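"""Stochastically stalling replication forks on a circular genome.

Two forks leave the origin in opposite directions; each is the running
extremum of a drift-diffusion process, so backwards excursions of the
auxiliary process appear as stalls.  The single-fork replication program
is an inverse-Gaussian first-passage law, and the meeting point of the two
forks is spread around the terminus by Delta Z = sqrt(D L / (2 v0)).
"""

import numpy as np

import repliprog as rp

growth = rp.GrowthRate(2.0 / 3600.0)  # 2 divisions per hour
params = rp.BacterialParams(L=5e6, v0=1e3, D=1.25e7, growth=growth)
print(f"Peclet number Pe = L v0 / 4D = {params.peclet:.0f} (large: stalls are short)")

traj = rp.simulate_forks(params, n_paths=4000, dt=0.25, seed=0)
z = traj.meeting_point
print(f"meeting point: mean {z.mean():.3e} bp (terminus at {params.L / 2:.3e})")
print(f"spread: simulated sd {z.std(ddof=1):.3e} bp, "
      f"theory sqrt(DL/2v0) = {rp.meeting_point_spread(params):.3e} bp")

# single-fork first-passage law vs the inverse-Gaussian program
level = 1e6
fp = rp.first_passage_times(params, level, n_paths=4000, dt=0.1, seed=1)
fp = np.sort(fp[np.isfinite(fp)])
cdf = rp.fork_program(params, level, fp, fork=1)
emp = np.arange(1, len(fp) + 1) / len(fp)
print(f"first passage at {level:.0e} bp: Kolmogorov distance to the "
      f"inverse-Gaussian CDF = {np.max(np.abs(cdf - emp)):.4f}")

# abundance: smooth near the terminus for D > 0, cusped for D = 0
xs = np.array([0.0, 1.25e6, 2.5e6])
p_stoch = rp.abundance(params, xs)
p_det = rp.abundance(rp.BacterialParams(L=5e6, v0=1e3, D=0.0, growth=growth), xs)
print(f"abundance at origin/quarter/terminus: stochastic {np.round(p_stoch, 4)}, "
      f"deterministic {np.round(p_det, 4)}")
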