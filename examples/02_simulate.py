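"""Draw networks from the two-layer ERGM and check a closed-form limit.

With only arc (density) effects the 2n(n-1) tie variables are independent
Bernoulli draws, so the expected density is logistic(theta_arc) — a useful
sanity check that the Metropolis chain targets the right distribution.
"""

import numpy as np

import dissonet as dn

spec = dn.ModelSpec(effects=(dn.EffectSpec("arc", "F"), dn.EffectSpec("arc", "D")))
theta = np.array([-2.0, -3.0])

batch = dn.simulate(theta, spec, None, n_actors=30,
                    settings=dn.SamplerSettings(n_samples=500, seed=11))
dens = batch.mean() / (30 * 29)
expected = 1 / (1 + np.exp(-theta))
print("realised density  F=%.4f  D=%.4f" % tuple(dens))
print("logistic(theta)   F=%.4f  D=%.4f" % tuple(expected))
print("acceptance rate   %.2f" % batch.acceptance_rate)

# with a positive reciprocity effect, mutual dyads appear far in excess of
# the independence expectation density^2 per dyad
spec2 = dn.ModelSpec(effects=(dn.EffectSpec("arc", "F"),
                              dn.EffectSpec("reciprocity", "F")))
batch2 = dn.simulate(np.array([-3.0, 2.0]), spec2, None, 30,
                     dn.SamplerSettings(n_samples=500, seed=12, return_graphs=True))
mean_recip = np.mean([dn.count_reciprocated_pairs(g.F) for g in batch2.graphs])
d = batch2.mean()[0] / (30 * 29)
print("\nreciprocity effect +2.0: %.1f mutual dyads per draw" % mean_recip)
print("independence expectation: %.1f" % (30 * 29 / 2 * d**2))
print("the excess is the reciprocity effect at work.")
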