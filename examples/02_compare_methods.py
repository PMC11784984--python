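"""Compare the three effect estimators on an all-linear system.

With linear models throughout, the analytic coefficient-function estimator
(method 1) and the partial-difference estimator (method 2) coincide per
posterior draw, and the re-sampling estimator (method 3) agrees with both up
to Monte-Carlo error — so the printed rows should be nearly identical.
"""

import numpy as np

import medbayes as mb

mediators = (
    mb.ContinuousMediatorSim("m1", a=0.8, sd=1.0),
    mb.ContinuousMediatorSim("m2", a=-0.6, sd=1.2),
)
outcome = mb.OutcomeSim(intercept=5.0, c=1.0, b={"m1": -0.5, "m2": 0.4}, sd=1.5)
cfg = mb.SyntheticConfig(n=2000, mediators=mediators, outcome=outcome, seed=10)
data = mb.generate(cfg)
truth = mb.true_effects(cfg)

od, md = mb.fit_models(data, mb.PriorConfig(),
                       mb.MCMCConfig(n_iter=4000, burn_in=1000, seed=11))

e1 = mb.method1_effects(od, md, data)
e2 = mb.method2_effects(od, md, data)
e3 = mb.method3_effects(od, md, data, resample_seed=12)

print(f"{'':14s}{'truth':>9s}{'method 1':>10s}{'method 2':>10s}{'method 3':>10s}")
rows = [("TE", truth["te"], e1.te, e2.te, e3.te),
        ("DE", truth["de"], e1.de, e2.de, e3.de)]
rows += [(f"IE {k}", truth["ie"][k], e1.ie[k], e2.ie[k], e3.ie[k]) for k in ("m1", "m2")]
for label, t, v1, v2, v3 in rows:
    print(f"{label:14s}{t:9.3f}{v1.mean():10.3f}{v2.mean():10.3f}{v3.mean():10.3f}")

print(f"\nmax per-draw |method1 - method2| on TE: {np.abs(e1.te - e2.te).max():.2e}")
print("Methods 1 and 2 are algebraically identical here; method 3 differs "
      "only by re-sampling noise.")
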