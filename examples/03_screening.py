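"""Pre-screen candidate mediators with the two-condition rule.

A candidate passes when it is (1) associated with the outcome after
adjustment (p-value 1) and (2) distributed differently across the exposure
groups (p-value 2), both at the 0.1 level; forced candidates bypass the
tests.  Here `signal` satisfies both conditions, `noise` fails both, and
`forced_noise` fails both but is declared forced.
"""

import numpy as np
import pandas as pd

import medbayes as mb

rng = np.random.default_rng(2)
n = 1000
x = rng.binomial(1, 0.3, n).astype(float)
signal = 0.8 * x + rng.standard_normal(n)
noise = rng.standard_normal(n)
forced_noise = rng.standard_normal(n)
y = 60.0 - 3.0 * x + 1.2 * signal + 8.0 * rng.standard_normal(n)

data = mb.MediationDataset(
    pd.DataFrame({"x": x, "signal": signal, "noise": noise,
                  "forced_noise": forced_noise, "y": y}),
    exposure="x", outcome="y",
    mediators=[mb.MediatorSpec("signal"),
               mb.MediatorSpec("noise"),
               mb.MediatorSpec("forced_noise", forced=True)],
)

report = mb.screen(data, alpha=0.1)
print(report)
print("\nIncluded:", report.included)
print("`noise` fails both conditions and is dropped; `forced_noise` fails "
      "them too but stays because it was forced on substantive grounds.")
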