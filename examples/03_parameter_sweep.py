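"""How vessel permeability and binding strength shape drug exposure.

Two one-at-a-time sweeps of the 72 h cord model. Increasing the vessel-wall
permeability k_v raises exposure everywhere. Lowering the binding ratio
beta = k_m2/k2 (stronger binding) always helps next to the vessel but has
an optimum far from it: bind too avidly and the drug never gets there.
"""

from cordsim import analysis

kv_sweep = analysis.parameter_sweep("kv", [2.8e-7, 2.8e-6, 2.8e-5], ["pk1"])
print("vessel-wall permeability sweep (exposures in uM h):")
print(kv_sweep.to_string(index=False))

beta_sweep = analysis.parameter_sweep("beta", [0.01, 1.0, 140 / 9, 150.0], ["pk1"])
print("\nbinding-ratio sweep (beta in uM; smaller = stronger binding):")
print(beta_sweep.to_string(index=False))
print(
    "\nNote the far-field maximum at an intermediate beta: the baseline"
    "\nvalue (140/9 uM) trades peak near-vessel exposure for uniformity."
)
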