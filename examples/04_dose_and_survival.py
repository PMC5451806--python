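"""Dose dependence and threshold cell-kill.

At 1000x the standard dose the intracellular binding sites saturate: the 3 h
constant profile (pk3) stops supplying drug early and falls well behind the
infusion profiles. The survival fraction applies a hard exposure threshold
(a cell dies if its bound-drug exposure exceeds it) to the same fields.
"""

from cordsim import analysis

D0 = 1.19827e2  # standard dose, umol

table = analysis.dose_sweep([D0, D0 * 1e3], ["pk1", "pk3"])
print("72 h bound-drug exposure (uM h) vs dose:")
print(table.to_string(index=False))

surv = analysis.survival_sweep(
    [D0 * 0.4, D0 * 0.6, D0], threshold=165.0, pk_ids=["pk1", "pk3"]
)
print("\nsurviving tissue fraction below a 165 uM h kill threshold:")
print(surv.to_string(index=False))
print("\nThe kill switch flips over a narrow dose window, and near the")
print("transition the delivery schedule decides which tissue survives:")
print("at 0.6x the standard dose the constant profile kills everything")
print("while the short infusion spares the distal two-thirds of the cord.")
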