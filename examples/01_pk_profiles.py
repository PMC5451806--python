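"""Evaluate the three vessel-inflow PK profiles and their exposures.

The single short infusion (pk1), three repeated one-third-dose infusions
(pk2) and the 3 h constant profile (pk3) all deliver the same total AUC;
what differs is when that exposure arrives.
"""

from cordsim import analytic_auc, make_profile

HOUR = 3600.0

for kind in ("pk1", "pk2", "pk3"):
    pk = make_profile(kind)
    print(f"{kind}: C_v(1 h) = {float(pk(HOUR)):.4f} uM"
          f" | AUC(72 h) = {analytic_auc(pk, 72 * HOUR) / HOUR:.4f} uM h"
          f" | AUC(inf) = {analytic_auc(pk) / HOUR:.4f} uM h")

# All three total AUCs match (~2.773 uM h, the clinically typical dose),
# but at 72 h the repeated-infusion profile has delivered the least:
# its later infusions are still washing out.
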