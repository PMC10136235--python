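"""Peripheral pressure does not determine the transvalvular gradient.

Runs a small factorial grid of arterial compliance (TAC) and resistance
(TVR) combinations with identical ventricular function and valve area,
then looks for pairs of cases with nearly the same systolic pressure but
clearly different mean gradients.
"""

from itertools import combinations

from stenoflow import bp_tpg_map, tree24

tree = tree24()
grid = bp_tpg_map(tac_grid=[0.6, 1.2, 1.8], tvr_grid=[0.7, 1.1, 1.5], tree=tree)
print(grid.round(1).to_string(index=False))

print("\nsimilar systolic pressure, different gradient:")
for i, j in combinations(range(len(grid)), 2):
    a, b = grid.iloc[i], grid.iloc[j]
    if abs(a.sbp_mmhg - b.sbp_mmhg) < 5 and abs(a.mean_tpg_mmhg - b.mean_tpg_mmhg) > 2:
        print(f"  (TAC {a.tac}, TVR {a.tvr}) vs (TAC {b.tac}, TVR {b.tvr}): "
              f"SBP {a.sbp_mmhg:.0f} vs {b.sbp_mmhg:.0f} mmHg, "
              f"TPG {a.mean_tpg_mmhg:.1f} vs {b.mean_tpg_mmhg:.1f} mmHg")
# Cuff pressure alone cannot substitute for a full afterload evaluation
# when interpreting a transvalvular gradient.
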