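"""Generate a synthetic systemic arterial tree and inspect its afterload.

The blueprint describes an aortic trunk with distal taper, the major
branch vessels, wave speeds rising toward the periphery, and terminal
Windkessels distributed by regional flow fractions.  The result is a
plausible but explicitly non-anatomical stand-in geometry.
"""

from stenoflow import TreeBlueprint, generate_tree
from stenoflow.fixtures import SYNTHETIC_HEADER, subdivide_tree
from stenoflow.network import P_REF, amax_from_reference, wave_speed

tree = generate_tree(TreeBlueprint(seed=42))
tree.save("my_tree.csv", header_comment=SYNTHETIC_HEADER + "\nseed 42")

tvr, tac = tree.aggregate_afterload()
print(f"{tree.n_segments()} segments, {len(tree.terminals)} Windkessel outlets")
print(f"aggregate TVR {tvr:.2f} mmHg*s/mL, TAC {tac:.2f} mL/mmHg")
root = tree.root
c_root = wave_speed(P_REF, amax_from_reference(root.area_prox, root.p0, root.p1),
                    root.p0, root.p1)
print(f"root area {root.area_prox:.1f} cm^2, wave speed {c_root/100:.1f} m/s")

dense = subdivide_tree(tree, 103)
print(f"refined copy: {dense.n_segments()} segments, "
      f"same afterload {dense.aggregate_afterload()[0]:.2f} / "
      f"{dense.aggregate_afterload()[1]:.2f}")
# Every generated tree passes the loader's validation (connectivity,
# positivity, distally rising wave speeds) and lands inside the
# physiological afterload ranges before any rescaling.
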