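"""Simulate a random network and draw a circular phylogram.

Branch lengths drive the radius; y-rows become angles via
angle = y / H * 360 with H = backbone leaves + 1.
"""

import phylodraw as pd
from phylodraw.simulate import SimulationSpec, random_network, render_svg

net = random_network(SimulationSpec(n=16, h=3, seed=4, weights=True))
print(f"simulated n={len(net.taxa)} taxa, "
      f"h={len(net.reticulate_nodes())} reticulations; "
      f"valid={not pd.validate_network(net)}")

lr = pd.compute_layout(net, style="phylogram", circular=True, seed=0)
angles = [lr.circular[v][1] for v in net.leaves()]
print(f"leaf angles span {min(angles):.1f}..{max(angles):.1f} degrees "
      f"(H={lr.H})")
print(f"displacement={lr.displacement:.3f}")

with open("example_circular.svg", "w") as fh:
    fh.write(render_svg(net, lr))
print("wrote example_circular.svg")
print(pd.write_extended_newick(net)[:70] + "...")
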