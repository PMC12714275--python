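"""Round-trip a tree through a raster image.

Renders a simulated tree to a black-on-white bitmap (labels exported as
a sidecar of bounding boxes, standing in for OCR), then captures the
topology back: skeletonize, detect branch points, trace paths, grow the
network from the root location, attach labels.
"""

import phylodraw as pd
from phylodraw.simulate import SimulationSpec, random_network, render_raster_fixture

net = random_network(SimulationSpec(n=10, h=0, seed=6))
lr = pd.compute_layout(net, optimize=False, equal_spacing=False)
img, boxes, node_px = render_raster_fixture(net, lr)
print(f"rendered {img.shape[1]}x{img.shape[0]} raster, "
      f"{len(boxes)} label boxes")

result = pd.capture_network(img, node_px[net.root], label_boxes=boxes)
print(f"orientation={result.orientation} "
      f"unresolved={len(result.unresolved_paths)}")

captured = pd.remove_through_nodes(result.network)
print("captured taxa:", sorted(captured.taxa))
print("isomorphic to the source tree:",
      pd.labeled_isomorphic(net, captured, check_weights=False))
# True: the capture recovered the exact labeled topology from pixels.
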