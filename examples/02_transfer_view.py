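"""Draw a horizontal-gene-transfer network in the transfer view.

The ## tag designates the transfer-acceptor edge: that parent is drawn
as the main lineage, the other parent as a transfer arc.  The
transfer-depth adjustment lifts the arc's source so both endpoints can
share a depth column where possible.
"""

import phylodraw as pd
from phylodraw.layout import adjust_transfer_depths, compute_depths
from phylodraw.network import EdgeKind, classify_edge

TEXT = "((a,(b)#H1),(##H1,c));"
net = pd.parse_extended_newick(TEXT)[0]

d0 = compute_depths(net)
d1 = adjust_transfer_depths(net, d0)
for e in net.edges:
    if classify_edge(net, e) is EdgeKind.TRANSFER:
        v, w = e
        print(f"transfer edge {v}->{w}: depth {d0[v]} -> {d1[v]} "
              f"(target at {d1[w]})")
# The source depth rises to at least the target depth, so the transfer
# arc never has to point back toward the root.

lr = pd.compute_layout(net, view="transfer", seed=0)
from phylodraw.layout import count_crossings, tree_edge_segments
print("crossings among tree + acceptor edges:",
      count_crossings(tree_edge_segments(net, lr)))
# Always 0: only transfer arcs are allowed to cross anything.
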