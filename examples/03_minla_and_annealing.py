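"""Reticulate-displacement minimization contains MinLA.

A Minimum Linear Arrangement instance embeds as a star network whose
displacement under a leaf order equals the arrangement cost exactly, so
the optimizer doubles as a MinLA heuristic — and MinLA enumeration
doubles as an exactness oracle for the optimizer.
"""

from phylodraw.optimize import (MinLAInstance, SAConfig, displacement_of,
                                minla_brute_force, minla_to_network,
                                optimize_child_orders)

# a 6-cycle: the optimal linear arrangement costs 10
g = MinLAInstance(vertices=list(range(6)),
                  edges={frozenset([i, (i + 1) % 6]) for i in range(6)})

opt = minla_brute_force(g)            # exact, by enumerating 6! orders
net, b = minla_to_network(g)
b.children[net.root] = b.children[net.root][::2] + b.children[net.root][1::2]
print(f"enumerated MinLA optimum: {opt}")
print(f"displacement of a scrambled order: {displacement_of(net, b)}")

b2 = optimize_child_orders(net, b, sa=SAConfig(seed=0))
print(f"displacement after optimization:  {displacement_of(net, b2)}")
# The heuristic reaches the enumerated optimum on instances this small;
# with more than 8 children per node it switches to simulated annealing
# (start T=1000, end T=0.01, 1000 iterations/step, cooling 0.95).
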