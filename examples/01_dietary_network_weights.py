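"""Food-group centrality weights from the published dietary network.

Loads the published 16-node partial-correlation network shipped with the
package, computes max-normalized eigenvector centralities, and prints the
weight of every food group.  The weight answers: how embedded is this food
group in the whole-diet consumption pattern?  Seasonings anchor the Korean
screenee diet (weight 1.00); milk/dairy and cereals sit at the periphery.
"""

from comorisk import PartialCorrelationNetwork, eigenvector_centrality, reference

network = PartialCorrelationNetwork(
    labels=list(reference.FOOD_GROUPS),
    weights=reference.reference_network_matrix().to_numpy(),
)
weights = eigenvector_centrality(network)

print(f"{'food group':24s} {'centrality':>10s} {'published':>10s}")
for label, w in zip(weights.labels, weights.weight):
    name = reference.FOOD_GROUP_NAMES[label]
    print(f"{name:24s} {w:10.2f} {reference.PUBLISHED_CENTRALITY[label]:10.2f}")
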