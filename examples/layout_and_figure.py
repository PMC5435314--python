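"""Force-directed layout of the hindlimb network.

The spring embedder places adjacent elements near each other, so the
anatomical modules emerge as spatially segregated clusters; the separation
score quantifies this (below 1 = segregated).
"""

from itertools import combinations

import numpy as np

from anna import (
    frog_hindlimb_fixture,
    frog_published_partition,
    fruchterman_reingold,
    layout_separation_score,
)
from anna.layout import LayoutConfig

net = frog_hindlimb_fixture()
published = frog_published_partition(net)
layout = fruchterman_reingold(net, LayoutConfig(iterations=500, seed=1))

edges = set(net.edges())
adj, non = [], []
for u, v in combinations(net.node_ids, 2):
    (xu, yu), (xv, yv) = layout.coordinates[u], layout.coordinates[v]
    (adj if (u, v) in edges else non).append(float(np.hypot(xu - xv, yu - yv)))
print(f"mean distance, adjacent pairs    : {np.mean(adj):.3f}")
print(f"mean distance, non-adjacent pairs: {np.mean(non):.3f}")

score = layout_separation_score(net, layout, published)
print(f"module separation score: {score:.3f}  (< 1 means modules segregate)")

# render the drawing (node colour = module, shape = type)
from anna.report import _draw  # noqa: E402
from pathlib import Path

Path("scratch").mkdir(exist_ok=True)
_draw(net, layout, published, Path("scratch/hindlimb_layout.png"))
print("figure written to scratch/hindlimb_layout.png")
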