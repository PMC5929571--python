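"""Virtual dissection: separate involuting from spreading cells.

Reproduces the gastrulation workflow end to end on simulated data:
keep tracks covering >= 70% of the movie, cluster them (k = 2) on the
displacement ratio, assign the short remainder by majority vote of their
nearest labelled neighbours, and check the result against the
generator's ground truth.  The exported selection tree is then replayed
unchanged on a second, independently simulated embryo.
"""

import numpy as np

import trajkit as tk
from trajkit.selection import SelectionTree, propagate_labels, replay_tree

def dissect(forest, truth, template=None):
    kept, short = tk.filter_by_span(forest, 0.7)
    if template is None:
        tree = SelectionTree(kept)
        lo, hi = tree.cluster_members(tree.root, ["displacement_ratio"], 2)
    else:
        tree = replay_tree(template, kept)
        lo, hi = sorted(
            (n for n in tree.nodes.values() if n.predicate.get("kind") == "cluster"),
            key=lambda n: n.predicate["index"],
        )
    labeled = {t: "hypoblast" for t in lo.members} | {t: "epiblast" for t in hi.members}
    propagated, unassigned = propagate_labels(forest, labeled, set(short.tracks))
    assigned = labeled | propagated
    acc = np.mean([assigned[t] == truth.labels[t] for t in assigned])
    print(f"  {len(labeled)} clustered + {len(propagated)} propagated tracks, "
          f"{len(unassigned)} unassigned; accuracy vs ground truth {acc*100:.2f}%")
    return tree

print("embryo A (seed 1): developing the selection")
forest_a, truth_a = tk.simulate_embryo(tk.EmbryoSimConfig(seed=1))
tree = dissect(forest_a, truth_a)
template = tree.to_json(include_members=False)

print("embryo B (seed 7): replaying the exported template")
forest_b, truth_b = tk.simulate_embryo(tk.EmbryoSimConfig(seed=7))
dissect(forest_b, truth_b, template=template)
# Both accuracies should sit near 99%: the recorded tree is a reusable
# analysis template, not a one-off interactive session.
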