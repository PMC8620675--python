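"""Random additive-tree generator shared by the phylogeny tests."""

import numpy as np


def _random_additive(rng, n):
    """Random binary tree over n leaves with branch lengths in [0.1, 5];
    returns (labels, D, set of non-trivial splits as frozensets)."""
    labels = [f"t{i}" for i in range(n)]
    # start as star, repeatedly join random pair of active subtrees
    nodes = {i: frozenset([labels[i]]) for i in range(n)}
    children = {}
    lengths = {}
    nxt = n
    active = list(range(n))
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False).tolist())
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        lengths[(nxt, a)] = rng.uniform(0.1, 5)
        lengths[(nxt, b)] = rng.uniform(0.1, 5)
        nodes[nxt] = nodes[a] | nodes[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    a, b = active
    root_len = rng.uniform(0.1, 5)
    # leaf-to-leaf path lengths by traversal
    def leaf_depths(node, depth, out):
        if node < n:
            out[labels[node]] = depth
            return
        for ch in children[node]:
            leaf_depths(ch, depth + lengths[(node, ch)], out)

    da, db = {}, {}
    leaf_depths(a, 0.0, da)
    leaf_depths(b, 0.0, db)

    def within(node, out):
        if node < n:
            return
        x, y = children[node]
        dx, dy = {}, {}
        leaf_depths(x, lengths[(node, x)], dx)
        leaf_depths(y, lengths[(node, y)], dy)
        for u, du in dx.items():
            for v, dv in dy.items():
                out[(u, v)] = du + dv
        within(x, out)
        within(y, out)

    pairs = {}
    within(a, pairs)
    within(b, pairs)
    for u, du in da.items():
        for v, dv in db.items():
            pairs[(u, v)] = du + dv + root_len
    D = np.zeros((n, n))
    for (u, v), d in pairs.items():
        iu, iv = labels.index(u), labels.index(v)
        D[iu, iv] = D[iv, iu] = d
    splits = {
        frozenset(nodes[x]) for x in children
    }
    return labels, D, splits


def _tree_splits(tree):
    leaves = frozenset(t.label for t in tree.taxon_namespace)
    tree.encode_bipartitions()
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(t.label for t in edge.bipartition.leafset_taxa(tree.taxon_namespace))
        if 1 < len(side) < len(leaves) - 1:
            out.add(min(side, leaves - side, key=sorted))
    return out
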