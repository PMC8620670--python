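"""Independent brute-force oracles used to verify the fast implementations.

Everything here works from first principles on tiny inputs: patristic
distances by explicit root-path walking, MNTD/comdistnt by exhaustive
nearest-neighbour enumeration over a plain dict-of-dicts distance table, and
NTI by full enumeration of every same-richness subset of the pool.  None of
it shares code with the package internals it checks.
"""

from __future__ import annotations

import math
import random
from itertools import combinations

import dendropy


def random_tree(rng: random.Random, n_tips: int) -> dendropy.Tree:
    """Random binary topology with uniform random branch lengths in (0.1, 2)."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node(taxon=taxa.get_taxon(f"t{i}"))
        node.edge.length = rng.uniform(0.1, 2.0)
        nodes.append(node)
    while len(nodes) > 2:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(0.1, 2.0)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    return dendropy.Tree(seed_node=root, taxon_namespace=taxa)


def path_walk_distances(tree: dendropy.Tree) -> dict[str, dict[str, float]]:
    """Patristic distances by walking each tip's path to the root."""
    paths: dict[str, list[tuple[int, float]]] = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = path
    out: dict[str, dict[str, float]] = {lab: {} for lab in paths}
    for a in paths:
        for b in paths:
            if a == b:
                out[a][b] = 0.0
                continue
            edges_a = dict(paths[a])
            edges_b = dict(paths[b])
            shared = set(edges_a) & set(edges_b)
            out[a][b] = sum(v for k, v in edges_a.items() if k not in shared) + sum(
                v for k, v in edges_b.items() if k not in shared
            )
    return out


def brute_mntd(d: dict[str, dict[str, float]], assemblage) -> float:
    members = sorted(assemblage)
    nearest = [min(d[t][s] for s in members if s != t) for t in members]
    return sum(nearest) / len(nearest)


def brute_comdistnt(
    d: dict[str, dict[str, float]], a, b, exclude_conspecifics: bool = False
) -> float:
    values = []
    for source, target in ((sorted(a), sorted(b)), (sorted(b), sorted(a))):
        for t in source:
            candidates = [s for s in target if not (exclude_conspecifics and s == t)]
            values.append(min(d[t][s] for s in candidates))
    return sum(values) / len(values)


def brute_exhaustive_nti(
    d: dict[str, dict[str, float]], assemblage, pool
) -> tuple[float, float, float, float | None]:
    """(observed, null mean, null sample sd, nti-or-None) over every subset."""
    observed = brute_mntd(d, assemblage)
    values = [brute_mntd(d, subset) for subset in combinations(sorted(pool), len(set(assemblage)))]
    mean = sum(values) / len(values)
    if len(values) > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
    else:
        sd = 0.0
    value = None if sd == 0 else -(observed - mean) / sd
    return observed, mean, sd, value
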