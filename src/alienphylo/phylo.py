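"""Phylogeny input and nearest-taxon distance statistics.

The tree is consumed as a rooted Newick with branch lengths (a mega-tree at
the scale of a national flora, a simulated Yule tree in tests).  All
statistics here are functions of the patristic distance matrix — the sum of
branch lengths along the tip-to-tip path — computed once into a dense
labelled matrix; at checklist scale (~2000 tips) this is a few dozen MB.

* ``mntd``: within one assemblage, the mean over taxa of the distance to the
  nearest other taxon in the assemblage.
* ``comdistnt``: between two assemblages, the mean over all taxa of both sets
  of each taxon's distance to its nearest taxon in the *other* set
  (abundance-unweighted).  Shared taxa contribute distance zero unless
  ``exclude_conspecifics`` is set, in which case a shared taxon is matched
  against the other set minus itself.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from .errors import AssemblageError, TreeError

__all__ = [
    "PatristicMatrix",
    "read_newick",
    "validate_tree",
    "patristic_matrix",
    "mntd",
    "comdistnt",
]


def _tip_key(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else ""


def canonical_label(label: str) -> str:
    """Tip labels are matched after replacing spaces with underscores."""
    return label.strip().replace(" ", "_")


def validate_tree(tree: dendropy.Tree) -> None:
    """Check tip-label uniqueness and that every non-root edge has a length.

    Missing branch lengths are an error (never silently zero); negative
    lengths are rejected.  Polytomies are allowed.
    """
    labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise TreeError("tree must have at least 2 tips")
    if any(not lab for lab in labels):
        raise TreeError("every tip must be labelled")
    counts = Counter(labels)
    dupes = sorted(lab for lab, c in counts.items() if c > 1)
    if dupes:
        raise TreeError(f"duplicate tip label(s): {dupes}")
    any_positive = False
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length
        if length is None:
            tips = [_tip_key(t) for t in node.leaf_iter()][:3]
            where = "tip" if node.is_leaf() else "internal edge above"
            raise TreeError(f"missing branch length on {where} {'/'.join(tips)}")
        if length < 0:
            raise TreeError(f"negative branch length {length} above {'/'.join(_tip_key(t) for t in node.leaf_iter())}")
        if length > 0:
            any_positive = True
    if not any_positive:
        raise TreeError("all branch lengths are zero")


def read_newick(path: str | Path, *, underscores_to_spaces: bool = False) -> dendropy.Tree:
    """Parse a single rooted Newick tree and validate it.

    Underscores in labels are preserved verbatim by default (the convention of
    mega-tree tools); set ``underscores_to_spaces`` to apply the classic
    Newick unquoted-underscore rule instead.
    """
    path = Path(path)
    if not path.exists():
        raise TreeError(f"tree file not found: {path}")
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=not underscores_to_spaces,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick in {path}: {exc}") from exc
    validate_tree(tree)
    return tree


@dataclass(frozen=True)
class PatristicMatrix:
    """Symmetric tip-to-tip path-length distances with labelled axes."""

    labels: tuple[str, ...]
    d: np.ndarray  # (n, n) float64, zero diagonal

    def __post_init__(self):
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise TreeError("distance matrix shape does not match labels")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    def indices(self, names: Iterable[str], *, what: str = "assemblage") -> np.ndarray:
        """Row indices for a set of tip names; missing names raise."""
        idx = self._index
        missing = sorted(n for n in names if n not in idx)
        if missing:
            raise AssemblageError(
                f"{what} taxa not on the tree: {missing[:10]}"
                + (f" (+{len(missing) - 10} more)" if len(missing) > 10 else "")
            )
        return np.fromiter((idx[n] for n in names), dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="")


def patristic_matrix(tree: dendropy.Tree) -> PatristicMatrix:
    """Dense patristic distance matrix over all tips.

    Single postorder pass: each node carries the distances of its subtended
    tips up to itself; tip pairs are completed with an outer sum where their
    paths join.  O(n²) time and memory, comfortable for mega-tree scale.
    Labels are sorted for a stable axis order.
    """
    validate_tree(tree)
    leaves = sorted(tree.leaf_node_iter(), key=_tip_key)
    labels = tuple(canonical_label(_tip_key(leaf)) for leaf in leaves)
    pos = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n), dtype=np.float64)

    # per-node: (tip index array, distances of those tips to this node)
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            carry[id(node)] = (
                np.array([pos[id(node)]], dtype=np.intp),
                np.zeros(1, dtype=np.float64),
            )
            continue
        parts = []
        for child in node.child_nodes():
            idx, dist = carry.pop(id(child))
            parts.append((idx, dist + (child.edge.length or 0.0)))
        for a in range(len(parts)):
            ia, da = parts[a]
            for b in range(a + 1, len(parts)):
                ib, db = parts[b]
                block = da[:, None] + db[None, :]
                d[np.ix_(ia, ib)] = block
                d[np.ix_(ib, ia)] = block.T
        carry[id(node)] = (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
    return PatristicMatrix(labels=labels, d=d)


def mntd(dm: PatristicMatrix, assemblage: Iterable[str]) -> float:
    """Mean nearest-taxon distance within an assemblage.

    Mean over taxa t of min over s ≠ t in the assemblage of d(t, s).
    Requires at least two taxa, all present on the tree.
    """
    names = set(assemblage)
    if len(names) < 2:
        raise AssemblageError(f"mntd needs at least 2 taxa, got {len(names)}")
    idx = dm.indices(names)
    sub = dm.d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def mntd_of_index_sets(dm: PatristicMatrix, index_sets: np.ndarray) -> np.ndarray:
    """Vectorized MNTD for many equal-richness assemblages.

    ``index_sets`` is an (m, k) integer array of tip indices; returns the m
    MNTD values.  Batched so peak memory stays bounded for large k.
    """
    m, k = index_sets.shape
    out = np.empty(m, dtype=np.float64)
    chunk = max(1, int(2e7 // (k * k)))
    for start in range(0, m, chunk):
        block = index_sets[start : start + chunk]
        sub = dm.d[block[:, :, None], block[:, None, :]]
        ii = np.arange(k)
        sub[:, ii, ii] = np.inf
        out[start : start + len(block)] = sub.min(axis=2).mean(axis=1)
    return out


def comdistnt(
    dm: PatristicMatrix,
    a: Iterable[str],
    b: Iterable[str],
    *,
    exclude_conspecifics: bool = False,
) -> float:
    """Mean nearest-taxon distance between two assemblages.

    Each taxon of ``a`` is matched to its nearest taxon in ``b`` and vice
    versa; the |a| + |b| nearest distances are averaged without abundance
    weights.  A taxon shared by both sets contributes distance 0; with
    ``exclude_conspecifics`` its nearest match is taken over the other set
    minus itself (an error if that leaves no candidates).  Symmetric in its
    arguments.  For nested assemblages (the invasion-stage sets) the default
    is pulled toward 0 by shared species — callers should log which mode they
    used.
    """
    set_a, set_b = set(a), set(b)
    if not set_a or not set_b:
        raise AssemblageError("comdistnt requires two non-empty assemblages")
    ia = dm.indices(sorted(set_a), what="first assemblage")
    ib = dm.indices(sorted(set_b), what="second assemblage")

    def nearest(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        sub = dm.d[np.ix_(rows, cols)]
        if exclude_conspecifics:
            sub = sub.copy()
            shared = rows[:, None] == cols[None, :]
            sub[shared] = np.inf
            dead = np.isinf(sub).all(axis=1)
            if dead.any():
                bad = [dm.labels[rows[i]] for i in np.flatnonzero(dead)]
                raise AssemblageError(
                    f"conspecific exclusion leaves no candidates for: {bad[:5]}"
                )
        return sub.min(axis=1)

    values = np.concatenate([nearest(ia, ib), nearest(ib, ia)])
    return float(values.mean())
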