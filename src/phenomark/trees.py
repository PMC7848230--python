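"""Phylogenetic machinery for phenotype alpha diversity.

Trees over ASV representative sequences are either built in-repo
(pairwise global-alignment distances + neighbor joining, suitable for the
few-hundred-tip synthetic scale) or imported as Newick produced by
external alignment/tree tools; either way they are midpoint-rooted before
use. Faith's phylogenetic diversity of a tip subset is the total branch
length of the minimal rooted subtree connecting those tips and the root;
:class:`FaithCalculator` evaluates it in bulk via an edge-incidence matrix
so the samples x phenotypes PAD matrix stays cheap.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .mta import naive_identity


#: p-distance ceiling before Jukes-Cantor correction diverges
_JC_MAX_P = 0.70


def pairwise_distance_matrix(
    rep_seqs: Mapping[str, str], jukes_cantor: bool = True
) -> DistanceMatrix:
    """Pairwise evolutionary distances between sequences.

    Raw p-distances (1 - global-alignment identity) are converted to
    expected substitutions per site with the Jukes-Cantor correction
    d = -3/4 ln(1 - 4p/3), the scale maximum-likelihood tree builders
    report branch lengths on (p is capped at 0.70 to keep near-saturated
    pairs finite). ``jukes_cantor=False`` returns plain p-distances.
    """
    ids = list(rep_seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - naive_identity(rep_seqs[ids[i]], rep_seqs[ids[j]])
            if jukes_cantor:
                p = min(p, _JC_MAX_P)
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest tip-to-tip path."""
    tips = list(tree.tips())
    if len(tips) == 2:
        # two-tip trees: bisect the single path directly
        a, b = tips
        d = (a.length or 0.0) + (b.length or 0.0)
        return TreeNode.read(StringIO(f"({a.name}:{d / 2},{b.name}:{d / 2});"))
    return tree.root_at_midpoint()


def build_tree(rep_seqs: Mapping[str, str]) -> TreeNode:
    """Distance + neighbor-joining tree over sequences, midpoint-rooted."""
    if len(rep_seqs) < 2:
        raise ValueError("tree construction needs at least 2 sequences")
    if len(rep_seqs) == 2:
        (a, _), (b, _) = rep_seqs.items()
        d = pairwise_distance_matrix(rep_seqs)[a, b]
        return TreeNode.read(StringIO(f"({a}:{d / 2},{b}:{d / 2});"))
    dm = pairwise_distance_matrix(rep_seqs)
    unrooted = nj(dm)
    # NJ can emit tiny negative branch lengths; clamp so PD stays >= 0
    for node in unrooted.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return midpoint_root(unrooted)


def read_newick(path: str | Path, rooted: bool = False) -> TreeNode:
    """Import an externally built tree; midpoint-roots unless told rooted."""
    tree = TreeNode.read(str(path))
    return tree if rooted else midpoint_root(tree)


def faith_pd(tree: TreeNode, tips: Iterable[str]) -> float:
    """Faith's phylogenetic diversity of ``tips`` on a rooted tree.

    Sum of branch lengths on the union of root-to-tip paths; the empty set
    has PD 0. Unknown tip names raise KeyError.
    """
    wanted = set(tips)
    if not wanted:
        return 0.0
    known = {t.name for t in tree.tips()}
    missing = wanted - known
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    total = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._pm_covered = node.name in wanted
        else:
            node._pm_covered = any(c._pm_covered for c in node.children)
        if node._pm_covered and node.length:
            total += node.length
    for node in tree.postorder(include_self=False):
        del node._pm_covered
    return total


class FaithCalculator:
    """Vectorised Faith's PD over many tip subsets of one rooted tree.

    Precomputes a tips x edges incidence matrix (edge e lies on the
    root-to-tip path of tip t); PD of a subset is then the branch-length
    total over the OR of its tips' rows.
    """

    def __init__(self, tree: TreeNode):
        edges = [n for n in tree.traverse(include_self=False)]
        self.tip_ids = [t.name for t in tree.tips()]
        tip_index = {t: i for i, t in enumerate(self.tip_ids)}
        self.lengths = np.array([e.length or 0.0 for e in edges])
        inc = np.zeros((len(self.tip_ids), len(edges)), dtype=bool)
        for j, e in enumerate(edges):
            for t in e.tips(include_self=True):
                inc[tip_index[t.name], j] = True
        self.incidence = inc

    def pd(self, tips: Iterable[str]) -> float:
        idx = [self.tip_ids.index(t) for t in tips]
        if not idx:
            return 0.0
        covered = self.incidence[idx].any(axis=0)
        return float(self.lengths @ covered)

    def pd_many(self, membership: np.ndarray) -> np.ndarray:
        """PD per row of a boolean subsets x tips membership matrix."""
        counts = membership.astype(np.float64) @ self.incidence
        return (counts > 0) @ self.lengths
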