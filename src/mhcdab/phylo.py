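"""Distance-based phylogeny of validated alleles.

p-distances or Jukes-Cantor corrected distances, Saitou-Nei neighbour
joining with a deterministic tie rule, and nonparametric bootstrap support
for the branching (percentage of replicate NJ trees containing each
bipartition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .errors import DataError, SaturationError


def alignment_to_array(seqs: dict) -> tuple:
    names = list(seqs)
    lens = {len(s) for s in seqs.values()}
    if len(lens) != 1:
        raise DataError("sequences must be aligned to equal length")
    arr = np.frombuffer("".join(seqs[n] for n in names).encode(),
                        dtype="S1").reshape(len(names), -1)
    return names, arr


def p_distance_matrix(arr: np.ndarray) -> np.ndarray:
    diff = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
    np.fill_diagonal(diff, 0.0)
    return diff


def jc_correct(p: np.ndarray, names=None) -> np.ndarray:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).

    Raises :class:`SaturationError` naming the first saturated pair
    (p >= 0.75), for which the correction is undefined.
    """
    p = np.asarray(p, dtype=float)
    bad = np.argwhere(p >= 0.75)
    if bad.size:
        i, j = bad[0]
        pair = f"({names[i]}, {names[j]})" if names is not None else f"({i}, {j})"
        raise SaturationError(f"pair {pair} has p = {p[i, j]:.3f} >= 0.75; "
                              "Jukes-Cantor distance undefined")
    return -0.75 * np.log1p(-4.0 / 3.0 * p)


def distance_matrix(seqs: dict, model: str = "jc") -> tuple:
    """(names, matrix) of pairwise distances in substitutions/site."""
    names, arr = alignment_to_array(seqs)
    p = p_distance_matrix(arr)
    if model == "p":
        return names, p
    if model == "jc":
        return names, jc_correct(p, names)
    raise ValueError(f"unknown distance model {model!r}")


# ---------------------------------------------------------------------------
# Neighbour joining

@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (child, branch_length)

    def newick(self, support: dict | None = None, min_support: float = 50.0) -> str:
        return self._nwk(support, min_support) + ";"

    def _nwk(self, support, min_support) -> str:
        if not self.children:
            return self.name or ""
        parts = ",".join(f"{c._nwk(support, min_support)}:{bl:.10g}"
                         for c, bl in self.children)
        label = ""
        if support is not None:
            key = frozenset(self.leaf_names())
            if key in support and support[key] > min_support:
                label = f"{support[key]:.0f}"
        return f"({parts}){label}"

    def leaf_names(self) -> list:
        if not self.children:
            return [self.name]
        out = []
        for c, _bl in self.children:
            out.extend(c.leaf_names())
        return out


def nj_tree(names: list, dm: np.ndarray, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Deterministic: ties in the Q criterion are broken by the smallest
    (i, j) taxon-index pair.  Negative branch-length estimates are clamped
    to zero when ``clamp_negative``.  Returns an unrooted tree represented
    with a trifurcating root.
    """
    n = len(names)
    if n < 3:
        raise DataError("neighbour joining needs at least 3 taxa")
    D = np.asarray(dm, dtype=float).copy()
    nodes = [TreeNode(name=nm) for nm in names]
    active = list(range(n))

    def clamp(x):
        return max(0.0, x) if clamp_negative else x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) pair among ties
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((min(i, j), max(i, j)) for i, j in ties)
        d_ij = sub[ai, aj]
        li = 0.5 * d_ij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = d_ij - li
        gi, gj = active[ai], active[aj]
        parent = TreeNode(children=[(nodes[gi], clamp(li)), (nodes[gj], clamp(lj))])
        new_d = 0.5 * (D[gi, :] + D[gj, :] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d
        D[:-1, -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    ga, gb, gc = active
    dab, dac, dbc = D[ga, gb], D[ga, gc], D[gb, gc]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    return TreeNode(children=[(nodes[ga], clamp(la)), (nodes[gb], clamp(lb)),
                              (nodes[gc], clamp(lc))])


def tree_bipartitions(tree: TreeNode, taxa: set | None = None) -> set:
    """Nontrivial bipartitions as frozensets of the smaller-or-canonical
    side (the side not containing the lexicographically first taxon)."""
    taxa = taxa or set(tree.leaf_names())
    anchor = min(taxa)
    splits = set()

    def walk(node):
        if not node.children:
            return {node.name}
        below = set()
        for c, _bl in node.children:
            below |= walk(c)
        if 1 < len(below) < len(taxa) - 1:
            side = below if anchor not in below else taxa - below
            splits.add(frozenset(side))
        return below

    walk(tree)
    return splits


def tree_path_distances(tree: TreeNode) -> tuple:
    """(names, matrix) of leaf-to-leaf path lengths along the tree."""
    dists = {}

    def walk(node):
        # returns dict leaf -> distance to this node
        if not node.children:
            return {node.name: 0.0}
        per_child = []
        for c, bl in node.children:
            d = walk(c)
            per_child.append({k: v + bl for k, v in d.items()})
        for i in range(len(per_child)):
            for j in range(i + 1, len(per_child)):
                for a, da in per_child[i].items():
                    for b, db in per_child[j].items():
                        dists[frozenset((a, b))] = da + db
        merged = {}
        for d in per_child:
            merged.update(d)
        return merged

    walk(tree)
    names = sorted(tree.leaf_names())
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dists[frozenset((names[i], names[j]))]
    return names, out


def bootstrap_support(seqs: dict, replicates: int = 1000, seed: int = 0,
                      model: str = "jc") -> tuple:
    """NJ tree plus bootstrap support (%) for each internal bipartition.

    Alignment columns are resampled with replacement; support is the
    percentage of replicate NJ trees containing each bipartition of the
    full-data tree.  Returns (tree, support dict keyed by canonical
    bipartition frozenset).
    """
    names, arr = alignment_to_array(seqs)
    if arr.shape[1] < 1:
        raise DataError("alignment must have at least one column")
    taxa = set(names)

    def dm_of(a):
        p = p_distance_matrix(a)
        if model == "p":
            return p
        # cap p just below saturation so single replicates cannot abort a run
        return jc_correct(np.minimum(p, 0.7499))

    base = nj_tree(names, dm_of(arr))
    target = tree_bipartitions(base, taxa)
    hits = {s: 0 for s in target}
    rng = substream(seed, "nj-bootstrap")
    L = arr.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(names, dm_of(arr[:, cols]))
        got = tree_bipartitions(rep, taxa)
        for s in target:
            if s in got:
                hits[s] += 1
    support = {s: 100.0 * h / replicates for s, h in hits.items()}
    return base, support
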