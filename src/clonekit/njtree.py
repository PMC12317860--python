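"""Neighbour-joining trees, newick IO and bootstrap bipartition support.

The agglomeration is the Saitou–Nei algorithm with the Studier–Keppler
Q-criterion: at each step the pair (i, j) minimising
``Q(i,j) = (r-2) d(i,j) - R_i - R_j`` is joined (``R_i`` the row sum over
the ``r`` active items). On an additive distance matrix the output tree
reproduces the input metric exactly. Ties in Q are broken by the
lexicographically smallest active index pair, which makes the result
deterministic on clone-heavy matrices where many distances are (near)
zero. Negative branch lengths, which NJ can produce on non-additive
input, are clamped to zero and logged.

dendropy supplies the tree container and newick serialisation; the NJ
agglomeration, bipartition counting and clade enumeration live here.
"""

from __future__ import annotations

import logging
from collections import Counter

import dendropy
import numpy as np

from .core import DistanceMatrix, ParameterError

logger = logging.getLogger(__name__)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("negative NJ branch length %.3g at %s clamped to 0",
                    length, context)
        return 0.0
    return float(length)


def nj(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining tree from a distance matrix.

    Returns an unrooted dendropy tree whose seed node is the final
    trifurcation. Requires n >= 3 and finite distances.
    """
    n = D.n
    if n < 3:
        raise ParameterError(f"NJ needs at least 3 taxa, got {n}")
    if not np.isfinite(D.values).all():
        raise ParameterError("distance matrix contains non-finite values")

    ns = dendropy.TaxonNamespace(list(D.labels))
    nodes = [dendropy.Node(taxon=ns.get_taxon(lab)) for lab in D.labels]
    d = D.values.astype(float).copy()

    while len(nodes) > 3:
        r = len(nodes)
        R = d.sum(axis=1)
        Q = (r - 2) * d - R[:, None] - R[None, :]
        # upper triangle only; row-major argmin = lexicographically
        # smallest (i, j) among ties
        Q[np.tril_indices(r)] = np.inf
        i, j = divmod(int(np.argmin(Q)), r)
        dij = d[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamp(li, f"join({i},{j})")
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamp(lj, f"join({i},{j})")

        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form resolution of the last three nodes around the
    # central (unrooted) vertex
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    root = dendropy.Node()
    for node, length in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        root.add_child(node)
        node.edge.length = _clamp(length, "final-three")
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise to newick (lengths at 6 significant digits, support as
    internal-node labels; the dialect ITOL accepts)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,  # keep underscores literal in ids
        real_value_format_specifier=".6g",
    ).strip()


def parse_newick(s: str) -> dendropy.Tree:
    """Parse a newick string; malformed input raises a parameter error
    carrying dendropy's position information."""
    try:
        tree = dendropy.Tree.get(
            data=s, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParameterError(f"malformed newick: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise ParameterError("malformed newick: no taxa parsed")
    return tree


def tip_labels(tree: dendropy.Tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions as frozensets of tip labels.

    Each internal edge induces a split; the side not containing the
    alphabetically first tip is reported, so the encoding is invariant
    to rooting. Trivial splits (single tip / all-but-one) are excluded.
    """
    labels = set(tip_labels(tree))
    ref = min(labels)
    out = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[ch] for ch in
                                              node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if ref in side:
            side = frozenset(labels - side)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def bootstrap_support(tree: dendropy.Tree, replicates) -> dendropy.Tree:
    """Annotate each internal edge of ``tree`` with the percentage of
    replicate trees containing the same bipartition (label =
    ``round(100 * count / B)``). Modifies and returns ``tree``."""
    main_tips = set(tip_labels(tree))
    counts: Counter = Counter()
    B = 0
    for rep in replicates:
        if set(tip_labels(rep)) != main_tips:
            raise ParameterError("replicate tip set differs from main tree")
        counts.update(bipartitions(rep))
        B += 1
    if B == 0:
        raise ParameterError("no replicate trees supplied")

    ref = min(main_tips)
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        below[node] = frozenset().union(*(below[ch] for ch in
                                          node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if ref in side:
            side = frozenset(main_tips - side)
        if 2 <= len(side) <= len(main_tips) - 2:
            node.label = str(int(round(100.0 * counts[side] / B)))
    return tree


def tight_clades(tree: dendropy.Tree) -> list:
    """Enumerate candidate clades of an unrooted tree.

    Every internal edge splits the tips in two; either side is a clade
    under a rooting on that edge, so both sides (sizes 2 .. n-2) are
    enumerated — the rooting-independent superset of any single rooting
    convention. Returns sorted tuples of tip labels ordered by
    (size, labels); trees with no internal edge (<= 3 tips) yield
    nothing.
    """
    labels = set(tip_labels(tree))
    n = len(labels)
    if n < 4:
        return []
    clades = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        below[node] = frozenset().union(*(below[ch] for ch in
                                          node.child_nodes()))
        if node.parent_node is None:
            continue
        for side in (below[node], labels - below[node]):
            if 2 <= len(side) <= n - 2:
                clades.add(tuple(sorted(side)))
    return sorted(clades, key=lambda c: (len(c), c))


def patristic_distances(tree: dendropy.Tree) -> tuple[list, np.ndarray]:
    """Path-length (patristic) distances between tips, for additivity
    checks against the distances a tree was built from. Returns
    (sorted tip labels, raw distance array)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(tip_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return labels, values
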