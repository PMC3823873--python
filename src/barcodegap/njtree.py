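"""Neighbour-joining trees and nonparametric bootstrap over sites.

Saitou-Nei agglomeration with the Q criterion.  Determinism: ties in the
Q matrix are broken by the lexicographically smallest pair of cluster
representatives (the minimal leaf id in each cluster).  Negative branch
lengths are clamped to zero with the deficit moved onto the sister edge;
downstream identification uses clades, not signed lengths.

Trees are dendropy objects; newick export keeps branch lengths and
integer bootstrap supports as internal-node labels.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Optional

import dendropy
import numpy as np

from .distances import DistanceMatrix, DistanceError, encode, matrix_from_codes
from .io import SequenceSet

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a distance matrix (>=3 taxa)."""
    n0 = len(m)
    if n0 < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(m.ids)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for sid in m.ids:
        nd = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(nd)
    reps = list(m.ids)                    # lexicographic representative per cluster
    D = m.d.copy()
    active = list(range(n0))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + _TIE_EPS * max(1.0, abs(qmin)))
        # tie rule: lexicographically smallest (sorted) representative pair
        best = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda ab: tuple(sorted((reps[active[ab[0]]], reps[active[ab[1]]]))),
        )
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (k - 2))
        vj = dij - vi
        # clamp negatives, deficit onto the sister edge
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)

        new = dendropy.Node()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj

        # distances from the new cluster to the remaining ones
        dn = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = dn
        D[:, i] = dn
        D[i, i] = 0.0
        nodes[i] = new
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, v in ((a, va), (b, vb), (c, vc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(v, 0.0)
    tree.seed_node = center
    tree.update_taxon_namespace()
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf patristic distances of a tree, as a DistanceMatrix."""
    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(t.label for t in tree.taxon_namespace)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        ti = tree.taxon_namespace.get_taxon(ids[i])
        for j in range(i + 1, n):
            tj = tree.taxon_namespace.get_taxon(ids[j])
            d[i, j] = d[j, i] = pdm.patristic_distance(ti, tj)
    return DistanceMatrix(ids, d, np.ones((n, n), dtype=int))


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    out: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            out[nd] = frozenset([nd.taxon.label])
        else:
            s: set[str] = set()
            for ch in nd.child_nodes():
                s |= out[ch]
            out[nd] = frozenset(s)
    return out


def bipartitions(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised.

    Each internal edge is keyed by its head node and valued by the side of
    the split *not* containing the lexicographically smallest leaf.
    """
    all_leaves = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(all_leaves)
    sets = _leafsets(tree)
    out: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        below = sets[nd]
        if len(below) < 2 or len(below) > len(all_leaves) - 2:
            continue
        side = below if ref not in below else all_leaves - below
        out[nd] = side
    return out


def bootstrap_support(
    sset: SequenceSet,
    n_reps: int = 1000,
    seed: int = 0,
    resampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
) -> dendropy.Tree:
    """NJ tree with bootstrap support from site resampling.

    Sites are resampled with replacement per replicate, the K2P matrix and
    NJ tree rebuilt, and each original internal bipartition scored by the
    percentage of successful replicates containing it.  Replicates with a
    saturated or undefined pair are skipped (logged and counted on the
    returned tree as ``bootstrap_skipped``).  ``resampler`` overrides the
    column sampler (for tests).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sset.check_aligned()
    codes = np.vstack([encode(r.sequence) for r in sset.records])
    m = matrix_from_codes(sset.ids, codes)
    tree = neighbor_joining(m)
    orig = bipartitions(tree)
    counts = {side: 0 for side in orig.values()}

    rng = np.random.default_rng(seed)
    if resampler is None:
        resampler = lambda g, L: g.integers(0, L, size=L)  # noqa: E731

    L = codes.shape[1]
    n_ok = 0
    n_skipped = 0
    for _ in range(n_reps):
        cols = resampler(rng, L)
        try:
            mb = matrix_from_codes(sset.ids, codes[:, cols])
            tb = neighbor_joining(mb)
        except DistanceError as err:
            n_skipped += 1
            logger.info("bootstrap replicate skipped: %s", err)
            continue
        n_ok += 1
        rep_sides = set(bipartitions(tb).values())
        for side in counts:
            if side in rep_sides:
                counts[side] += 1

    support: dict[frozenset[str], float] = {}
    for nd, side in orig.items():
        pct = 100.0 * counts[side] / n_ok if n_ok else 0.0
        support[side] = pct
        nd.label = str(int(round(pct)))
    tree.bipartition_support = support
    tree.bootstrap_skipped = n_skipped
    tree.bootstrap_replicates_used = n_ok
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
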