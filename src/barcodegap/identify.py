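"""Specimen-identification methods for barcode libraries.

Five methods, all evaluated leave-one-out (the query's own record never
serves as its reference):

* ``best_match`` -- nearest reference wins, no threshold;
* ``best_close_match`` -- nearest reference, but only within a threshold;
* ``all_species_barcodes`` -- every reference within the threshold must be
  conspecific;
* ``exemplar`` -- distance to the nearest designated species exemplar;
* ``nj`` -- placement relative to exemplars in a neighbour-joining tree.

Threshold comparisons use closed intervals: a distance exactly equal to
the threshold counts as within it.

The NJ clade criteria are a reconstruction of tree-based identification
with revised criteria (Meier-style): the tree is midpoint-rooted, the
maximal exemplar-free clade A containing the query is found, and the
exemplar species entering at its parent decide the outcome.  When that
clade is pure (all leaves share the query's label) but no conspecific
exemplar enters, the query is ambiguous and flagged as a candidate new
species rather than misidentified; when the query nests among
heterospecific specimens (e.g. captured mitochondria after
hybridisation), it is misidentified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .io import TaxonomyMap

OUTCOMES = ("success", "ambiguous", "misidentified", "no_match")

METHODS = ("nj", "exemplar", "best_match", "best_close_match", "all_species_barcodes")


@dataclass
class IdentificationResult:
    query_id: str
    method: str
    threshold: Optional[float]
    assigned: Optional[str]
    outcome: str
    evidence: dict = field(default_factory=dict)


def _nearest(q: str, ref_ids: Sequence[str], m: DistanceMatrix):
    row = m.row(q)
    idx = [m.index(r) for r in ref_ids]
    dists = row[idx]
    dmin = float(dists.min())
    ties = [ref_ids[k] for k in np.flatnonzero(dists == dmin)]
    return dmin, ties


def best_match(
    q: str, ref_ids: Sequence[str], m: DistanceMatrix, tax: TaxonomyMap
) -> IdentificationResult:
    """Assign the query to the species of its nearest reference(s)."""
    if not ref_ids:
        raise ValueError("reference set is empty")
    dmin, ties = _nearest(q, ref_ids, m)
    species = {tax.label_of[r] for r in ties}
    ev = {"nearest_ids": ties, "nearest_distance": dmin, "tied_species": sorted(species)}
    if len(species) > 1:
        return IdentificationResult(q, "best_match", None, None, "ambiguous", ev)
    sp = next(iter(species))
    outcome = "success" if sp == tax.label_of.get(q) else "misidentified"
    return IdentificationResult(q, "best_match", None, sp, outcome, ev)


def best_close_match(
    q: str, ref_ids: Sequence[str], m: DistanceMatrix, tax: TaxonomyMap, t: float
) -> IdentificationResult:
    """Best match, accepted only when the nearest reference is within t."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    dmin, ties = _nearest(q, ref_ids, m)
    species = {tax.label_of[r] for r in ties}
    ev = {"nearest_ids": ties, "nearest_distance": dmin, "tied_species": sorted(species)}
    if dmin > t:
        return IdentificationResult(q, "best_close_match", t, None, "no_match", ev)
    if len(species) > 1:
        return IdentificationResult(q, "best_close_match", t, None, "ambiguous", ev)
    sp = next(iter(species))
    outcome = "success" if sp == tax.label_of.get(q) else "misidentified"
    return IdentificationResult(q, "best_close_match", t, sp, outcome, ev)


def all_species_barcodes(
    q: str, ref_ids: Sequence[str], m: DistanceMatrix, tax: TaxonomyMap, t: float
) -> IdentificationResult:
    """Require every reference within t to be conspecific with the query."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    row = m.row(q)
    within = [r for r in ref_ids if row[m.index(r)] <= t]
    species = sorted({tax.label_of[r] for r in within})
    ev = {"n_within": len(within), "species_within": species}
    if not within:
        return IdentificationResult(q, "all_species_barcodes", t, None, "no_match", ev)
    if len(species) > 1:
        return IdentificationResult(q, "all_species_barcodes", t, None, "ambiguous", ev)
    sp = species[0]
    outcome = "success" if sp == tax.label_of.get(q) else "misidentified"
    return IdentificationResult(q, "all_species_barcodes", t, sp, outcome, ev)


def distance_to_exemplar(
    q: str, m: DistanceMatrix, tax: TaxonomyMap, t: float
) -> IdentificationResult:
    """Compare the query against the designated exemplar of each species.

    A query beyond t from every exemplar is a no_match: a candidate new
    species.  Exemplar queries are compared against the other exemplars
    (self excluded).
    """
    if t <= 0:
        raise ValueError("threshold must be positive")
    exemplars = [e for e in sorted(tax.exemplar_ids()) if e != q and e in m._index]
    if not exemplars:
        raise ValueError("no exemplar references available")
    dmin, ties = _nearest(q, exemplars, m)
    species = sorted({tax.label_of[e] for e in ties})
    ev = {"nearest_ids": ties, "nearest_distance": dmin, "tied_species": species}
    if dmin > t:
        return IdentificationResult(q, "exemplar", t, None, "no_match", ev)
    if len(species) > 1:
        return IdentificationResult(q, "exemplar", t, None, "ambiguous", ev)
    sp = species[0]
    outcome = "success" if sp == tax.label_of.get(q) else "misidentified"
    return IdentificationResult(q, "exemplar", t, sp, outcome, ev)


# ---------------------------------------------------------------------------
# NJ tree-based identification
# ---------------------------------------------------------------------------

def nj_identify(
    tree: dendropy.Tree,
    tax: TaxonomyMap,
    exemplar_ids: Optional[set[str]] = None,
) -> list[IdentificationResult]:
    """Tree-based identification of every non-exemplar leaf.

    See the module docstring for the clade criteria.  Exemplars must be
    leaves of the tree.
    """
    if exemplar_ids is None:
        exemplar_ids = tax.exemplar_ids()
    leaf_labels = {t.label for t in tree.taxon_namespace}
    missing = set(exemplar_ids) - leaf_labels
    if missing:
        raise ValueError(f"exemplars absent from tree: {sorted(missing)}")
    if not exemplar_ids:
        raise ValueError("no exemplars designated")

    work = tree.clone(depth=1)
    work.reroot_at_midpoint(update_bipartitions=False)

    leaves_below: dict[dendropy.Node, frozenset[str]] = {}
    exemplars_below: dict[dendropy.Node, frozenset[str]] = {}
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            leaves_below[nd] = frozenset([lab])
            exemplars_below[nd] = frozenset([lab]) if lab in exemplar_ids else frozenset()
        else:
            lv: set[str] = set()
            ex: set[str] = set()
            for ch in nd.child_nodes():
                lv |= leaves_below[ch]
                ex |= exemplars_below[ch]
            leaves_below[nd] = frozenset(lv)
            exemplars_below[nd] = frozenset(ex)

    leaf_node = {nd.taxon.label: nd for nd in work.leaf_node_iter()}
    results: list[IdentificationResult] = []
    for qid in sorted(leaf_labels - set(exemplar_ids)):
        q_label = tax.label_of.get(qid)
        # maximal exemplar-free ancestor clade A of the query
        node = leaf_node[qid]
        while (
            node.parent_node is not None
            and not exemplars_below[node.parent_node]
        ):
            node = node.parent_node
        A_node = node
        P = A_node.parent_node
        if P is None:
            raise ValueError("no exemplar found anywhere in the tree")
        entering = exemplars_below[P] - exemplars_below[A_node]
        # walk further up if the sibling subtrees at P carry no exemplar
        while not entering:
            A_node, P = P, P.parent_node
            if P is None:
                raise ValueError("no exemplar found above the query")
            entering = exemplars_below[P] - exemplars_below[A_node]
        species_entering = sorted({tax.label_of[e] for e in entering})
        A_leaves = leaves_below[A_node]
        A_pure = all(tax.label_of.get(l) == q_label for l in A_leaves)
        ev = {
            "clade_size": len(A_leaves),
            "entering_exemplar_species": species_entering,
            "clade_pure": A_pure,
        }
        if species_entering == [q_label]:
            results.append(
                IdentificationResult(qid, "nj", None, q_label, "success", ev)
            )
        elif len(species_entering) >= 2:
            if q_label not in species_entering and A_pure:
                ev["candidate_new"] = True
            results.append(
                IdentificationResult(qid, "nj", None, None, "ambiguous", ev)
            )
        else:  # exactly one, heterospecific
            if A_pure:
                ev["candidate_new"] = True
                results.append(
                    IdentificationResult(qid, "nj", None, None, "ambiguous", ev)
                )
            else:
                results.append(
                    IdentificationResult(
                        qid, "nj", None, species_entering[0], "misidentified", ev
                    )
                )
    return results


# ---------------------------------------------------------------------------
# batch runner
# ---------------------------------------------------------------------------

def run_method(
    m: DistanceMatrix,
    tax: TaxonomyMap,
    method: str,
    t: Optional[float] = None,
    query_ids: Optional[Sequence[str]] = None,
    ref_ids: Optional[Sequence[str]] = None,
    tree: Optional[dendropy.Tree] = None,
    exemplar_queries: str = "skip",
) -> list[IdentificationResult]:
    """Run one identification method over a set of queries, leave-one-out.

    ``exemplar_queries`` controls the exemplar method: ``"skip"``
    (default) omits exemplar specimens from scoring (their self-distance of
    zero is uninformative); ``"self_excluded"`` scores every specimen,
    matching each exemplar against the other exemplars.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if method == "nj":
        if tree is None:
            raise ValueError("nj method requires a tree")
        return nj_identify(tree, tax)

    if query_ids is None:
        query_ids = [s for s in m.ids if s in tax.label_of]
    if method == "exemplar":
        out = []
        for q in query_ids:
            if exemplar_queries == "skip" and q in tax.exemplar_ids():
                continue
            out.append(distance_to_exemplar(q, m, tax, t))
        return out

    pool = ref_ids if ref_ids is not None else [s for s in m.ids if s in tax.label_of]
    out = []
    for q in query_ids:
        refs = [r for r in pool if r != q]
        if method == "best_match":
            out.append(best_match(q, refs, m, tax))
        elif method == "best_close_match":
            out.append(best_close_match(q, refs, m, tax, t))
        else:
            out.append(all_species_barcodes(q, refs, m, tax, t))
    return out
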