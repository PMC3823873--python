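"""The five identification methods against constructed cases and a
brute-force classifier."""

import numpy as np
import pytest

import barcodegap as bg
from barcodegap.distances import DistanceMatrix
from barcodegap.identify import (
    all_species_barcodes,
    best_close_match,
    best_match,
    distance_to_exemplar,
    nj_identify,
)
from barcodegap.io import TaxonomyMap
from barcodegap.njtree import neighbor_joining
from barcodegap.simulate import PopulationSpec, SimulationConfig


def matrix_from_positions(ids, pos):
    pos = np.asarray(pos, float)
    arr = np.abs(pos[:, None] - pos[None, :])
    return DistanceMatrix(ids, arr, np.ones_like(arr, dtype=int))


def tax(labels, exemplars=None):
    t = TaxonomyMap("t", label_of=dict(labels))
    if exemplars:
        t.exemplar_of = dict(exemplars)
    return t


# a, b conspecific (A); c, d conspecific (B); e singleton (C)
IDS = list("abcde")
POS = [0.00, 0.01, 0.05, 0.055, 0.20]
LABELS = {"a": "A", "b": "A", "c": "B", "d": "B", "e": "C"}


@pytest.fixture()
def m():
    return matrix_from_positions(IDS, POS)


@pytest.fixture()
def t5():
    return tax(LABELS, exemplars={"A": "a", "B": "c", "C": "e"})


class TestBestMatch:
    def test_nearest_conspecific(self, m, t5):
        r = best_match("a", ["b", "c", "d"], m, t5)
        assert (r.outcome, r.assigned) == ("success", "A")

    def test_nearest_heterospecific(self, m, t5):
        r = best_match("e", ["a", "b", "c", "d"], m, t5)
        assert (r.outcome, r.assigned) == ("misidentified", "B")

    def test_exact_tie_spanning_species(self):
        ids = ["q", "r1", "r2"]
        arr = np.array([[0, 0.02, 0.02], [0.02, 0, 0.04], [0.02, 0.04, 0]])
        mm = DistanceMatrix(ids, arr, np.ones((3, 3), dtype=int))
        tt = tax({"q": "A", "r1": "A", "r2": "B"})
        r = best_match("q", ["r1", "r2"], mm, tt)
        assert r.outcome == "ambiguous"
        assert r.assigned is None
        assert r.evidence["tied_species"] == ["A", "B"]


class TestBestCloseMatch:
    def test_within_threshold(self, m, t5):
        r = best_close_match("a", ["b", "c"], m, t5, t=0.02)
        assert r.outcome == "success"

    def test_beyond_threshold(self, m, t5):
        r = best_close_match("a", ["c", "d"], m, t5, t=0.02)
        assert r.outcome == "no_match"

    def test_threshold_boundary_counts_inside(self, m, t5):
        r = best_close_match("a", ["b"], m, t5, t=0.01)
        assert r.outcome == "success"

    def test_singleton_query_forced_misidentification(self, m, t5):
        # e has no conspecific reference; c is within the threshold
        r = best_close_match("e", ["a", "b", "c", "d"], m, t5, t=0.16)
        assert (r.outcome, r.assigned) == ("misidentified", "B")


class TestAllSpeciesBarcodes:
    def test_pure_neighbourhood(self, m, t5):
        r = all_species_barcodes("a", ["b", "c", "d", "e"], m, t5, t=0.02)
        assert (r.outcome, r.assigned) == ("success", "A")

    def test_mixed_neighbourhood(self, m, t5):
        r = all_species_barcodes("a", ["b", "c", "d", "e"], m, t5, t=0.06)
        assert r.outcome == "ambiguous"
        assert r.evidence["species_within"] == ["A", "B"]

    def test_wrong_species_only(self, m, t5):
        r = all_species_barcodes("e", ["a", "b", "c", "d"], m, t5, t=0.16)
        assert (r.outcome, r.assigned) == ("misidentified", "B")

    def test_empty_neighbourhood(self, m, t5):
        r = all_species_barcodes("e", ["a", "b"], m, t5, t=0.05)
        assert r.outcome == "no_match"


class TestDistanceToExemplar:
    def test_conspecific_within(self, m, t5):
        r = distance_to_exemplar("b", m, t5, t=0.02)
        assert (r.outcome, r.assigned) == ("success", "A")

    def test_heterospecific_within(self, m, t5):
        r = distance_to_exemplar("e", m, t5, t=0.16)
        # e is an exemplar: nearest OTHER exemplar is c (species B)
        assert (r.outcome, r.assigned) == ("misidentified", "B")

    def test_no_match_beyond_all(self, m, t5):
        tt = tax(LABELS, exemplars={"A": "a", "B": "c"})
        r = distance_to_exemplar("e", m, tt, t=0.02)
        assert r.outcome == "no_match"

    def test_no_exemplars_error(self, m):
        with pytest.raises(ValueError):
            distance_to_exemplar("a", m, tax(LABELS), t=0.02)


def brute_force_outcomes(m, labels, q, refs, t):
    """Definition-level classifier for BM/BCM/ASB on raw distances."""
    dists = {r: m.distance(q, r) for r in refs}
    dmin = min(dists.values())
    nearest_species = {labels[r] for r in refs if dists[r] == dmin}
    bm = (
        "ambiguous" if len(nearest_species) > 1
        else ("success" if nearest_species == {labels[q]} else "misidentified")
    )
    bcm = "no_match" if dmin > t else bm
    within = {labels[r] for r in refs if dists[r] <= t}
    if not within:
        asb = "no_match"
    elif len(within) > 1:
        asb = "ambiguous"
    else:
        asb = "success" if within == {labels[q]} else "misidentified"
    return bm, bcm, asb


class TestMatchingProperties:
    def random_dataset(self, rng):
        n = int(rng.integers(5, 13))
        ids = [f"s{i}" for i in range(n)]
        pos = np.sort(rng.random(n))
        labels = {s: str(rng.choice(list("ABCD"))) for s in ids}
        return matrix_from_positions(ids, pos), labels

    def test_matches_brute_force(self, rng):
        for _ in range(40):
            m, labels = self.random_dataset(rng)
            tt = tax(labels)
            t = float(rng.choice([0.05, 0.2, 0.5]))
            for q in m.ids:
                refs = [r for r in m.ids if r != q]
                bm, bcm, asb = brute_force_outcomes(m, labels, q, refs, t)
                assert best_match(q, refs, m, tt).outcome == bm
                assert best_close_match(q, refs, m, tt, t).outcome == bcm
                assert all_species_barcodes(q, refs, m, tt, t).outcome == asb

    def test_bcm_equals_bm_within_threshold(self, rng):
        for _ in range(20):
            m, labels = self.random_dataset(rng)
            tt = tax(labels)
            for q in m.ids:
                refs = [r for r in m.ids if r != q]
                rb = best_match(q, refs, m, tt)
                rc = best_close_match(q, refs, m, tt, t=0.3)
                if rb.evidence["nearest_distance"] <= 0.3:
                    assert rc.outcome == rb.outcome

    def test_bcm_equals_bm_at_infinite_threshold(self, rng):
        m, labels = self.random_dataset(rng)
        tt = tax(labels)
        for q in m.ids:
            refs = [r for r in m.ids if r != q]
            assert (
                best_close_match(q, refs, m, tt, t=np.inf).outcome
                == best_match(q, refs, m, tt).outcome
            )

    def test_asb_success_implies_bcm_success(self, rng):
        for _ in range(20):
            m, labels = self.random_dataset(rng)
            tt = tax(labels)
            for q in m.ids:
                refs = [r for r in m.ids if r != q]
                for t in (0.05, 0.2):
                    if all_species_barcodes(q, refs, m, tt, t).outcome == "success":
                        assert (
                            best_close_match(q, refs, m, tt, t).outcome
                            == "success"
                        )

    def test_shrinking_threshold_never_creates_success_from_no_match(self, rng):
        thresholds = [0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        for _ in range(10):
            m, labels = self.random_dataset(rng)
            tt = tax(labels, exemplars={
                lab: next(s for s in m.ids if labels[s] == lab)
                for lab in set(labels.values())
            })
            for q in m.ids:
                refs = [r for r in m.ids if r != q]
                for fn in (
                    lambda t: best_close_match(q, refs, m, tt, t).outcome,
                    lambda t: all_species_barcodes(q, refs, m, tt, t).outcome,
                    lambda t: distance_to_exemplar(q, m, tt, t).outcome,
                ):
                    seen_no_match = False
                    for t in thresholds:
                        out = fn(t)
                        if seen_no_match:
                            assert out == "no_match"
                        seen_no_match = seen_no_match or out == "no_match"


# ---------------------------------------------------------------------------
# NJ-based identification
# ---------------------------------------------------------------------------

def _simulate_tree(cfg):
    sset = bg.simulate_dataset(cfg)
    m = bg.build_matrix(sset)
    return sset, m, neighbor_joining(m)


def _clean_config(seed=0):
    pops = [
        PopulationSpec(s, s, 5, 0.002, s) for s in ("spA", "spB", "spC")
    ]
    return SimulationConfig(
        seed=seed, populations=pops,
        tree_newick="(spA:0.05,spB:0.05,spC:0.05);",
    )


class TestNJIdentify:
    def test_clean_radiation_all_success(self):
        sset, m, tree = _simulate_tree(_clean_config(seed=2))
        results = nj_identify(tree, sset.taxonomies["current"])
        assert results and all(r.outcome == "success" for r in results)

    def test_unsampled_species_flagged_as_candidate(self):
        sset, m, tree = _simulate_tree(_clean_config(seed=3))
        # drop spC's exemplar: its queries form an exemplar-free clade
        tax_c = sset.taxonomies["current"]
        t2 = TaxonomyMap("t", label_of=dict(tax_c.label_of))
        t2.exemplar_of = {
            sp: ex for sp, ex in tax_c.exemplar_of.items() if sp != "spC"
        }
        results = {r.query_id: r for r in nj_identify(tree, t2)}
        for sid, lab in t2.label_of.items():
            if lab == "spC":
                r = results[sid]
                assert r.outcome == "ambiguous"
                assert r.evidence.get("candidate_new") is True

    def test_introgressed_query_misidentified(self):
        cfg = _clean_config(seed=4)
        sset = bg.simulate_dataset(cfg)
        sset = bg.inject_hybrids(
            sset, sset.taxonomies["current"], donor="spA", recipient="spB",
            k=1, seed=5,
        )
        m = bg.build_matrix(sset)
        tree = neighbor_joining(m)
        captured = sset.sim["captured"][0]
        results = {r.query_id: r for r in nj_identify(tree, sset.taxonomies["current"])}
        r = results[captured]
        assert r.outcome == "misidentified"
        assert r.assigned == "spA"

    def test_exemplar_missing_from_tree_error(self):
        sset, m, tree = _simulate_tree(_clean_config(seed=2))
        t2 = TaxonomyMap(
            "t", label_of=dict(sset.taxonomies["current"].label_of)
        )
        t2.exemplar_of = {"spA": "ghost"}
        t2.label_of["ghost"] = "spA"
        with pytest.raises(ValueError, match="ghost"):
            nj_identify(tree, t2)
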