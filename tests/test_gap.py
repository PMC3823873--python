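"""Distance pools, overlap statistics, local gaps, thresholds, ANOVA."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import barcodegap as bg
from barcodegap.distances import DistanceMatrix
from barcodegap.gap import (
    AbgdConfig,
    DistancePools,
    GapError,
    local_gap_table,
    status_counts,
)
from barcodegap.io import TaxonomyMap


def matrix_from_square(ids, arr):
    arr = np.asarray(arr, dtype=float)
    return DistanceMatrix(ids, arr, np.ones_like(arr, dtype=int))


def matrix_from_positions(ids, pos):
    """1-D metric: d(i,j) = |pos_i - pos_j| (always a valid distance matrix)."""
    pos = np.asarray(pos, float)
    return matrix_from_square(ids, np.abs(pos[:, None] - pos[None, :]))


def tax(labels: dict) -> TaxonomyMap:
    return TaxonomyMap("t", label_of=dict(labels))


class TestPools:
    def test_two_by_two_counts(self):
        m = matrix_from_positions(list("abcd"), [0.0, 0.01, 0.5, 0.52])
        pools = bg.pool_distances(m, tax({"a": "A", "b": "A", "c": "B", "d": "B"}))
        assert len(pools.intra_pooled) == 2
        assert len(pools.inter_pooled) == 4

    def test_singleton_species(self):
        m = matrix_from_positions(list("abc"), [0.0, 0.01, 0.5])
        pools = bg.pool_distances(m, tax({"a": "A", "b": "A", "c": "B"}))
        assert "B" not in pools.intra_by_species
        assert "B" in pools.nn_dist
        assert pools.nn_dist["B"] == pytest.approx(0.49)

    def test_matches_exhaustive_enumeration(self, rng):
        ids = [f"s{i}" for i in range(5)]
        pos = rng.random(5)
        labels = {s: rng.choice(["A", "B"]) for s in ids}
        while len(set(labels.values())) < 2:
            labels = {s: rng.choice(["A", "B"]) for s in ids}
        m = matrix_from_positions(ids, pos)
        pools = bg.pool_distances(m, tax(labels))
        intra, inter = [], []
        nn = {}
        for a, b in itertools.combinations(ids, 2):
            d = m.distance(a, b)
            if labels[a] == labels[b]:
                intra.append(d)
            else:
                inter.append(d)
                for sp in (labels[a], labels[b]):
                    nn[sp] = min(nn.get(sp, np.inf), d)
        assert sorted(pools.intra_pooled) == sorted(intra)
        assert sorted(pools.inter_pooled) == sorted(inter)
        assert pools.nn_dist == pytest.approx(nn)

    def test_unlabelled_id_error(self):
        m = matrix_from_positions(list("ab"), [0.0, 0.1])
        with pytest.raises(GapError, match="b"):
            bg.pool_distances(m, tax({"a": "A"}))


def overlap_oracle(intra, inter, trim):
    """Independent enumeration: trim by repeatedly removing extremes."""
    intra, inter = list(intra), list(inter)
    for _ in range(math.ceil(trim * len(intra)) if trim else 0):
        intra.remove(max(intra))
    for _ in range(math.ceil(trim * len(inter)) if trim else 0):
        inter.remove(min(inter))
    upper, lower = max(intra), min(inter)
    if upper <= lower:
        return lower, upper, 0.0, 0.0
    n_in = 0
    return lower, upper, upper - lower, None  # pct filled by caller


class TestOverlap:
    def make(self, intra, inter):
        return DistancePools({}, list(intra), list(inter), {}, {})

    def test_disjoint_pools(self):
        r = bg.overlap_report(self.make([0.01, 0.02], [0.05, 0.06]))
        assert r.width == 0.0
        assert r.pct_observations == 0.0

    def test_hand_enumerated_example(self):
        r = bg.overlap_report(self.make([0.01, 0.02, 0.05], [0.03, 0.06, 0.08]))
        assert (r.lower, r.upper) == (0.03, 0.05)
        assert r.width == pytest.approx(0.02)
        assert r.pct_observations == pytest.approx(100 * 2 / 6)

    def test_trim_zero_is_exact_extremes(self, rng):
        intra = rng.random(17).tolist()
        inter = (rng.random(23) + 0.2).tolist()
        r = bg.overlap_report(self.make(intra, inter), 0.0)
        assert r.upper == max(intra)
        assert r.lower == min(inter)

    def test_empty_pool_error(self):
        with pytest.raises(GapError):
            bg.overlap_report(self.make([], [0.1]))

    @given(
        intra=st.lists(st.floats(0, 0.3), min_size=1, max_size=40),
        inter=st.lists(st.floats(0, 0.3), min_size=1, max_size=40),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_trim_monotonicity(self, intra, inter):
        pools = self.make(intra, inter)
        pcts = []
        for trim in (0.0, 0.01, 0.02, 0.03, 0.04, 0.05):
            try:
                pcts.append(bg.overlap_report(pools, trim).pct_observations)
            except GapError:
                return  # trim ate an entire pool; nothing to compare
        assert all(a >= b - 1e-12 for a, b in zip(pcts, pcts[1:]))

    def test_exhaustive_small_pools_match_oracle(self):
        grid = [0.01, 0.03, 0.05, 0.08]
        for ni, ne in itertools.product(range(1, 5), range(1, 5)):
            for intra in itertools.combinations_with_replacement(grid, ni):
                for inter in itertools.combinations_with_replacement(grid, ne):
                    r = bg.overlap_report(self.make(intra, inter), 0.0)
                    lo, up, width, _ = overlap_oracle(intra, inter, 0.0)
                    assert (r.lower, r.upper) == (lo, up)
                    assert r.width == pytest.approx(width)
                    if width > 0:
                        n_in = sum(
                            1 for d in list(intra) + list(inter)
                            if lo <= d <= up
                        )
                        assert r.pct_observations == pytest.approx(
                            100 * n_in / (ni + ne)
                        )
                    else:
                        assert r.pct_observations == 0.0
                    # count-trim of the extremes: removing one value from a
                    # singleton pool leaves nothing and must be refused
                    if ni == 1 or ne == 1:
                        with pytest.raises(GapError):
                            bg.overlap_report(self.make(intra, inter), 0.05)
                    else:
                        r5 = bg.overlap_report(self.make(intra, inter), 0.05)
                        lo5, up5, w5, _ = overlap_oracle(intra, inter, 0.05)
                        assert (r5.lower, r5.upper) == (lo5, up5)
                        assert r5.width == pytest.approx(w5)


class TestLocalGap:
    def make(self, max_intra, nn):
        return DistancePools({}, [0.0], [0.1], dict(max_intra), dict(nn))

    def test_statuses(self):
        pools = self.make(
            {"A": 0.01, "B": 0.05, "C": 0.03},
            {"A": 0.05, "B": 0.02, "C": 0.03},
        )
        recs = {r.species: r.status for r in local_gap_table(pools)}
        assert recs == {
            "A": "gap_present",
            "B": "absent_below",
            "C": "absent_on_line",
        }

    def test_singleton_has_gap_by_construction(self):
        pools = self.make({"A": 0.01}, {"A": 0.05, "S": 0.04})
        recs = {r.species: r for r in local_gap_table(pools)}
        assert recs["S"].max_intra == 0.0
        assert recs["S"].status == "gap_present"

    def test_counts(self):
        pools = self.make({"A": 0.01, "B": 0.05}, {"A": 0.05, "B": 0.02})
        assert status_counts(local_gap_table(pools)) == {
            "gap_present": 1,
            "absent_below": 1,
            "absent_on_line": 0,
        }

    def test_lumped_complex_loses_local_gap(self, skink_1977):
        sset, m77 = skink_1977
        pools = bg.pool_distances(m77, sset.taxonomies["historic"])
        recs = {r.species: r.status for r in local_gap_table(pools)}
        for lumped in ("c1", "c2", "c3"):
            assert recs[lumped] == "absent_below"


class TestThreshold10x:
    def test_all_zero(self):
        pools = DistancePools({}, [0.0, 0.0], [0.1], {}, {})
        assert bg.threshold_10x(pools) == 0.0

    def test_arithmetic(self):
        pools = DistancePools({}, [0.01, 0.03], [0.1], {}, {})
        assert bg.threshold_10x(pools) == pytest.approx(0.2)

    def test_empty_error(self):
        with pytest.raises(GapError):
            bg.threshold_10x(DistancePools({}, [], [0.1], {}, {}))


class TestAbgd:
    def test_two_clusters_wide_gap(self):
        # two tight clusters 0.3 apart; every prior below the gap splits them
        pos = [0.0, 0.002, 0.004, 0.3, 0.302, 0.304]
        ids = [f"s{i}" for i in range(6)]
        m = matrix_from_positions(ids, pos)
        res = bg.abgd_partition(m, AbgdConfig(p_min=0.01, p_max=0.1, steps=8))
        assert res.modal_n_groups == 2
        lo, hi = res.consensus_threshold
        assert 0.004 < lo <= hi < 0.296
        truth = {frozenset(ids[:3]), frozenset(ids[3:])}
        for r in res.modal_partitions():
            assert set(r.partition) == truth

    def test_uniform_ladder_no_gap(self):
        ids = [f"s{i}" for i in range(8)]
        m = matrix_from_positions(ids, [i * 0.001 for i in range(8)])
        res = bg.abgd_partition(m)  # default priors start at 0.001 with X=1.5
        assert res.no_gap
        assert res.modal_n_groups == 1
        assert res.per_prior[0].partition == (frozenset(ids),)

    def test_too_few_specimens(self):
        m = matrix_from_positions(["a", "b"], [0.0, 0.1])
        with pytest.raises(GapError):
            bg.abgd_partition(m)

    def test_recovers_simulated_species(self):
        cfg = bg.get_preset("gapped", seed=5)
        cfg.populations = cfg.populations[:5]  # 5 species x 5 specimens
        import dendropy

        tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick")
        tree.retain_taxa_with_labels([p.name for p in cfg.populations])
        cfg.tree_newick = tree.as_string(schema="newick")
        sset = bg.simulate_dataset(cfg)
        m = bg.build_matrix(sset)
        res = bg.abgd_partition(m)
        truth_tax = sset.taxonomies["current"]
        truth = {
            frozenset(truth_tax.specimens_of(sp)) for sp in truth_tax.species()
        }
        assert set(res.modal_partitions()[0].partition) == truth
        pools = bg.pool_distances(m, truth_tax)
        lo, hi = res.consensus_threshold
        assert max(pools.intra_pooled) < lo <= hi < min(pools.inter_pooled)


class TestAnova:
    def test_identical_groups(self):
        r = bg.anova_intraspecific([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.F == pytest.approx(0.0)
        assert (r.df1, r.df2) == (1, 4)

    def test_hand_decomposition(self):
        r = bg.anova_intraspecific([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert r.F == pytest.approx(1.5)
        assert (r.df1, r.df2) == (1, 4)
        assert 0 < r.p <= 1

    def test_matches_closed_form(self, rng):
        for _ in range(20):
            a = rng.random(int(rng.integers(2, 12))).tolist()
            b = rng.random(int(rng.integers(2, 12))).tolist()
            na, nb = len(a), len(b)
            grand = (sum(a) + sum(b)) / (na + nb)
            ssb = na * (np.mean(a) - grand) ** 2 + nb * (np.mean(b) - grand) ** 2
            ssw = sum((x - np.mean(a)) ** 2 for x in a) + sum(
                (x - np.mean(b)) ** 2 for x in b
            )
            expected = (ssb / 1) / (ssw / (na + nb - 2))
            r = bg.anova_intraspecific(a, b)
            assert r.F == pytest.approx(expected, abs=1e-10)

    def test_small_group_error(self):
        with pytest.raises(GapError):
            bg.anova_intraspecific([1.0], [1.0, 2.0])
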