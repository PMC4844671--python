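"""Permutation tests: statistics, null invariants, oracles and reproducibility."""

import itertools

import numpy as np
import pytest

from invnet.association import (
    ContingencyTable2x2,
    bistability_inhibition_test,
    enrichment_ratio,
    gap_controlled_invader_test,
    hubs_of_bistability_test,
    invader_advantage_test,
    randomize_inhibition,
    resident_protection_test,
    top_k_bistability,
)
from invnet.networks import (
    INVADES,
    MISSING,
    NO_INVASION,
    InhibitionMatrix,
    bistability_degrees,
    outcome_counts,
)
from invnet.synthetic_data import (
    inhibition_from_hierarchy,
    planted_hierarchy_matrix,
    random_invasion_matrix,
)

from conftest import all_bistable, make_inhibition, make_invasion


def _random_inhibition(n, rng, p=0.35):
    e = (rng.random((n, n)) < p).astype(np.int8)
    return make_inhibition(e, labels=[f"s{i + 1}" for i in range(n)])


class TestEnrichmentRatio:
    def test_arithmetic(self):
        r, corrected = enrichment_ratio(ContingencyTable2x2(1, 4, 10, 5))
        assert r == pytest.approx((1 / 4) / (10 / 5))
        assert not corrected

    def test_no_association_is_one(self):
        r, _ = enrichment_ratio(ContingencyTable2x2(3, 6, 5, 10))
        assert r == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        r, corrected = enrichment_ratio(ContingencyTable2x2(0, 4, 10, 5))
        assert corrected
        assert r == pytest.approx((0.5 / 4.5) / (10.5 / 5.5))


class TestRandomizeInhibition:
    def test_preserves_pairwise_link_counts(self):
        rng = np.random.default_rng(0)
        inh = _random_inhibition(10, rng)
        as_inv = make_invasion(inh.entries, labels=list(inh.strains.ids))
        before = outcome_counts(as_inv)
        for _ in range(20):
            null = randomize_inhibition(inh, rng)
            after = outcome_counts(make_invasion(null.entries, labels=list(inh.strains.ids)))
            assert after == before

    def test_empty_matrix_fixed_point(self):
        inh = make_inhibition(np.zeros((4, 4), dtype=np.int8))
        assert randomize_inhibition(inh, rng=1) == inh


def test_protection_extreme_case_yields_small_p():
    # single inhibition A -| B; B fails to invade A while every other
    # ordered invasion succeeds: the most protective table possible
    n = 4
    inv_e = np.full((n, n), INVADES, dtype=np.int8)
    inv_e[1, 0] = NO_INVASION  # B does not invade A
    inv = make_invasion(inv_e)
    inh_e = np.zeros((n, n), dtype=np.int8)
    inh_e[0, 1] = 1  # A inhibits B
    inh = make_inhibition(inh_e)
    res = resident_protection_test(inh, inv, n_perm=2000, rng=0)
    assert res.table.a == 0 and res.table.b == 1
    assert res.haldane_corrected
    assert res.direction == "le"
    # exact enumeration: the null repositions the single inhibition over
    # 12 equally likely (pair, direction) slots and only the original one
    # reproduces the fully protective table, so p converges to 1/12
    exact = 1 / 12
    assert res.p_value == pytest.approx(exact, abs=4 * np.sqrt(exact * (1 - exact) / 2000) + 1e-3)


def test_advantage_when_inhibitors_always_invade():
    n = 5
    rng = np.random.default_rng(2)
    inh = _random_inhibition(n, rng, p=0.4)
    inv_e = np.where(inh.entries == 1, INVADES, NO_INVASION).astype(np.int8)
    inv = make_invasion(inv_e, labels=list(inh.strains.ids))
    res = invader_advantage_test(inh, inv, n_perm=100, rng=3)
    assert res.observed > 1.0
    assert res.direction == "ge"


def test_tests_refuse_empty_inhibition_class():
    inv, _ = random_invasion_matrix(5, rng=0)
    empty = make_inhibition(np.zeros((5, 5), dtype=np.int8), labels=list(inv.strains.ids))
    with pytest.raises(ValueError, match="degenerate"):
        resident_protection_test(empty, inv, n_perm=10, rng=0)


def test_missing_entries_excluded_and_reported():
    inv, _ = random_invasion_matrix(6, rng=1, category_probs=(0.3, 0.4, 0.1))
    rng = np.random.default_rng(5)
    inh = _random_inhibition(6, rng)
    res = resident_protection_test(inh, inv, n_perm=10, rng=0)
    assert res.n_excluded_pairs > 0
    assert res.table.total == 6 * 5 - res.n_excluded_pairs


class TestGapControlled:
    def test_empty_restricted_set_refused(self):
        inv, planted = planted_hierarchy_matrix(6, 3, rng=0)
        rng = np.random.default_rng(1)
        inh = inhibition_from_hierarchy(planted, rng=rng)
        with pytest.raises(ValueError, match="gap"):
            gap_controlled_invader_test(inh, inv, planted, n_perm=10, rng=0, gap_max=0)

    def test_p_matches_exact_enumeration_oracle(self):
        # small instance: enumerate every placement of the down-pointing
        # inhibitions over the restricted pairs and compare the exact tail
        # probability with the empirical permutation p-value
        inv, planted = planted_hierarchy_matrix(5, 5, rng=3, flip_prob=0.25)
        rng = np.random.default_rng(4)
        inh = inhibition_from_hierarchy(planted, rng=rng, p_down=0.5, p_up=0.1)
        levels = np.array([planted[s] for s in inv.strains])
        gap = levels[:, None] - levels[None, :]
        pairs = np.argwhere((gap > 0) & (gap <= 3))
        down = inh.entries[pairs[:, 0], pairs[:, 1]] == 1
        invades = inv.entries[pairs[:, 0], pairs[:, 1]] == INVADES

        def stat(d):
            t = ContingencyTable2x2(
                int((d & invades).sum()), int((d & ~invades).sum()),
                int((~d & invades).sum()), int((~d & ~invades).sum()),
            )
            return enrichment_ratio(t)[0]

        obs = stat(down)
        k, m = int(down.sum()), len(down)
        hits = total = 0
        for pos in itertools.combinations(range(m), k):
            d = np.zeros(m, dtype=bool)
            d[list(pos)] = True
            total += 1
            if stat(d) <= obs:
                hits += 1
        exact_p = hits / total
        res = gap_controlled_invader_test(inh, inv, planted, n_perm=4000, rng=7)
        assert res.observed == pytest.approx(obs)
        tol = 4 * np.sqrt(exact_p * (1 - exact_p) / 4000) + 1 / 4000
        assert abs(res.p_value - exact_p) <= tol

    def test_null_preserves_up_down_inhibition_counts(self):
        # the permuted vector is a rearrangement, so the number of down-
        # pointing inhibitions in the restricted set is invariant; verify
        # via the observed table margins being reproduced under the null
        inv, planted = planted_hierarchy_matrix(8, 8, rng=5, flip_prob=0.2)
        rng = np.random.default_rng(6)
        inh = inhibition_from_hierarchy(planted, rng=rng, p_down=0.5, p_up=0.2)
        res = gap_controlled_invader_test(inh, inv, planted, n_perm=50, rng=8)
        assert res.table.a + res.table.b == int(
            sum(
                inh.entries[inv.strains.index(a), inv.strains.index(b)] == 1
                for a in planted
                for b in planted
                if a != b and 0 < planted[a] - planted[b] <= 3
            )
        )


class TestHubsOfBistability:
    def test_statistic_equals_hand_computed_top3(self):
        inv, _ = random_invasion_matrix(6, rng=10)
        degs = sorted(bistability_degrees(inv).values(), reverse=True)
        assert top_k_bistability(inv, 3) == sum(degs[:3])

    def test_all_bistable_network_gives_p_one(self):
        res = hubs_of_bistability_test(all_bistable(6), n_perm=50, rng=0)
        assert res.p_value == 1.0

    def test_concentrated_bistability_detected(self):
        # all bistable pairs sit inside one triple of a 10-strain network
        # whose remaining pairs are hierarchical
        n = 10
        inv, _ = planted_hierarchy_matrix(n, n, rng=0)
        e = inv.entries.copy()
        for i, j in itertools.combinations(range(3), 2):
            e[i, j] = e[j, i] = NO_INVASION
        concentrated = make_invasion(e, labels=list(inv.strains.ids))
        res = hubs_of_bistability_test(concentrated, n_perm=400, rng=1)
        assert res.p_value < 0.05


class TestBistabilityInhibition:
    def test_statistic_matches_hand_computation(self):
        # pairs: (A,B) inhibited+bistable, (A,C) inhibited+hierarchical,
        # (B,C) free+bistable, (A,D),(B,D),(C,D) free+hierarchical
        inv_e = np.array(
            [
                [-1, 0, 1, 1],
                [0, -1, 0, 1],
                [0, 0, -1, 1],
                [0, 0, 0, -1],
            ],
            dtype=np.int8,
        )
        inh_e = np.zeros((4, 4), dtype=np.int8)
        inh_e[0, 1] = 1
        inh_e[2, 0] = 1
        res = bistability_inhibition_test(
            make_inhibition(inh_e), make_invasion(inv_e), n_perm=10, rng=0
        )
        assert res.observed == pytest.approx((1 / 2) / (1 / 4))

    def test_equal_fractions_give_unit_statistic(self):
        # bistable fraction is 1/2 both among inhibited pairs (AB bistable,
        # AC hierarchical) and among free pairs (BD, CD bistable; AD, BC not)
        inv_e = np.array(
            [
                [-1, 0, 1, 1],
                [0, -1, 1, 0],
                [0, 0, -1, 0],
                [0, 0, 0, -1],
            ],
            dtype=np.int8,
        )
        inh_e = np.zeros((4, 4), dtype=np.int8)
        inh_e[0, 1] = 1  # AB inhibited (bistable)
        inh_e[0, 2] = 1  # AC inhibited (hierarchical)
        res = bistability_inhibition_test(
            make_inhibition(inh_e), make_invasion(inv_e), n_perm=10, rng=0
        )
        assert res.observed == pytest.approx(1.0)

    def test_excluded_strains_dropped(self):
        inv, _ = random_invasion_matrix(8, rng=3)
        rng = np.random.default_rng(4)
        inh = _random_inhibition(8, rng)
        res = bistability_inhibition_test(
            inh, inv, n_perm=10, rng=0, exclude=("s1", "s8")
        )
        assert res.excluded_strains == ("s1", "s8")

    def test_single_class_refused(self):
        inv = all_bistable(3)
        inh = make_inhibition(np.ones((3, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="degenerate"):
            bistability_inhibition_test(inh, inv, n_perm=10, rng=0)


def test_results_reproducible_bit_for_bit():
    inv, _ = random_invasion_matrix(9, rng=6)
    rng = np.random.default_rng(7)
    inh = _random_inhibition(9, rng)
    a = resident_protection_test(inh, inv, n_perm=200, rng=42)
    b = resident_protection_test(inh, inv, n_perm=200, rng=42)
    assert a.p_value == b.p_value and a.observed == b.observed
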