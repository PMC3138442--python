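import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import segdistort as sd
from segdistort.genotypes import Cohort
from segdistort.linkage import (
    LinkageGroupMap,
    TwoPointResult,
    all_pair_tables,
    build_map,
    estimate_two_point,
    genome_coverage,
    group_markers,
    kosambi_cm,
    kosambi_r,
    map_summary,
    order_group,
    pair_count_table,
)


# ---------------------------------------------------------------------
# independent likelihood oracle: explicit gamete enumeration + grid search
# ---------------------------------------------------------------------

def oracle_cell_probs(r, model):
    """Two-locus genotype class probabilities by brute-force gamete
    enumeration.  ``r`` may be scalar or a grid; output shape is
    r.shape + (3, 3)."""
    r = np.asarray(r, dtype=float)
    one = np.ones_like(r)
    male = [((0, 0), (1 - r) / 2), ((1, 1), (1 - r) / 2),
            ((0, 1), r / 2), ((1, 0), r / 2)]
    female = male if model == "symmetric" else [((0, 0), one / 2), ((1, 1), one / 2)]
    probs = np.zeros(r.shape + (3, 3))
    for (fa, fb), pf in female:
        for (ma, mb), pm in male:
            probs[..., fa + ma, fb + mb] += pf * pm
    return probs


def oracle_r_hat(table, model="symmetric", step=1e-4):
    """Grid-search ML recombination fraction over r in [0, 0.5]."""
    grid = np.arange(0.0, 0.5 + step / 2, step)
    t = np.asarray(table, dtype=float)
    if model == "female_achiasmatic":
        t = t.copy()
        t[0, 2] = t[2, 0] = 0.0  # classes impossible under the model
    probs = oracle_cell_probs(grid, model)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    lls = (t * np.where(t > 0, logp, 0.0)).sum(axis=(1, 2))
    return float(grid[int(np.argmax(lls))])


def simulate_table(r, n, model, rng):
    probs = oracle_cell_probs(r, model)
    return rng.multinomial(n, probs.ravel()).reshape(3, 3)


# ---------------------------------------------------------------------


class TestKosambi:
    def test_zero_fraction_maps_to_zero(self):
        assert kosambi_cm(0.0) == 0.0

    def test_closed_form_value(self):
        assert kosambi_cm(0.1) == pytest.approx(25 * np.log(1.2 / 0.8))
        assert kosambi_cm(0.1) == pytest.approx(10.14, abs=0.005)

    @pytest.mark.parametrize("r", np.arange(0.01, 0.50, 0.04).tolist())
    def test_forward_inverse_round_trip(self, r):
        assert kosambi_r(kosambi_cm(r)) == pytest.approx(r, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)
        with pytest.raises(ValueError):
            kosambi_cm(-0.01)
        with pytest.raises(ValueError):
            kosambi_r(-1.0)


class TestTwoPoint:
    def test_fully_parental_table_gives_zero_r(self):
        counts = np.zeros((3, 3))
        counts[0, 0], counts[1, 1], counts[2, 2] = 25, 50, 25
        res = estimate_two_point(counts, "symmetric")
        assert res.r_hat == pytest.approx(0.0, abs=1e-6)
        assert res.p_linkage < 1e-10
        assert res.n_informative == 100

    def test_independence_table_gives_half(self):
        marginals = np.array([0.25, 0.5, 0.25])
        counts = np.outer(marginals, marginals) * 400
        res = estimate_two_point(counts, "symmetric")
        assert res.r_hat == pytest.approx(0.5, abs=1e-6)
        assert res.lod == pytest.approx(0.0, abs=1e-9)
        assert res.p_linkage == 1.0

    @pytest.mark.parametrize("model", ["symmetric", "female_achiasmatic"])
    @pytest.mark.parametrize("r_true", [0.05, 0.2, 0.4])
    def test_em_matches_grid_oracle_on_simulated_tables(self, model, r_true):
        rng = np.random.default_rng(hash((model, r_true)) % 2**31)
        table = simulate_table(r_true, 500, model, rng)
        res = estimate_two_point(table, model)
        assert res.r_hat == pytest.approx(oracle_r_hat(table, model), abs=1e-3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=60), min_size=9, max_size=9).filter(
            lambda c: sum(c) > 0
        )
    )
    def test_em_matches_grid_oracle_on_arbitrary_tables(self, cells):
        table = np.array(cells, dtype=float).reshape(3, 3)
        res = estimate_two_point(table, "symmetric")
        assert res.r_hat == pytest.approx(oracle_r_hat(table), abs=1e-3)

    def test_achiasmatic_model_recovers_male_map_fraction(self):
        rng = np.random.default_rng(42)
        table = simulate_table(0.2, 5000, "female_achiasmatic", rng)
        res = estimate_two_point(table, "female_achiasmatic")
        assert res.r_hat == pytest.approx(0.2, abs=0.02)

    def test_symmetric_fit_of_achiasmatic_data_is_attenuated(self):
        # model mismatch shrinks r toward 1 - sqrt(1 - r_male)
        rng = np.random.default_rng(43)
        table = simulate_table(0.2, 10_000, "female_achiasmatic", rng)
        res = estimate_two_point(table, "symmetric")
        assert res.r_hat == pytest.approx(1 - np.sqrt(0.8), abs=0.02)

    def test_lod_zero_iff_r_half(self):
        marginals = np.array([0.25, 0.5, 0.25])
        indep = estimate_two_point(np.outer(marginals, marginals) * 400)
        assert indep.r_hat == pytest.approx(0.5, abs=1e-6)
        assert indep.lod == pytest.approx(0.0, abs=1e-9)
        linked = np.zeros((3, 3))
        linked[0, 0], linked[1, 1], linked[2, 2] = 10, 20, 10
        res = estimate_two_point(linked)
        assert res.r_hat < 0.5 and res.lod > 1

    def test_empty_and_negative_tables_rejected(self):
        with pytest.raises(ValueError):
            estimate_two_point(np.zeros((3, 3)))
        bad = np.ones((3, 3))
        bad[0, 0] = -1
        with pytest.raises(ValueError):
            estimate_two_point(bad)

    def test_pairwise_complete_counts(self):
        from conftest import make_matrix

        gm = make_matrix([["AA", "AB"], ["NA", "AB"], ["BB", "NA"], ["AB", "AB"]])
        table = pair_count_table(gm, "M1", "M2", Cohort.F2_ADULT_MALE)
        assert table.sum() == 2  # rows with either call missing drop out
        assert table[0, 1] == 1 and table[1, 1] == 1

    def test_all_pair_tables_matches_single_pair(self, null_cross):
        _, _, adults, _ = null_cross
        pairs, tables = all_pair_tables(adults, Cohort.F2_ADULT_MALE)
        k = 100
        a, b = pairs[k]
        assert np.array_equal(tables[k], pair_count_table(adults, a, b, Cohort.F2_ADULT_MALE))


def _result(a, b, p):
    return TwoPointResult(a, b, 0.1, 3.0, p, 100)


class TestGrouping:
    def test_no_significant_pairs_gives_singletons(self):
        markers = ["A", "B", "C"]
        results = [_result(a, b, 0.5) for a, b in itertools.combinations(markers, 2)]
        groups = group_markers(markers, results)
        assert groups == [["A"], ["B"], ["C"]]

    def test_alpha_one_merges_everything(self):
        markers = ["A", "B", "C", "D"]
        results = [_result(a, b, 0.99) for a, b in itertools.combinations(markers, 2)]
        assert group_markers(markers, results, alpha=1.0) == [markers]

    def test_transitive_closure(self):
        markers = ["A", "B", "C"]
        results = [_result("A", "B", 1e-6), _result("B", "C", 1e-6),
                   _result("A", "C", 0.9)]
        assert group_markers(markers, results) == [["A", "B", "C"]]


class TestOrdering:
    def test_two_markers_single_canonical_order(self):
        assert order_group(["B", "A"], {("A", "B"): 0.1}) == ["A", "B"]

    def test_recovers_positional_order(self):
        # markers at 0, 10, 20 cM; pairwise r from Kosambi distances
        markers = ["M0", "M1", "M2"]
        pos = {"M0": 0.0, "M1": 10.0, "M2": 20.0}
        r = {
            (a, b): kosambi_r(abs(pos[a] - pos[b]))
            for a, b in itertools.combinations(markers, 2)
        }
        assert order_group(["M1", "M2", "M0"], r) == ["M0", "M1", "M2"]

    def test_sarf_beats_random_permutations(self):
        rng = np.random.default_rng(7)
        markers = [f"X{i}" for i in range(9)]  # exercises the greedy path
        r = {
            (a, b): float(rng.uniform(0.01, 0.49))
            for a, b in itertools.combinations(markers, 2)
        }

        def sarf(order):
            return sum(
                r.get((x, y), r.get((y, x))) for x, y in zip(order, order[1:])
            )

        best = order_group(markers, r)
        for _ in range(100):
            perm = list(rng.permutation(markers))
            assert sarf(best) <= sarf(perm) + 1e-12

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            order_group(["A"], {})


class TestBuildMap:
    def test_two_unlinked_markers_two_singletons(self):
        rng = np.random.default_rng(1)
        from conftest import make_matrix

        tokens = np.array(["AA", "AB", "BB"])
        rows = [
            [tokens[rng.choice(3, p=[0.25, 0.5, 0.25])] for _ in range(2)]
            for _ in range(300)
        ]
        gm = make_matrix(rows)
        maps, _ = build_map(gm, Cohort.F2_ADULT_MALE)
        assert [g.m for g in maps] == [1, 1]

    def test_deterministic(self, null_cross):
        _, _, adults, _ = null_cross
        maps1, _ = build_map(adults, Cohort.F2_ADULT_MALE)
        maps2, _ = build_map(adults, Cohort.F2_ADULT_MALE)
        assert [(g.markers, g.positions_cM) for g in maps1] == [
            (g.markers, g.positions_cM) for g in maps2
        ]

    def test_recovers_simulated_linkage_groups(self, null_cross):
        cfg, _, adults, _ = null_cross
        maps, results = build_map(adults, Cohort.F2_ADULT_MALE)
        truth = {
            frozenset(n for n, _ in markers) for _, markers in cfg.layout.chromosomes
        }
        inferred = {frozenset(g.markers) for g in maps}
        assert inferred == truth
        assert all(r.lod >= 0 and 0 <= r.r_hat <= 0.5 for r in results)


class TestMapSummary:
    def test_coverage_formula_printed_values(self):
        # d = 6.5 cM, n = 52 assigned markers, L = 484.8 cM -> 75.2%
        assert round(100 * genome_coverage(6.5, 52, 484.8), 1) == 75.2

    def test_group_length_correction(self):
        g = LinkageGroupMap("LG01", [f"M{i}" for i in range(5)],
                            [0.0, 5.0, 10.0, 15.0, 20.0])
        s = map_summary([g])
        assert s.corrected_length == pytest.approx((20 + 2) * 6 / 4)  # 33.0

    def test_mean_spacing_from_total_and_intervals(self):
        # 266.7 cM over 41 adjacent intervals -> d = 6.5 cM
        positions = np.linspace(0.0, 266.7, 42)
        g = LinkageGroupMap("LG01", [f"M{i}" for i in range(42)], positions.tolist())
        assert round(map_summary([g]).d, 1) == 6.5

    def test_singletons_excluded_from_statistics(self):
        multi = LinkageGroupMap("LG01", ["A", "B", "C"], [0.0, 10.0, 20.0])
        single = LinkageGroupMap("LG02", ["D"], [0.0])
        s = map_summary([multi, single])
        assert s.n == 3 and s.n_singletons == 1
        assert s.total_length == pytest.approx(20.0)

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            map_summary([LinkageGroupMap("LG01", ["A"], [0.0])])

    def test_coverage_monotonicity(self):
        base = genome_coverage(6.5, 52, 484.8)
        assert genome_coverage(7.5, 52, 484.8) > base   # increasing in d
        assert genome_coverage(6.5, 60, 484.8) > base   # increasing in n
        assert genome_coverage(6.5, 52, 600.0) < base   # decreasing in L
        assert 0.0 <= base <= 1.0
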