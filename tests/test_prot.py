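"""Spectral-counting differential expression: filters, statistics, calls."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.special import gammaln

from retquant.prot import (
    DepThresholds,
    PeptideFilterThresholds,
    SpectralCountMatrix,
    calibrate_fc_threshold,
    call_deps,
    enrich_sets,
    filter_peptides,
    fold_change,
    hypergeom_enrichment_p,
    normalize_counts,
    rank_and_compare,
    sam_weight,
    welch_one_tail_p,
)
from retquant.synthgen import CountTableSpec, make_count_table, protein_id

# ---------------------------------------------------------------------------
# independent oracles


def sam_weight_oracle(x1, x2, mode="sum"):
    m1, m2 = statistics.fmean(x1), statistics.fmean(x2)
    d1, d2 = statistics.stdev(x1), statistics.stdev(x2)
    denom = d1 + d2 if mode == "sum" else d1 - d2
    return (m1 - m2) / denom


def welch_one_tail_oracle(x1, x2):
    """Numerical integration of the t density at Welch-Satterthwaite df."""
    n1, n2 = len(x1), len(x2)
    v1, v2 = statistics.variance(x1), statistics.variance(x2)
    se2 = v1 / n1 + v2 / n2
    t = abs(statistics.fmean(x1) - statistics.fmean(x2)) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))

    def pdf(u):
        return math.exp(
            gammaln((df + 1) / 2) - gammaln(df / 2)
            - 0.5 * math.log(df * math.pi)
            - (df + 1) / 2 * math.log1p(u * u / df)
        )

    tail, _ = integrate.quad(pdf, t, np.inf)
    return tail


def hypergeom_oracle(k, m, n, N):
    """Brute-force sum of the hypergeometric mass for overlap >= k."""
    total = 0.0
    for j in range(k, min(m, n) + 1):
        total += math.comb(m, j) * math.comb(N - m, n - j)
    return total / math.comb(N, n)


def two_group_matrix(x1, x2, normalized=True):
    data = {f"A{i}": [v] for i, v in enumerate(x1)}
    data.update({f"B{i}": [v] for i, v in enumerate(x2)})
    groups = {f"A{i}": "A" for i in range(len(x1))}
    groups.update({f"B{i}": "B" for i in range(len(x2))})
    return SpectralCountMatrix(
        pd.DataFrame(data, index=["P1"]), groups, normalized=normalized
    )


# ---------------------------------------------------------------------------


class TestSamWeight:
    def test_equal_means_zero(self):
        assert sam_weight([5.0, 6.0, 7.0], [7.0, 6.0, 5.0]) == 0.0

    def test_worked_example_sum_mode(self):
        # mu = 12 vs 7, sd = 1.633 and 0.816: W = 5 / 2.449 = 2.041
        w = sam_weight([10, 12, 14, 12], [6, 8, 7, 7], "sum")
        assert w == pytest.approx(2.041, abs=1e-3)
        assert w == pytest.approx(sam_weight_oracle([10, 12, 14, 12], [6, 8, 7, 7]))

    def test_antisymmetry(self):
        x1, x2 = [10.0, 12.0, 14.0], [6.0, 8.0, 7.0]
        assert sam_weight(x1, x2) == pytest.approx(-sam_weight(x2, x1))

    def test_as_printed_mode_matches_difference_form(self):
        x1, x2 = [10.0, 12.0, 14.0, 12.0], [6.0, 8.0, 7.0, 7.0]
        assert sam_weight(x1, x2, "as_printed") == pytest.approx(
            sam_weight_oracle(x1, x2, "as_printed")
        )

    def test_zero_denominator_signed_infinity(self):
        with pytest.warns(UserWarning, match="zero W denominator"):
            w = sam_weight([2.0, 2.0], [1.0, 1.0])
        assert w == np.inf

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            sam_weight([1.0], [2.0, 3.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6),
           st.lists(st.floats(0, 100), min_size=2, max_size=6))
    def test_matches_oracle_on_random_fixtures(self, x1, x2):
        d1 = statistics.stdev(x1)
        d2 = statistics.stdev(x2)
        if d1 + d2 == 0:
            return
        assert sam_weight(x1, x2) == pytest.approx(
            sam_weight_oracle(x1, x2), rel=1e-10, abs=1e-12
        )


class TestWelchOneTail:
    def test_identical_groups_half(self):
        assert welch_one_tail_p([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.5)

    def test_one_tail_is_half_two_tail(self):
        from scipy import stats

        x1, x2 = [10.0, 12.0, 14.0, 12.0], [6.0, 8.0, 7.0, 7.0]
        two = stats.ttest_ind(x1, x2, equal_var=False).pvalue
        assert welch_one_tail_p(x1, x2) == pytest.approx(two / 2, rel=1e-12)

    def test_zero_variance_equal_means_p_one(self):
        with pytest.warns(UserWarning):
            assert welch_one_tail_p([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_matches_reference_tail_integration(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x1 = list(rng.normal(10, 3, int(rng.integers(2, 7))))
            x2 = list(rng.normal(12, 2, int(rng.integers(2, 7))))
            assert welch_one_tail_p(x1, x2) == pytest.approx(
                welch_one_tail_oracle(x1, x2), rel=1e-6
            )


class TestFoldChange:
    def test_equal_means_unity(self):
        assert fold_change([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_arithmetic(self):
        assert fold_change([20.0, 20.0], [10.0, 10.0], pseudocount=0.0) == 2.0

    def test_zero_mean_guarded_by_pseudocount(self):
        fc = fold_change([10.0, 10.0], [0.0, 0.0], pseudocount=0.5)
        assert fc == pytest.approx(10.5 / 0.5)
        # auto mode engages only when a mean falls below 0.5
        assert np.isfinite(fold_change([10.0, 10.0], [0.0, 0.0]))
        assert fold_change([20.0], [10.0]) == 2.0


class TestHypergeom:
    def test_zero_overlap_p_one(self):
        assert hypergeom_enrichment_p(0, 5, 4, 20) == 1.0

    def test_enumeration_oracle_example(self):
        # N=20, m=5, n=4, k=3: mass at k in {3, 4}
        want = hypergeom_oracle(3, 5, 4, 20)
        assert want == pytest.approx(155 / 4845)
        assert hypergeom_enrichment_p(3, 5, 4, 20) == pytest.approx(want, rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_on_random_fixtures(self, data):
        N = data.draw(st.integers(4, 40))
        m = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(m, n)))
        assert hypergeom_enrichment_p(k, m, n, N) == pytest.approx(
            hypergeom_oracle(k, m, n, N), rel=1e-10
        )


class TestPeptideFilter:
    @pytest.fixture()
    def toy_table(self):
        # 12 peptide rows with hand-annotated pass/fail against the rules:
        # length > 5, no 1+ charge, peptide prob > 80, >= 2 peptides/protein,
        # protein prob > 99, FDR < 1
        rows = [
            # P1: two clean peptides -> survives
            ("P1", "AAAAAA", 6, 2, 95.0, 99.5, 0.5, 10, 12),
            ("P1", "CCCCCCC", 7, 3, 90.0, 99.5, 0.5, 8, 9),
            # P2: one peptide too short (== 5 fails strict rule), leaving 1 -> drop
            ("P2", "DDDDD", 5, 2, 95.0, 99.9, 0.2, 5, 5),
            ("P2", "EEEEEE", 6, 2, 95.0, 99.9, 0.2, 6, 6),
            # P3: singly charged peptide removed, leaving 1 -> drop
            ("P3", "FFFFFF", 6, 1, 95.0, 99.9, 0.2, 4, 4),
            ("P3", "GGGGGG", 6, 2, 95.0, 99.9, 0.2, 3, 3),
            # P4: low peptide probability removed, leaving 1 -> drop
            ("P4", "HHHHHH", 6, 2, 79.0, 99.9, 0.2, 2, 2),
            ("P4", "IIIIII", 6, 2, 85.0, 99.9, 0.2, 2, 2),
            # P5: protein probability exactly 99 (not > 99) -> drop
            ("P5", "KKKKKK", 6, 2, 95.0, 99.0, 0.2, 7, 7),
            ("P5", "LLLLLL", 6, 2, 95.0, 99.0, 0.2, 7, 7),
            # P6: FDR 1.0 (not < 1) -> drop
            ("P6", "MMMMMM", 6, 2, 95.0, 99.9, 1.0, 9, 9),
            ("P6", "NNNNNN", 6, 2, 95.0, 99.9, 1.0, 9, 9),
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "protein_id", "peptide_sequence", "length_aa", "charge_state",
                "peptide_probability_pct", "protein_probability_pct",
                "protein_fdr_pct", "s1", "s2",
            ],
        )

    def test_hand_annotated_fixture(self, toy_table):
        proteins, matrix = filter_peptides(
            toy_table, ["s1", "s2"], {"s1": "KO", "s2": "WT"}
        )
        assert proteins == ["P1"]
        assert matrix.counts.loc["P1", "s1"] == 18  # 10 + 8
        assert matrix.counts.loc["P1", "s2"] == 21

    @pytest.mark.parametrize(
        "mutate,survivor_present",
        [
            (dict(length_aa=6), True),    # boundary fixed: now long enough
            (dict(length_aa=5), False),   # rule is strictly > 5
            (dict(charge_state=1), False),
            (dict(peptide_probability_pct=80.0), False),  # strictly > 80
        ],
    )
    def test_boundary_rules(self, toy_table, mutate, survivor_present):
        table = toy_table.copy()
        idx = table.index[table["protein_id"] == "P2"][0]  # the short peptide row
        for col, val in mutate.items():
            table.loc[idx, col] = val
        proteins, _ = filter_peptides(table, ["s1", "s2"], {"s1": "KO", "s2": "WT"})
        assert ("P2" in proteins) == survivor_present

    def test_missing_column_named(self, toy_table):
        with pytest.raises(KeyError, match="charge_state"):
            filter_peptides(
                toy_table.drop(columns=["charge_state"]), ["s1", "s2"],
                {"s1": "KO", "s2": "WT"},
            )


class TestNormalize:
    def _matrix(self, cols):
        df = pd.DataFrame(cols, index=[f"P{i}" for i in range(len(next(iter(cols.values()))))])
        groups = {c: "A" for c in cols}
        return SpectralCountMatrix(df, groups)

    def test_equal_totals_unchanged(self):
        m = self._matrix({"s1": [10, 20], "s2": [20, 10]})
        norm = normalize_counts(m)
        pd.testing.assert_frame_equal(norm.counts, m.counts.astype(float))

    def test_scale_factors_to_mean_total(self):
        m = self._matrix({"s1": [100], "s2": [200]})
        norm = normalize_counts(m)
        assert norm.counts["s1"].iloc[0] == pytest.approx(150.0)  # factor 1.5
        assert norm.counts["s2"].iloc[0] == pytest.approx(150.0)  # factor 0.75

    def test_column_totals_equal_after(self):
        rng = np.random.default_rng(0)
        m = self._matrix({f"s{i}": list(rng.integers(0, 50, 30)) for i in range(4)})
        totals = normalize_counts(m).counts.sum(axis=0)
        assert totals.max() - totals.min() <= 1e-9 * totals.mean()

    def test_idempotent(self):
        m = self._matrix({"s1": [100, 3], "s2": [200, 7]})
        once = normalize_counts(m)
        twice = normalize_counts(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="s2"):
            normalize_counts(self._matrix({"s1": [1], "s2": [0]}))


class TestCalibration:
    @staticmethod
    def _control(seed=3):
        matrix, _ = make_count_table(CountTableSpec(seed=seed))
        return normalize_counts(matrix)

    def test_threshold_in_window_and_coverage_holds(self):
        for seed in (1, 2, 3):
            m = self._control(seed)
            cal = calibrate_fc_threshold(
                m, (m.samples_in_group("KO"), m.samples_in_group("WT"))
            )
            assert 1.5 <= cal.threshold <= 2.0
            assert cal.fraction_within >= 0.99

    def test_identical_replicates_clamp_to_lower_edge(self):
        counts = pd.DataFrame(
            np.tile(np.arange(10, 110, dtype=float), (4, 1)).T,
            index=[f"P{i}" for i in range(100)],
            columns=["a1", "a2", "b1", "b2"],
        )
        m = SpectralCountMatrix(counts, {c: "A" for c in counts.columns}, normalized=True)
        cal = calibrate_fc_threshold(m, (["a1", "a2"], ["b1", "b2"]))
        assert cal.threshold == 1.5
        assert cal.fraction_within == 1.0

    def test_coverage_verified_by_direct_count(self):
        m = self._control(9)
        ids_a, ids_b = m.samples_in_group("KO"), m.samples_in_group("WT")
        cal = calibrate_fc_threshold(m, (ids_a, ids_b))
        mean_a = m.counts[ids_a].mean(axis=1)
        mean_b = m.counts[ids_b].mean(axis=1)
        ok = (mean_a > 0) & (mean_b > 0)
        ab = (mean_a + mean_b) / 2
        q1, q3 = ab[ok].quantile([0.25, 0.75])
        inner = ok & (ab >= q1) & (ab <= q3)
        ratios = (mean_a / mean_b)[inner]
        frac = ((ratios >= 1 / cal.threshold) & (ratios <= cal.threshold)).mean()
        assert frac == pytest.approx(cal.fraction_within)
        assert frac >= 0.99

    def test_too_few_proteins_rejected(self):
        matrix, _ = make_count_table(CountTableSpec(n_proteins=10))
        m = normalize_counts(matrix)
        with pytest.raises(ValueError, match="unstable"):
            calibrate_fc_threshold(
                m, (m.samples_in_group("KO"), m.samples_in_group("WT"))
            )


class TestCallDeps:
    def test_null_gives_zero_deps_on_identical_groups(self):
        counts = pd.DataFrame(
            {
                "a1": [10.0, 20], "a2": [12.0, 22], "b1": [10.0, 20], "b2": [12.0, 22],
            },
            index=["P1", "P2"],
        )
        m = SpectralCountMatrix(
            counts, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, normalized=True
        )
        table = call_deps(m)
        assert not table["is_dep"].any()
        assert (table["fc"] == 1.0).all()
        assert (table["p_one_tail"] == 0.5).all()

    def test_constructed_fixture_exact_pass_set(self):
        rng = np.random.default_rng(5)
        n = 20
        base = rng.uniform(20, 80, n)
        x1 = np.tile(base, (4, 1)).T + rng.normal(0, 2.0, (n, 4))
        x2 = np.tile(base, (4, 1)).T + rng.normal(0, 2.0, (n, 4))
        x1[:3] *= 3.0  # three clear DEPs
        counts = pd.DataFrame(
            np.hstack([x1, x2]).clip(0),
            index=[f"P{i:02d}" for i in range(n)],
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        groups = {c: c[0].upper() for c in counts.columns}
        m = SpectralCountMatrix(counts, groups, normalized=True)
        table = call_deps(m)
        # brute-force evaluation of each criterion per protein
        thr = DepThresholds()
        for pid, row in table.iterrows():
            x1r = counts.loc[pid, [f"a{i}" for i in range(4)]].to_numpy()
            x2r = counts.loc[pid, [f"b{i}" for i in range(4)]].to_numpy()
            assert row["pass_sam"] == (abs(sam_weight_oracle(list(x1r), list(x2r))) > thr.w_cut)
            assert row["pass_t"] == (welch_one_tail_oracle(list(x1r), list(x2r)) < thr.p_cut)
            fc = statistics.fmean(x1r) / statistics.fmean(x2r)
            assert row["pass_fc"] == (fc >= 1.5 or fc <= 1 / 1.5)
        assert set(table.index[table["is_dep"]]) == {"P00", "P01", "P02"}

    def test_dep_set_is_intersection_of_criteria(self):
        matrix, _ = make_count_table(CountTableSpec(seed=0, n_proteins=300))
        table = call_deps(normalize_counts(matrix))
        want = table["pass_sam"] & table["pass_t"] & table["pass_fc"]
        assert (table["is_dep"] == want).all()

    def test_unnormalized_refused(self):
        matrix, _ = make_count_table(CountTableSpec(seed=0, n_proteins=10))
        with pytest.raises(ValueError, match="normalize"):
            call_deps(matrix)
        call_deps(matrix, allow_unnormalized=True)  # explicit override works

    def test_scale_invariance_of_statistics(self):
        matrix, _ = make_count_table(CountTableSpec(seed=4, n_proteins=100))
        t1 = call_deps(normalize_counts(matrix))
        scaled = matrix.counts.copy()
        scaled.iloc[:, 0] *= 7.0
        m2 = SpectralCountMatrix(scaled, dict(matrix.groups))
        t2 = call_deps(normalize_counts(m2))
        for col in ("W", "p_one_tail", "fc", "is_dep"):
            np.testing.assert_allclose(
                t1[col].to_numpy(float), t2[col].to_numpy(float), rtol=1e-9
            )

    def test_null_simulation_dep_fraction_below_t_level(self):
        fracs, t_fracs = [], []
        for seed in range(20):
            matrix, _ = make_count_table(CountTableSpec(seed=seed))
            table = call_deps(normalize_counts(matrix))
            fracs.append(table["is_dep"].mean())
            t_fracs.append(table["pass_t"].mean())
        assert np.mean(fracs) <= 0.05
        assert all(f <= t for f, t in zip(fracs, t_fracs))

    def test_power_simulation_sensitivity(self):
        planted = {protein_id(i): 2.5 for i in range(100)}
        matrix, truth = make_count_table(
            CountTableSpec(seed=21, planted_effects=planted)
        )
        table = call_deps(normalize_counts(matrix))
        hits = table.loc[[protein_id(i) for i in range(100)], "is_dep"]
        assert hits.mean() >= 0.8
        fc = table.loc[[protein_id(i) for i in range(100)], "fc"]
        assert fc.mean() == pytest.approx(2.5, rel=0.2)


class TestCompareAndEnrich:
    def _dep_table(self, ids, dep_ids):
        df = pd.DataFrame(
            {
                "p_one_tail": np.linspace(0.001, 0.2, len(ids)),
                "is_dep": [i in dep_ids for i in ids],
                "fc": 2.0,
            },
            index=pd.Index(ids, name="protein_id"),
        )
        return df

    def test_disjoint_and_identical_sets(self):
        ids = [f"P{i}" for i in range(6)]
        a = self._dep_table(ids, {"P0", "P1"})
        b = self._dep_table(ids, {"P4", "P5"})
        res = rank_and_compare(a, b)
        assert res["overlap"] == 0
        res2 = rank_and_compare(a, a)
        assert res2["overlap"] == 2

    def test_enumerated_overlap(self):
        ids = ["A", "B", "C", "D"]
        a = self._dep_table(ids, {"A", "B", "C"})
        b = self._dep_table(ids, {"B", "C", "D"})
        res = rank_and_compare(a, b)
        assert (res["overlap"], res["unique_a"], res["unique_b"]) == (2, 1, 1)

    def test_ranking_ascending_by_p_truncated(self):
        ids = [f"P{i}" for i in range(60)]
        a = self._dep_table(ids, set(ids))
        res = rank_and_compare(a, a, top_n=40)
        assert len(res["top_a"]) == 40
        assert res["top_a"]["p_one_tail"].is_monotonic_increasing

    def test_enrichment_zero_overlap_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        table = enrich_sets(universe[:4], {"set1": universe[10:15]}, universe)
        assert table.loc[0, "p"] == 1.0

    def test_enrichment_ranks_and_truncates(self):
        universe = [f"G{i}" for i in range(50)]
        deps = universe[:10]
        sets = {f"path{j}": universe[j : j + 8] for j in range(30)}
        table = enrich_sets(deps, sets, universe, top_n=20)
        assert len(table) == 20
        assert table["p"].is_monotonic_increasing
        assert (table["k"] <= np.minimum(table["m"], table["n"])).all()

    def test_dep_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_sets(["X"], {"s": ["A"]}, ["A", "B"])
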