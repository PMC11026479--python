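import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utrscreen import clinical, simulate
from utrscreen.clinical import (
    UTMB_COLUMNS, annotate_effect, classify_variant_effect, compute_utmb,
    cooccurrence_counts, detect_outliers, logrank_test,
    outlier_proportion_test, survival_by_utmb, tertile_groups,
)


class TestEffectClassification:
    @pytest.mark.parametrize(
        "functional,direction,role,expected",
        [
            (False, "up", "oncogene", "none"),
            (True, "up", "oncogene", "detrimental"),
            (True, "down", "oncogene", "benign"),
            (True, "down", "tsg", "detrimental"),
            (True, "up", "tsg", "benign"),
            (True, "up", "ambiguous", "ambiguous"),
            (True, "up", "none", "ambiguous"),
        ],
    )
    def test_rule_table(self, functional, direction, role, expected):
        assert classify_variant_effect(functional, direction, role) == expected


def _calls():
    return pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4", "v5"],
        "functional": [True, True, True, False, False],
        "direction": ["up", "down", "up", "up", "down"],
        "driver_role": ["oncogene", "oncogene", "none", "tsg", "none"],
        "gene": ["ONC1", "ONC1", "OTHER", "TSG1", "OTHER"],
        "lnFC": [0.8, -0.6, 0.4, 0.02, -0.01],
    })


class TestComputeUtmb:
    def test_hand_counted_example(self):
        mutations = pd.DataFrame({
            "patient_id": ["P1", "P1", "P1", "P2", "P2"],
            "variant_id": ["v1", "v2", "v4", "v3", "v5"],
        })
        out = compute_utmb(mutations, _calls()).set_index("patient_id")
        p1 = out.loc["P1"]
        # v1 func oncogene up (detrimental), v2 func oncogene down (benign),
        # v4 nonfunc tsg
        assert p1["utmb_func_overall"] == 2
        assert p1["utmb_driver_func_overall"] == 2
        assert p1["utmb_driver_func_detrimental"] == 1
        assert p1["utmb_driver_func_benign"] == 1
        assert p1["utmb_nonfunc"] == 1
        assert p1["utmb_driver_nonfunc"] == 1
        p2 = out.loc["P2"]
        # v3 func non-driver, v5 nonfunc non-driver
        assert p2["utmb_func_overall"] == 1
        assert p2["utmb_driver_func_overall"] == 0
        assert p2["utmb_nonfunc"] == 1
        assert p2["utmb_driver_nonfunc"] == 0

    def test_category_inequalities_on_random_cohorts(self):
        rng = np.random.default_rng(0)
        calls = _calls()
        for _ in range(20):
            n = int(rng.integers(1, 30))
            mutations = pd.DataFrame({
                "patient_id": rng.choice(["P1", "P2", "P3"], size=n),
                "variant_id": rng.choice(calls.variant_id, size=n),
            })
            out = compute_utmb(mutations, calls)
            assert (out.utmb_driver_func_overall <= out.utmb_func_overall).all()
            assert (out.utmb_driver_func_detrimental
                    + out.utmb_driver_func_benign
                    <= out.utmb_driver_func_overall).all()
            assert (out.utmb_driver_nonfunc <= out.utmb_nonfunc).all()
            assert (out[UTMB_COLUMNS] >= 0).all().all()

    def test_patients_argument_adds_zero_rows(self):
        mutations = pd.DataFrame({"patient_id": ["P1"], "variant_id": ["v1"]})
        out = compute_utmb(mutations, _calls(), patients=["P1", "P9"])
        assert set(out.patient_id) == {"P1", "P9"}
        assert out.set_index("patient_id").loc["P9"].sum() == 0


class TestTertiles:
    def test_one_to_nine(self):
        vals = pd.Series(range(1, 10), index=[f"P{i}" for i in range(9)])
        labels = tertile_groups(vals)
        assert set(vals[labels == "low"]) == {1, 2, 3}
        assert set(vals[labels == "high"]) == {7, 8, 9}

    def test_boundary_ties_stable_by_index_order(self):
        vals = pd.Series([1, 2, 2, 2, 3, 4], index=list("abcdef"))
        labels = tertile_groups(vals)
        # sorted stably: a(1) b(2) c(2) d(2) e(3) f(4)
        assert list(labels[list("abcdef")]) == [
            "low", "low", "mid", "mid", "high", "high"]

    def test_group_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(1)
        for n in (7, 8, 9, 10, 23):
            vals = pd.Series(rng.choice(1000, size=n, replace=False))
            sizes = tertile_groups(vals).value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_degenerate_single_group(self):
        vals = pd.Series([2, 2, 2, 2])
        assert set(tertile_groups(vals)) == {"mid"}

    def test_too_few_patients(self):
        with pytest.raises(ValueError, match=">= 3"):
            tertile_groups(pd.Series([1, 2]))


class TestLogrank:
    def test_identical_groups_null_identity(self):
        g = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 0, 1]})
        stat, p = logrank_test(g, g.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_five_subject_oracle(self):
        a = pd.DataFrame({"time": [1.0, 3.0], "event": [1, 1]})
        b = pd.DataFrame({"time": [2.0, 4.0, 5.0], "event": [1, 0, 1]})
        # by hand: event times 1,2,3,5; O_A = 2,
        # E_A = 2/5 + 1/4 + 1/3 + 0; V = 0.24 + 0.1875 + 2/9 + 0
        e_a = 2 / 5 + 1 / 4 + 1 / 3
        v = 0.24 + 0.1875 + 2 / 9
        expected = (2 - e_a) ** 2 / v
        stat, p = logrank_test(a, b)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)

    def test_power_under_hazard_ratio_three(self):
        hits = 0
        n_seeds = 40
        for s in range(n_seeds):
            rng = np.random.default_rng(np.random.SeedSequence([77, s]))
            a = pd.DataFrame({"time": rng.exponential(1.0, 100),
                              "event": np.ones(100, dtype=int)})
            b = pd.DataFrame({"time": rng.exponential(1 / 3, 100),
                              "event": np.ones(100, dtype=int)})
            _, p = logrank_test(a, b)
            hits += p < 0.01
        assert hits >= 0.9 * n_seeds

    def test_errors(self):
        g = pd.DataFrame({"time": [1.0], "event": [1]})
        empty = pd.DataFrame({"time": [], "event": []})
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test(g, empty)
        censored = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError, match="at least one event"):
            logrank_test(censored, censored.copy())


class TestSurvivalByUtmb:
    def test_simulated_cohort_separates(self):
        cfg = simulate.SimConfig(seed=5, n_variants=40, n_patients=300,
                                 mean_mutations_per_patient=6.0,
                                 utmb_hazard_coef=1.0, frac_functional=0.6)
        _, variants, truth, _ = simulate.build_library(cfg)
        calls = variants.merge(truth, on="variant_id")
        calls["functional"] = calls["is_functional"]
        calls["lnFC"] = calls["true_lnFC"]
        calls["direction"] = np.where(calls.lnFC > 0, "up", "down")
        cohort = simulate.simulate_cohort(cfg, calls)
        utmb = compute_utmb(cohort.mutations, calls,
                            patients=cohort.survival.patient_id)
        out = survival_by_utmb(utmb, cohort.survival)
        row = out.iloc[0]
        assert not row.skipped
        assert row.p_value < 0.01

    def test_degenerate_cohort_skipped(self):
        utmb = pd.DataFrame({"patient_id": ["P1", "P2", "P3"],
                             "utmb_func_overall": [1, 1, 1]})
        surv = pd.DataFrame({"patient_id": ["P1", "P2", "P3"],
                             "time": [1.0, 2.0, 3.0], "event": [1, 1, 0],
                             "cohort": "X"})
        out = survival_by_utmb(utmb, surv)
        assert bool(out.iloc[0].skipped)

    def test_top_vs_rest_grouping(self):
        rng = np.random.default_rng(2)
        n = 60
        utmb = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                             "utmb_func_overall": rng.integers(0, 10, n)})
        surv = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                             "time": rng.exponential(1, n),
                             "event": np.ones(n, dtype=int), "cohort": "X"})
        out = survival_by_utmb(utmb, surv, grouping="top_vs_rest")
        row = out.iloc[0]
        assert row.n_high + row.n_low == n


class TestOutliers:
    def _cohort(self):
        patients = [f"P{i}" for i in range(12)]
        expr = pd.DataFrame(
            {"G1": np.linspace(-1, 1, 12)}, index=patients
        )
        expr.index.name = "patient_id"
        return patients, expr

    def test_z_formula_and_flags(self):
        patients, expr = self._cohort()
        carrier = patients[0]
        ref = expr.drop(index=carrier)["G1"]
        expr.loc[carrier, "G1"] = ref.mean() + 3 * ref.std(ddof=1)
        mutations = pd.DataFrame({"patient_id": [carrier],
                                  "variant_id": ["v1"]})
        calls = pd.DataFrame({"variant_id": ["v1"], "gene": ["G1"],
                              "lnFC": [-0.5]})
        out = detect_outliers(expr, mutations, calls)
        row = out.iloc[0]
        assert row.z == pytest.approx(3.0)
        assert row.outlier
        assert not row.consistent  # z > 0 but lnFC < 0

    def test_carrier_at_mean_not_outlier(self):
        patients, expr = self._cohort()
        carrier = patients[0]
        ref = expr.drop(index=carrier)["G1"]
        expr.loc[carrier, "G1"] = ref.mean()
        mutations = pd.DataFrame({"patient_id": [carrier], "variant_id": ["v1"]})
        calls = pd.DataFrame({"variant_id": ["v1"], "gene": ["G1"], "lnFC": [0.5]})
        out = detect_outliers(expr, mutations, calls)
        assert out.iloc[0].z == pytest.approx(0.0, abs=1e-12)
        assert not out.iloc[0].outlier

    def test_zero_sd_and_small_reference_skipped(self):
        patients = [f"P{i}" for i in range(6)]
        expr = pd.DataFrame({"G1": [1.0] * 6}, index=patients)
        mutations = pd.DataFrame({"patient_id": ["P0"], "variant_id": ["v1"]})
        calls = pd.DataFrame({"variant_id": ["v1"], "gene": ["G1"], "lnFC": [0.5]})
        assert detect_outliers(expr, mutations, calls).empty  # sd = 0
        expr2 = pd.DataFrame({"G1": np.arange(4.0)}, index=patients[:4])
        assert detect_outliers(expr2, mutations, calls).empty  # < 5 refs

    def test_matched_carrier_outlier_rate_near_expected(self):
        # carriers drawn from the reference distribution should be outliers
        # at about the two-sided |z| > 2 normal mass (~4.6%)
        rng = np.random.default_rng(3)
        n = 2000
        patients = [f"P{i}" for i in range(n)]
        expr = pd.DataFrame({"G1": rng.normal(size=n)}, index=patients)
        carriers = patients[:1000]
        mutations = pd.DataFrame({
            "patient_id": carriers, "variant_id": "v1",
        })
        calls = pd.DataFrame({"variant_id": ["v1"], "gene": ["G1"], "lnFC": [0.5]})
        out = detect_outliers(expr, mutations, calls)
        rate = out.outlier.mean()
        assert abs(rate - 0.0455) < 0.015


class TestOutlierProportion:
    def test_balanced_table(self):
        odds, p = outlier_proportion_test(5, 10, 5, 10)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_oracle(self):
        odds, p = outlier_proportion_test(9, 10, 1, 10)
        # two-sided Fisher by direct hypergeometric enumeration: sum the
        # probabilities of all tables (fixed margins 10/10, 10/10) that are
        # no more probable than the observed one
        obs = stats.hypergeom.pmf(9, 20, 10, 10)
        expected = sum(
            pk for k in range(11)
            if (pk := stats.hypergeom.pmf(k, 20, 10, 10)) <= obs * (1 + 1e-9)
        )
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(0.00115, abs=1e-4)

    def test_row_swap_symmetry(self):
        o1, p1 = outlier_proportion_test(9, 10, 1, 10)
        o2, p2 = outlier_proportion_test(1, 10, 9, 10)
        assert o1 == pytest.approx(1 / o2)
        assert p1 == pytest.approx(p2)

    def test_empty_margin(self):
        odds, p = outlier_proportion_test(0, 10, 0, 10)
        assert np.isnan(odds)
        assert p == 1.0


class TestCooccurrence:
    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        calls = _calls()
        mutations = pd.DataFrame({
            "patient_id": rng.choice(["P1", "P2"], size=30),
            "variant_id": rng.choice(calls.variant_id, size=30),
        })
        out = cooccurrence_counts(mutations, calls)
        func = calls[calls.functional].set_index("variant_id")
        seen = mutations.drop_duplicates()
        for row in out.itertuples(index=False):
            sub = seen[(seen.patient_id == row.patient_id)]
            vids = [v for v in sub.variant_id
                    if v in func.index and func.loc[v, "gene"] == row.gene]
            assert row.n_variants == len(set(vids))
            assert row.n_up == sum(func.loc[v, "direction"] == "up"
                                   for v in set(vids))

    def test_empty(self):
        out = cooccurrence_counts(
            pd.DataFrame(columns=["patient_id", "variant_id"]), _calls())
        assert out.empty
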