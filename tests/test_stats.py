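"""Statistical battery: exact tests, mixed ANOVA, post-hocs, allocation."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rehabtap.clinical import PatientRecord
from rehabtap.stats import (
    AssignmentState,
    ContingencyTable2x2,
    assign_minimized,
    fisher_exact_2x2,
    friedman_test,
    log_transform_outcomes,
    mann_whitney,
    mixed_anova,
    tukey_hsd,
    welch_t,
)


class TestFisher:
    def test_sex_distribution_table(self):
        """6F/8M vs 10F/4M across two groups of 14."""
        assert fisher_exact_2x2([[6, 10], [8, 4]]) == pytest.approx(0.2519, abs=5e-5)

    def test_single_count_diagonal(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_lesion_site_table(self):
        """3/11 vs 1/13 with-lesion/without-lesion counts."""
        assert fisher_exact_2x2([[3, 1], [11, 13]]) == pytest.approx(0.60, abs=5e-3)

    def test_transposition_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t.T) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2], [3, -1]])
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)
        assert fisher_exact_2x2(ContingencyTable2x2(6, 10, 8, 4)) == pytest.approx(
            0.2519, abs=5e-5
        )


class TestMannWhitney:
    def test_identical_samples(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.Z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_complete_separation(self):
        r = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert r.W == 0.0  # x entirely below y: minimal rank-sum form
        assert r.p < 0.05

    def test_near_exact_enumeration(self):
        """Normal approximation within 0.02 of the exact C(10,5)-split
        null distribution at n = 5 vs 5."""
        rng = np.random.default_rng(13)
        x = rng.normal(0.0, 1.0, 5)
        y = rng.normal(0.9, 1.0, 5)
        r = mann_whitney(x, y)
        p_exact = sps.mannwhitneyu(x, y, method="exact").pvalue
        assert abs(r.p - p_exact) < 0.02

    def test_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.4, 1, 15)
        r = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert r.W == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_signed_z_direction(self):
        r = mann_whitney([1, 2, 3], [10, 11, 12])
        assert r.Z < 0  # first sample ranks lower -> negative deviate

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWelch:
    def test_equal_samples_t_zero(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)

    def test_equal_variance_df_limit(self):
        """Equal sample variances and sizes: Satterthwaite df = 2n - 2."""
        x = [0.0, 1.0, 2.0, 3.0]
        y = [10.0, 11.0, 12.0, 13.0]
        r = welch_t(x, y)
        assert r.df == pytest.approx(2 * 4 - 2)

    def test_formula_oracle(self):
        x = np.array([3.1, 4.5, 2.2, 5.0, 3.3])
        y = np.array([6.0, 7.1, 5.5])
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_expected = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_expected = (vx + vy) ** 2 / (
            vx**2 / (x.size - 1) + vy**2 / (y.size - 1)
        )
        r = welch_t(x, y)
        assert r.t == pytest.approx(t_expected, rel=1e-12)
        assert r.df == pytest.approx(df_expected, rel=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestFriedman:
    def test_constant_rows_chi2_zero(self):
        data = np.tile([2.0, 2.0, 2.0], (6, 1))
        r = friedman_test(data)
        assert r.chi2 == 0.0 and r.p == 1.0

    def test_perfect_ordering_maximal_chi2(self):
        """A common strict ordering across n subjects at k = 3 yields
        the rank-algebra maximum chi2 = 2n."""
        n = 9
        data = np.tile([1.0, 2.0, 3.0], (n, 1)) + np.arange(n)[:, None] * 10
        r = friedman_test(data)
        assert r.chi2 == pytest.approx(2 * n)
        assert r.df == 2

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(15)
        data = rng.integers(0, 4, size=(12, 5)).astype(float)
        r = friedman_test(data)
        ref = sps.friedmanchisquare(*data.T)
        assert r.chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_exhaustive_permutation_oracle(self):
        """Asymptotic p within 0.01 of the exact within-row permutation
        distribution for a clear monotone trend (8 subjects, 3 levels)."""
        rng = np.random.default_rng(12)
        data = rng.normal(0, 1, (8, 3)) + np.array([0.0, 1.0, 2.0])
        obs = friedman_test(data)
        perms = np.array(list(itertools.permutations([1.0, 2.0, 3.0])))
        idx = np.array(list(itertools.product(range(6), repeat=8)))
        colsums = perms[idx].sum(axis=1)
        n, k = 8, 3
        chi2_all = 12.0 / (n * k * (k + 1)) * (colsums**2).sum(axis=1) - 3 * n * (k + 1)
        p_exact = float(np.mean(chi2_all >= obs.chi2 - 1e-9))
        assert abs(obs.p - p_exact) < 0.01

    def test_incomplete_block_rejected(self):
        data = np.ones((4, 3))
        data[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_test(data)


def _toy_mixed_frame():
    """4 subjects x 2 groups x 3 sessions with hand-checkable values."""
    rows = []
    values = {
        ("A", 0): [10.0, 12.0, 14.0], ("A", 1): [11.0, 14.0, 15.0],
        ("A", 2): [9.0, 11.0, 14.0], ("A", 3): [10.0, 13.0, 13.0],
        ("B", 0): [10.0, 10.0, 11.0], ("B", 1): [12.0, 11.0, 12.0],
        ("B", 2): [11.0, 12.0, 11.0], ("B", 3): [11.0, 11.0, 12.0],
    }
    for (g, i), ys in values.items():
        for j, y in enumerate(ys):
            rows.append(dict(subject=f"{g}{i}", group=g, session=f"s{j}", dv=y))
    return pd.DataFrame(rows)


def _brute_force_ss(df):
    """Independent SS computation from cell/marginal means (balanced)."""
    y = df.pivot(index="subject", columns="session", values="dv")
    groups = df.groupby("subject")["group"].first().loc[y.index]
    k = y.shape[1]
    grand = y.to_numpy().mean()
    ss = {}
    subj_means = y.mean(axis=1)
    ss["between_subj"] = k * ((subj_means - grand) ** 2).sum()
    gm = subj_means.groupby(groups).mean()
    ng = groups.value_counts()
    ss["group"] = k * sum(ng[g] * (gm[g] - grand) ** 2 for g in gm.index)
    ss["subj"] = ss["between_subj"] - ss["group"]
    sess_means = y.mean(axis=0)
    N = y.shape[0]
    ss["session"] = N * ((sess_means - grand) ** 2).sum()
    cell = y.groupby(groups).mean()
    ss["cells"] = sum(
        ng[g] * ((cell.loc[g] - gm[g]) ** 2).sum() for g in cell.index
    )
    ss["interaction"] = ss["cells"] - ss["session"]
    ss["total"] = ((y.to_numpy() - grand) ** 2).sum()
    ss["error_within"] = (
        ss["total"] - ss["between_subj"] - ss["session"] - ss["interaction"]
    )
    return ss


class TestMixedAnova:
    def test_toy_design_matches_brute_force(self):
        df = _toy_mixed_frame()
        res = mixed_anova(df, dv="dv", within="session", between="group",
                          subject="subject")
        ss = _brute_force_ss(df)
        assert res.effect("group")["ss"] == pytest.approx(ss["group"], rel=1e-12)
        assert res.effect("session")["ss"] == pytest.approx(ss["session"], rel=1e-12)
        assert res.effect("group:session")["ss"] == pytest.approx(
            ss["interaction"], rel=1e-12
        )
        assert res.ss_subject == pytest.approx(ss["subj"], rel=1e-12)
        assert res.ss_error_within == pytest.approx(ss["error_within"], abs=1e-9)
        # F ratios recomputed independently
        f_group = (ss["group"] / 1) / (ss["subj"] / 6)
        assert res.effect("group")["f"] == pytest.approx(f_group, rel=1e-12)
        f_sess = (ss["session"] / 2) / (ss["error_within"] / 12)
        assert res.effect("session")["f"] == pytest.approx(f_sess, rel=1e-12)

    def test_ss_conservation_on_random_data(self):
        rng = np.random.default_rng(16)
        rows = []
        for g, n in (("A", 5), ("B", 7)):  # unequal group sizes
            for i in range(n):
                for j in range(4):
                    rows.append(dict(subject=f"{g}{i}", group=g,
                                     session=f"s{j}", dv=rng.normal()))
        df = pd.DataFrame(rows)
        res = mixed_anova(df, dv="dv", within="session", between="group",
                          subject="subject")
        parts = res.table["ss"].sum() + res.ss_subject + res.ss_error_within
        assert parts == pytest.approx(res.ss_total, rel=1e-10)

    def test_two_within_levels_epsilon_exactly_one(self):
        rng = np.random.default_rng(17)
        rows = [
            dict(subject=f"{g}{i}", group=g, session=s, dv=rng.normal())
            for g in "AB" for i in range(5) for s in ("PRE", "POST")
        ]
        res = mixed_anova(pd.DataFrame(rows), dv="dv", within="session",
                          between="group", subject="subject")
        sess = res.effect("session")
        assert sess["gg_eps"] == 1.0
        assert sess["p_gg"] == sess["p_unc"]

    def test_compound_symmetry_epsilon_near_one(self):
        """Under exchangeable (compound-symmetric) covariance the GG
        epsilon estimate approaches 1 with growing n."""
        rng = np.random.default_rng(18)
        rows = []
        for g in "AB":
            for i in range(150):
                base = rng.normal(0, 1)
                for j in range(4):
                    rows.append(dict(subject=f"{g}{i}", group=g,
                                     session=f"s{j}", dv=base + rng.normal()))
        res = mixed_anova(pd.DataFrame(rows), dv="dv", within="session",
                          between="group", subject="subject")
        assert res.effect("session")["gg_eps"] > 0.95

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(19)
        rows = []
        for g in "AB":
            for i in range(8):
                base = rng.normal(0, 1)
                for j in range(4):
                    rows.append(dict(subject=f"{g}{i}", group=g, session=f"s{j}",
                                     dv=base + 0.3 * j * (g == "A") + rng.normal()))
        df = pd.DataFrame(rows)
        res = mixed_anova(df, dv="dv", within="session", between="group",
                          subject="subject")
        ref = pg.mixed_anova(df, dv="dv", within="session", between="group",
                             subject="subject")
        for ours, theirs in (("group", "group"), ("session", "session"),
                             ("group:session", "Interaction")):
            row = res.effect(ours)
            ref_row = ref[ref.Source == theirs].iloc[0]
            assert row["ss"] == pytest.approx(ref_row.SS, rel=1e-9)
            assert row["f"] == pytest.approx(ref_row.F, rel=1e-9)
            assert row["p_unc"] == pytest.approx(ref_row["p_unc"], rel=1e-9)

    def test_incomplete_design_rejected(self):
        df = _toy_mixed_frame().iloc[:-1]  # drop one cell
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova(df, dv="dv", within="session", between="group",
                        subject="subject")

    def test_epsilon_within_bounds(self):
        rng = np.random.default_rng(20)
        rows = []
        for g in "AB":
            for i in range(6):
                trend = rng.normal(0, 2)
                for j in range(5):
                    rows.append(dict(subject=f"{g}{i}", group=g, session=f"s{j}",
                                     dv=trend * j + rng.normal()))
        res = mixed_anova(pd.DataFrame(rows), dv="dv", within="session",
                          between="group", subject="subject")
        eps = res.effect("session")["gg_eps"]
        assert 1.0 / 4 < eps <= 1.0


class TestTukey:
    def test_identical_means_p_one(self):
        p = tukey_hsd([5.0, 5.0, 5.0], error_ms=2.0, df_error=27, n_per_cell=10)
        off_diag = p[~np.eye(3, dtype=bool)]
        assert np.all(off_diag > 0.999)

    def test_two_cells_reduce_to_t_test(self):
        """With two cells the studentized-range p equals the two-sided
        pooled t p via q = t * sqrt(2)."""
        m, ms, df, n = [1.0, 2.3], 1.7, 18, 10
        p = tukey_hsd(m, error_ms=ms, df_error=df, n_per_cell=n)
        t = abs(m[0] - m[1]) / math.sqrt(2 * ms / n)
        p_t = 2 * sps.t.sf(t, df)
        assert p[0, 1] == pytest.approx(p_t, rel=1e-6)

    def test_outlying_cell_flagged(self):
        p = tukey_hsd([0.0, 0.2, 8.0], error_ms=1.0, df_error=27, n_per_cell=10)
        assert p[0, 2] < 0.001 and p[1, 2] < 0.001
        assert p[0, 1] > 0.85  # near-identical pair not flagged

    def test_invalid_error_ms(self):
        with pytest.raises(ValueError):
            tukey_hsd([1.0, 2.0], error_ms=0.0, df_error=10, n_per_cell=5)


def _patient(pid, age, sex, barthel, peg):
    return PatientRecord(patient_id=pid, group="together", age=age, sex=sex,
                         barthel_pre=barthel, pegboard_pre_s=peg)


class TestMinimization:
    def test_identical_pair_split_across_groups(self):
        state = AssignmentState()
        pair = [_patient("a", 65, "F", 50, 60), _patient("b", 65, "F", 50, 60)]
        labels = assign_minimized(pair, state, seed=1)
        assert sorted(labels) == ["in_turn", "together"]
        sizes = state.sizes
        assert sizes["together"] == 1 and sizes["in_turn"] == 1

    def test_size_rule_dominates_single_candidate(self):
        state = AssignmentState()
        for pid, g in (("a", "together"), ("b", "together"), ("c", "in_turn")):
            state.add(g, _patient(pid, 65, "F", 50, 60))
        labels = assign_minimized([_patient("d", 30, "M", 20, 120)], state, seed=0)
        assert labels == ["in_turn"]  # |nA - nB| <= 1 forces group B

    def test_batch_size_validated(self):
        state = AssignmentState()
        four = [_patient(str(i), 60, "F", 50, 60) for i in range(4)]
        with pytest.raises(ValueError):
            assign_minimized(four, state, seed=0)
        with pytest.raises(ValueError):
            assign_minimized([], state, seed=0)

    def test_size_constraint_never_violated(self):
        """Random accrual sequences of batches of 2-3 always keep the
        group sizes within one of each other."""
        rng = np.random.default_rng(21)
        for trial in range(30):
            state = AssignmentState()
            total = 0
            while total < 28:
                b = min(int(rng.integers(2, 4)), 28 - total)
                batch = [
                    _patient(f"t{trial}p{total + j}", rng.uniform(30, 75),
                             "F" if rng.random() < 0.5 else "M",
                             rng.uniform(25, 90), rng.uniform(20, 150))
                    for j in range(b)
                ]
                assign_minimized(batch, state, seed=int(rng.integers(2**31)))
                total += b
                sizes = state.sizes
                assert abs(sizes["together"] - sizes["in_turn"]) <= 1

    def test_beats_random_assignment_on_average(self):
        """Minimized accrual achieves lower final covariate imbalance
        than the median of purely random balanced assignments."""
        rng = np.random.default_rng(22)
        def make_patients(n):
            return [
                _patient(f"p{j}", rng.uniform(30, 75),
                         "F" if rng.random() < 0.5 else "M",
                         rng.uniform(25, 90), rng.uniform(20, 150))
                for j in range(n)
            ]
        imb_min, imb_rand = [], []
        for trial in range(40):
            patients = make_patients(28)
            state = AssignmentState()
            i = 0
            while i < len(patients):
                b = min(int(rng.integers(2, 4)), len(patients) - i)
                assign_minimized(patients[i:i + b], state, seed=int(rng.integers(2**31)))
                i += b
            imb_min.append(state.imbalance())
            perm = rng.permutation(28)
            rand_state = AssignmentState()
            for pos, j in enumerate(perm):
                rand_state.add("together" if pos < 14 else "in_turn", patients[j])
            imb_rand.append(rand_state.imbalance())
        assert np.median(imb_min) < np.median(imb_rand)


class TestLogTransform:
    def test_known_values(self):
        df = pd.DataFrame({"median_iti_ms": [1.0, math.e], "cv": [1.0, 1.0]})
        out = log_transform_outcomes(df, ["median_iti_ms"])
        np.testing.assert_allclose(out["median_iti_ms"], [0.0, 1.0])
        assert (out["transform"] == "log(median_iti_ms)").all()
        np.testing.assert_allclose(out["cv"], 1.0)  # untouched

    def test_nonpositive_value_named(self):
        df = pd.DataFrame({"v": [2.0, 0.0]}, index=["r1", "r2"])
        with pytest.raises(ValueError, match="r2"):
            log_transform_outcomes(df, ["v"])

    def test_reduces_lognormal_skewness(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({"v": rng.lognormal(5.5, 0.4, size=400)})
        out = log_transform_outcomes(df, ["v"])
        assert abs(sps.skew(out["v"])) < abs(sps.skew(df["v"]))
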