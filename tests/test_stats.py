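import numpy as np
import pandas as pd
import pytest

from graspkin.metrics import PARAMETERS
from graspkin.stats import (
    bonferroni_pairwise,
    gg_epsilon,
    mauchly,
    quartile_drift,
    rm_anova,
    spearman,
)

# a fixed 5 subjects x 4 conditions integer matrix used across oracle tests
FIXTURE = np.array([
    [3, 5, 7, 4],
    [2, 4, 6, 5],
    [4, 6, 9, 6],
    [3, 7, 8, 5],
    [5, 6, 7, 7],
], dtype=float)


def anova_oracle(m):
    """Textbook sums-of-squares decomposition, written independently with
    explicit loops."""
    n, k = m.shape
    grand = m.sum() / m.size
    ss_total = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_cond = n * sum((m[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_subj = k * sum((m[i, :].sum() / k - grand) ** 2 for i in range(n))
    ss_err = ss_total - ss_cond - ss_subj
    df_e, df_r = k - 1, (n - 1) * (k - 1)
    return {
        "F": (ss_cond / df_e) / (ss_err / df_r),
        "df_effect": df_e, "df_error": df_r,
        "MSE": ss_err / df_r,
        "peta": ss_cond / (ss_cond + ss_err),
    }


class TestRmAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        r = rm_anova(FIXTURE)
        o = anova_oracle(FIXTURE)
        assert r.F == pytest.approx(o["F"], abs=1e-8)
        assert r.df_effect == o["df_effect"] and r.df_error == o["df_error"]
        assert r.MSE == pytest.approx(o["MSE"], abs=1e-8)
        assert r.partial_eta_sq == pytest.approx(o["peta"], abs=1e-8)

    def test_all_cells_equal_degenerate(self):
        r = rm_anova(np.full((6, 4), 3.3))
        assert r.F == 0.0 and r.partial_eta_sq == 0.0 and r.degenerate

    def test_invariant_to_per_subject_constant(self):
        rng = np.random.default_rng(41)
        m = rng.normal(size=(10, 4))
        shifted = m + rng.normal(scale=50, size=(10, 1))
        a, b = rm_anova(m), rm_anova(shifted)
        assert a.F == pytest.approx(b.F, rel=1e-9)
        assert a.partial_eta_sq == pytest.approx(b.partial_eta_sq, rel=1e-9)

    def test_invariant_to_affine_unit_rescaling(self):
        rng = np.random.default_rng(43)
        m = rng.normal(size=(8, 4))
        a, b = rm_anova(m), rm_anova(1000.0 * m + 7.0)
        assert a.F == pytest.approx(b.F, rel=1e-9)
        assert a.partial_eta_sq == pytest.approx(b.partial_eta_sq, rel=1e-9)
        assert a.p_uncorrected == pytest.approx(b.p_uncorrected, rel=1e-9)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(47)
        m = rng.normal(size=(12, 4)) + np.array([0.0, 0.3, 0.1, 0.5])
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "cond": np.tile(np.arange(4), 12),
            "y": m.ravel(),
        })
        ours = rm_anova(m)
        theirs = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                             correction=True, detailed=False)
        assert ours.F == pytest.approx(float(theirs["F"].iloc[0]), rel=1e-6)
        assert ours.p_uncorrected == pytest.approx(float(theirs["p_unc"].iloc[0]), rel=1e-6)
        assert ours.gg_epsilon == pytest.approx(float(theirs["eps"].iloc[0]), rel=1e-6)
        assert ours.p_gg == pytest.approx(float(theirs["p_GG_corr"].iloc[0]), rel=1e-4)
        assert ours.mauchly_W == pytest.approx(float(theirs["W_spher"].iloc[0]), rel=1e-6)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(np.ones((1, 4)))

    def test_power_with_one_sd_effect(self):
        """Planted 1-within-SD condition effect, 21 subjects: the test
        rejects in >90% of replicates."""
        rng = np.random.default_rng(42)
        rej = sum(
            rm_anova(rng.normal(size=(21, 4)) + np.array([0, 1, 1, 1])).p_reported < 0.05
            for _ in range(400)
        )
        assert rej / 400 > 0.9


class TestSphericity:
    def test_compound_symmetry_gives_epsilon_one(self):
        rng = np.random.default_rng(53)
        subj = rng.normal(scale=2.0, size=(400, 1))
        m = subj + rng.normal(size=(400, 4))  # exchangeable conditions
        assert gg_epsilon(m) > 0.97

    def test_exact_compound_symmetric_covariance(self):
        # construct data whose sample covariance is exactly compound symmetric
        base = np.eye(4) * 2.0 + 1.0
        chol = np.linalg.cholesky(base)
        z = np.random.default_rng(59).normal(size=(200, 4))
        z = (z - z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(z, rowvar=False)).T)
        m = z @ chol.T
        assert gg_epsilon(m) == pytest.approx(1.0, abs=1e-6)

    def test_two_conditions_forced_to_one(self):
        m = np.random.default_rng(61).normal(size=(10, 2))
        assert gg_epsilon(m) == 1.0

    def test_lower_bound(self):
        # a single dominant contrast drives epsilon to its floor 1/(k-1)
        t = np.linspace(0, 1, 12)[:, None]
        m = t @ np.array([[1.0, -1.0, 0.0, 0.0]]) + 1e-9 * np.random.default_rng(2).normal(size=(12, 4))
        eps = gg_epsilon(m)
        assert 1 / 3 - 1e-9 <= eps <= 1.0
        assert eps == pytest.approx(1 / 3, abs=0.01)

    def test_epsilon_matches_eigenvalue_formula(self):
        rng = np.random.default_rng(67)
        m = rng.normal(size=(8, 4)) * np.array([1.0, 2.0, 0.5, 3.0])
        S = np.cov(m, rowvar=False)
        k = 4
        C = np.eye(k) - np.ones((k, k)) / k
        lam = np.linalg.eigvalsh(C @ S @ C)
        lam = lam[lam > 1e-12]
        expected = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
        assert gg_epsilon(m) == pytest.approx(expected, abs=1e-10)

    def test_mauchly_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(71)
        m = rng.normal(size=(15, 4)) * np.array([1.0, 1.5, 0.7, 2.0])
        W, p = mauchly(m)
        res = pg.sphericity(pd.DataFrame(m), method="mauchly")
        assert W == pytest.approx(float(res.W), rel=1e-6)
        # identical chi-square statistic; pingouin adds Box's second-order
        # term to the tail probability, so p agrees only approximately
        assert p == pytest.approx(float(res.pval), rel=0.05)


class TestPairwise:
    def test_identical_samples(self):
        t = bonferroni_pairwise(np.tile([[1.0, 1.0, 1.0, 1.0]], (6, 1)))
        assert (t.table["mean_diff"] == 0).all()
        assert (t.table["p_bonferroni"] == 1.0).all()

    def test_six_pairs_and_times_six_rule(self):
        rng = np.random.default_rng(73)
        m = rng.normal(size=(10, 4))
        t = bonferroni_pairwise(m).table
        assert len(t) == 6
        assert np.allclose(t["p_bonferroni"], np.minimum(1.0, 6 * t["p_raw"]))

    def test_t_statistics_match_paired_oracle(self):
        t = bonferroni_pairwise(FIXTURE).table
        for _, row in t.iterrows():
            i = {"N1": 0, "N2": 1, "N3": 2, "N4": 3}[row["a"]]
            j = {"N1": 0, "N2": 1, "N3": 2, "N4": 3}[row["b"]]
            d = FIXTURE[:, i] - FIXTURE[:, j]
            se = d.std(ddof=1) / np.sqrt(len(d))
            assert row["t"] == pytest.approx(d.mean() / se, abs=1e-8)


class TestSpearman:
    def test_monotone_increasing(self):
        x = np.arange(20.0)
        assert spearman(x, np.exp(x / 5)).rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        x = np.arange(20.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_ties_match_manual_ranking(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 5.0, 8.0, 7.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        r = spearman(x, y)
        assert r.rho == pytest.approx(expected, abs=1e-12)
        assert r.n == 10

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        assert spearman(x, y).n == 3


def drift_metrics(values_fn, n_participants=8, n_trials=64, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for i in range(1, n_trials + 1):
            v = values_fn(i, rng)
            rows.append({"participant_id": f"P{p:02d}", "trial_index": i,
                         "condition": "N1",
                         **{param: v for param in PARAMETERS}})
    return pd.DataFrame(rows)


class TestQuartileDrift:
    def test_constant_metric_no_drift(self):
        df = drift_metrics(lambda i, rng: 2.0)
        out = quartile_drift(df)
        assert np.allclose(out["quartile_means"]["total_time"], 2.0)
        assert np.allclose(out["first_vs_last"]["mean_diff_first_minus_last"], 0.0)

    def test_identity_metric_quartile_means(self):
        df = drift_metrics(lambda i, rng: float(i))
        out = quartile_drift(df)
        assert list(out["quartile_means"]["total_time"]) == [8.5, 24.5, 40.5, 56.5]

    def test_linear_learning_drift_recovered(self):
        # planted improvement of 5 ms per trial: first-minus-last quartile
        # difference is 48 trials x 5 ms = 240 ms
        df = drift_metrics(
            lambda i, rng: 6.0 - 0.005 * i + rng.normal(0, 0.05), seed=3
        )
        out = quartile_drift(df)
        row = out["first_vs_last"].set_index("parameter").loc["total_time"]
        diff = row["mean_diff_first_minus_last"]
        se = 0.05 / np.sqrt(16 * 8)  # within-cell SE of a quartile mean
        assert abs(diff - 0.240) < 2 * np.sqrt(2) * se

    def test_bad_trial_index_rejected(self):
        df = drift_metrics(lambda i, rng: 1.0)
        df.loc[0, "trial_index"] = 99
        with pytest.raises(ValueError):
            quartile_drift(df)
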