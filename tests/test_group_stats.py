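import numpy as np
import pandas as pd
import pytest

from gabashift.group_stats import (
    paired_comparison,
    paired_t,
    pearson_with_normality,
    percent_change,
    rm_anova,
)


def splitplot_ss_oracle(df):
    """Direct sums-of-squares decomposition for the split-plot design.

    Scans (subject x condition) are the units; condition is the
    between-unit factor and region the within-unit factor.  Returns F
    statistics for condition, region and the interaction.
    """
    df = df.copy()
    df["scan"] = df.subject.astype(str) + "/" + df.condition.astype(str)
    y = df.value.to_numpy()
    grand = y.mean()
    regions = df.region.unique()
    conds = df.condition.unique()
    r, c = len(regions), len(conds)
    n_scans = df.scan.nunique()
    ss_total = ((y - grand) ** 2).sum()
    scan_means = df.groupby("scan").value.mean()
    cond_means = df.groupby("condition").value.mean()
    reg_means = df.groupby("region").value.mean()
    cell = df.groupby(["region", "condition"]).value.mean()
    ss_cond = r * (n_scans / c) * ((cond_means - grand) ** 2).sum()
    ss_scan = r * ((scan_means - df.groupby("scan").condition.first().map(cond_means)) ** 2).sum()
    ss_reg = n_scans * ((reg_means - grand) ** 2).sum()
    ss_int = (n_scans / c) * sum(
        (cell[(rr, cc)] - reg_means[rr] - cond_means[cc] + grand) ** 2
        for rr in regions
        for cc in conds
    )
    ss_err = ss_total - ss_cond - ss_scan - ss_reg - ss_int
    f_cond = (ss_cond / (c - 1)) / (ss_scan / (n_scans - c))
    f_reg = (ss_reg / (r - 1)) / (ss_err / ((r - 1) * (n_scans - c)))
    f_int = (ss_int / ((r - 1) * (c - 1))) / (ss_err / ((r - 1) * (n_scans - c)))
    return {"condition": f_cond, "region": f_reg, "region:condition": f_int}


def make_grid(n_subj, regions, seed=0, cond_effect=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        for i, r in enumerate(regions):
            for c in ("baseline", "post"):
                rows.append(
                    {
                        "subject": f"s{s}",
                        "region": r,
                        "condition": c,
                        "value": rng.normal(5 + i + (c == "post") * cond_effect, 0.5),
                    }
                )
    return pd.DataFrame(rows)


class TestPairedT:
    def test_identical_vectors(self):
        t, p, d = paired_t([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert t == 0.0 and p == 1.0 and np.isnan(d)

    def test_hand_example(self):
        # diffs (-1, -1, -2): mean -4/3, sd 0.5774 -> d = -2.309, t = -4.0
        t, p, d = paired_t([5.0, 6.0, 7.0], [6.0, 7.0, 9.0])
        assert t == pytest.approx(-4.0, rel=1e-6)
        assert d == pytest.approx(-4.0 / 3.0 / np.std([-1, -1, -2], ddof=1), rel=1e-9)
        assert d == pytest.approx(-2.309, abs=0.001)

    def test_swap_symmetry(self):
        base, post = [5.0, 6.2, 7.1, 6.6], [5.5, 6.1, 7.9, 7.0]
        t1, p1, d1 = paired_t(base, post)
        t2, p2, d2 = paired_t(post, base)
        assert t2 == pytest.approx(-t1) and d2 == pytest.approx(-d1)
        assert p2 == pytest.approx(p1)

    def test_increase_gives_negative_d(self):
        _, _, d = paired_t([5.0, 6.0, 7.0], [5.5, 6.5, 7.6])
        assert d < 0


class TestPercentChange:
    def test_no_change(self):
        assert percent_change([10.0, 12.0], [10.0, 12.0]) == (0.0, 0.0)

    def test_hand_example(self):
        mean, sd = percent_change([10.0, 10.0], [11.0, 12.0])
        assert mean == pytest.approx(15.0)
        assert sd == pytest.approx(np.sqrt(50) / 1, abs=1e-9)  # sd of (10, 20)

    def test_mean_of_ratios_is_not_ratio_of_means(self):
        base, post = np.array([10.0, 20.0]), np.array([12.0, 22.0])
        mean, _ = percent_change(base, post)
        ratio_of_means = 100.0 * (post.mean() - base.mean()) / base.mean()
        assert mean != pytest.approx(ratio_of_means, abs=1e-6)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change([0.0, 1.0], [1.0, 2.0])


class TestRmAnova:
    @pytest.mark.parametrize("n_subj,regions", [(3, ["r1", "r2"]), (4, ["r1", "r2", "r3"])])
    def test_matches_ss_oracle(self, n_subj, regions):
        df = make_grid(n_subj, regions, seed=42)
        res = rm_anova(df).set_index("effect")
        oracle = splitplot_ss_oracle(df)
        for effect, f in oracle.items():
            assert res.loc[effect, "F"] == pytest.approx(f, rel=1e-10)

    def test_condition_effect_zero_when_no_change(self):
        df = make_grid(3, ["r1", "r2"], seed=1, cond_effect=0.0)
        # force post == baseline exactly
        wide = df.pivot_table(index=["subject", "region"], columns="condition", values="value")
        wide["post"] = wide["baseline"]
        df = wide.reset_index().melt(
            id_vars=["subject", "region"], var_name="condition", value_name="value"
        )
        res = rm_anova(df).set_index("effect")
        assert res.loc["condition", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_subject_order_invariance(self):
        df = make_grid(4, ["r1", "r2", "r3"], seed=7)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = rm_anova(df).set_index("effect").F
        b = rm_anova(shuffled).set_index("effect").F
        assert np.allclose(a, b)

    def test_incomplete_design_rejected(self):
        df = make_grid(3, ["r1", "r2"]).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(df)

    def test_fully_repeated_option_runs(self):
        df = make_grid(5, ["r1", "r2"], seed=3)
        res = rm_anova(df, design="within-subject")
        assert set(res.effect) == {"region", "condition", "region:condition"}


class TestPearson:
    def test_colinear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p, _ = pearson_with_normality(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_normality([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ks_flag_on_gross_nonnormality(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(30), np.ones(3) * 50])
        y = rng.normal(size=33)
        _, _, ks_pass = pearson_with_normality(x, y)
        assert not ks_pass


def test_paired_comparison_row():
    row = paired_comparison([6.8, 7.0, 6.5], [7.2, 7.4, 7.1])
    assert row.n == 3
    assert row.cohen_d < 0
    assert row.percent_change_mean > 0
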