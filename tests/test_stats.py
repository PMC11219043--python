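"""Normality screening, t-tests and repeated-measures ANOVA + Tukey."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oculearn import (
    ComparisonSpec,
    InvalidArgumentError,
    rm_anova_tukey,
    shapiro_wilk,
    t_test,
)
from oculearn.stats import run_comparison


def long_table(values, groups, times, subjects):
    return pd.DataFrame(
        {"delta": values, "group": groups, "time": times, "animal": subjects}
    )


def simulated_table(rng, group_means, n_per_group=6, sd=1.0):
    """group_means: {name: [mean per time]}; adds a subject random effect."""
    rows = []
    for g, means in group_means.items():
        for s in range(n_per_group):
            subj_eff = rng.normal(0, sd)
            for t, mu in enumerate(means):
                rows.append(
                    {
                        "group": g,
                        "animal": f"{g}{s}",
                        "time": float(t),
                        "delta": mu + subj_eff + rng.normal(0, sd),
                    }
                )
    return pd.DataFrame(rows)


class TestShapiroWilk:
    def test_holds_level_under_normal_null(self):
        rng = np.random.default_rng(0)
        hits = sum(
            shapiro_wilk(rng.normal(0, 1, 50)).p > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_detects_exponential_departure(self):
        rng = np.random.default_rng(1)
        hits = sum(
            shapiro_wilk(rng.exponential(1.0, 50)).p < 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(InvalidArgumentError):
            shapiro_wilk([3.0] * 10)


class TestTTest:
    def test_paired_identical_samples_report_p_one(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert r.statistic == 0.0 and r.p == 1.0 and not r.significant

    def test_hand_computed_paired_case(self):
        # diffs {-1,-1,0}: mean -2/3, sd 1/sqrt(3), t = -2 exactly
        r = t_test([1.0, 2.0, 4.0], [2.0, 3.0, 4.0], paired=True)
        assert r.statistic == pytest.approx(-2.0, abs=1e-12)
        assert r.df == 2.0

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (1000, 20))
        b = rng.normal(0, 1, (1000, 20))
        rejections = np.mean(
            [t_test(x, y).p < 0.05 for x, y in zip(a, b)]
        )
        assert 0.03 <= rejections <= 0.07

    def test_length_mismatch_when_paired(self):
        with pytest.raises(InvalidArgumentError):
            t_test([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)

    def test_significance_flag_is_p_below_alpha(self):
        r = t_test(np.arange(10.0), np.arange(10.0) + 50.0)
        assert r.p < 0.05 and r.significant


class TestRmAnovaTukey:
    def test_detects_group_by_time_interaction(self):
        rng = np.random.default_rng(3)
        d = simulated_table(rng, {"WT": [0, 10, 20, 30], "KO": [0, 0, 0, 0]})
        aov, tukey, results = rm_anova_tukey(
            d, ComparisonSpec("delta", "group", "time", "animal")
        )
        inter = next(r for r in results if r.label == "Interaction")
        assert inter.significant
        assert "p_GG_corr" in aov.columns  # corrected p reported alongside

    def test_reduces_to_paired_t_when_two_levels_one_group(self):
        rng = np.random.default_rng(4)
        d = simulated_table(rng, {"WT": [0.0, 5.0]}, n_per_group=8)
        aov, _, results = rm_anova_tukey(
            d, ComparisonSpec("delta", None, "time", "animal")
        )
        wide = d.pivot_table(index="animal", columns="time", values="delta")
        t = t_test(wide[1.0], wide[0.0], paired=True)
        assert results[0].statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert results[0].p == pytest.approx(t.p, rel=1e-9)

    def test_p_invariant_to_label_permutation_and_affine_response(self):
        rng = np.random.default_rng(5)
        d = simulated_table(rng, {"WT": [0, 3, 6], "KO": [0, 1, 2]})
        spec = ComparisonSpec("delta", "group", "time", "animal")
        _, _, res = rm_anova_tukey(d, spec)
        swapped = d.assign(group=d["group"].map({"WT": "KO", "KO": "WT"}))
        _, _, res_sw = rm_anova_tukey(swapped, spec)
        affine = d.assign(delta=2.5 * d["delta"] - 7.0)
        _, _, res_af = rm_anova_tukey(affine, spec)
        for r, rs, ra in zip(res, res_sw, res_af):
            assert rs.p == pytest.approx(r.p, rel=1e-9)
            assert ra.p == pytest.approx(r.p, rel=1e-9)

    def test_tukey_flags_only_the_shifted_group(self):
        rng = np.random.default_rng(6)
        rows = []
        for g, shift in [("A", 0.0), ("B", 0.0), ("C", 10.0)]:
            for s in range(5):
                for t in [0.0, 1.0]:
                    rows.append(
                        {
                            "group": g,
                            "animal": f"{g}{s}",
                            "time": t,
                            "delta": shift + rng.normal(0, 1e-6),
                        }
                    )
        d = pd.DataFrame(rows)
        _, tukey, _ = rm_anova_tukey(
            d, ComparisonSpec("delta", "group", "time", "animal")
        )
        flagged = tukey[tukey["reject"].astype(bool)]
        assert len(flagged) > 0
        for _, row in tukey.iterrows():
            crosses_c = (str(row["group1"]).startswith("C@")) != (
                str(row["group2"]).startswith("C@")
            )
            assert bool(row["reject"]) == crosses_c

    def test_incomplete_subjects_are_dropped(self):
        rng = np.random.default_rng(7)
        d = simulated_table(rng, {"WT": [0, 1, 2], "KO": [0, 1, 2]})
        d = d[~((d.animal == "WT0") & (d.time == 2.0))]  # break one subject
        aov, _, _ = rm_anova_tukey(d, ComparisonSpec("delta", "group", "time", "animal"))
        # 5 complete WT + 6 KO subjects -> between df2 = 9
        assert float(aov.loc[aov.Source == "group", "DF2"].iloc[0]) == 9.0

    def test_single_level_within_factor_rejected(self):
        d = long_table([1.0, 2.0], ["A", "B"], [0.0, 0.0], ["s1", "s2"])
        with pytest.raises(InvalidArgumentError):
            rm_anova_tukey(d, ComparisonSpec("delta", "group", "time", "animal"))


def test_run_comparison_dispatch():
    rng = np.random.default_rng(8)
    d = pd.DataFrame(
        {
            "delta": np.r_[rng.normal(0, 1, 10), rng.normal(5, 1, 10)],
            "group": ["A"] * 10 + ["B"] * 10,
            "animal": [f"s{i}" for i in range(10)] * 2,
        }
    )
    two = run_comparison(d, ComparisonSpec("delta", between="group", kind="t_two_sample"))
    paired = run_comparison(
        d, ComparisonSpec("delta", between="group", subject="animal", kind="t_paired")
    )
    assert two.significant and paired.significant
    sh = run_comparison(d, ComparisonSpec("delta", kind="shapiro"))
    assert 0.0 <= sh.p <= 1.0
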