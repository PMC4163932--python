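"""Summary assembly, ANOVAs and Tukey post hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from lfpmodes import build_summary, oneway_anova_zt, tukey_hsd, twoway_rm_anova

# fixed toy table: group means 2, 4, 6; SSB=24 (df 2), SSW=16 (df 6) -> F=4.5
TOY_GROUPS = {
    "ZT1": [1.0, 2.0, 3.0],
    "ZT7": [2.0, 4.0, 6.0],
    "ZT13": [5.0, 5.0, 8.0],
}


def _summary_frame(values_by_zt, condition="pre", measure="pct_slow"):
    rows = []
    for zt, values in values_by_zt.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "animal": f"zt{zt}_a{i}", "zt": zt, "condition": condition,
                    "unit": f"u{i}", "measure": measure, "band": "", "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestBuildSummary:
    def _full_table(self):
        rows = []
        for a in range(4):
            for cond in ("pre", "post"):
                for u in range(6):
                    for m in ("pct_slow", "pct_theta", "spindle_rate"):
                        rows.append(
                            {
                                "animal": f"r{a}", "zt": 1, "condition": cond,
                                "unit": f"u{u}", "measure": m, "band": "",
                                "value": float(a + u),
                            }
                        )
        return pd.DataFrame(rows)

    def test_cardinality(self):
        df = build_summary(self._full_table())
        assert len(df) == 4 * 2 * 6 * 3

    def test_missing_condition_names_animal(self):
        t = self._full_table()
        t = t[~((t["animal"] == "r2") & (t["condition"] == "post"))]
        with pytest.raises(ValueError, match="r2"):
            build_summary(t)

    def test_invalid_zt_rejected(self):
        t = self._full_table()
        t.loc[t.index[0], "zt"] = 5
        with pytest.raises(ValueError, match="invalid zt"):
            build_summary(t)

    def test_csv_round_trip(self, tmp_path):
        df = build_summary(self._full_table())
        path = tmp_path / "summary.csv"
        df.to_csv(path, index=False)
        loaded = pd.read_csv(path).fillna({"band": ""})
        loaded["band"] = loaded["band"].astype(str).replace("nan", "")
        pd.testing.assert_frame_equal(
            loaded.reset_index(drop=True).astype({"value": float}),
            df.reset_index(drop=True),
            check_dtype=False,
        )


class TestOneWayAnova:
    def test_matches_sum_of_squares_oracle(self):
        res = oneway_anova_zt(_summary_frame(
            {1: TOY_GROUPS["ZT1"], 7: TOY_GROUPS["ZT7"], 13: TOY_GROUPS["ZT13"]}
        ), "pct_slow")
        assert res.F == pytest.approx(4.5, abs=1e-9)
        assert (res.df_num, res.df_den) == (2, 6)
        # independent reference: scipy's one-way ANOVA
        F_ref, p_ref = spstats.f_oneway(*TOY_GROUPS.values())
        assert res.F == pytest.approx(F_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_identical_groups_give_zero_F(self):
        res = oneway_anova_zt(_summary_frame({1: [1.0, 2.0, 3.0], 13: [1.0, 2.0, 3.0]}), "pct_slow")
        assert res.F == 0.0

    def test_posthoc_pairs_present(self):
        res = oneway_anova_zt(_summary_frame(
            {1: TOY_GROUPS["ZT1"], 7: TOY_GROUPS["ZT7"], 13: TOY_GROUPS["ZT13"]}
        ), "pct_slow")
        assert len(res.posthoc) == 3

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            oneway_anova_zt(_summary_frame({1: [1.0], 13: [1.0, 2.0]}), "pct_slow")


class TestTukey:
    def test_identical_groups_adjusted_p_near_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        out = tukey_hsd(g)
        assert (out["p_adj"] > 0.999).all()

    def test_q_statistic_matches_studentized_range_formula(self):
        out = tukey_hsd(TOY_GROUPS)
        # brute-force: q = |diff| / sqrt(MSW / n); p = sf of studentized range
        msw = 16.0 / 6.0
        for _, row in out.iterrows():
            q = abs(row["diff"]) / np.sqrt(msw / 3.0)
            p_ref = spstats.studentized_range.sf(q, k=3, df=6)
            assert row["p_adj"] == pytest.approx(p_ref, abs=1e-6)

    def test_symmetry_in_pair_order(self):
        g = {"a": [1.0, 2.0], "b": [4.0, 5.0]}
        rev = {"b": [4.0, 5.0], "a": [1.0, 2.0]}
        p1 = tukey_hsd(g)["p_adj"].iloc[0]
        p2 = tukey_hsd(rev)["p_adj"].iloc[0]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestTwoWayMixed:
    def _paired_frame(self, post_shift_by_zt, n=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for zt in (1, 7, 13, 19):
            for u in range(n):
                base = 50.0 + rng.normal(0, 8)
                for cond in ("pre", "post"):
                    v = base + rng.normal(0, 3)
                    if cond == "post":
                        v += post_shift_by_zt.get(zt, 0.0)
                    rows.append(
                        {
                            "animal": f"zt{zt}_a{u}", "zt": zt, "condition": cond,
                            "unit": f"u{u}", "measure": "pct_slow", "band": "", "value": v,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_conditions_give_zero_condition_effect(self):
        df = self._paired_frame({}, seed=1)
        pre = df[df["condition"] == "pre"].copy()
        post = pre.copy()
        post["condition"] = "post"
        res = twoway_rm_anova(pd.concat([pre, post], ignore_index=True), "pct_slow")
        assert res.condition.F == 0.0

    def test_swapped_labels_preserve_F(self):
        df = self._paired_frame({13: 15.0}, seed=2)
        res1 = twoway_rm_anova(df, "pct_slow")
        swapped = df.copy()
        swapped["condition"] = swapped["condition"].map({"pre": "post", "post": "pre"})
        res2 = twoway_rm_anova(swapped, "pct_slow")
        assert res1.condition.F == pytest.approx(res2.condition.F, rel=1e-9)
        assert res1.interaction.F == pytest.approx(res2.interaction.F, rel=1e-9)

    def test_strong_zt13_shift_detected(self):
        df = self._paired_frame({13: 20.0}, n=8, seed=3)
        res = twoway_rm_anova(df, "pct_slow")
        assert res.interaction.p < 0.05
        tk = res.cell_tukey
        mask = tk["group_i"].str.startswith("ZT13:") & tk["group_j"].str.startswith("ZT13:")
        assert tk.loc[mask, "p_adj"].min() < 0.05

    def test_unbalanced_design_rejected(self):
        df = self._paired_frame({}, seed=4)
        df = df.drop(df[(df["zt"] == 7) & (df["unit"] == "u0") & (df["condition"] == "post")].index)
        with pytest.raises(ValueError, match="unbalanced"):
            twoway_rm_anova(df, "pct_slow")
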