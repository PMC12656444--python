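"""Factorial ANOVA, post hoc letters and assumption checks against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import thri
from thri.stats import compact_letter_display, tukey_hsd, two_way_anova_cells


def brute_force_anova(y):
    """Naive 2x2 ANOVA straight from the textbook SS definitions."""
    y = np.asarray(y, dtype=float)
    r = y.shape[2]
    grand = y.mean()
    ss_t = sum(2 * r * (y[i].mean() - grand) ** 2 for i in range(2))
    ss_c = sum(2 * r * (y[:, j].mean() - grand) ** 2 for j in range(2))
    ss_cells = sum(
        r * (y[i, j].mean() - grand) ** 2 for i in range(2) for j in range(2)
    )
    ss_txc = ss_cells - ss_t - ss_c
    ss_total = ((y - grand) ** 2).sum()
    ss_res = ss_total - ss_cells
    df_res = y.size - 4
    out = {}
    for name, ss in [("T", ss_t), ("C", ss_c), ("TxC", ss_txc)]:
        F = (ss / 1) / (ss_res / df_res)
        out[name] = (ss, F, sps.f.sf(F, 1, df_res))
    out["residual"] = (ss_res, None, None)
    return out


class TestTwoWayAnova:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.integers(2, 6)
        y = rng.normal(10, 3, (2, 2, r))
        res = two_way_anova_cells(y)
        oracle = brute_force_anova(y)
        for term in ("T", "C", "TxC"):
            ss, F, p = oracle[term]
            assert res.terms[term].ss == pytest.approx(ss, rel=1e-12, abs=1e-12)
            assert res.terms[term].F == pytest.approx(F, rel=1e-12)
            assert res.terms[term].p == pytest.approx(p, rel=1e-10)
        assert res.terms["residual"].ss == pytest.approx(oracle["residual"][0])

    @pytest.mark.parametrize("seed", range(6))
    def test_ss_partition_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = rng.normal(0, rng.uniform(0.5, 5), (2, 2, int(rng.integers(2, 8))))
        res = two_way_anova_cells(y)
        parts = sum(res.terms[t].ss for t in ("T", "C", "TxC", "residual"))
        assert parts == pytest.approx(res.ss_total, rel=1e-9)

    def test_affine_invariance_of_f_statistics(self):
        rng = np.random.default_rng(2)
        y = rng.normal(5, 2, (2, 2, 4))
        a = two_way_anova_cells(y)
        b = two_way_anova_cells(3.7 * y + 11.0)
        for term in ("T", "C", "TxC"):
            assert b.terms[term].F == pytest.approx(a.terms[term].F, rel=1e-9)

    def test_pure_main_effect_has_no_interaction(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, (2, 2, 5))
        base -= base.mean(axis=2, keepdims=True)  # kill cell-mean noise
        delta = np.array([[0.0, 3.0], [0.0, 3.0]])  # condition shift only
        y = base + delta[:, :, None]
        res = two_way_anova_cells(y)
        assert res.terms["TxC"].ss == pytest.approx(0.0, abs=1e-18)
        assert res.terms["C"].ss > 0

    def test_degenerate_constant_data_flagged(self):
        y = np.full((2, 2, 3), 7.0)
        res = two_way_anova_cells(y)
        assert res.degenerate
        assert all(res.terms[t].ss == 0 for t in ("T", "C", "TxC", "residual"))
        assert np.isnan(res.terms["C"].F)

    def test_balanced_path_agrees_with_statsmodels(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "timepoint": np.repeat(["June", "August"], 8),
                "condition": np.tile(np.repeat(["control", "urban"], 4), 2),
                "value": rng.normal(10, 2, 16),
            }
        )
        res = thri.two_way_anova(df)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        tbl = sm.stats.anova_lm(
            smf.ols("value ~ C(timepoint) * C(condition)", data=df).fit(), typ=2
        )
        assert res.terms["T"].ss == pytest.approx(tbl.loc["C(timepoint)", "sum_sq"])
        assert res.terms["C"].p == pytest.approx(tbl.loc["C(condition)", "PR(>F)"])
        assert res.terms["TxC"].F == pytest.approx(
            tbl.loc["C(timepoint):C(condition)", "F"]
        )

    def test_unbalanced_uses_type_two(self):
        rng = np.random.default_rng(9)
        rows = []
        for tp, cond, n in [
            ("June", "control", 4), ("June", "urban", 6),
            ("August", "control", 5), ("August", "urban", 3),
        ]:
            for v in rng.normal(5, 1, n):
                rows.append({"timepoint": tp, "condition": cond, "value": v})
        res = thri.two_way_anova(pd.DataFrame(rows))
        assert res.ss_type == "II" and not res.balanced
        assert res.terms["residual"].df == 18 - 4

    def test_empty_cell_is_design_error(self):
        df = pd.DataFrame(
            {
                "timepoint": ["June"] * 4 + ["August"] * 2,
                "condition": ["control", "control", "urban", "urban", "control", "control"],
                "value": np.arange(6.0),
            }
        )
        with pytest.raises(ValueError, match="cell"):
            thri.two_way_anova(df)


class TestTukey:
    def test_identical_cells_share_a_letter(self):
        means = {"a1": 5.0, "a2": 5.0}
        res = tukey_hsd(means, {"a1": 5, "a2": 5}, ms_residual=1.0, df_residual=8)
        assert res.p_value("a1", "a2") > 0.9
        assert res.letters["a1"] == res.letters["a2"]

    def test_extreme_separation_distinct_letters(self):
        means = {"lo": 0.0, "hi": 50.0}
        res = tukey_hsd(means, {"lo": 5, "hi": 5}, ms_residual=0.5, df_residual=8)
        assert res.p_value("lo", "hi") < 1e-6
        assert set(res.letters["lo"]) & set(res.letters["hi"]) == set()

    def test_two_pairs_pattern_aabb(self):
        means = {"c1": 0.0, "c2": 0.0, "c3": 10.0, "c4": 10.0}
        ns = {c: 4 for c in means}
        res = tukey_hsd(means, ns, ms_residual=0.01, df_residual=12)
        # letters ordered from the highest mean: c3/c4 get 'a', c1/c2 'b'
        assert res.letters["c3"] == res.letters["c4"] == "a"
        assert res.letters["c1"] == res.letters["c2"] == "b"

    def test_tukey_p_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1.0, 6) for m in (0.0, 0.8, 2.5, 2.6)]
        k = len(groups)
        n = 6
        resid = np.concatenate([g - g.mean() for g in groups])
        ms = (resid**2).sum() / (k * n - k)
        means = {i: g.mean() for i, g in enumerate(groups)}
        ns = {i: n for i in range(k)}
        mine = tukey_hsd(means, ns, ms_residual=ms, df_residual=k * n - k)
        ref = sps.tukey_hsd(*groups)
        for i, j in itertools.combinations(range(k), 2):
            assert mine.p_value(i, j) == pytest.approx(
                ref.pvalue[i, j], abs=1e-4
            )

    def test_sidak_never_less_conservative_than_raw_t(self):
        means = {"x": 0.0, "y": 1.0, "z": 3.0}
        ns = {c: 4 for c in means}
        res = tukey_hsd(means, ns, ms_residual=1.0, df_residual=9, method="sidak")
        for (a, b), p_adj in res.pairwise.items():
            se = np.sqrt(1.0 * (1 / 4 + 1 / 4))
            t = abs(means[a] - means[b]) / se
            p_raw = 2 * sps.t.sf(t, 9)
            assert p_adj >= p_raw - 1e-12

    def test_df_residual_below_one_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": 1.0, "b": 2.0}, {"a": 2, "b": 2}, 1.0, 0.5)


def _contract_holds(letters, sig, cells):
    for a, b in itertools.combinations(cells, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        significant = (a, b) in sig or (b, a) in sig
        if share == significant:
            return False
    return True


class TestCompactLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        letters = compact_letter_display(set(), ["w", "x", "y"])
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        cells = [1, 2, 3]
        sig = {(1, 2), (1, 3), (2, 3)}
        letters = compact_letter_display(sig, cells)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_non_transitive_pattern_verified_exhaustively(self):
        cells = [1, 2, 3, 4]
        sig = {(1, 3), (1, 4), (2, 4)}
        letters = compact_letter_display(sig, cells)
        assert _contract_holds(letters, sig, cells)

    def test_first_cell_gets_letter_a(self):
        letters = compact_letter_display({(1, 2)}, [1, 2])
        assert letters[1] == "a" and letters[2] == "b"

    @given(data=st.data(), n=st.integers(2, 7))
    @settings(max_examples=200, deadline=None)
    def test_contract_on_random_relations(self, data, n):
        cells = list(range(n))
        pairs = list(itertools.combinations(cells, 2))
        sig = {
            p for p in pairs if data.draw(st.booleans(), label=f"sig{p}")
        }
        letters = compact_letter_display(sig, cells)
        assert _contract_holds(letters, sig, cells)
        assert all(letters[c] for c in cells)

    def test_reflexive_pair_rejected(self):
        with pytest.raises(ValueError):
            compact_letter_display({(1, 1)}, [1, 2])


class TestAssumptionChecks:
    def test_clean_normal_groups_mostly_pass(self):
        rng = np.random.default_rng(21)
        n_pass_shapiro = n_pass_bartlett = 0
        n_sim = 300
        for _ in range(n_sim):
            values = rng.normal(0, 1, 40)
            groups = np.repeat(list("abcd"), 10)
            rep = thri.assumption_checks(values, groups)
            n_pass_shapiro += bool(rep.normality_ok)
            n_pass_bartlett += bool(rep.homogeneity_ok)
        # four Shapiro tests at alpha=0.05 jointly pass ~0.95^4 ~ 0.81 of runs
        assert 0.72 <= n_pass_shapiro / n_sim <= 0.90
        assert 0.92 <= n_pass_bartlett / n_sim <= 0.98

    def test_tenfold_variance_flagged(self):
        rng = np.random.default_rng(22)
        flagged = 0
        for _ in range(100):
            values = np.concatenate(
                [rng.normal(0, 1, 30), rng.normal(0, np.sqrt(10), 30)]
            )
            groups = np.repeat(["a", "b"], 30)
            flagged += not thri.assumption_checks(values, groups).homogeneity_ok
        assert flagged >= 90

    def test_tiny_groups_not_computed(self):
        rep = thri.assumption_checks([1.0, 2.0, 1.5, 2.5], ["a", "a", "b", "b"])
        assert all(p is None for p in rep.shapiro_p.values())
        assert rep.normality_ok is None
        assert rep.bartlett_p is not None  # Bartlett needs only n >= 2 per group


class TestSignificanceCodes:
    @pytest.mark.parametrize(
        "p,code",
        [(0.04, "*"), (0.0005, "***"), (0.2, "ns"), (0.009, "**"), (1.0, "ns")],
    )
    def test_thresholds(self, p, code):
        assert thri.significance_codes(p) == code

    def test_nan_maps_to_na(self):
        assert thri.significance_codes(float("nan")) == "na"


class TestAnovaBySpeciesTrait:
    def test_long_tables_cover_species_and_traits(self, synthetic_table):
        anova_df, posthoc_df = thri.anova_by_species_trait(synthetic_table)
        combos = anova_df[["species", "trait"]].drop_duplicates()
        assert len(combos) == 3 * 13  # three species, 13 published traits
        assert set(anova_df["term"]) == {"T", "C", "TxC", "residual"}
        # CLD contract holds on every emitted species x trait table
        for (sp, tr), sub in posthoc_df.groupby(["species", "trait"]):
            letters = dict(
                zip(zip(sub.condition, sub.timepoint), sub.letters)
            )
            assert all(letters.values())

    def test_strong_published_effect_is_significant(self, synthetic_table):
        anova_df, _ = thri.anova_by_species_trait(synthetic_table)
        row = anova_df[
            (anova_df.species == "Tilia")
            & (anova_df.trait == "Proline")
            & (anova_df.term == "C")
        ].iloc[0]
        assert row["p"] < 0.001 and row["code"] == "***"
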