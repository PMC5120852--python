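"""Welch-ANOVA, BH, Games-Howell, compact letters, differential calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epihet.diffmeth import (
    bh_adjust,
    call_differential,
    cluster_differential,
    compact_letters,
    games_howell,
    studentized_range_sf,
    welch_anova,
    welch_anova_rows,
)
from epihet.methcalls import SampleSheet


class TestWelchAnova:
    def test_matches_independent_implementation(self, rng):
        """Agrees with pingouin's Welch ANOVA on random heteroscedastic data."""
        pingouin = pytest.importorskip("pingouin")
        for _ in range(25):
            sizes = rng.integers(3, 12, size=3)
            groups = [rng.normal(rng.normal(), rng.uniform(0.5, 3), n) for n in sizes]
            mine = welch_anova(groups)
            df = pd.DataFrame(
                {
                    "y": np.concatenate(groups),
                    "g": np.repeat(np.arange(3), sizes),
                }
            )
            ref = pingouin.welch_anova(dv="y", between="g", data=df)
            assert mine.f_star == pytest.approx(float(ref["F"][0]), rel=1e-9)
            assert mine.df2 == pytest.approx(float(ref["ddof2"][0]), rel=1e-9)
            assert mine.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_two_groups_reduce_to_welch_t(self, rng):
        """At k=2, F* = t^2 and the p-values coincide (100 random instances)."""
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(3, 15)))
            b = rng.normal(0.3, 2.5, int(rng.integers(3, 15)))
            mine = welch_anova([a, b])
            t, p = stats.ttest_ind(a, b, equal_var=False)
            assert mine.p_value == pytest.approx(p, rel=1e-10)
            assert mine.f_star == pytest.approx(t**2, rel=1e-10)

    def test_identical_groups_give_null_result(self):
        res = welch_anova([[0.2, 0.2, 0.2], [0.2, 0.2, 0.2], [0.2, 0.2, 0.2]])
        assert res.variance_floored
        assert res.f_star == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0], [1.0, 2.0]])

    def test_rowwise_matches_scalar(self, rng):
        x = rng.normal(size=(20, 10))
        cols = [np.arange(0, 4), np.arange(4, 7), np.arange(7, 10)]
        f, df2, p = welch_anova_rows(x, cols)
        for i in range(20):
            ref = welch_anova([x[i, c] for c in cols])
            assert f[i] == pytest.approx(ref.f_star, rel=1e-12)
            assert p[i] == pytest.approx(ref.p_value, rel=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_step_up(self, rng):
        """q_i = min_{j: p_(j) >= p_(i)} p_(j) * m / rank(j), capped at 1."""
        for _ in range(10):
            m = int(rng.integers(1, 400))
            p = rng.random(m)
            q = bh_adjust(p)
            order = np.argsort(p, kind="stable")
            brute = np.empty(m)
            for pos_in_sort, idx in enumerate(order):
                candidates = [
                    p[order[j]] * m / (j + 1) for j in range(pos_in_sort, m)
                ]
                brute[idx] = min(1.0, min(candidates))
            assert np.allclose(q, brute)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.random(500)
        assert np.allclose(bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1])

    def test_permutation_equivariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestGamesHowell:
    def test_two_groups_reduce_to_welch_t(self, rng):
        """q = sqrt(2)|t| and the studentized-range p equals the t p at k=2."""
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(3, 15)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 15)))
            gh = games_howell([a, b])
            t, p = stats.ttest_ind(a, b, equal_var=False)
            assert gh.loc[0, "q"] == pytest.approx(np.sqrt(2) * abs(t), rel=1e-10)
            assert gh.loc[0, "p_value"] == pytest.approx(p, rel=1e-6)

    def test_matches_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        sizes = [7, 3, 7]
        groups = [rng.normal(i * 0.5, 1 + i, n) for i, n in enumerate(sizes)]
        mine = games_howell(groups, labels=["a", "b", "c"])
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(["a", "b", "c"], sizes)}
        )
        ref = pingouin.pairwise_gameshowell(dv="y", between="g", data=df)
        for r in ref.itertuples(index=False):
            row = mine[(mine.group_i == r.A) & (mine.group_j == r.B)].iloc[0]
            assert row.p_value == pytest.approx(r.pval, abs=1e-6)
            assert row.df == pytest.approx(r.df, rel=1e-9)

    def test_identical_groups_not_significant(self):
        gh = games_howell([[0.1] * 4, [0.1] * 4, [0.1] * 4])
        assert (gh["p_value"] > 0.999).all()

    def test_p_increases_as_means_approach(self, rng):
        base = rng.normal(0, 1, 8)
        other = rng.normal(0, 1, 8)
        other -= other.mean()
        ps = []
        for shift in (2.0, 1.0, 0.5, 0.25):
            gh = games_howell([base - base.mean(), other + shift])
            ps.append(gh.loc[0, "p_value"])
        assert ps == sorted(ps)

    def test_studentized_range_tail_reference_value(self):
        # classical q-table: k=3, df=10, alpha=0.05 -> critical q ~= 3.88
        assert studentized_range_sf(3.88, 3, 10) == pytest.approx(0.05, abs=0.002)


class TestCompactLetters:
    def _pmat(self, labels, sig_pairs):
        m = pd.DataFrame(1.0, index=labels, columns=labels)
        for a, b in sig_pairs:
            m.loc[a, b] = m.loc[b, a] = 0.01
        return m

    def test_no_significant_pairs_single_letter(self):
        letters = compact_letters(self._pmat(["8w", "18w", "17m"], []))
        assert set(letters.values()) == {"a"}

    def test_one_group_apart(self):
        # 8w differs from both others; 18w vs 17m not significant
        letters = compact_letters(
            self._pmat(["8w", "18w", "17m"], [("8w", "18w"), ("8w", "17m")])
        )
        assert letters["18w"] == letters["17m"]
        assert letters["8w"] != letters["18w"]
        assert len(letters["8w"]) == 1

    def test_all_pairs_significant_distinct_letters(self):
        labels = ["a1", "a2", "a3"]
        letters = compact_letters(
            self._pmat(labels, [("a1", "a2"), ("a1", "a3"), ("a2", "a3")])
        )
        assert len(set(letters.values())) == 3

    def test_round_trip_reproduces_significance(self, rng):
        """Groups share a letter iff their pairwise p >= alpha."""
        labels = [f"g{i}" for i in range(5)]
        for _ in range(20):
            pairs = [
                (labels[i], labels[j])
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.4
            ]
            pmat = self._pmat(labels, pairs)
            letters = compact_letters(pmat)
            for i in range(5):
                for j in range(i + 1, 5):
                    share = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
                    assert share == (pmat.iloc[i, j] >= 0.05)

    def test_incomplete_matrix_rejected(self):
        m = self._pmat(["a", "b"], [])
        m.loc["a", "b"] = np.nan
        with pytest.raises(ValueError):
            compact_letters(m)


def _sheet(n8=7, n18=3, n17=7):
    entries = (
        [(f"8w_{i}", "8w") for i in range(n8)]
        + [(f"18w_{i}", "18w") for i in range(n18)]
        + [(f"17m_{i}", "17m") for i in range(n17)]
    )
    return SampleSheet(entries)


class TestCallDifferential:
    def _matrix(self, rows, sheet, rng, sigma=0.005):
        data = {}
        for region, means in rows.items():
            vals = []
            for g, m in zip(sheet.groups, means):
                vals.extend(rng.normal(m, sigma, len(sheet.samples_in(g))))
            data[region] = vals
        return pd.DataFrame(data, index=sheet.samples).T

    def test_effect_gate_boundary_inclusive(self, rng):
        sheet = _sheet()
        mat = self._matrix(
            {"at_gate": (0.10, 0.052, 0.050), "below_gate": (0.098, 0.050, 0.050)},
            sheet,
            rng,
            sigma=0.0005,
        )
        # pin the group means exactly so delta_max is exactly 0.05 / 0.048
        for region, means in (
            ("at_gate", (0.10, 0.052, 0.050)),
            ("below_gate", (0.098, 0.050, 0.050)),
        ):
            for g, m in zip(sheet.groups, means):
                cols = sheet.samples_in(g)
                row = mat.loc[region, cols]
                mat.loc[region, cols] = (row - row.mean() + m).values
        res = call_differential(mat, sheet)
        assert res.loc["at_gate", "delta_max"] == pytest.approx(0.05)
        assert bool(res.loc["at_gate", "differential"])
        assert res.loc["below_gate", "delta_max"] == pytest.approx(0.048)
        assert not res.loc["below_gate", "differential"]

    def test_delta_gate_strictly_reduces_calls(self, rng):
        """Small but consistent shifts pass BH yet fail the >=5% effect gate."""
        sheet = _sheet()
        rows = {f"tiny_{i}": (0.03, 0.0, 0.0) for i in range(30)}
        rows.update({f"big_{i}": (0.10, 0.0, 0.0) for i in range(5)})
        mat = self._matrix(rows, sheet, rng, sigma=0.004)
        res = call_differential(mat, sheet)
        q_only = ((res["q_value"] < 0.05) & res["testable"]).sum()
        assert res["differential"].sum() < q_only

    def test_region_with_missing_group_skipped(self, rng):
        sheet = _sheet(n8=2, n18=2, n17=2)
        mat = self._matrix({"r1": (0.1, 0.2, 0.3), "r2": (0.1, 0.1, 0.1)}, sheet, rng)
        mat.loc["r1", sheet.samples_in("18w")[0]] = np.nan  # leaves n=1 in 18w
        res = call_differential(mat, sheet)
        assert not res.loc["r1", "testable"]
        assert res.loc["r2", "testable"]

    def test_letters_consistent_with_pairwise(self, rng):
        sheet = _sheet()
        mat = self._matrix({"r": (0.20, 0.05, 0.05)}, sheet, rng, sigma=0.004)
        res = call_differential(mat, sheet)
        assert bool(res.loc["r", "differential"])
        l8, l18, l17 = res.loc["r", "letters"].split(",")
        assert l18 == l17 and l8 != l18

    def test_fewer_than_two_groups_rejected(self, rng):
        sheet = SampleSheet([("s1", "only"), ("s2", "only")])
        mat = pd.DataFrame({"s1": [0.1], "s2": [0.2]}, index=["r"])
        with pytest.raises(ValueError):
            call_differential(mat, sheet)


class TestClusterDifferential:
    def _patterned_matrix(self, n_I, n_II, sheet, rng, effect=0.1, sigma=0.01):
        rows = {}
        for i in range(n_I):
            rows[f"cI_{i}"] = (effect, 0.0, 0.0)
        for i in range(n_II):
            rows[f"cII_{i}"] = (0.0, effect, effect)
        data = {}
        for region, means in rows.items():
            vals = []
            for g, m in zip(sheet.groups, means):
                vals.extend(rng.normal(m, sigma, len(sheet.samples_in(g))))
            data[region] = vals
        return pd.DataFrame(data, index=sheet.samples).T

    def test_opposite_patterns_split(self, rng):
        sheet = _sheet()
        mat = self._patterned_matrix(1, 1, sheet, rng)
        labels, excluded = cluster_differential(mat, list(mat.index), sheet)
        assert labels["cI_0"] == "I"
        assert labels["cII_0"] == "II"
        assert not excluded

    def test_label_recovery_over_seeds(self):
        """30 cluster-I-like + 10 cluster-II-like regions: >=38/40 recovered."""
        sheet = _sheet()
        for seed in range(20):
            r = np.random.default_rng(seed)
            mat = self._patterned_matrix(30, 10, sheet, r)
            labels, _ = cluster_differential(mat, list(mat.index), sheet)
            correct = sum(
                1
                for region, lab in labels.items()
                if (region.startswith("cI_") and lab == "I")
                or (region.startswith("cII_") and lab == "II")
            )
            assert correct >= 38

    def test_invariant_to_sample_column_order(self, rng):
        sheet = _sheet()
        mat = self._patterned_matrix(5, 5, sheet, rng)
        labels_a, _ = cluster_differential(mat, list(mat.index), sheet)
        shuffled = mat[list(rng.permutation(mat.columns))]
        labels_b, _ = cluster_differential(shuffled, list(mat.index), sheet)
        pd.testing.assert_series_equal(labels_a, labels_b)

    def test_flat_region_excluded(self, rng):
        sheet = _sheet()
        mat = self._patterned_matrix(2, 2, sheet, rng)
        mat.loc["flat"] = 0.25
        labels, excluded = cluster_differential(mat, list(mat.index), sheet)
        assert excluded == ["flat"]
        assert "flat" not in labels.index
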