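"""Standard curves, normalization, fold changes, letters and rank tests."""

import math

import numpy as np
import pandas as pd
import pytest

from ovamir.expression import (
    anova_letters,
    fit_standard_curve,
    fold_changes,
    kw_test,
    quantify_normalize,
    rank_values,
)


class TestStandardCurve:
    def test_perfect_doubling_gives_100_percent_efficiency(self):
        lg = [0.0, -1.0, -2.0, -3.0, -4.0]
        cq = [20.0 + 3.3219 * k for k in range(5)]
        c = fit_standard_curve("t", lg, cq)
        assert c.slope == pytest.approx(-3.3219)
        assert c.efficiency == pytest.approx(100.0, abs=0.02)
        assert c.r2 == pytest.approx(1.0)

    def test_efficiency_closed_form_for_slope_3_59(self):
        lg = [0.0, -1.0, -2.0, -3.0]
        cq = [18.0 + 3.59 * k for k in range(4)]
        c = fit_standard_curve("t", lg, cq)
        expected = (10 ** (1 / 3.59) - 1) * 100
        assert c.efficiency == pytest.approx(expected, rel=1e-6)
        assert round(expected) == 90

    def test_noisy_curve_recovers_slope(self, rng):
        lg = np.repeat([0.0, -1.0, -2.0, -3.0, -4.0], 3)
        cq = 21.0 - 3.3219 * lg + rng.normal(0, 0.1, size=lg.size)
        c = fit_standard_curve("t", lg.tolist(), cq.tolist())
        assert c.slope == pytest.approx(-3.3219, abs=0.1)

    def test_interpolation_inverts_the_curve(self):
        c = fit_standard_curve("t", [0, -1, -2], [20.0, 23.3219, 26.6438])
        assert c.quantity(20.0) == pytest.approx(1.0, rel=1e-4)
        assert c.quantity(23.3219) == pytest.approx(0.1, rel=1e-4)

    def test_too_few_points_or_flat_dilutions_error(self):
        with pytest.raises(ValueError):
            fit_standard_curve("t", [0, -1], [20, 23])
        with pytest.raises(ValueError):
            fit_standard_curve("t", [0, 0, 0], [20, 21, 22])


def _curves(targets, slope=-3.3219, intercept=30.0):
    from ovamir.expression import StandardCurve

    return {
        t: StandardCurve(t, slope, intercept,
                         (10 ** (-1 / slope) - 1) * 100, 1.0)
        for t in targets
    }


def _cq_for(q, slope=-3.3219, intercept=30.0):
    return slope * math.log10(q) + intercept


class TestQuantifyNormalize:
    def test_geometric_mean_of_references(self):
        curves = _curves(["mir", "ref1", "ref2"])
        rows = [
            dict(sample="s1", tissue="egg", target="mir", cq=_cq_for(8)),
            dict(sample="s1", tissue="egg", target="ref1", cq=_cq_for(4)),
            dict(sample="s1", tissue="egg", target="ref2", cq=_cq_for(16)),
        ]
        out = quantify_normalize(pd.DataFrame(rows), curves, ["ref1", "ref2"])
        assert len(out) == 1
        assert out[0].normalized == pytest.approx(1.0, rel=1e-6)

    def test_equal_references_divide_exactly(self):
        curves = _curves(["mir", "ref1", "ref2"])
        rows = [
            dict(sample="s1", tissue="egg", target="mir", cq=_cq_for(6)),
            dict(sample="s1", tissue="egg", target="ref1", cq=_cq_for(3)),
            dict(sample="s1", tissue="egg", target="ref2", cq=_cq_for(3)),
        ]
        out = quantify_normalize(pd.DataFrame(rows), curves, ["ref1", "ref2"])
        assert out[0].normalized == pytest.approx(2.0, rel=1e-6)

    def test_reference_relabeling_symmetry(self):
        curves = _curves(["mir", "ref1", "ref2"])
        rows = [
            dict(sample="s1", tissue="egg", target="mir", cq=_cq_for(5)),
            dict(sample="s1", tissue="egg", target="ref1", cq=_cq_for(2)),
            dict(sample="s1", tissue="egg", target="ref2", cq=_cq_for(9)),
        ]
        a = quantify_normalize(pd.DataFrame(rows), curves, ["ref1", "ref2"])
        b = quantify_normalize(pd.DataFrame(rows), curves, ["ref2", "ref1"])
        assert a[0].normalized == pytest.approx(b[0].normalized)

    def test_missing_reference_excludes_sample(self):
        curves = _curves(["mir", "ref1", "ref2"])
        rows = [
            dict(sample="s1", tissue="egg", target="mir", cq=_cq_for(5)),
            dict(sample="s1", tissue="egg", target="ref1", cq=_cq_for(2)),
        ]
        assert quantify_normalize(pd.DataFrame(rows), curves, ["ref1", "ref2"]) == []

    def test_exactly_two_references_required(self):
        with pytest.raises(ValueError):
            quantify_normalize(pd.DataFrame(), _curves(["r"]), ["r"])


class TestFoldChanges:
    def test_lowest_group_is_the_calibrator(self):
        folds = fold_changes({"a": [2, 2], "b": [4, 4], "c": [8, 8]})
        assert folds == {"a": 1.0, "b": 2.0, "c": 4.0}

    def test_single_group_fold_one(self):
        assert fold_changes({"a": [3.0, 5.0]}) == {"a": 1.0}

    def test_exactly_one_group_at_unity(self, rng):
        groups = {f"g{k}": (rng.lognormal(0, 0.3, size=4) * (k + 1)).tolist()
                  for k in range(6)}
        folds = fold_changes(groups)
        assert sum(1 for v in folds.values() if v == 1.0) == 1
        assert min(folds.values()) == 1.0


class TestAnovaLetters:
    def test_identical_constants_share_one_letter(self):
        F, p, letters = anova_letters({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert math.isnan(F) and p == 1.0
        assert set(letters.values()) == {"a"}

    def test_planted_large_separation_gets_distinct_letters(self, rng):
        lo = rng.normal(0, 1, size=6)
        hi = rng.normal(10, 1, size=6)
        F, p, letters = anova_letters({"low": lo.tolist(), "high": hi.tolist()})
        assert p < 0.05
        assert set(letters["low"]).isdisjoint(set(letters["high"]))

    def test_f_statistic_matches_manual_sums_of_squares(self):
        groups = {"a": [1.0, 2.0, 3.0, 2.0], "b": [4.0, 5.0, 6.0, 5.0],
                  "c": [2.0, 3.0, 4.0, 3.0]}
        F, p, _ = anova_letters(groups)
        flat = [v for vs in groups.values() for v in vs]
        grand = sum(flat) / len(flat)
        ssb = sum(len(v) * (sum(v) / len(v) - grand) ** 2 for v in groups.values())
        ssw = sum((x - sum(v) / len(v)) ** 2 for v in groups.values() for x in v)
        manual_F = (ssb / 2) / (ssw / (len(flat) - 3))
        assert F == pytest.approx(manual_F)

    def test_intermediate_group_shares_letters_both_ways(self, rng):
        a = rng.normal(0, 1, size=8)
        b = rng.normal(1.2, 1, size=8)   # between a and c
        c = rng.normal(2.4, 1, size=8)
        _, _, letters = anova_letters(
            {"a": a.tolist(), "b": b.tolist(), "c": c.tolist()})
        # display consistency: every non-rejected pair shares a letter
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        flat = np.concatenate([a, b, c])
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = pairwise_tukeyhsd(flat, labels)
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        for (g1, g2), reject in zip(pairs, res.reject):
            share = bool(set(letters[g1]) & set(letters[g2]))
            assert share != bool(reject)


def _matrix(values_by_tissue):
    rows = []
    for tissue, vals in values_by_tissue.items():
        for k, v in enumerate(vals):
            rows.append(dict(gene=f"g{k}", tissue=tissue, value=float(v)))
    return pd.DataFrame(rows)


class TestKruskalWallis:
    def test_printed_three_group_example(self):
        ranked = rank_values(_matrix({"egg": [1, 2, 3], "liver": [4, 5, 6],
                                      "muscle": [7, 8, 9]}))
        H, p, mean_ranks = kw_test(ranked)
        assert H == pytest.approx(7.2)
        assert mean_ranks == {"egg": 2.0, "liver": 5.0, "muscle": 8.0}

    def test_identical_groups_give_zero(self):
        ranked = rank_values(_matrix({"a": [5, 5, 5], "b": [5, 5, 5]}))
        H, p, _ = kw_test(ranked)
        assert H == 0.0 and p == 1.0

    def test_matches_formula_reimplementation(self, rng):
        vals = {g: rng.normal(0, 1, size=5).tolist() for g in ("a", "b", "c")}
        ranked = rank_values(_matrix(vals))
        H, p, _ = kw_test(ranked)
        # independent textbook formula, no ties by construction
        from scipy.stats import rankdata

        flat = [v for vs in vals.values() for v in vs]
        r = rankdata(flat)
        n = len(flat)
        sizes = [5, 5, 5]
        start = 0
        h = 0.0
        for sz in sizes:
            h += (r[start:start + sz].sum()) ** 2 / sz
            start += sz
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        assert H == pytest.approx(h)

    def test_invariant_under_monotone_transform(self, rng):
        vals = {g: np.abs(rng.normal(2, 1, size=6)).tolist() for g in ("a", "b", "c")}
        h1, _, _ = kw_test(rank_values(_matrix(vals)))
        logged = {g: [math.log(v) for v in vs] for g, vs in vals.items()}
        h2, _, _ = kw_test(rank_values(_matrix(logged)))
        assert h1 == pytest.approx(h2)

    def test_gene_subset_selection(self):
        df = _matrix({"a": [1, 2, 10], "b": [3, 4, 20]})
        ranked = rank_values(df)
        H_all, _, _ = kw_test(ranked)
        H_sub, _, mean_ranks = kw_test(ranked, gene_subset=["g0", "g1"])
        assert H_sub != H_all
        assert set(mean_ranks) == {"a", "b"}
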