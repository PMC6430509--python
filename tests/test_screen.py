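"""ASV filtering, the clr-vs-residual-yield screen and the balance index."""

import numpy as np
import pandas as pd
import pytest

from sbipy.composition import impute_zeros
from sbipy.errors import EmptyTableError, SbiUndefinedError, UnknownFeatureError
from sbipy.screen import (
    compute_sbi,
    correlate_asvs,
    filter_features,
    select_significant,
    tally_by_phylum,
)


class TestFilter:
    def test_presence_boundary(self):
        # presence in columns: 4, 3, 2, 1, 0 samples
        counts = pd.DataFrame(
            {"a": [1, 1, 1, 1], "b": [1, 1, 1, 0], "c": [1, 1, 0, 0],
             "d": [1, 0, 0, 0], "e": [0, 0, 0, 0]},
            index=[f"s{i}" for i in range(4)])
        out = filter_features(counts, min_samples=2)
        assert list(out.columns) == ["a", "b", "c"]
        assert out.index.equals(counts.index)

    def test_total_mode(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [1, 0]}, index=["s1", "s2"])
        out = filter_features(counts, min_samples=2, mode="total")
        assert list(out.columns) == ["a"]

    def test_empty_result_raises(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]}, index=["s1", "s2"])
        with pytest.raises(EmptyTableError):
            filter_features(counts, min_samples=2)


class TestCorrelate:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.resid = pd.Series(rng.normal(size=30),
                               index=[f"s{i:02d}" for i in range(30)],
                               name="residual_yield")

    def test_identical_column_r_one(self):
        clr = pd.DataFrame({"a": self.resid, "b": -self.resid,
                            "c": np.random.default_rng(1).normal(size=30)},
                           index=self.resid.index)
        out = correlate_asvs(clr, self.resid)
        assert out.loc["a", "r"] == pytest.approx(1.0)
        assert out.loc["a", "p"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["a", "sign"] == "+"
        assert out.loc["b", "r"] == pytest.approx(-1.0)
        assert out.loc["b", "sign"] == "-"

    def test_constant_column_neutral_not_crash(self):
        clr = pd.DataFrame({"a": 1.0, "b": self.resid}, index=self.resid.index)
        out = correlate_asvs(clr, self.resid)
        assert out.loc["a", "sign"] == "neutral"
        assert np.isnan(out.loc["a", "r"])
        pos, neg = select_significant(out)
        assert "a" not in pos + neg

    def test_null_calibration(self):
        """Independent normal ASVs: about 5% reach p < 0.05."""
        rng = np.random.default_rng(123)
        n, m = 51, 2000
        clr = pd.DataFrame(rng.normal(size=(n, m)),
                           index=[f"s{i:02d}" for i in range(n)],
                           columns=[f"asv{j}" for j in range(m)])
        resid = pd.Series(rng.normal(size=n), index=clr.index)
        out = correlate_asvs(clr, resid)
        frac = np.mean(out["p"] < 0.05)
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_matches_scipy_pearson(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        clr = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"),
                           index=[f"s{i}" for i in range(25)])
        resid = pd.Series(rng.normal(size=25), index=clr.index)
        out = correlate_asvs(clr, resid)
        for col in clr:
            r, p = stats.pearsonr(clr[col], resid)
            assert out.loc[col, "r"] == pytest.approx(r, abs=1e-12)
            assert out.loc[col, "p"] == pytest.approx(p, abs=1e-12)

    def test_spearman_option(self):
        from scipy import stats
        rng = np.random.default_rng(6)
        clr = pd.DataFrame(rng.normal(size=(20, 2)), columns=list("ab"),
                           index=[f"s{i}" for i in range(20)])
        resid = pd.Series(rng.normal(size=20), index=clr.index)
        out = correlate_asvs(clr, resid, method="spearman")
        rho, _ = stats.spearmanr(clr["a"], resid)
        assert out.loc["a", "r"] == pytest.approx(rho, abs=1e-12)


class TestSelect:
    def test_all_nonsignificant_empty(self):
        corr = pd.DataFrame({"r": [0.1, -0.1], "p": [0.5, 0.9]}, index=["a", "b"])
        assert select_significant(corr) == ([], [])

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        corr = pd.DataFrame({"r": rng.uniform(-1, 1, 50),
                             "p": rng.uniform(0, 1, 50)},
                            index=[f"asv{j}" for j in range(50)])
        a = select_significant(corr)
        b = select_significant(corr.sample(frac=1, random_state=1))
        assert a == b

    def test_planted_recovery(self, default_dataset, default_result):
        """On the default survey the screen recovers >= 80% of each planted set
        with the planted sign for every recovered ASV."""
        truth = default_dataset.truth
        pos = set(default_result.sbi.positive_set)
        neg = set(default_result.sbi.negative_set)
        sens_pos = len(pos & set(truth.positive_asvs)) / len(truth.positive_asvs)
        sens_neg = len(neg & set(truth.negative_asvs)) / len(truth.negative_asvs)
        assert sens_pos >= 0.8 and sens_neg >= 0.8
        assert not pos & set(truth.negative_asvs)  # no sign flips
        assert not neg & set(truth.positive_asvs)


class TestSbi:
    def make_imputed(self):
        counts = pd.DataFrame({"a": [4, 2], "b": [1, 2], "c": [95, 96]},
                              index=["s1", "s2"])
        return impute_zeros(counts)

    def test_single_pair_hand_value(self):
        # sqrt(1/2) * ln(0.04/0.01)
        imp = self.make_imputed()
        res = compute_sbi(imp, ["a"], ["b"])
        assert res.sbi["s1"] == pytest.approx(0.9802581434685472, abs=1e-9)
        assert res.sbi["s2"] == pytest.approx(0.0, abs=1e-12)

    def test_unnormalized_variant(self):
        imp = self.make_imputed()
        res = compute_sbi(imp, ["a"], ["b"], normalized=False)
        assert res.sbi["s1"] == pytest.approx(np.log(4.0), abs=1e-9)

    def test_monotone_in_positive_counts(self):
        counts = pd.DataFrame({"a": [4, 8], "b": [1, 1], "c": [95, 91]},
                              index=["s1", "s2"])
        res = compute_sbi(impute_zeros(counts), ["a"], ["b"])
        assert res.sbi["s2"] > res.sbi["s1"]

    def test_empty_set_undefined(self):
        with pytest.raises(SbiUndefinedError):
            compute_sbi(self.make_imputed(), [], ["b"])

    def test_unknown_feature(self):
        with pytest.raises(UnknownFeatureError):
            compute_sbi(self.make_imputed(), ["zz"], ["b"])

    def test_depth_rescaling_invariance(self):
        """Multiplying every count by a constant leaves the SBI unchanged."""
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.poisson(5.0, size=(6, 10)),
                              index=[f"s{i}" for i in range(6)],
                              columns=[f"asv{j}" for j in range(10)])
        counts += 1  # keep support identical under rescaling
        a = compute_sbi(impute_zeros(counts), ["asv0", "asv1"], ["asv2"])
        b = compute_sbi(impute_zeros(counts * 7), ["asv0", "asv1"], ["asv2"])
        assert np.allclose(a.sbi, b.sbi, atol=1e-12)


class TestTally:
    def test_empty_sets(self):
        out = tally_by_phylum([], [], pd.Series(dtype=object))
        assert out.empty

    def test_counting_and_conservation(self):
        tax = pd.Series({"a1": "P", "a2": "P", "a3": "P", "b1": "Q"})
        out = tally_by_phylum(["a1", "a2", "a3"], ["b1", "zz"], tax)
        assert out.loc["P", "n_positive"] == 3
        assert out.loc["Q", "n_negative"] == 1
        assert out.loc["Unassigned", "n_negative"] == 1
        assert out["n_positive"].sum() == 3
        assert out["n_negative"].sum() == 2
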