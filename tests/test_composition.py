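"""Closure, clr, ilr balances and multiplicative zero replacement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sbipy.composition import (
    SOIL_PARTITION,
    BalanceNode,
    BalancePartition,
    close,
    clr_transform,
    ilr_all,
    ilr_balance,
    impute_zeros,
)
from sbipy.errors import (
    DegenerateCompositionError,
    EmptyFeatureError,
    EmptySampleError,
    InvalidPartitionError,
    UnknownPartError,
    ZeroOrNegativePartError,
)

positive_parts = st.lists(st.floats(0.01, 100.0), min_size=5, max_size=5)


class TestClose:
    def test_integer_ratios(self):
        assert np.allclose(close([1, 1, 2]), [0.25, 0.25, 0.5])

    def test_already_closed_unchanged(self):
        assert np.allclose(close([0.2, 0.3, 0.5]), [0.2, 0.3, 0.5])

    @pytest.mark.parametrize("bad", [[3, 0, 1], [1, -2, 1]])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ZeroOrNegativePartError):
            close(bad)

    def test_single_part_degenerate(self):
        with pytest.raises(DegenerateCompositionError):
            close([1.0])

    def test_names_and_order_preserved(self):
        out = close(pd.Series({"b": 2.0, "a": 1.0, "c": 1.0}))
        assert list(out.index) == ["b", "a", "c"]


class TestClr:
    def test_uniform_is_zero(self):
        assert np.allclose(clr_transform(close([1, 1, 1])), 0.0)

    def test_hand_value_1_2_4(self):
        # log of parts over geometric mean 2/7: (-ln2, 0, ln2)
        out = clr_transform(close([1, 2, 4]))
        assert np.allclose(out, [-0.6931471805599453, 0.0, 0.6931471805599453])

    @given(positive_parts)
    def test_zero_sum(self, values):
        assert abs(clr_transform(close(values)).sum()) < 1e-9

    @given(positive_parts)
    def test_scale_invariance(self, values):
        v = np.asarray(values)
        a = clr_transform(pd.Series(v, index=list("abcde")))
        b = clr_transform(pd.Series(7.3 * v, index=list("abcde")))
        assert np.allclose(a, b, atol=1e-10)


class TestIlrBalance:
    def test_equal_subsets_zero(self):
        node = BalanceNode(numerator=("Sand",), denominator=("Silt",))
        comp = close(pd.Series({"Silt": 0.25, "Sand": 0.25, "Clay": 0.5}))
        assert ilr_balance(comp, node) == pytest.approx(0.0, abs=1e-12)

    def test_one_vs_one_hand_value(self):
        # sqrt(1/2) * ln(0.50/0.25)
        node = BalanceNode(numerator=("Sand",), denominator=("Silt",))
        comp = pd.Series({"Silt": 0.25, "Sand": 0.50, "Clay": 0.25})
        assert ilr_balance(comp, node) == pytest.approx(0.4901290717342736, abs=1e-6)

    def test_one_vs_two_hand_value(self):
        # sqrt(2*1/3) * ln(gm(0.3, 0.5)/0.2), evaluated independently
        node = BalanceNode(numerator=("Silt", "Sand"), denominator=("Clay",))
        comp = pd.Series({"Clay": 0.2, "Silt": 0.3, "Sand": 0.5})
        expected = np.sqrt(2 / 3) * np.log(np.sqrt(0.3 * 0.5) / 0.2)
        assert expected == pytest.approx(0.5396045620834091, abs=1e-12)
        assert ilr_balance(comp, node) == pytest.approx(expected, abs=1e-6)

    def test_unknown_part(self):
        node = BalanceNode(numerator=("Quartz",), denominator=("Silt",))
        with pytest.raises(UnknownPartError):
            ilr_balance(close([1, 1, 2], parts=["Silt", "Sand", "Clay"]), node)

    def test_overlapping_subsets_rejected(self):
        with pytest.raises(InvalidPartitionError):
            BalanceNode(numerator=("Silt",), denominator=("Silt", "Sand"))

    @given(positive_parts, st.floats(1.05, 5.0))
    def test_sign_convention_monotone(self, values, factor):
        """Increasing a numerator part (pre-closure) strictly raises the balance."""
        node = SOIL_PARTITION.nodes[0]  # numerator (N, C)
        parts = list(SOIL_PARTITION.parts)
        base = pd.Series(values, index=parts)
        bumped = base.copy()
        bumped["N"] *= factor
        assert ilr_balance(bumped, node) > ilr_balance(base, node)


class TestPartition:
    def test_soil_partition_labels(self):
        assert SOIL_PARTITION.labels == [
            "[Clay, Silt, Sand | N, C]",
            "[Clay | Silt, Sand]",
            "[Silt | Sand]",
            "[N | C]",
        ]

    def test_wrong_node_count_rejected(self):
        with pytest.raises(InvalidPartitionError):
            BalancePartition(parts=("a", "b", "c"),
                             nodes=(BalanceNode(("a",), ("b",)),))

    def test_non_bifurcating_rejected(self):
        nodes = (
            BalanceNode(numerator=("a",), denominator=("b", "c")),
            BalanceNode(numerator=("a",), denominator=("b",)),  # not a subset split
        )
        with pytest.raises(InvalidPartitionError):
            BalancePartition(parts=("a", "b", "c"), nodes=nodes)


class TestIlrAll:
    def test_uniform_rows_all_zero(self):
        table = pd.DataFrame(np.full((3, 5), 0.2), columns=SOIL_PARTITION.parts)
        out = ilr_all(table, SOIL_PARTITION)
        assert out.shape == (3, 4)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_partition_must_cover_parts(self):
        table = pd.DataFrame(np.full((2, 4), 0.25), columns=list("abcd"))
        with pytest.raises(UnknownPartError):
            ilr_all(table, SOIL_PARTITION)

    def test_isometry_against_clr_distance(self):
        """A full SBP ilr basis is an isometry: ilr distances == clr distances."""
        rng = np.random.default_rng(42)
        table = close(pd.DataFrame(rng.uniform(0.05, 5.0, size=(100, 5)),
                                   columns=SOIL_PARTITION.parts))
        bal = ilr_all(table, SOIL_PARTITION).to_numpy()
        clr = clr_transform(table).to_numpy()

        def pdist(mat):
            diff = mat[:, None, :] - mat[None, :, :]
            return np.sqrt((diff**2).sum(-1))

        assert np.allclose(pdist(bal), pdist(clr), atol=1e-8)


class TestImputeZeros:
    def test_no_zeros_is_closure(self):
        counts = pd.DataFrame([[1, 1, 2], [3, 3, 6]], columns=list("abc"))
        out = impute_zeros(counts)
        assert np.allclose(out, [[0.25, 0.25, 0.5]] * 2)

    def test_replacement_below_min_nonzero(self):
        counts = pd.DataFrame([[0, 5, 10, 85], [2, 5, 10, 83]], columns=list("abcd"))
        out = impute_zeros(counts)
        min_nz = 5 / 100
        assert 0 < out.iloc[0, 0] < min_nz
        assert out.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_ratio_preservation(self):
        """Non-zero parts shrink by one common row factor."""
        counts = pd.DataFrame([[0, 2, 6, 12], [5, 5, 5, 5], [1, 0, 0, 9]],
                              columns=list("abcd"))
        out = impute_zeros(counts)
        props = counts.div(counts.sum(axis=1), axis=0)
        for i in counts.index:
            nz = counts.loc[i] > 0
            ratio = out.loc[i, nz] / props.loc[i, nz]
            assert np.allclose(ratio, ratio.iloc[0], atol=1e-9)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out.to_numpy() > 0).all()

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], columns=list("ab"))
        with pytest.raises(EmptySampleError):
            impute_zeros(counts)

    def test_all_zero_feature_rejected(self):
        counts = pd.DataFrame([[1, 0], [2, 0]], columns=list("ab"))
        with pytest.raises(EmptyFeatureError):
            impute_zeros(counts)
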