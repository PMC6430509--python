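"""Aitchison-geometry primitives: closure, clr, ilr balances, zero replacement.

Compositions are held as :class:`pandas.Series` (one sample) or
:class:`pandas.DataFrame` (samples x parts) of strictly positive proportions
that sum to one per row. Balances follow the sequential-binary-partition
convention: each internal node of a strictly bifurcating tree over the parts
defines one isometric log-ratio

    ilr = sqrt(r s / (r + s)) * ln( gm(numerator) / gm(denominator) )

with ``r`` and ``s`` the numerator and denominator subset sizes and ``gm``
the geometric mean. Labels read ``[denominator | numerator]``, so the balance
is positive when the numerator subset outweighs the denominator subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr

from .errors import (
    DegenerateCompositionError,
    EmptyFeatureError,
    EmptySampleError,
    InvalidPartitionError,
    UnknownPartError,
    ZeroOrNegativePartError,
)

__all__ = [
    "close",
    "clr_transform",
    "BalanceNode",
    "BalancePartition",
    "SOIL_PARTITION",
    "ilr_balance",
    "ilr_all",
    "impute_zeros",
]

CLOSURE_TOL = 1e-9


def _as_frame(values) -> tuple[pd.DataFrame, bool]:
    """Coerce a Series / 1-D array / DataFrame to a 2-D frame; remember shape."""
    if isinstance(values, pd.DataFrame):
        return values, False
    if isinstance(values, pd.Series):
        return values.to_frame().T, True
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        return pd.DataFrame(arr[None, :]), True
    return pd.DataFrame(arr), False


def close(values, parts=None):
    """Close a strictly positive vector (or table of rows) to unit sum.

    Parameters
    ----------
    values
        Positive reals; a sequence, Series, 2-D array or DataFrame.
    parts
        Optional part names when ``values`` carries none.

    Returns
    -------
    pandas.Series or pandas.DataFrame
        Proportions summing to 1 per row, names and order preserved.
    """
    frame, squeeze = _as_frame(values)
    if parts is not None:
        frame = frame.set_axis(list(parts), axis=1)
    if frame.shape[1] < 2:
        raise DegenerateCompositionError(
            f"need at least 2 parts, got {frame.shape[1]}"
        )
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].tolist()
        raise InvalidPartitionError(f"duplicate part names: {dupes}")
    arr = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ZeroOrNegativePartError("non-finite part value")
    if np.any(arr <= 0):
        i, j = np.argwhere(arr <= 0)[0]
        raise ZeroOrNegativePartError(
            f"part {frame.columns[j]!r} of row {frame.index[i]!r} is "
            f"{arr[i, j]!r}; parts must be strictly positive"
        )
    out = frame.div(frame.sum(axis=1), axis=0)
    return out.iloc[0] if squeeze else out


def _validated_log(frame: pd.DataFrame) -> np.ndarray:
    arr = frame.to_numpy(dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ZeroOrNegativePartError("composition has non-positive entries")
    return np.log(arr)


def clr_transform(comp):
    """Centered log-ratio: log of each part over the geometric mean of all parts.

    Accepts one composition (Series) or a table (DataFrame); rows need not be
    closed — clr is scale invariant. Output rows sum to zero.
    """
    frame, squeeze = _as_frame(comp)
    if frame.shape[1] < 2:
        raise DegenerateCompositionError("clr needs at least 2 parts")
    _validated_log(frame)  # validation; skbio clr does the arithmetic
    out = pd.DataFrame(
        _skbio_clr(frame.to_numpy(dtype=float)),
        index=frame.index,
        columns=frame.columns,
    )
    return out.iloc[0] if squeeze else out


@dataclass(frozen=True)
class BalanceNode:
    """One internal node of a sequential binary partition.

    ``numerator`` parts enter the geometric mean on top; the balance is
    positive when they dominate the ``denominator`` parts.
    """

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self):
        if not self.numerator or not self.denominator:
            raise InvalidPartitionError("balance node with an empty subset")
        if set(self.numerator) & set(self.denominator):
            overlap = sorted(set(self.numerator) & set(self.denominator))
            raise InvalidPartitionError(f"overlapping subsets: {overlap}")

    @property
    def label(self) -> str:
        return f"[{', '.join(self.denominator)} | {', '.join(self.numerator)}]"

    @property
    def parts(self) -> frozenset:
        return frozenset(self.numerator) | frozenset(self.denominator)


@dataclass(frozen=True)
class BalancePartition:
    """A strictly bifurcating tree over D named parts, as D-1 ordered nodes.

    The first node splits the full part set; every later node splits a subset
    introduced by an earlier node. Balances are addressed by label, never by
    position.
    """

    parts: tuple[str, ...]
    nodes: tuple[BalanceNode, ...] = field(default_factory=tuple)

    def __post_init__(self):
        parts = set(self.parts)
        if len(parts) != len(self.parts):
            raise InvalidPartitionError("duplicate part names")
        if len(self.nodes) != len(self.parts) - 1:
            raise InvalidPartitionError(
                f"{len(self.parts)} parts require {len(self.parts) - 1} nodes, "
                f"got {len(self.nodes)}"
            )
        for node in self.nodes:
            unknown = node.parts - parts
            if unknown:
                raise UnknownPartError(f"unknown parts {sorted(unknown)}")
        # Tree check: each node must consume an available subset and release
        # its two halves for deeper splits.
        available = {frozenset(parts)}
        for node in self.nodes:
            if node.parts not in available:
                raise InvalidPartitionError(
                    f"node {node.label} does not split an available subset "
                    f"(not strictly bifurcating, or nodes out of root-first order)"
                )
            available.remove(node.parts)
            for half in (node.numerator, node.denominator):
                if len(half) > 1:
                    available.add(frozenset(half))

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]


#: The soil partition used throughout: organic parts (N, C) against the
#: mineral texture triplet, then texture split coarse-ward, then N against C.
SOIL_PARTITION = BalancePartition(
    parts=("Clay", "Silt", "Sand", "N", "C"),
    nodes=(
        BalanceNode(numerator=("N", "C"), denominator=("Clay", "Silt", "Sand")),
        BalanceNode(numerator=("Silt", "Sand"), denominator=("Clay",)),
        BalanceNode(numerator=("Sand",), denominator=("Silt",)),
        BalanceNode(numerator=("C",), denominator=("N",)),
    ),
)


def _node_balance(logmat: np.ndarray, cols: pd.Index, node: BalanceNode) -> np.ndarray:
    missing = node.parts - set(cols)
    if missing:
        raise UnknownPartError(f"parts {sorted(missing)} not in composition")
    num_idx = [cols.get_loc(p) for p in node.numerator]
    den_idx = [cols.get_loc(p) for p in node.denominator]
    r, s = len(num_idx), len(den_idx)
    coef = math.sqrt(r * s / (r + s))
    # geometric means in log space: mean of logs, stable for long part lists
    return coef * (logmat[:, num_idx].mean(axis=1) - logmat[:, den_idx].mean(axis=1))


def ilr_balance(comp, node: BalanceNode):
    """Evaluate one ilr balance for a composition (or one value per table row)."""
    frame, squeeze = _as_frame(comp)
    vals = _node_balance(_validated_log(frame), frame.columns, node)
    return float(vals[0]) if squeeze else pd.Series(vals, index=frame.index, name=node.label)


def ilr_all(table, partition: BalancePartition) -> pd.DataFrame:
    """All D-1 balances of a partition for every row of a composition table.

    Columns are named by node labels; the partition must cover exactly the
    table's parts.
    """
    frame, _ = _as_frame(table)
    if set(frame.columns) != set(partition.parts):
        raise UnknownPartError(
            f"partition parts {sorted(partition.parts)} do not match table parts "
            f"{sorted(frame.columns)}"
        )
    logmat = _validated_log(frame)
    data = {
        node.label: _node_balance(logmat, frame.columns, node)
        for node in partition.nodes
    }
    return pd.DataFrame(data, index=frame.index)


def impute_zeros(counts: pd.DataFrame, delta_fraction: float = 0.65) -> pd.DataFrame:
    """Multiplicative replacement of count zeros (CZM-style), then closure.

    Each zero cell in a sample becomes ``delta_fraction`` times that sample's
    smallest non-zero proportion; the non-zero parts are shrunk by a common
    row factor so the row re-closes to 1, preserving their mutual ratios.

    Parameters
    ----------
    counts
        samples x features non-negative counts.
    delta_fraction
        Fraction of the per-row minimum non-zero proportion used as the
        replacement value; must lie in (0, 1) so the replacement stays below
        every observed proportion.
    """
    if not 0 < delta_fraction < 1:
        raise ValueError("delta_fraction must be in (0, 1)")
    arr = counts.to_numpy(dtype=float)
    if arr.size == 0:
        raise EmptySampleError("empty count table")
    if np.any(arr < 0):
        raise ZeroOrNegativePartError("negative counts")
    row_tot = arr.sum(axis=1)
    if np.any(row_tot == 0):
        bad = counts.index[np.argwhere(row_tot == 0)[0][0]]
        raise EmptySampleError(f"sample {bad!r} has zero total count")
    col_tot = arr.sum(axis=0)
    if np.any(col_tot == 0):
        bad = counts.columns[np.argwhere(col_tot == 0)[0][0]]
        raise EmptyFeatureError(f"feature {bad!r} is zero in every sample")

    props = arr / row_tot[:, None]
    zero = props == 0
    min_nz = np.where(zero, np.inf, props).min(axis=1)
    delta = delta_fraction * min_nz  # per-row replacement value
    n_zero = zero.sum(axis=1)
    shrink = 1.0 - n_zero * delta  # mass left for the observed parts
    out = props * shrink[:, None]
    out[zero] = np.broadcast_to(delta[:, None], out.shape)[zero]
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
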