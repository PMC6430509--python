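"""Supervised ASV screen and the species balance index (SBI).

The screen correlates each ASV's clr abundance with residual yield, keeps the
ASVs significant at a raw two-sided level (no multiplicity correction — the
selection is deliberately liberal and in-sample), and builds a single balance

    SBI = sqrt(r s / (r + s)) * ln( gm(positive set) / gm(negative set) )

per sample from the zero-imputed proportions, where the positive/negative
sets are the ASVs whose clr correlates positively/negatively with residual
yield. By construction the index correlates strongly with residual yield in
the sample it was selected on; it is a descriptive index, not an out-of-sample
predictor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyTableError, SbiUndefinedError, UnknownFeatureError

__all__ = [
    "filter_features",
    "correlate_asvs",
    "select_significant",
    "compute_sbi",
    "tally_by_phylum",
    "SbiResult",
]

logger = logging.getLogger(__name__)


def filter_features(table: pd.DataFrame, min_samples: int = 2,
                    mode: str = "presence") -> pd.DataFrame:
    """Keep ASVs observed in at least ``min_samples`` samples (contingency filter).

    ``mode="presence"`` (default) counts samples with a non-zero count;
    ``mode="total"`` instead requires the summed count to reach ``min_samples``.
    The sample set is never changed.
    """
    if mode == "presence":
        keep = (table > 0).sum(axis=0) >= min_samples
    elif mode == "total":
        keep = table.sum(axis=0) >= min_samples
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out = table.loc[:, keep]
    if out.shape[1] == 0:
        raise EmptyTableError("no ASVs survive the contingency filter")
    return out


def correlate_asvs(clr_table: pd.DataFrame, residual_yield: pd.Series,
                   alpha: float = 0.05, method: str = "pearson") -> pd.DataFrame:
    """Correlate each clr-ASV with residual yield.

    Returns a frame indexed by asv_id with columns ``r``, ``p`` and ``sign``
    ('+'/'-' when p < alpha, 'neutral' otherwise). Pearson p-values come from
    the t statistic r*sqrt((n-2)/(1-r^2)) with n-2 df; Spearman is available
    as an alternative. Constant clr columns are flagged neutral with r = NaN
    rather than raising.
    """
    if not clr_table.index.equals(residual_yield.index):
        raise ValueError("clr table and residual yield have mismatched samples")
    n = clr_table.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for the correlation screen")

    if method == "spearman":
        X = clr_table.rank(axis=0).to_numpy(dtype=float)
        y = residual_yield.rank().to_numpy(dtype=float)
    elif method == "pearson":
        X = clr_table.to_numpy(dtype=float)
        y = residual_yield.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0, ddof=1)
    sy = yc.std(ddof=1)
    constant = sx == 0
    if constant.any():
        logger.warning("%d constant clr columns excluded from selection",
                       int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / ((n - 1) * sx * sy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    r[constant] = np.nan
    p[constant] = np.nan

    sign = np.full(clr_table.shape[1], "neutral", dtype=object)
    sig = ~constant & (p < alpha)
    sign[sig & (r > 0)] = "+"
    sign[sig & (r < 0)] = "-"
    return pd.DataFrame({"r": r, "p": p, "sign": sign},
                        index=clr_table.columns.rename("asv_id"))


def select_significant(correlations: pd.DataFrame,
                       alpha: float = 0.05) -> tuple[list, list]:
    """Split ASVs with raw two-sided p < alpha by correlation sign.

    Returns sorted (positive_set, negative_set) id lists; either may be empty
    (downstream SBI computation then raises).
    """
    ok = correlations["p"].notna() & (correlations["p"] < alpha)
    pos = sorted(correlations.index[ok & (correlations["r"] > 0)])
    neg = sorted(correlations.index[ok & (correlations["r"] < 0)])
    return pos, neg


@dataclass(frozen=True)
class SbiResult:
    """Selected ASV sets and the per-sample species balance index values."""

    positive_set: tuple
    negative_set: tuple
    sbi: pd.Series


def compute_sbi(imputed: pd.DataFrame, positive_set, negative_set,
                normalized: bool = True) -> SbiResult:
    """Per-sample SBI from zero-imputed proportions and the two selected sets.

    ``normalized=True`` (default) applies the orthonormal balance coefficient
    sqrt(r s/(r+s)); the plain ln(gm+/gm-) variant is a monotone rescaling of
    the same index.
    """
    pos = sorted(positive_set)
    neg = sorted(negative_set)
    if not pos or not neg:
        raise SbiUndefinedError(
            "SBI undefined: positive and negative sets must both be non-empty "
            f"(got {len(pos)} positive, {len(neg)} negative)"
        )
    if set(pos) & set(neg):
        raise ValueError("positive and negative sets overlap")
    missing = (set(pos) | set(neg)) - set(imputed.columns)
    if missing:
        raise UnknownFeatureError(f"ASVs not in table: {sorted(missing)[:5]} ...")
    logp = np.log(imputed[pos].to_numpy(dtype=float))
    logn = np.log(imputed[neg].to_numpy(dtype=float))
    r, s = len(pos), len(neg)
    coef = math.sqrt(r * s / (r + s)) if normalized else 1.0
    vals = coef * (logp.mean(axis=1) - logn.mean(axis=1))
    return SbiResult(
        positive_set=tuple(pos),
        negative_set=tuple(neg),
        sbi=pd.Series(vals, index=imputed.index, name="sbi_py"),
    )


def tally_by_phylum(positive_set, negative_set,
                    taxonomy: pd.Series | dict) -> pd.DataFrame:
    """Signed per-phylum counts of selected ASVs (missing taxonomy -> Unassigned)."""
    tax = pd.Series(taxonomy) if not isinstance(taxonomy, pd.Series) else taxonomy
    rows: dict[str, dict[str, int]] = {}
    for ids, col in ((positive_set, "n_positive"), (negative_set, "n_negative")):
        for asv in ids:
            phylum = tax.get(asv, "Unassigned")
            if pd.isna(phylum):
                phylum = "Unassigned"
            rows.setdefault(phylum, {"n_positive": 0, "n_negative": 0})[col] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if out.empty:
        out = pd.DataFrame(columns=["n_positive", "n_negative"], dtype=int)
    out.index.name = "phylum"
    return out.sort_index()
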