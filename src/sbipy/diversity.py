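"""Alpha-diversity indices: Shannon entropy, Pielou evenness, Chao1 richness.

Shannon and Pielou delegate to scikit-bio (natural log, for consistency with
the clr/ilr machinery). Chao1 uses the classic estimator S_obs + F1^2/(2 F2)
when doubletons exist and the bias-corrected form S_obs + F1(F1-1)/(2(F2+1))
when F2 = 0, computed on raw (unrarefied) counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.diversity.alpha import pielou_e as _skbio_pielou
from skbio.diversity.alpha import shannon as _skbio_shannon

from .errors import EmptySampleError, UndefinedIndexError

__all__ = ["shannon", "pielou", "chao1", "diversity_profile", "correlate_indices"]


def _clean(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative counts")
    if arr.sum() == 0:
        raise EmptySampleError("all-zero sample")
    return arr


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over non-zero proportions, in nats."""
    return float(_skbio_shannon(_clean(counts), base=np.e))


def pielou(counts) -> float:
    """Pielou evenness J = H / ln(S); requires at least 2 observed species."""
    arr = _clean(counts)
    if np.count_nonzero(arr) < 2:
        raise UndefinedIndexError("Pielou evenness undefined for fewer than 2 species")
    return float(_skbio_pielou(arr, base=np.e))


def chao1(counts) -> float:
    """Chao1 estimated richness from singleton (F1) and doubleton (F2) counts."""
    arr = _clean(counts)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("Chao1 requires integer counts")
    s_obs = int(np.count_nonzero(arr))
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0  # bias-corrected branch, F2 = 0


def diversity_profile(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity table (columns shannon, pielou, chao1)."""
    rows = {
        sid: {
            "shannon": shannon(row.to_numpy()),
            "pielou": pielou(row.to_numpy()),
            "chao1": chao1(row.to_numpy()),
        }
        for sid, row in counts.iterrows()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = counts.index.name or "sample_id"
    return out


def correlate_indices(
    profiles: pd.DataFrame,
    sbi: pd.Series,
    yield_tha: pd.Series,
    residual_yield: pd.Series,
) -> pd.DataFrame:
    """Pearson r of each diversity index (and the SBI) vs yield and residual yield.

    All inputs must share the same sample index. Returns indices as rows and
    the two responses as columns.
    """
    indices = profiles.copy()
    if not sbi.index.equals(indices.index):
        raise ValueError("misaligned sample ids between SBI and diversity profiles")
    indices["sbi_py"] = sbi
    responses = pd.DataFrame({"yield": yield_tha, "residual_yield": residual_yield})
    if not indices.index.equals(responses.index):
        raise ValueError("misaligned sample ids between indices and responses")
    corr = {
        col: {resp: float(indices[col].corr(responses[resp])) for resp in responses}
        for col in indices
    }
    out = pd.DataFrame.from_dict(corr, orient="index")
    out.index.name = "index"
    return out
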