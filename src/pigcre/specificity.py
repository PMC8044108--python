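"""Tissue-specificity machinery.

Quantile normalization (rank-mean, ties averaged), the Z-score 3-fold rule
for tissue-specific genes with its sign casework, the Tau index, and the
quantile-normalized-change rule for tissue-specific enhancers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError

SIGN_EPS = 1e-9  # |Z| below this joins the mixed-sign branch of the fold rule


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization.

    After normalization every column holds the same multiset of values: the
    cross-column mean of order statistics. Tied values within a column
    receive the mean of the tied quantile values (average ranks).
    """
    if matrix.shape[1] < 2:
        raise InputError("quantile normalization needs >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).all(axis=0).any():
        raise InputError("column with all-missing values")
    ref = np.sort(x, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        sv = x[order, j]
        i = 0
        while i < n:  # runs of tied values share the mean reference value
            h = i
            while h + 1 < n and sv[h + 1] == sv[i]:
                h += 1
            out[order[i:h + 1], j] = ref[i:h + 1].mean()
            i = h + 1
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def average_replicates(matrix: pd.DataFrame, groups: pd.Series | dict) -> pd.DataFrame:
    """Average columns sharing a group label (e.g. (tissue, breed))."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise InputError("every column needs a replicate group label")
    return matrix.T.groupby(groups.values).mean().T


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z scores ((x - mean) / sd, sample sd), as R's scale() on rows."""
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.nan
    return pd.DataFrame((x - mu) / sd, index=matrix.index, columns=matrix.columns)


def fold_rule_passes(a: float, b: float, fold: float = 3.0) -> bool:
    """The 3-fold comparison of Z values with sign casework.

    ``a`` is the value in the candidate tissue, ``b`` in another tissue.
    Both positive: require a/b >= fold. Mixed signs (or either value within
    SIGN_EPS of zero): the fold is deemed +fold when a > b and -fold
    otherwise, so the comparison passes iff a > b. Both negative: use the
    reciprocal of a/b and require it >= fold.
    """
    if abs(a) < SIGN_EPS or abs(b) < SIGN_EPS or (a > 0) != (b > 0):
        return a > b
    if a > 0 and b > 0:
        return a / b >= fold
    return b / a >= fold  # both negative: reciprocal of the ratio


def zscore_specific_genes(tpm: pd.DataFrame, sample_tissue: pd.Series,
                          sample_group: pd.Series, min_tpm: float = 1.0,
                          fold: float = 3.0) -> pd.DataFrame:
    """Tissue-specific genes by the Z-score 3-fold rule.

    Pipeline: drop genes with TPM < min_tpm in every sample, quantile
    normalize, average replicates into (tissue, breed) groups, Z-score each
    gene row, then assign a gene to tissue T iff the fold rule passes for
    every T column against every column of every other tissue.

    ``sample_tissue`` maps each column to its tissue; ``sample_group`` maps
    each column to its replicate-averaging group (e.g. "tissue|breed").
    Returns a two-column frame (gene_id, tissue).
    """
    tissues = sorted(sample_tissue.unique())
    if len(tissues) < 2:
        raise InputError("tissue-specificity undefined for a single-tissue design")
    expressed = (tpm >= min_tpm).any(axis=1)
    qn = quantile_normalize(tpm.loc[expressed])
    avg = average_replicates(qn, sample_group)
    # tissue of each averaged column
    group_tissue = {}
    for col, t, g in zip(tpm.columns, sample_tissue.reindex(tpm.columns),
                         sample_group.reindex(tpm.columns)):
        group_tissue[g] = t
    z = zscore_rows(avg)
    cols_by_tissue = {
        t: [c for c in avg.columns if group_tissue[c] == t] for t in tissues
    }
    out = []
    zv = z.to_numpy()
    col_idx = {c: i for i, c in enumerate(avg.columns)}
    for gi, gene in enumerate(z.index):
        row = zv[gi]
        if np.isnan(row).any():
            continue
        for t in tissues:
            own = [col_idx[c] for c in cols_by_tissue[t]]
            others = [col_idx[c] for tt in tissues if tt != t
                      for c in cols_by_tissue[tt]]
            if all(fold_rule_passes(row[i], row[j], fold)
                   for i in own for j in others):
                out.append((gene, t))
    return pd.DataFrame(out, columns=["gene_id", "tissue"])


def tau_index(values) -> float:
    """Tau tissue-specificity index over per-tissue means.

    tau = sum(1 - x_i / max(x)) / (n - 1); 0 for uniform expression, 1 for
    single-tissue expression. All-zero rows are undefined (NaN).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise InputError("tau needs >= 2 tissues")
    if (x < 0).any():
        raise InputError("tau requires non-negative values")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def tissue_specific_enhancers(qn_changes: pd.DataFrame, col_tissue: pd.Series,
                              col_breed: pd.Series, high: float = 1.0,
                              low: float = 0.5) -> pd.DataFrame:
    """Tissue-specific enhancers from quantile-normalized coverage changes.

    An enhancer is specific to tissue T iff its value is > high in T for
    every breed present AND < low in every column of every other tissue
    (both strict). Tissues observed in only one breed are flagged.
    Returns (element_id, tissue, single_breed).
    """
    col_tissue = col_tissue.reindex(qn_changes.columns)
    col_breed = col_breed.reindex(qn_changes.columns)
    tissues = sorted(col_tissue.unique())
    single_breed = {
        t: col_breed[col_tissue == t].nunique() < 2 for t in tissues
    }
    for t, flag in single_breed.items():
        if flag:
            warnings.warn(f"tissue {t} present in a single breed; calls flagged")
    out = []
    x = qn_changes.to_numpy(dtype=float)
    for t in tissues:
        own = (col_tissue == t).to_numpy()
        other = ~own
        hit = (x[:, own] > high).all(axis=1) & (x[:, other] < low).all(axis=1)
        for elem in qn_changes.index[hit]:
            out.append((elem, t, single_breed[t]))
    return pd.DataFrame(out, columns=["element_id", "tissue", "single_breed"])
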