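"""1D structure from Hi-C contact matrices.

Insulation scores with iqrMean window aggregation and delta-based boundary
calls (crane-style, windows -is 480 kb, -ids 320 kb, smoothing span
-ss 160 kb at 40 kb bins), the directionality index, and A/B compartments
from the leading eigenvector of the distance-normalized correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError


def _check_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError("contact matrix must be square")
    if (m < 0).any():
        raise InputError("contact matrix must be non-negative")
    return m


def iqr_mean(values: np.ndarray) -> float:
    """Mean of values lying within the interquartile range [Q1, Q3]."""
    v = np.asarray(values, dtype=float).ravel()
    q1, q3 = np.percentile(v, [25, 75])
    inside = v[(v >= q1) & (v <= q3)]
    return float(inside.mean()) if inside.size else float(v.mean())


@dataclass
class InsulationProfile:
    insulation: np.ndarray   # log2 ratio to chromosomal mean (NaN near edges)
    smoothed: np.ndarray
    delta: np.ndarray
    bin_size: int


def insulation_score(m: np.ndarray, bin_size: int, window: int = 480_000,
                     delta_span: int = 320_000, smooth_span: int = 160_000,
                     mode: str = "iqrMean") -> InsulationProfile:
    """Per-bin insulation from the off-diagonal square window.

    For each bin b, contacts in the square spanning rows (b-w .. b-1) and
    columns (b+1 .. b+w) are aggregated (iqrMean by default) and log2-scaled
    against the chromosomal mean of aggregates. The profile is smoothed by a
    centered running mean of span ``smooth_span`` and the delta at b is the
    mean of the smoothed profile over the ``delta_span`` to the left minus
    the mean over the span to the right. Bins within w of an edge are
    undefined (NaN), never extrapolated.
    """
    m = _check_matrix(m)
    for name, span in (("window", window), ("delta_span", delta_span),
                       ("smooth_span", smooth_span)):
        if span % bin_size != 0:
            raise InputError(f"{name} {span} is not a multiple of bin size {bin_size}")
    n = m.shape[0]
    w = window // bin_size
    agg = np.full(n, np.nan)
    aggregate = iqr_mean if mode == "iqrMean" else (
        lambda v: float(np.mean(v)) if mode == "mean" else None)
    if aggregate is None:
        raise InputError(f"unknown aggregation mode {mode!r}")
    for b in range(w, n - w):
        block = m[b - w:b, b + 1:b + 1 + w]
        agg[b] = aggregate(block)
    valid = ~np.isnan(agg)
    chrom_mean = np.nanmean(agg) if valid.any() else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ins = np.where(valid & (agg > 0) & (chrom_mean > 0),
                       np.log2(agg / chrom_mean), np.nan)

    # centered running mean over the smoothing span
    h = max(1, smooth_span // bin_size // 2)
    smoothed = np.full(n, np.nan)
    for b in range(n):
        lo, hi = max(0, b - h), min(n, b + h + 1)
        seg = ins[lo:hi]
        if np.isnan(seg).any() or len(seg) == 0:
            continue
        smoothed[b] = seg.mean()

    d = delta_span // bin_size
    delta = np.full(n, np.nan)
    for b in range(n):
        left = smoothed[max(0, b - d):b]
        right = smoothed[b + 1:b + 1 + d]
        if (len(left) < d or len(right) < d
                or np.isnan(left).any() or np.isnan(right).any()):
            continue
        delta[b] = left.mean() - right.mean()
    return InsulationProfile(insulation=ins, smoothed=smoothed, delta=delta,
                             bin_size=bin_size)


@dataclass
class TADSet:
    boundaries: list          # bin indices, strictly increasing
    strengths: list
    tads: pd.DataFrame        # start_bin, end_bin (half-open, tiling)
    chrom: str = "."

    @property
    def n_boundaries(self) -> int:
        return len(self.boundaries)


def call_boundaries(profile: InsulationProfile, strength_min: float = 0.1,
                    chrom: str = ".") -> TADSet:
    """TAD boundaries at positive-to-negative delta zero-crossings.

    Boundary strength is the difference between the nearest delta local
    maximum left of the crossing and the nearest local minimum right of it;
    crossings below ``strength_min`` are dropped. TADs tile the span between
    consecutive boundaries (and the profile edges).
    """
    delta = profile.delta
    n = len(delta)
    valid = np.nonzero(~np.isnan(delta))[0]
    boundaries, strengths = [], []
    if len(valid) >= 2:
        for k in range(len(valid) - 1):
            i, j = valid[k], valid[k + 1]
            if not (delta[i] > 0 and delta[j] <= 0):
                continue
            # local max scanning left while delta increases, min scanning right
            li = i
            while li - 1 in valid and delta[li - 1] >= delta[li]:
                li -= 1
            rj = j
            while rj + 1 in valid and delta[rj + 1] <= delta[rj]:
                rj += 1
            strength = float(delta[li] - delta[rj])
            if strength >= strength_min:
                # boundary at the bin whose delta is closer to zero
                b = i if abs(delta[i]) <= abs(delta[j]) else j
                boundaries.append(int(b))
                strengths.append(strength)
    if not boundaries:
        warnings.warn("no boundaries found; whole chromosome is one TAD")
        tads = pd.DataFrame({"start_bin": [0], "end_bin": [n]})
        return TADSet(boundaries=[], strengths=[], tads=tads, chrom=chrom)
    edges = [0] + boundaries + [n]
    tads = pd.DataFrame({"start_bin": edges[:-1], "end_bin": edges[1:]})
    return TADSet(boundaries=boundaries, strengths=strengths, tads=tads, chrom=chrom)


def directionality_index(m: np.ndarray, bin_size: int,
                         window: int = 2_000_000) -> np.ndarray:
    """Signed chi-square-like statistic of upstream vs downstream contact bias.

    A (B) is the sum of contacts from a bin to the ``window`` bp upstream
    (downstream); E = (A+B)/2 and DI = sign(B-A) * ((A-E)^2 + (B-E)^2) / E,
    0 when A = B or A + B = 0.
    """
    m = _check_matrix(m)
    if window % bin_size != 0:
        raise InputError("window must be a multiple of bin size")
    n = m.shape[0]
    k = window // bin_size
    di = np.zeros(n)
    for b in range(n):
        a = float(m[b, max(0, b - k):b].sum())
        bb = float(m[b, b + 1:min(n, b + 1 + k)].sum())
        if a + bb == 0 or a == bb:
            continue
        e = (a + bb) / 2.0
        di[b] = np.sign(bb - a) * ((a - e) ** 2 / e + (bb - e) ** 2 / e)
    return di


@dataclass
class CompartmentResult:
    eigenvector: np.ndarray   # per-bin coordinate (NaN at dropped bins)
    labels: np.ndarray        # 'A', 'B' or '' at dropped bins
    degenerate: bool


def observed_over_expected(m: np.ndarray, pseudocount: float = 1e-9) -> np.ndarray:
    """Divide each diagonal by its mean contact."""
    m = _check_matrix(m)
    n = m.shape[0]
    oe = np.zeros_like(m)
    for d in range(n):
        idx = np.arange(n - d)
        vals = m[idx, idx + d]
        mean = vals.mean()
        oe[idx, idx + d] = vals / (mean + pseudocount)
        oe[idx + d, idx] = oe[idx, idx + d]
    return oe


def ab_compartments(m: np.ndarray, activity: np.ndarray) -> CompartmentResult:
    """A/B compartments from the leading eigenvector of the correlation of
    the distance-normalized matrix, sign-oriented by the activity track
    (bins with higher mean activity are 'A')."""
    m = _check_matrix(m)
    n = m.shape[0]
    activity = np.asarray(activity, dtype=float)
    if len(activity) != n:
        raise InputError("activity track length mismatch")
    if n < 10:
        raise InputError("need >= 10 usable bins")
    oe = observed_over_expected(m)
    keep = oe.std(axis=1) > 0
    if keep.sum() < n / 2:
        raise InputError("more than half of the bins are zero-variance")
    sub = oe[np.ix_(keep, keep)]
    corr = np.corrcoef(sub)
    vals, vecs = np.linalg.eigh(corr)
    ev = vecs[:, -1]
    full = np.full(n, np.nan)
    full[keep] = ev
    labels = np.array([""] * n, dtype=object)
    pos = full > 0
    neg = full < 0
    degenerate = not (pos.any() and neg.any())
    if degenerate:
        warnings.warn("no stable sign structure; compartments degenerate")
        labels[keep] = "A"
        return CompartmentResult(eigenvector=full, labels=labels, degenerate=True)
    if np.nanmean(activity[pos]) < np.nanmean(activity[neg]):
        full = -full
        pos, neg = neg, pos
    labels[pos] = "A"
    labels[neg] = "B"
    return CompartmentResult(eigenvector=full, labels=labels, degenerate=False)
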