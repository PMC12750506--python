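"""Paired-difference agreement statistics and stride matching.

Implements the Bland–Altman style battery used to compare two measurement
conditions (estimated vs fixed groundline, handheld vs stationary camera):
mean signed difference, 95% limits of agreement (mean ± 1.96 SD), mean
absolute error (MAE), and a normal-approximation confidence interval for
the MAE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .strides import StrideRecord

__all__ = ["PairedDiffs", "AgreementStats", "agreement", "bland_altman",
           "match_strides"]


@dataclass
class PairedDiffs:
    """A vector of signed paired differences (condition A minus B)."""

    diffs: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    metric: str = ""

    def __post_init__(self):
        self.diffs = np.asarray(self.diffs, dtype=float)
        if not np.isfinite(self.diffs).all():
            raise ValueError("paired differences must be finite")

    @property
    def n(self) -> int:
        return len(self.diffs)


@dataclass
class AgreementStats:
    """Summary of a paired-difference vector.

    loa_low/high = mean ± 1.96 SD (95% limits of agreement);
    mae_ci_low/high = MAE ± z(ci_level) * SD(|d|) / sqrt(n).
    """

    n: int
    mean_signed: float
    sd: float
    loa_low: float
    loa_high: float
    mae: float
    mae_ci_low: float
    mae_ci_high: float
    ci_level: float = 0.99

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "mean_signed", "sd", "loa_low", "loa_high",
            "mae", "mae_ci_low", "mae_ci_high", "ci_level")}


def agreement(diffs: PairedDiffs | np.ndarray,
              ci_level: float = 0.99) -> AgreementStats:
    """Agreement statistics of a signed difference vector (n >= 2).

    Sample SD uses n-1; LoA use the conventional 1.96 multiplier; the MAE
    confidence interval uses the normal approximation on |d| at
    ``ci_level`` (z = 2.576 at 99%, 1.96 at 95%), which is essentially
    exact at the large n these pipelines pool.
    """
    d = diffs.diffs if isinstance(diffs, PairedDiffs) else np.asarray(diffs, float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need a 1-D difference vector with n >= 2")
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    absd = np.abs(d)
    mae = float(np.mean(absd))
    z = float(_stats.norm.ppf(0.5 + ci_level / 2.0))
    half = z * float(np.std(absd, ddof=1)) / np.sqrt(n)
    return AgreementStats(
        n=n, mean_signed=mean, sd=sd,
        loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
        mae=mae, mae_ci_low=mae - half, mae_ci_high=mae + half,
        ci_level=ci_level)


def bland_altman(a_vals, b_vals, ci_level: float = 0.99,
                 plot_range: tuple[float, float] | None = None):
    """Bland–Altman table of (pair mean, pair difference a - b) plus stats.

    Returns (table, stats, outliers): the table is a DataFrame with columns
    ``mean`` and ``diff``; ``outliers`` lists (mean, diff) rows whose
    difference falls outside ``plot_range`` (reported separately, the way a
    plot caption would note points beyond its axes), or None when no range
    is given.
    """
    a = np.asarray(a_vals, dtype=float)
    b = np.asarray(b_vals, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    table = pd.DataFrame({"mean": (a + b) / 2.0, "diff": a - b})
    stats = agreement(table["diff"].to_numpy(), ci_level=ci_level)
    outliers = None
    if plot_range is not None:
        lo, hi = plot_range
        mask = (table["diff"] < lo) | (table["diff"] > hi)
        outliers = table[mask]
    return table, stats, outliers


def match_strides(a: list[StrideRecord], b: list[StrideRecord],
                  sync_offset: int = 0,
                  min_overlap_frac: float = 0.5) -> list[tuple[int, int]]:
    """Pair strides from two synchronized recordings by temporal overlap.

    ``b``'s frames are shifted by ``sync_offset`` onto ``a``'s clock.
    Pairs are formed greedily by decreasing overlap (ties favour earlier
    strides); each stride is used at most once, and pairs overlapping less
    than ``min_overlap_frac`` of the shorter stride are dropped.  Returns
    index pairs (i_a, i_b).
    """
    if not a or not b:
        return []
    a_iv = np.array([[s.start, s.end] for s in a], dtype=float)
    b_iv = np.array([[s.start + sync_offset, s.end + sync_offset] for s in b],
                    dtype=float)
    lo = np.maximum(a_iv[:, None, 0], b_iv[None, :, 0])
    hi = np.minimum(a_iv[:, None, 1], b_iv[None, :, 1])
    overlap = np.clip(hi - lo, 0.0, None)
    shorter = np.minimum((a_iv[:, 1] - a_iv[:, 0])[:, None],
                         (b_iv[:, 1] - b_iv[:, 0])[None, :])
    ii, jj = np.nonzero(overlap >= min_overlap_frac * shorter)
    order = sorted(range(len(ii)),
                   key=lambda k: (-overlap[ii[k], jj[k]], ii[k], jj[k]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs
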