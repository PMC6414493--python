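"""SNP selection for polygenic scores: greedy LD clumping that keeps the
most significant variant of each correlated group, then P-value
thresholding.

The pipeline prunes the full summary-statistics set once (r² ≤ 0.1 within
a 1000 kb window by default) and applies the threshold grid
{5e-8, 1e-5, 1e-3, 0.05, 0.1, 0.5} to the pruned set, so selections at
successive thresholds are nested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_THRESHOLDS", "SelectionConfig", "ld_r2", "prune",
           "select_by_threshold"]

DEFAULT_THRESHOLDS = (5e-8, 1e-5, 1e-3, 0.05, 0.1, 0.5)


@dataclass(frozen=True)
class SelectionConfig:
    r2_max: float = 0.1
    window_bp: int = 1_000_000
    thresholds: tuple = field(default_factory=lambda: DEFAULT_THRESHOLDS)

    def __post_init__(self):
        if not (0 <= self.r2_max <= 1):
            raise ValueError("r2_max must be in [0, 1]")
        ts = tuple(self.thresholds)
        if list(ts) != sorted(ts) or any(not (0 < t <= 1) for t in ts):
            raise ValueError("thresholds must be ascending and in (0, 1]")


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete individuals; a constant vector has
    undefined correlation and is treated as r² = 0 with a warning.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    a, b = g1[ok], g2[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn("constant dosage vector in ld_r2; returning 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune(stats: pd.DataFrame, dosages: np.ndarray,
          config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Greedy LD clumping prioritized by significance.

    Variants are visited by ascending P (ties broken by chromosome then
    position, so runs are reproducible); a variant is kept iff its r² with
    every already-kept variant on the same chromosome within
    ``window_bp`` (center-to-center) is ≤ ``r2_max``.  Rows with NaN P are
    dropped.  The kept subset is returned in the original row order.
    """
    if len(stats) != dosages.shape[1]:
        raise ValueError("stats rows and dosage columns must correspond")
    st = stats.reset_index(drop=True)
    usable = st["p"].notna().to_numpy()
    order = st[usable].sort_values(
        ["p", "chromosome", "position"], kind="stable").index.to_numpy()

    chrom = st["chromosome"].to_numpy()
    pos = st["position"].to_numpy(dtype=np.int64)
    kept: list[int] = []
    for j in order:
        ok = True
        for k in kept:
            if chrom[k] == chrom[j] and abs(pos[k] - pos[j]) <= config.window_bp:
                if ld_r2(dosages[:, j], dosages[:, k]) > config.r2_max:
                    ok = False
                    break
        if ok:
            kept.append(j)
    kept_mask = np.zeros(len(st), dtype=bool)
    kept_mask[kept] = True
    return st[kept_mask].reset_index(drop=True)


def select_by_threshold(stats: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain variants with p ≤ threshold (inclusive)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out = stats[stats["p"].notna() & (stats["p"] <= threshold)].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no variants pass p <= {threshold}")
    return out
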