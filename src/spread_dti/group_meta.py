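"""Group-level meta-combination of per-subject p-value maps.

At each voxel the n subjects' raw permutation p-values are combined through a
robust order-statistic beta test: with p_(r) the r-th smallest value,

    combined p = I_{p_(r)}(r, n - r + 1)   (the Beta(r, n-r+1) CDF),

which is exactly the probability that the r-th of n independent uniform order
statistics falls at or below p_(r) — so the combined statistic is itself
uniform under the global null. r = 1 recovers Tippett's minimum-p test,
1 - (1 - p_(1))^n; mid-range r makes the test robust, rejecting only when a
substantial fraction of subjects show signal. The default r = ceil(n/4)
requires a quarter of subjects to carry signal; r is configurable.

The combined raw map is then BH-adjusted across voxels once at group level
(per-subject maps enter raw, avoiding double correction), and displayed as a
two-tier overlay (adjusted p < 0.05 and < 0.005).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def default_rank(n_subjects: int) -> int:
    """Lower-quartile order statistic, r = ceil(n/4)."""
    return max(1, math.ceil(n_subjects / 4))


def combine_beta(pvalues, rank_r: int) -> float | np.ndarray:
    """Order-statistic beta combination of p-values.

    ``pvalues`` is a 1-D array of n per-subject p-values (a single voxel) or
    a (n, ...) stack (subject axis first); combination is over axis 0.
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.shape[0]
    if n < 1:
        raise ValueError("need at least one p-value")
    if not 1 <= rank_r <= n:
        raise ValueError(f"rank_r={rank_r} out of range 1..{n}")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    p_r = np.sort(p, axis=0)[rank_r - 1]
    out = stats.beta.cdf(p_r, rank_r, n - rank_r + 1)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


@dataclass
class CombinedMap:
    """Group-level combined p-value map with BH adjustment."""

    combined_raw: np.ndarray
    combined_adjusted: np.ndarray
    rank_r: int
    n_subjects: int
    foreground: np.ndarray

    def tier_overlay(self, loose: float = 0.05, strict: float = 0.005) -> np.ndarray:
        """Integer display mask: 0 n.s., 1 = adjusted < loose, 2 = adjusted < strict."""
        with np.errstate(invalid="ignore"):
            out = (self.combined_adjusted < loose).astype(np.int8)
            out[self.combined_adjusted < strict] = 2
        return out


def combine_map(
    maps: list[np.ndarray], foreground: np.ndarray, rank_r: int | None = None
) -> CombinedMap:
    """Voxel-wise beta combination of per-subject raw p-maps, then BH across
    voxels.

    All maps must share one grid and foreground (bringing per-subject maps to
    a common reference grid is the caller's contract).
    """
    if not maps:
        raise ValueError("need at least one subject map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("per-subject maps are not on a common grid")
    if foreground.shape != shape:
        raise ValueError("foreground grid mismatch")
    n = len(maps)
    r = default_rank(n) if rank_r is None else rank_r
    stack = np.stack([m[foreground] for m in maps], axis=0)
    if np.isnan(stack).any():
        raise ValueError("NaN p-values inside the common foreground")
    combined_fg = combine_beta(stack, r)
    combined = np.full(shape, np.nan)
    combined[foreground] = combined_fg
    adjusted = np.full(shape, np.nan)
    adjusted[foreground] = multipletests(combined_fg, method="fdr_bh")[1]
    return CombinedMap(
        combined_raw=combined, combined_adjusted=adjusted,
        rank_r=r, n_subjects=n, foreground=foreground,
    )
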