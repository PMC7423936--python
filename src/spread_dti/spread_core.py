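"""Kernel spatial regression and per-voxel permutation inference.

The change statistic at voxel v is

    T(v) = | S[post](v) - S[pre](v) | = | S[post - pre](v) |,

where S is a Nadaraya–Watson kernel smoother over the foreground: a weighted
average with Gaussian weights w(d) = exp(-d^2 / (2 h^2)) truncated at a
spherical support cutoff (default 3h), renormalized over foreground voxels
only. The two expressions are identical because the smoother is linear with
mask-determined weights; the implementation smooths the difference field once
per permutation.

The null distribution is built by independently re-randomizing the pre/post
time labels at every voxel — equivalent to an independent fair sign flip of
the difference field per voxel — and recomputing T. Permutation p-values use
the add-one convention (1 + #{k : T_k >= T_obs}) / (K + 1) with ties counted
against the null, so p is never 0 and is valid under exchangeability.

Map-level correction: Benjamini–Hochberg (FDR) across foreground voxels, and
Westfall–Young family-wise control as single-step maxT against the recorded
per-permutation map-wide maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from statsmodels.stats.multitest import multipletests

from .volume_prep import ScanPair


@dataclass
class KernelConfig:
    """Gaussian kernel: bandwidth h (voxels) and spherical support cutoff.

    ``truncation_radius_vox`` defaults to 3h (Gaussian mass beyond 3h is
    negligible; truncation bounds the cost). Weight at distance d is
    exp(-d^2/(2 h^2)) for d <= cutoff, else 0.
    """

    bandwidth_vox: float
    truncation_radius_vox: float | None = None

    def __post_init__(self) -> None:
        if self.bandwidth_vox <= 0:
            raise ValueError("bandwidth_vox must be positive")
        if self.truncation_radius_vox is None:
            self.truncation_radius_vox = 3.0 * self.bandwidth_vox
        if self.truncation_radius_vox < self.bandwidth_vox:
            raise ValueError("truncation_radius_vox must be >= bandwidth_vox")


@dataclass
class PermutationPlan:
    """Per-voxel independent fair-coin time-label flips, reproducible from seed."""

    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")

    def flip_iter(self, n_voxels: int):
        """Yield ``n_permutations`` boolean flip vectors of length n_voxels.

        Flips are drawn lazily from a generator seeded with ``seed``;
        iterating twice reproduces the identical sequence.
        """
        rng = np.random.default_rng(self.seed)
        for _ in range(self.n_permutations):
            yield rng.random(n_voxels) < 0.5


def gaussian_ball_kernel(cfg: KernelConfig) -> np.ndarray:
    """Dense (2R+1)^3 kernel of Gaussian weights on the spherical support."""
    r = int(np.floor(cfg.truncation_radius_vox))
    ax = np.arange(-r, r + 1)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    w = np.exp(-d2 / (2.0 * cfg.bandwidth_vox**2))
    w[d2 > cfg.truncation_radius_vox**2] = 0.0
    return w


class KernelSmoother:
    """Nadaraya–Watson smoother for many fields on one fixed foreground.

    Precomputes the kernel spectrum and the foreground-weight denominator so
    each additional field costs one forward/inverse FFT pair.
    """

    def __init__(self, foreground: np.ndarray, cfg: KernelConfig):
        foreground = np.asarray(foreground, dtype=bool)
        if not foreground.any():
            raise ValueError("empty foreground")
        self.foreground = foreground
        self.cfg = cfg
        kernel = gaussian_ball_kernel(cfg)
        self._r = kernel.shape[0] // 2
        full = [n + kernel.shape[i] - 1 for i, n in enumerate(foreground.shape)]
        self._fast = [spfft.next_fast_len(n, real=True) for n in full]
        self._kf = spfft.rfftn(kernel, self._fast)
        den = self._convolve(foreground.astype(np.float64))
        # self-weight is 1, so the denominator is >= 1 on the foreground
        self._den = np.where(foreground, den, 1.0)

    def _convolve(self, arr: np.ndarray) -> np.ndarray:
        out = spfft.irfftn(spfft.rfftn(arr, self._fast) * self._kf, self._fast)
        sl = tuple(slice(self._r, self._r + n) for n in arr.shape)
        return out[sl]

    def smooth(self, values: np.ndarray) -> np.ndarray:
        """Fitted field on the foreground (0 outside). Background voxels are
        excluded from both sums, i.e. weights renormalize over foreground."""
        num = self._convolve(np.where(self.foreground, values, 0.0))
        return np.where(self.foreground, num / self._den, 0.0)


def nw_smooth(values: np.ndarray, foreground: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """One-shot Nadaraya–Watson kernel smoothing (see :class:`KernelSmoother`)."""
    return KernelSmoother(foreground, cfg).smooth(values)


def observed_statistic(pair: ScanPair, cfg: KernelConfig) -> np.ndarray:
    """|fitted post - fitted pre| per foreground voxel (FA units)."""
    return np.abs(nw_smooth(pair.difference(), pair.foreground, cfg))


def _field_norms(absfield: np.ndarray, foreground: np.ndarray) -> tuple[float, float, float]:
    vals = absfield[foreground]
    return float(vals.mean()), float(np.sqrt(np.mean(vals**2))), float(vals.max())


@dataclass
class SpreadResult:
    """Per-subject maps and permutation records of one run.

    Maps are full-grid arrays; p-value maps are NaN outside the foreground,
    ``stat`` and ``fitted_diff`` are 0 there. ``perm_max`` holds the K
    map-wide maxima of the permuted statistic; ``perm_norms`` the K rows of
    (L1, L2, Linf) norms of the permuted fitted difference.
    """

    stat: np.ndarray
    fitted_diff: np.ndarray
    raw: np.ndarray
    foreground: np.ndarray
    perm_max: np.ndarray
    perm_norms: np.ndarray  # (K, 3): L1, L2, Linf
    cfg: KernelConfig
    plan: PermutationPlan
    bh: np.ndarray | None = None
    wy: np.ndarray | None = None

    @property
    def n_permutations(self) -> int:
        return self.plan.n_permutations


def permutation_pvalues(
    pair: ScanPair, cfg: KernelConfig, plan: PermutationPlan
) -> SpreadResult:
    """Raw per-voxel permutation p-values for |fitted FA difference|.

    For permutation k the difference field has its sign flipped independently
    at each foreground voxel (= swapping that voxel's two time labels), is
    smoothed, and compared to the observed statistic:
    raw(v) = (1 + #{k : T_k(v) >= T_obs(v)}) / (K + 1). Records map-wide
    maxima and L^p norms of each permuted fitted field for WY correction and
    global norm p-values.
    """
    fg = pair.foreground
    smoother = KernelSmoother(fg, cfg)
    diff = pair.difference()
    fitted_diff = smoother.smooth(diff)
    t_obs = np.abs(fitted_diff)

    k_total = plan.n_permutations
    count = np.zeros(fg.shape, dtype=np.int64)
    perm_max = np.empty(k_total)
    perm_norms = np.empty((k_total, 3))
    signs = np.ones(fg.shape)
    n_fg = int(fg.sum())
    for k, flips in enumerate(plan.flip_iter(n_fg)):
        signs[fg] = np.where(flips, -1.0, 1.0)
        t_k = np.abs(smoother.smooth(diff * signs))
        count += (t_k >= t_obs) & fg
        perm_max[k] = t_k[fg].max()
        perm_norms[k] = _field_norms(t_k, fg)

    raw = np.where(fg, (1.0 + count) / (k_total + 1.0), np.nan)
    return SpreadResult(
        stat=t_obs, fitted_diff=fitted_diff, raw=raw, foreground=fg,
        perm_max=perm_max, perm_norms=perm_norms, cfg=cfg, plan=plan,
    )


def adjust_bh(raw: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-value map (capped at 1,
    monotone), defined on the foreground, NaN outside."""
    out = np.full(raw.shape, np.nan)
    out[foreground] = multipletests(raw[foreground], method="fdr_bh")[1]
    return out


def adjust_wy(result: SpreadResult) -> np.ndarray:
    """Westfall–Young single-step maxT adjusted map.

    wy(v) = (1 + #{k : max_u T_k(u) >= T_obs(v)}) / (K + 1), floored at the
    raw p-value so wy >= raw everywhere.
    """
    if result.perm_max is None or len(result.perm_max) == 0:
        raise ValueError("per-permutation maxima were not recorded")
    fg = result.foreground
    k_total = len(result.perm_max)
    sorted_max = np.sort(result.perm_max)
    # count of maxima >= t, via position of t in the sorted maxima
    ge_count = k_total - np.searchsorted(sorted_max, result.stat[fg], side="left")
    wy = np.full(result.stat.shape, np.nan)
    wy[fg] = (1.0 + ge_count) / (k_total + 1.0)
    wy[fg] = np.maximum(wy[fg], result.raw[fg])
    return wy


def run_spread(pair: ScanPair, cfg: KernelConfig, plan: PermutationPlan) -> SpreadResult:
    """Full per-subject run: statistic, raw, BH and WY adjusted p-value maps."""
    result = permutation_pvalues(pair, cfg, plan)
    result.bh = adjust_bh(result.raw, result.foreground)
    result.wy = adjust_wy(result)
    return result
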