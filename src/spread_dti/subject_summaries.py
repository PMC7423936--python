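"""Scalar per-subject summaries of a change-detection run.

Three detection summaries over the significant set S = {v : p(v) < threshold}
(default: raw p < 0.002, the single-subject map display rule; BH/WY maps are
selectable):

* NSV  — number of significantly changed voxels, |S|;
* TDSV — signed sum of (post - pre) FA differences over S;
* ADSV — sum of |post - pre| over S.

Three functional norms of the fitted FA difference field Δ over the
foreground — L1 = mean |Δ|, L2 = sqrt(mean Δ^2), Linf = max |Δ| — each with a
global permutation p-value (1 + #{k : norm_k >= norm_obs}) / (K + 1) from the
per-permutation norms recorded by the permutation engine. All quantities are
in FA units (unitless, [0, 1] scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spread_core import SpreadResult
from .volume_prep import ScanPair

NORM_NAMES = ("l1", "l2", "linf")


def significant_voxel_stats(
    diff: np.ndarray, pmap: np.ndarray, threshold: float
) -> tuple[int, float, float]:
    """(NSV, TDSV, ADSV) over the set {v : p(v) < threshold}.

    ``diff`` is the raw (unfitted) post - pre difference; NaN p-values
    (background) never count as significant.
    """
    if diff.shape != pmap.shape:
        raise ValueError("diff and p-map shapes differ")
    with np.errstate(invalid="ignore"):
        sig = pmap < threshold
    d = diff[sig]
    return int(sig.sum()), float(d.sum()), float(np.abs(d).sum())


def fitted_norms(fitted_diff: np.ndarray, foreground: np.ndarray) -> tuple[float, float, float]:
    """(L1, L2, Linf) of the fitted difference field over foreground voxels."""
    if not foreground.any():
        raise ValueError("empty foreground")
    vals = np.abs(fitted_diff[foreground])
    return float(vals.mean()), float(np.sqrt(np.mean(vals**2))), float(vals.max())


def global_norm_pvalues(
    observed: tuple[float, float, float], perm_norms: np.ndarray
) -> dict[str, float]:
    """Global permutation p-value per norm, add-one convention, ties against
    the null."""
    perm_norms = np.asarray(perm_norms, dtype=float)
    if perm_norms.ndim != 2 or perm_norms.shape[1] != 3 or perm_norms.shape[0] < 1:
        raise ValueError("perm_norms must be a (K, 3) record of permutation norms")
    k_total = perm_norms.shape[0]
    return {
        name: float((1 + np.sum(perm_norms[:, i] >= observed[i])) / (k_total + 1))
        for i, name in enumerate(NORM_NAMES)
    }


def decrease_fraction(diff: np.ndarray, pmap: np.ndarray, threshold: float) -> float:
    """Fraction of significant voxels with decreased FA (post < pre).

    Voxels with an exactly zero difference carry no direction and are
    excluded (they arise only in noise-free synthetic data). NaN if no
    directed voxel is significant.
    """
    with np.errstate(invalid="ignore"):
        sig = (pmap < threshold) & (diff != 0)
    if not sig.any():
        return float("nan")
    return float(np.mean(diff[sig] < 0))


@dataclass
class SubjectSummary:
    subject_id: str
    bandwidth: float
    nsv: int
    tdsv: float
    adsv: float
    l1: float
    l2: float
    linf: float
    global_p_l1: float
    global_p_l2: float
    global_p_linf: float
    threshold_used: float
    mtp_used: str

    def __post_init__(self) -> None:
        if self.adsv + 1e-12 < abs(self.tdsv):
            raise ValueError("ADSV must be >= |TDSV|")
        if self.nsv == 0 and (self.tdsv != 0 or self.adsv != 0):
            raise ValueError("empty significant set must have zero TDSV/ADSV")


def summarize_subject(
    pair: ScanPair,
    result: SpreadResult,
    threshold: float = 0.002,
    mtp: str = "raw",
) -> SubjectSummary:
    """Reduce one run to a :class:`SubjectSummary`.

    ``mtp`` selects which p-value map defines the significant set: ``raw``
    (default, threshold 0.002 as in single-subject map display), ``bh`` or
    ``wy``.
    """
    pmap = {"raw": result.raw, "bh": result.bh, "wy": result.wy}.get(mtp)
    if pmap is None:
        raise ValueError(f"mtp must be raw|bh|wy with the map computed, got {mtp!r}")
    nsv, tdsv, adsv = significant_voxel_stats(pair.difference(), pmap, threshold)
    norms = fitted_norms(result.fitted_diff, result.foreground)
    global_p = global_norm_pvalues(norms, result.perm_norms)
    return SubjectSummary(
        subject_id=pair.subject_id,
        bandwidth=result.cfg.bandwidth_vox,
        nsv=nsv, tdsv=tdsv, adsv=adsv,
        l1=norms[0], l2=norms[1], linf=norms[2],
        global_p_l1=global_p["l1"], global_p_l2=global_p["l2"],
        global_p_linf=global_p["linf"],
        threshold_used=threshold, mtp_used=mtp,
    )


def summaries_to_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """One row per subject, columns as in :class:`SubjectSummary`."""
    return pd.DataFrame([vars(s) for s in summaries])
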