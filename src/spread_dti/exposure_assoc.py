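"""Season-level head-impact exposure metrics and their association with
subject-level white-matter change summaries.

Helmet telemetry records five helmet impact measures (HIMs) per hit above the
10 g linear-acceleration recording threshold: linear acceleration (LA, g),
rotational acceleration (RA, rad/s^2), HIC15, GSI and HITsp. A season of hits
is reduced to six metrics per HIM:

* ``mean`` and ``peak`` — average and maximum over the season;
* ``CUW`` — cumulative unweighted sum;
* ``TBH`` — time-between-hits weighted sum: each hit is amplified by the
  magnitude of, and elapsed time since, every earlier hit (exponential decay
  with time constant ``tau_tbh_days``); weights are >= 1, so TBH >= CUW;
* ``TUA`` — time-until-assessment weighted sum: each hit is discounted by the
  time remaining until the post-season scan (decay ``tau_tua_days``);
  weights are <= 1, so TUA <= CUW;
* ``TBH+TUA`` — both weight factors applied per hit.

The exact weighting laws behind the TBH/TUA names are not standardized; the
exponential-decay forms used here are explicit, documented choices with
configurable time constants (:class:`WeightConfig`).

Associations between exposure metrics and change summaries use Spearman rank
correlation (two-sided), with the exact permutation null for small samples
(n < 10) and the t approximation otherwise, and Benjamini–Hochberg adjustment
within each summary column (30 metric x HIM tests per column).
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: canonical HIM column order (internal names -> display names)
HIM_COLUMNS = {
    "la_g": "LA",
    "ra_rads2": "RA",
    "hic15": "HIC15",
    "gsi": "GSI",
    "hitsp": "HITsp",
}
#: CSV header names, in file order
CSV_COLUMNS = ["time_iso", "LA_g", "RA_rads2", "HIC15", "GSI", "HITsp"]
EXPOSURE_METRICS = ["mean", "peak", "CUW", "TBH", "TUA", "TBH+TUA"]

#: recording threshold of the helmet accelerometer system, in g
LA_RECORDING_THRESHOLD_G = 10.0


@dataclass
class WeightConfig:
    """Time constants (days) of the exponential exposure-weighting kernels."""

    tau_tbh_days: float = 7.0
    tau_tua_days: float = 30.0

    def __post_init__(self) -> None:
        if self.tau_tbh_days <= 0 or self.tau_tua_days <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class ImpactLog:
    """Time-ordered helmet impact events plus the post-season scan time.

    ``events`` has columns ``time`` (datetime64) and the five HIM columns
    ``la_g, ra_rads2, hic15, gsi, hitsp``.
    """

    events: pd.DataFrame
    scan_time: pd.Timestamp
    subject_id: str = ""

    def __post_init__(self) -> None:
        cols = ["time", *HIM_COLUMNS]
        missing = set(cols) - set(self.events.columns)
        if missing:
            raise ValueError(f"ImpactLog events missing columns: {sorted(missing)}")
        self.events = self.events[cols].reset_index(drop=True)
        self.scan_time = pd.Timestamp(self.scan_time)
        t = self.events["time"]
        if len(t) > 1 and not t.is_monotonic_increasing:
            raise ValueError("impact events must be time-sorted")
        if len(t) and self.scan_time < t.iloc[-1]:
            raise ValueError("scan_time precedes the last impact")
        if len(t) and (self.events["la_g"] <= LA_RECORDING_THRESHOLD_G).any():
            raise ValueError(
                f"linear accelerations at or below the {LA_RECORDING_THRESHOLD_G} g "
                "recording threshold are not valid events"
            )

    @property
    def n_hits(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        """Write events as CSV with a `# scan_time=` sidecar comment line."""
        with open(path, "w") as fh:
            fh.write(f"# scan_time={self.scan_time.isoformat()}\n")
            out = self.events.rename(
                columns=dict(zip(["time", *HIM_COLUMNS], CSV_COLUMNS))
            ).copy()
            out["time_iso"] = out["time_iso"].map(lambda ts: ts.isoformat())
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "") -> "ImpactLog":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# scan_time="):
                raise ValueError(f"{path}: missing '# scan_time=' sidecar line")
            scan_time = pd.Timestamp(first.split("=", 1)[1].strip())
            df = pd.read_csv(io.StringIO(fh.read()))
        df = df.rename(columns=dict(zip(CSV_COLUMNS, ["time", *HIM_COLUMNS])))
        df["time"] = pd.to_datetime(df["time"])
        return cls(events=df, scan_time=scan_time, subject_id=subject_id)


def _tbh_weights(t_days: np.ndarray, x: np.ndarray, tau: float) -> np.ndarray:
    """Per-hit amplification from prior hits: 1 + sum_{j<i} (x_j/x_max) e^{-(t_i-t_j)/tau}."""
    n = len(x)
    if n == 0:
        return np.empty(0)
    xmax = float(np.max(x))
    dt = t_days[:, None] - t_days[None, :]  # dt[i, j] = t_i - t_j
    prior = np.tril(np.exp(-dt / tau) * (x / xmax)[None, :], k=-1)
    return 1.0 + prior.sum(axis=1)


def summarize_exposure(log: ImpactLog, weights: WeightConfig | None = None) -> pd.DataFrame:
    """Six season metrics for each of the five HIMs.

    Returns a DataFrame indexed by metric (``mean, peak, CUW, TBH, TUA,
    TBH+TUA``) with one column per HIM display name (``LA, RA, HIC15, GSI,
    HITsp``). An empty log yields 0 for the cumulative metrics and NaN for
    mean/peak (undefined, recorded as missing).
    """
    weights = weights or WeightConfig()
    out = pd.DataFrame(
        index=pd.Index(EXPOSURE_METRICS, name="metric"),
        columns=list(HIM_COLUMNS.values()),
        dtype=float,
    )
    if log.n_hits == 0:
        out.loc[["CUW", "TBH", "TUA", "TBH+TUA"]] = 0.0
        return out
    t_days = (
        (log.events["time"] - log.events["time"].iloc[0]).dt.total_seconds().to_numpy()
        / 86400.0
    )
    until_scan = (
        (log.scan_time - log.events["time"]).dt.total_seconds().to_numpy() / 86400.0
    )
    tua_w = np.exp(-until_scan / weights.tau_tua_days)
    for col, him in HIM_COLUMNS.items():
        x = log.events[col].to_numpy(dtype=float)
        tbh_w = _tbh_weights(t_days, x, weights.tau_tbh_days)
        out.loc["mean", him] = x.mean()
        out.loc["peak", him] = x.max()
        out.loc["CUW", him] = x.sum()
        out.loc["TBH", him] = float(np.sum(x * tbh_w))
        out.loc["TUA", him] = float(np.sum(x * tua_w))
        out.loc["TBH+TUA", him] = float(np.sum(x * tbh_w * tua_w))
    return out


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (n < 10).

    Enumerates all n! pairings of the rank vectors; ties are handled by
    computing rho as the Pearson correlation of (mid-)ranks. Permutations
    with |rho| >= |rho_obs| count against the null (ties inclusive).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / np.linalg.norm(rx - rx.mean())
    ryc = ry - ry.mean()
    ryn = ryc / np.linalg.norm(ryc)
    perms = np.array(list(itertools.permutations(range(len(y)))))
    rhos = ryn[perms] @ rx
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation null for n < 10, t approximation otherwise. Returns
    (nan, nan) when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    if len(x) < 10:
        p = _exact_spearman_pvalue(x, y, rho)
    return float(rho), float(p)


def associate(
    exposures: dict[str, pd.DataFrame],
    outputs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate exposure metrics with change summaries across subjects.

    Parameters
    ----------
    exposures
        Mapping subject_id -> :func:`summarize_exposure` table.
    outputs
        One row per subject (index = subject_id), one column per change
        summary (e.g. ``linf_bw15``); column names are carried through as
        ``spread_output``.

    Returns
    -------
    Long table with columns ``metric, him, spread_output, rho, p_raw,
    p_adjusted, significant``. BH adjustment runs within each spread_output
    column over its valid (non-constant) metric x HIM tests.
    """
    subjects = [s for s in outputs.index if s in exposures]
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects with both exposures and outputs")
    rows = []
    for out_col in outputs.columns:
        yvals = outputs.loc[subjects, out_col].to_numpy(dtype=float)
        col_rows = []
        for metric in EXPOSURE_METRICS:
            for him in HIM_COLUMNS.values():
                xvals = np.array(
                    [exposures[s].loc[metric, him] for s in subjects], dtype=float
                )
                if np.isnan(xvals).any():
                    rho, p = math.nan, math.nan
                else:
                    rho, p = spearman_test(xvals, yvals)
                col_rows.append(
                    {"metric": metric, "him": him, "spread_output": out_col,
                     "rho": rho, "p_raw": p}
                )
        df = pd.DataFrame(col_rows)
        valid = df["p_raw"].notna()
        df["p_adjusted"] = np.nan
        if valid.any():
            df.loc[valid, "p_adjusted"] = multipletests(
                df.loc[valid, "p_raw"], method="fdr_bh"
            )[1]
        df["significant"] = df["p_adjusted"] < alpha
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
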