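"""Synthetic fixtures: smooth FA volume pairs with planted spherical lesions,
and helmet-impact logs with heavy-tailed magnitudes.

The generator emulates the statistical structure the change-detection method
relies on — a spatially smooth baseline field shared by the two time points,
independent additive voxel noise per scan, and optional localized FA changes
— without any anatomical realism. The baseline is white noise convolved with
a Gaussian of width ``smoothness_mm`` and affinely rescaled to
``baseline_mean ± baseline_amplitude``; lesions are additive ``delta_fa``
offsets inside a Euclidean ball, applied to the post scan only; all values
are clipped to [0, 1].

Impact logs draw per-hit magnitudes from correlated lognormal laws truncated
below at the 10 g linear-acceleration recording threshold, with uniformly
scattered hit times over the season window and a scan date shortly after the
season ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exposure_assoc import HIM_COLUMNS, LA_RECORDING_THRESHOLD_G, ImpactLog
from .volume_prep import FAVolume, ScanPair


@dataclass
class FieldSpec:
    """Parameters of a synthetic FA volume pair.

    Defaults give a 48^3 grid of 2 mm voxels with a 6-voxel background shell,
    a baseline FA field of mean 0.5 ± 0.15 with 6 mm correlation length, and
    per-scan i.i.d. Gaussian noise of SD 0.02 FA units.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 2.0
    smoothness_mm: float = 6.0
    noise_sd: float = 0.02
    baseline_mean: float = 0.5
    baseline_amplitude: float = 0.15
    mask_margin: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError("shape must be 3 positive extents")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.smoothness_mm < 0 or self.noise_sd < 0:
            raise ValueError("smoothness_mm and noise_sd must be nonnegative")
        if not 0 < self.baseline_mean < 1:
            raise ValueError("baseline_mean must lie in (0, 1)")
        if self.mask_margin < 0:
            raise ValueError("mask_margin must be nonnegative")
        if any(n <= 2 * self.mask_margin for n in self.shape):
            raise ValueError(
                f"shape {self.shape} too small for mask_margin={self.mask_margin}: "
                "foreground would be empty"
            )

    def foreground_mask(self) -> np.ndarray:
        """Boolean mask: True strictly inside the mask_margin shell."""
        fg = np.zeros(self.shape, dtype=bool)
        m = self.mask_margin
        fg[m : self.shape[0] - m, m : self.shape[1] - m, m : self.shape[2] - m] = True
        return fg


@dataclass
class LesionSpec:
    """A spherical FA offset: ``delta_fa`` added inside a Euclidean ball
    (negative = FA decrease)."""

    center: tuple[int, int, int]
    radius_vox: float
    delta_fa: float

    def __post_init__(self) -> None:
        self.center = tuple(int(c) for c in self.center)
        if len(self.center) != 3:
            raise ValueError("center must have 3 coordinates")
        if self.radius_vox < 0:
            raise ValueError("radius_vox must be nonnegative")


def ball_mask(
    center: tuple[int, int, int], radius_vox: float, shape: tuple[int, int, int]
) -> np.ndarray:
    """Boolean mask of voxels with center-to-center Euclidean distance
    <= radius_vox from ``center``. Radius 0 selects exactly the center voxel."""
    center = tuple(int(c) for c in center)
    if any(not 0 <= c < n for c, n in zip(center, shape)):
        raise ValueError(f"center {center} outside shape {shape}")
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_vox**2


def _smooth_baseline(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(spec.shape)
    sigma_vox = spec.smoothness_mm / spec.voxel_size_mm
    base = ndimage.gaussian_filter(white, sigma_vox) if sigma_vox > 0 else white
    lo, hi = float(base.min()), float(base.max())
    if hi > lo:
        base = 2.0 * (base - lo) / (hi - lo) - 1.0  # -> [-1, 1]
    else:
        base = np.zeros_like(base)
    return spec.baseline_mean + spec.baseline_amplitude * base


def generate_pair(
    spec: FieldSpec, lesions: list[LesionSpec] | tuple[LesionSpec, ...] = (),
    subject_id: str = "synthetic",
) -> ScanPair:
    """Generate a pre/post FA pair: shared smooth baseline, independent noise
    draws, lesions applied additively to the post scan only.

    Bit-reproducible from ``spec.seed``. Raises if any lesion ball is not
    entirely inside the foreground.
    """
    fg = spec.foreground_mask()
    for les in lesions:
        ball = ball_mask(les.center, les.radius_vox, spec.shape)
        if not ball.any() or not np.all(fg[ball]):
            raise ValueError(
                f"lesion at {les.center} (radius {les.radius_vox}) extends outside "
                "the foreground"
            )
    rng = np.random.default_rng(spec.seed)
    base = _smooth_baseline(spec, rng)
    noise1 = rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd > 0 else 0.0
    noise2 = rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd > 0 else 0.0
    pre = base + noise1
    post = base + noise2
    for les in lesions:
        post = np.where(ball_mask(les.center, les.radius_vox, spec.shape),
                        post + les.delta_fa, post)
    pre = np.where(fg, np.clip(pre, 0.0, 1.0), 0.0)
    post = np.where(fg, np.clip(post, 0.0, 1.0), 0.0)
    vs = spec.voxel_size_mm
    return ScanPair(
        pre=FAVolume(pre, fg, vs, provenance=f"synthetic seed={spec.seed} pre"),
        post=FAVolume(post, fg, vs, provenance=f"synthetic seed={spec.seed} post"),
        subject_id=subject_id,
    )


#: lognormal magnitude laws per HIM: (median, sigma_log, lower_truncation).
#: LA is truncated at the 10 g recording threshold; medians are typical
#: collegiate-football helmet telemetry magnitudes.
DEFAULT_MAGNITUDE_PARAMS: dict[str, tuple[float, float, float]] = {
    "la_g": (20.0, 0.45, LA_RECORDING_THRESHOLD_G),
    "ra_rads2": (1400.0, 0.60, 0.0),
    "hic15": (6.5, 0.90, 0.0),
    "gsi": (9.0, 0.90, 0.0),
    "hitsp": (14.0, 0.50, 0.0),
}


def generate_impact_log(
    n_hits: int,
    season_days: float = 90.0,
    magnitude_params: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
    season_start: str | pd.Timestamp = "2013-08-15",
    him_correlation: float = 0.7,
    subject_id: str = "synthetic",
) -> ImpactLog:
    """Synthetic helmet-impact log: ``n_hits`` events at strictly increasing
    times within the season window, correlated heavy-tailed HIM magnitudes
    (shared lognormal severity factor), scan date 1–7 days after season end.
    """
    if n_hits < 0:
        raise ValueError("n_hits must be >= 0")
    params = dict(DEFAULT_MAGNITUDE_PARAMS)
    if magnitude_params:
        params.update(magnitude_params)
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(season_start)
    scan_time = start + pd.Timedelta(days=season_days + float(rng.uniform(1.0, 7.0)))

    t = np.sort(rng.uniform(0.0, season_days, n_hits))
    t = t + np.arange(n_hits) * 1e-9  # enforce strictly increasing
    values = {c: np.empty(n_hits) for c in HIM_COLUMNS}
    todo = np.arange(n_hits)
    while todo.size:
        z = rng.standard_normal(todo.size)  # shared severity factor
        draw = {}
        for col, (median, sig, _floor) in params.items():
            eps = rng.standard_normal(todo.size)
            mix = him_correlation * z + np.sqrt(1 - him_correlation**2) * eps
            draw[col] = median * np.exp(sig * mix)
        ok = np.ones(todo.size, dtype=bool)
        for col, (_m, _s, floor) in params.items():
            ok &= draw[col] > floor
        for col in HIM_COLUMNS:
            values[col][todo[ok]] = draw[col][ok]
        todo = todo[~ok]  # redraw whole rows below a recording floor

    events = pd.DataFrame({"time": start + pd.to_timedelta(t, unit="D"), **values})
    return ImpactLog(events=events, scan_time=scan_time, subject_id=subject_id)


def generate_exposed_cohort(
    n_subjects: int = 12,
    seed: int = 0,
    shape: tuple[int, int, int] = (28, 28, 28),
    mask_margin: int = 5,
    lesion_radius: float = 4.0,
    noise_sd: float = 0.02,
    base_delta: float = -0.02,
    delta_range: float = -0.08,
    hits_range: tuple[int, int] = (37, 1057),
) -> list[tuple[ScanPair, ImpactLog]]:
    """A cohort with a planted dose-response: each subject's lesion contrast
    is a monotone (affine in min-max-normalized cumulative rotational
    acceleration) function of their season exposure, plus imaging noise.

    Hit counts span ``hits_range`` (the observed season range); subjects keep
    matched scan pairs and impact logs under ids ``s00, s01, ...``.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    logs = [
        generate_impact_log(
            int(rng.integers(hits_range[0], hits_range[1] + 1)),
            seed=int(rng.integers(2**31 - 1)),
            subject_id=f"s{i:02d}",
        )
        for i in range(n_subjects)
    ]
    cuw_ra = np.array([log.events["ra_rads2"].sum() for log in logs])
    norm = (cuw_ra - cuw_ra.min()) / max(cuw_ra.max() - cuw_ra.min(), 1e-12)
    center = tuple(n // 2 for n in shape)
    cohort = []
    for i, log in enumerate(logs):
        spec = FieldSpec(
            shape=shape, mask_margin=mask_margin, noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        lesion = LesionSpec(center, lesion_radius, base_delta + delta_range * norm[i])
        cohort.append((generate_pair(spec, [lesion], subject_id=log.subject_id), log))
    return cohort
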