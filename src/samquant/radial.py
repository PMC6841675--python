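"""Radial quantification of reporter signals around the meristem center.

Signals (stem-cell reporter CLV3, auxin-output reporter DR5) are quantified
as a function of distance from the estimated meristem center:

* :func:`cross_section_profiles` — intensity histograms along rotated
  central cross-sections of a top-view surface projection, averaged into a
  radial profile;
* :func:`central_window_test` — comparison of mean signal within a central
  window (default ±12.5 µm) between two groups by Student's t-test;
* :func:`threshold_distance` — the "central minimum size": the distance at
  which signal first reaches a factor (default 120%) of the center
  background level;
* :func:`gate_stem_cells` / :func:`minmax_normalize` — the per-cell stem
  cell gate (axis distance <= 1/4 of the fitted sphere radius) and per-
  meristem min-max normalization;
* :func:`kernel_profile` — Nadaraya–Watson kernel regression of signal on
  axis distance, with bootstrap percentile confidence bands;
* :func:`central_zone_timecourse` — one-way ANOVA plus Tukey HSD across
  condition/time groups of per-meristem central means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from . import groupstats
from .errors import DegenerateNormalizationError, ValidationError

__all__ = [
    "ProfileConfig",
    "SurfaceGrid",
    "RadialProfile",
    "CentralWindowTest",
    "ThresholdDistance",
    "KernelProfileResult",
    "AnovaTukeyResult",
    "cross_section_profiles",
    "center_and_align",
    "central_window_test",
    "threshold_distance",
    "gate_stem_cells",
    "minmax_normalize",
    "kernel_profile",
    "central_zone_timecourse",
]


@dataclass(frozen=True)
class ProfileConfig:
    """Quantification parameters.

    Defaults follow the study conventions: 100 cross-sections rotated by
    3.6° each, a ±12.5 µm central comparison window, a 120%-of-background
    threshold for the central-minimum size, a stem-cell gate at 1/4 of the
    fitted sphere radius, and 10 000 bootstrap iterations for kernel-
    regression confidence bands.
    """

    n_sections: int = 100
    section_step: float = 3.6  # degrees
    central_halfwidth: float = 12.5  # µm
    background_threshold_factor: float = 1.2
    stem_cell_radius_fraction: float = 0.25
    bootstrap_iterations: int = 10_000
    kernel_bandwidth: float | str = "auto"
    background_halfwidth: float = 0.0  # µm; 0 = distance-0 bin only

    def __post_init__(self):
        if self.n_sections < 1:
            raise ValidationError("n_sections must be >= 1")
        if abs(self.n_sections * self.section_step - 360.0) > 1e-9:
            raise ValidationError(
                f"n_sections * section_step must equal 360, got "
                f"{self.n_sections} * {self.section_step}"
            )
        if self.central_halfwidth <= 0:
            raise ValidationError("central_halfwidth must be > 0")
        if self.background_threshold_factor <= 0:
            raise ValidationError("background_threshold_factor must be > 0")
        if not 0 < self.stem_cell_radius_fraction <= 1:
            raise ValidationError("stem_cell_radius_fraction must be in (0, 1]")
        if self.bootstrap_iterations < 1:
            raise ValidationError("bootstrap_iterations must be >= 1")
        if self.kernel_bandwidth != "auto" and not (
            isinstance(self.kernel_bandwidth, (int, float)) and self.kernel_bandwidth > 0
        ):
            raise ValidationError("kernel_bandwidth must be 'auto' or a positive number")
        if self.background_halfwidth < 0:
            raise ValidationError("background_halfwidth must be >= 0")


@dataclass(frozen=True)
class SurfaceGrid:
    """Top-view surface-projected intensity image with isotropic µm pixels.

    ``data[row, col]`` maps to the physical point
    ``(origin[0] + col * pixel_size, origin[1] + row * pixel_size)``.
    """

    data: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValidationError(f"grid data must be 2D, got {data.ndim}D")
        if np.isscalar(self.pixel_size):
            if self.pixel_size <= 0:
                raise ValidationError("pixel_size must be > 0")
        else:
            raise ValidationError("pixel_size must be a scalar (isotropic pixels required)")
        if not np.all(np.isfinite(data)) or np.any(data < 0):
            raise ValidationError("grid intensities must be finite and >= 0")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))


@dataclass(frozen=True)
class RadialProfile:
    """Mean signal intensity per radial distance bin.

    ``per_section`` (n_sections x n_bins) keeps the individual cross-section
    profiles for audit; missing bins (beyond the grid edge for a given
    section) are NaN.
    """

    distances: np.ndarray  # µm, bin centers, ascending from 0
    mean_intensity: np.ndarray
    per_section: np.ndarray
    pixel_size: float

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        m = np.asarray(self.mean_intensity, dtype=float)
        if d.ndim != 1 or m.shape != d.shape:
            raise ValidationError("distances and mean_intensity must be matching 1D arrays")
        if len(d) and np.any(np.diff(d) <= 0):
            raise ValidationError("distances must be strictly increasing")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "mean_intensity", m)
        object.__setattr__(self, "per_section", np.asarray(self.per_section, dtype=float))


def _nanmean_quiet(a: np.ndarray, axis=None) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis)


def cross_section_profiles(
    grid: SurfaceGrid, center_2d, cfg: ProfileConfig = ProfileConfig()
) -> RadialProfile:
    """Average intensity along rotated central cross-sections.

    For each of ``cfg.n_sections`` angles (step ``cfg.section_step``°) the
    grid is sampled by bilinear interpolation along the full line through
    ``center_2d``, at ``pixel_size`` spacing out to the grid edge.  Signed
    positions are folded to radial distance (the two half-rays of a section
    are averaged), and sections are averaged into one mean radial profile
    with bin width ``pixel_size``.  Samples outside the grid are missing
    (NaN) and excluded from the averages.
    """
    center = np.asarray(center_2d, dtype=float)
    ny, nx = grid.data.shape
    cx = (center[0] - grid.origin[0]) / grid.pixel_size
    cy = (center[1] - grid.origin[1]) / grid.pixel_size
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValidationError(
            f"center {tuple(center)} lies outside the grid extent "
            f"[{grid.origin[0]}, {grid.origin[0] + (nx - 1) * grid.pixel_size}] x "
            f"[{grid.origin[1]}, {grid.origin[1] + (ny - 1) * grid.pixel_size}]"
        )

    corners = np.array([[0, 0], [nx - 1, 0], [0, ny - 1], [nx - 1, ny - 1]], dtype=float)
    max_px = float(np.max(np.hypot(corners[:, 0] - cx, corners[:, 1] - cy)))
    n_bins = int(np.floor(max_px)) + 1

    angles = np.deg2rad(np.arange(cfg.n_sections) * cfg.section_step)
    steps = np.arange(n_bins, dtype=float)  # pixel units (= pixel_size µm)
    # (n_sections, n_bins) sampling coordinates for each half-ray
    cos_a = np.cos(angles)[:, None]
    sin_a = np.sin(angles)[:, None]

    per_section = np.empty((cfg.n_sections, n_bins))
    sides = []
    for sign in (+1.0, -1.0):
        cols = cx + sign * steps[None, :] * cos_a
        rows = cy + sign * steps[None, :] * sin_a
        vals = ndimage.map_coordinates(
            grid.data, [rows.ravel(), cols.ravel()], order=1, mode="constant", cval=np.nan
        ).reshape(cfg.n_sections, n_bins)
        sides.append(vals)
    per_section = _nanmean_quiet(np.stack(sides), axis=0)

    mean_profile = _nanmean_quiet(per_section, axis=0)
    valid = ~np.isnan(mean_profile)
    last = int(np.max(np.nonzero(valid))) if valid.any() else -1
    if last < 0:
        raise ValidationError("no valid samples: grid is empty at all section positions")
    keep = slice(0, last + 1)
    return RadialProfile(
        distances=steps[keep] * grid.pixel_size,
        mean_intensity=mean_profile[keep],
        per_section=per_section[:, keep],
        pixel_size=grid.pixel_size,
    )


def center_and_align(profiles: list[RadialProfile]) -> list[RadialProfile]:
    """Resample profiles onto a common distance grid starting at 0.

    All profiles share bin width ``pixel_size`` and start at distance 0, so
    alignment pads shorter profiles with NaN out to the longest grid; values
    are never extrapolated.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    px = profiles[0].pixel_size
    if any(abs(p.pixel_size - px) > 1e-12 for p in profiles):
        raise ValidationError("profiles have mixed pixel sizes; resample upstream")
    n = max(len(p.distances) for p in profiles)
    common = np.arange(n) * px
    out = []
    for p in profiles:
        pad = n - len(p.distances)
        mean = np.concatenate([p.mean_intensity, np.full(pad, np.nan)])
        sect = np.pad(p.per_section, ((0, 0), (0, pad)), constant_values=np.nan)
        out.append(
            RadialProfile(distances=common, mean_intensity=mean, per_section=sect, pixel_size=px)
        )
    return out


@dataclass(frozen=True)
class CentralWindowTest:
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    per_profile_means_a: np.ndarray = field(repr=False, default=None)
    per_profile_means_b: np.ndarray = field(repr=False, default=None)


def central_mean(profile: RadialProfile, cfg: ProfileConfig = ProfileConfig()) -> float:
    """Mean intensity over distance bins within ``central_halfwidth`` of the center."""
    mask = profile.distances <= cfg.central_halfwidth
    if not mask.any():
        raise ValidationError("no bins within the central window")
    return float(_nanmean_quiet(profile.mean_intensity[mask]))


def central_window_test(
    group_a: list[RadialProfile],
    group_b: list[RadialProfile],
    cfg: ProfileConfig = ProfileConfig(),
    welch: bool = False,
) -> CentralWindowTest:
    """Compare central signal (within ±``central_halfwidth``) between groups.

    One mean per profile (= per meristem) enters a two-sample Student's
    t-test (equal-variance by default, Welch by flag), two-sided.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 profiles")
    means_a = np.array([central_mean(p, cfg) for p in group_a])
    means_b = np.array([central_mean(p, cfg) for p in group_b])
    t, df, p = groupstats.student_t(means_a, means_b, welch=welch)
    return CentralWindowTest(
        mean_a=float(means_a.mean()),
        mean_b=float(means_b.mean()),
        t=t,
        df=df,
        p=p,
        per_profile_means_a=means_a,
        per_profile_means_b=means_b,
    )


@dataclass(frozen=True)
class ThresholdDistance:
    """Distance at which signal first reaches the background threshold.

    ``censored`` marks profiles that never reach the threshold; ``distance``
    is then the maximal measured distance (a lower bound).
    """

    distance: float
    censored: bool


def threshold_distance(
    profile: RadialProfile, cfg: ProfileConfig = ProfileConfig()
) -> ThresholdDistance:
    """Central-minimum size: first distance where the mean profile reaches
    ``background_threshold_factor`` x the center background signal.

    The center background is the distance-0 bin of the averaged profile
    (with ``cfg.background_halfwidth > 0``, the mean over all bins within
    that distance — a noise-robust alternative when the central bin rests
    on very few cells).  The crossing is linearly interpolated between
    bins, so sub-pixel values are returned.  A profile that never reaches
    the threshold is censored at its maximal measured distance.
    """
    if len(profile.distances) == 0:
        raise ValidationError("empty profile")
    if cfg.background_halfwidth > 0:
        mask = profile.distances <= cfg.background_halfwidth
        background = _nanmean_quiet(profile.mean_intensity[mask])
    else:
        background = profile.mean_intensity[0]
    if not np.isfinite(background) or background == 0:
        raise ValidationError("center background signal is zero or missing: ratio undefined")
    thr = cfg.background_threshold_factor * background
    intens = profile.mean_intensity
    above = np.asarray(intens >= thr)
    above &= np.isfinite(intens)
    if not above.any():
        return ThresholdDistance(distance=float(profile.distances[-1]), censored=True)
    j = int(np.argmax(above))
    if j == 0:
        return ThresholdDistance(distance=0.0, censored=False)
    d0, d1 = profile.distances[j - 1], profile.distances[j]
    i0, i1 = intens[j - 1], intens[j]
    if not np.isfinite(i0) or i1 == i0:
        return ThresholdDistance(distance=float(d1), censored=False)
    frac = (thr - i0) / (i1 - i0)
    return ThresholdDistance(distance=float(d0 + frac * (d1 - d0)), censored=False)


def gate_stem_cells(cells: pd.DataFrame, fit, axis, cfg: ProfileConfig = ProfileConfig()):
    """Per-cell axis distances and the stem-cell gate.

    A cell is a stem cell iff its distance to the central axis is at most
    ``stem_cell_radius_fraction * rad_sphere`` (boundary inclusive).
    Returns a copy of the table with ``dist`` (µm) and ``is_stem_cell``
    columns appended.
    """
    from .geometry import distance_to_axis  # local import to avoid cycle at module load

    if cells.empty:
        raise ValidationError("empty cell table")
    out = cells.copy()
    xyz = out[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    out["dist"] = [distance_to_axis(p, axis) for p in xyz]
    out["is_stem_cell"] = out["dist"] <= cfg.stem_cell_radius_fraction * fit.radius
    return out


def minmax_normalize(
    records: pd.DataFrame, columns: list[str], by: str | None = "meristem_id"
) -> pd.DataFrame:
    """Min-max normalize the given columns to [0, 1], independently within
    each group of ``by`` (per meristem, so different meristems and imaging
    sessions become comparable).  Appends ``<col>_norm`` columns.
    """
    out = records.copy()
    if by is not None and by in out.columns:
        items = list(out.groupby(by, sort=False))
    else:
        items = [(None, out)]
    for col in columns:
        if col not in out.columns:
            raise ValidationError(f"column {col!r} not in records")
        normed = pd.Series(index=out.index, dtype=float)
        for key, sub in items:
            vals = sub[col].to_numpy(dtype=float)
            lo, hi = np.nanmin(vals), np.nanmax(vals)
            if hi == lo:
                raise DegenerateNormalizationError(
                    f"column {col!r} constant within group {key!r}: min-max undefined"
                )
            normed.loc[sub.index] = (vals - lo) / (hi - lo)
        out[f"{col}_norm"] = normed
    return out


@dataclass(frozen=True)
class KernelProfileResult:
    """Nadaraya–Watson fit with bootstrap percentile confidence band."""

    eval_points: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    bandwidth: float


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        raise ValidationError("all distances identical: bandwidth undefined")
    return 0.9 * scale * n ** (-1 / 5)


def _nw_curves(weights: np.ndarray, kernel: np.ndarray, y: np.ndarray) -> np.ndarray:
    """NW estimates for (B, n) nonnegative case weights against (n, m) kernel."""
    num = weights @ (kernel * y[:, None])
    den = weights @ kernel
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def kernel_profile(
    distances,
    signal,
    eval_points,
    cfg: ProfileConfig = ProfileConfig(),
    seed: int | None = None,
    meristem_ids=None,
    resample: str = "cell",
) -> KernelProfileResult:
    """Kernel regression of signal on center distance, with bootstrap CI.

    Nadaraya–Watson estimate with a Gaussian kernel; bandwidth "auto" uses
    Silverman's rule of thumb on the distances.  The 95% confidence band is
    the pointwise 2.5/97.5 percentile of ``cfg.bootstrap_iterations``
    case-resampled refits.  Cells are the default resampling unit (pooled
    across meristems); ``resample="meristem"`` resamples whole meristems
    (requires ``meristem_ids``).
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("distances and signal must be matching 1D arrays")
    n = len(x)
    if n < 10:
        raise ValidationError(f"kernel regression needs >= 10 records, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("all records at one distance: regression undefined")
    ev = np.asarray(eval_points, dtype=float)

    h = _silverman_bandwidth(x) if cfg.kernel_bandwidth == "auto" else float(cfg.kernel_bandwidth)
    kernel = np.exp(-0.5 * ((x[:, None] - ev[None, :]) / h) ** 2)  # (n, m)

    estimate = _nw_curves(np.ones((1, n)), kernel, y)[0]

    rng = np.random.default_rng(seed)
    B = cfg.bootstrap_iterations
    if resample == "cell":
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
    elif resample == "meristem":
        if meristem_ids is None:
            raise ValidationError("meristem-level resampling requires meristem_ids")
        ids = np.asarray(meristem_ids)
        uniq, inverse = np.unique(ids, return_inverse=True)
        k = len(uniq)
        mcounts = rng.multinomial(k, np.full(k, 1.0 / k), size=B).astype(float)
        counts = mcounts[:, inverse]
    else:
        raise ValidationError(f"unknown resample unit {resample!r}")

    curves = _nw_curves(counts, kernel, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        lower = np.nanpercentile(curves, 2.5, axis=0)
        upper = np.nanpercentile(curves, 97.5, axis=0)
    return KernelProfileResult(
        eval_points=ev, estimate=estimate, lower=lower, upper=upper, bandwidth=h
    )


@dataclass(frozen=True)
class AnovaTukeyResult:
    f: float
    p: float
    tukey: pd.DataFrame  # columns: group_a, group_b, mean_diff, p_adj, ci_low, ci_high


def central_zone_timecourse(groups: dict[str, np.ndarray]) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD over condition x time groups of
    per-meristem central means.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(arrays)) == 0:
        # All observations identical: no variance at all, F defined as 0.
        f_stat, p = 0.0, 1.0
        rows = [
            (labels[i], labels[j], 0.0, 1.0, 0.0, 0.0)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = sps.f_oneway(*arrays)
            res = sps.tukey_hsd(*arrays)
            ci = res.confidence_interval()
        if np.isnan(f_stat):  # zero within-group variance, equal means
            f_stat, p = 0.0, 1.0
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                rows.append(
                    (
                        labels[i],
                        labels[j],
                        float(res.statistic[i, j]),
                        float(res.pvalue[i, j]),
                        float(ci.low[i, j]),
                        float(ci.high[i, j]),
                    )
                )
    table = pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "p_adj", "ci_low", "ci_high"]
    )
    return AnovaTukeyResult(f=float(f_stat), p=float(p), tukey=table)
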