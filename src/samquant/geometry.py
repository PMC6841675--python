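"""Meristem-center estimation from segmented L1 nuclei.

The shoot apical meristem (SAM) summit is well approximated by a spherical
cap.  The analysis chain here mirrors the standard confocal workflow:

1. fit a sphere through the centroids of L1 (epidermal) nuclei by least
   squared distances (:func:`fit_sphere`);
2. project three manually-picked primordium centers onto that sphere and
   take the spherical-Voronoi vertex equidistant to all three — the point
   ``P_center`` — as the meristem center (:func:`spherical_center`);
3. the central axis runs from the sphere center through ``P_center``;
   per-cell distances to this axis drive all downstream radial statistics.

The independently measured stem-cell reporter (CLV3) center
(:func:`clv3_center`) serves to validate the geometric estimate: both are
expected to agree within about one cell diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "SphereFit",
    "Axis",
    "MeristemCenter",
    "fit_sphere",
    "project_to_sphere",
    "spherical_center",
    "distance_to_axis",
    "geodesic_distance",
    "clv3_center",
    "estimate_center",
]


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere through a 3D point cloud.

    Attributes
    ----------
    center : (3,) ndarray, µm
    radius : float, µm
        ``rad_sphere`` — also the length scale for the stem-cell gate
        (cells with axis distance <= radius/4).
    rms_residual : float, µm
        Root-mean-square of the geometric residuals ``| |p - c| - r |``.
    n_points : int
    """

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        if self.rms_residual < 0:
            raise ValidationError("rms_residual must be >= 0")
        if self.n_points < 4:
            raise ValidationError("n_points must be >= 4")


@dataclass(frozen=True)
class Axis:
    """A line in 3D: ``anchor + t * direction`` with unit ``direction``."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        anchor = np.asarray(self.anchor, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise DegenerateGeometryError("axis direction has zero length")
        object.__setattr__(self, "anchor", anchor)
        object.__setattr__(self, "direction", direction / norm)


@dataclass(frozen=True)
class MeristemCenter:
    """The estimated meristem center ``P_center`` and its central axis.

    ``candidate_discarded`` keeps the antipodal circumcenter for audit: the
    spherical circumcenter construction yields two antipodal solutions and
    the one nearer the dome summit is selected.
    """

    p_center: np.ndarray
    seeds_projected: np.ndarray  # (3, 3)
    axis: Axis
    candidate_discarded: np.ndarray

    @property
    def axis_direction(self) -> np.ndarray:
        return self.axis.direction


def fit_sphere(points, refine: bool = True) -> SphereFit:
    """Fit a sphere to 3D points by least squared distances.

    Uses the algebraic (linearised) least-squares formulation: with
    ``|p|^2 = 2 c·p + (r^2 - |c|^2)`` the center and radius follow from one
    linear solve.  With ``refine=True`` (default) a single Gauss–Newton pass
    on the geometric residuals ``|p - c| - r`` polishes the estimate; the
    reported ``rms_residual`` is always geometric.

    Raises
    ------
    ValidationError
        Fewer than 4 points.
    DegenerateGeometryError
        Coplanar (or otherwise rank-deficient) configurations for which the
        sphere is not identifiable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"points must be (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain non-finite coordinates")
    n = pts.shape[0]
    if n < 4:
        raise ValidationError(f"sphere fit needs >= 4 points, got {n}")

    # Work in centered coordinates for conditioning.
    mean = pts.mean(axis=0)
    q = pts - mean
    design = np.column_stack([2.0 * q, np.ones(n)])
    rhs = np.einsum("ij,ij->i", q, q)
    if np.linalg.matrix_rank(design, tol=1e-8 * max(1.0, np.abs(design).max())) < 4:
        raise DegenerateGeometryError(
            "degenerate configuration: points are coplanar or otherwise rank-deficient"
        )
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    center = center + mean

    if refine:
        center, radius = _gauss_newton_step(pts, center, radius)

    dists = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms, n_points=n)


def _gauss_newton_step(pts: np.ndarray, center: np.ndarray, radius: float):
    """One Gauss–Newton pass on geometric residuals sum(|p-c| - r)^2."""
    diff = pts - center
    dists = np.linalg.norm(diff, axis=1)
    if np.any(dists == 0):
        return center, radius  # a point at the center: keep algebraic solution
    units = diff / dists[:, None]
    resid = dists - radius
    jac = np.column_stack([-units, -np.ones(len(pts))])
    step, *_ = np.linalg.lstsq(jac, -resid, rcond=None)
    new_center = center + step[:3]
    new_radius = radius + step[3]
    if new_radius <= 0:
        return center, radius
    return new_center, float(new_radius)


def project_to_sphere(point, fit: SphereFit) -> np.ndarray:
    """Radially project ``point`` onto the fitted sphere surface."""
    p = np.asarray(point, dtype=float)
    v = p - fit.center
    norm = np.linalg.norm(v)
    if norm == 0:
        raise DegenerateGeometryError(
            "cannot project the sphere center: projection direction undefined"
        )
    return fit.center + fit.radius * v / norm


def geodesic_distance(p, q, fit: SphereFit) -> float:
    """Great-circle distance between two points on (or near) the fitted sphere, µm."""
    u = np.asarray(p, dtype=float) - fit.center
    v = np.asarray(q, dtype=float) - fit.center
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("geodesic distance undefined at the sphere center")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(fit.radius * np.arccos(cosang))


def spherical_center(seeds, fit: SphereFit, summit_hint) -> MeristemCenter:
    """``P_center``: the on-sphere point equidistant to three primordium seeds.

    The seeds (picked near the sphere surface) are projected onto the sphere;
    the two antipodal spherical circumcenters are the intersections of the
    sphere with the line through its center along the normal of the seed
    plane.  The candidate closer to ``summit_hint`` (a point marking the dome
    summit, e.g. the projected centroid of the fitted L1 nuclei) is selected;
    the antipode is retained in ``candidate_discarded``.
    """
    seeds = np.asarray(seeds, dtype=float)
    if seeds.shape != (3, 3):
        raise ValidationError(f"exactly 3 seed points required, got shape {seeds.shape}")
    summit_hint = np.asarray(summit_hint, dtype=float)

    proj = np.array([project_to_sphere(s, fit) for s in seeds])
    rel = proj - fit.center
    normal = np.cross(rel[1] - rel[0], rel[2] - rel[0])
    nn = np.linalg.norm(normal)
    if nn < 1e-12 * fit.radius**2:
        raise DegenerateGeometryError(
            "seed projections are coincident or collinear: circumcenter undefined"
        )
    normal = normal / nn
    cand_a = fit.center + fit.radius * normal
    cand_b = fit.center - fit.radius * normal
    if np.linalg.norm(cand_a - summit_hint) <= np.linalg.norm(cand_b - summit_hint):
        p_center, discarded = cand_a, cand_b
    else:
        p_center, discarded = cand_b, cand_a
    axis = Axis(anchor=fit.center, direction=p_center - fit.center)
    return MeristemCenter(
        p_center=p_center, seeds_projected=proj, axis=axis, candidate_discarded=discarded
    )


def distance_to_axis(point, axis: Axis) -> float:
    """Perpendicular distance from a point to the (infinite) axis line, µm."""
    v = np.asarray(point, dtype=float) - axis.anchor
    return float(np.linalg.norm(np.cross(v, axis.direction)))


def clv3_center(
    cells: pd.DataFrame, channel: str, fit: SphereFit, layer: str = "L1"
) -> np.ndarray:
    """Reporter-defined meristem center: intensity-weighted centroid of L1
    cells, projected to the sphere.

    This is the reference center used to validate :func:`spherical_center`;
    the stem-cell reporter (CLV3) peaks at the true center.
    """
    if channel not in cells.columns:
        raise ValidationError(f"channel column {channel!r} not in table")
    sub = cells[cells["layer"] == layer] if layer is not None else cells
    if sub.empty:
        raise ValidationError(f"no cells in layer {layer!r}")
    weights = sub[channel].to_numpy(dtype=float)
    if np.any(weights < 0):
        raise ValidationError(f"channel {channel!r} has negative intensities")
    total = weights.sum()
    if total == 0:
        raise ValidationError(f"channel {channel!r} is all zero: centroid undefined")
    xyz = sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    centroid = (weights[:, None] * xyz).sum(axis=0) / total
    return project_to_sphere(centroid, fit)


def estimate_center(
    cells: pd.DataFrame,
    seeds,
    layer: str = "L1",
    refine: bool = True,
    summit_hint=None,
) -> tuple[SphereFit, MeristemCenter]:
    """Full center-estimation chain: sphere fit on one layer's nuclei, then
    the spherical circumcenter of three primordium seeds.

    When ``summit_hint`` is not given it defaults to the projected centroid
    of the fitted nuclei, which formalises "the summit candidate" antipode
    selection.
    """
    sub = cells[cells["layer"] == layer]
    pts = sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(pts) < 4:
        raise ValidationError(f"layer {layer!r} has {len(pts)} cells; >= 4 required")
    fit = fit_sphere(pts, refine=refine)
    if summit_hint is None:
        summit_hint = project_to_sphere(pts.mean(axis=0), fit)
    center = spherical_center(seeds, fit, summit_hint)
    return fit, center
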