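"""Seeded synthetic-data generators with recorded ground truth.

Two generators stand in for the study's raw data:

* :func:`generate_sam` builds a hemispherical dome of cells emulating a
  shoot apical meristem: L1 nuclei on a spherical cap (near-uniform
  Fibonacci-lattice spacing of about one cell diameter), optional deeper
  layers, a central stem-cell reporter field (CLV3: Gaussian peak in
  geodesic distance from the apex), a peripheral auxin-output field (DR5:
  deep central minimum around the axis with wedge maxima at the primordium
  azimuths), and multiplicative (lognormal) plus additive (Gaussian)
  intensity noise.  A top-view surface grid rasterises the L1 intensities.

* :func:`generate_interval_world` builds a toy one-chromosome genome with
  gene models, transcription-factor binding sites concentrated near
  promoters (Gaussian TSS offsets), correlated "acetylation-change"
  intervals spawned near binding sites, and open-chromatin promoter
  regions used as the enrichment background.

Every generator is fully determined by its spec (including the seed) and
writes its ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .intervals import GeneModel, IntervalSet
from .radial import SurfaceGrid

__all__ = [
    "SamSpec",
    "SamGroundTruth",
    "IntervalWorldSpec",
    "IntervalGroundTruth",
    "generate_sam",
    "generate_interval_world",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class SamSpec:
    """Parameters of a synthetic shoot apical meristem.

    Geometry is in µm, intensities in arbitrary units.  The dome radius and
    cell diameter are order-of-magnitude choices for an Arabidopsis
    inflorescence meristem (dome of a few tens of µm, nuclei ~5 µm apart)
    and stay configurable.  ``dr5_central_min_radius`` is defined as the
    radius at which the noise-free auxin-output field reaches 120% of its
    central value, i.e. exactly the quantity the 120%-threshold readout
    estimates.
    """

    dome_radius: float = 40.0
    cell_diameter: float = 5.0
    n_layers: int = 2
    summit_colatitude: float = 75.0  # degrees of cap populated with cells
    primordium_azimuths: tuple = (0.0, 137.5, 275.0)
    primordium_colatitude: float = 65.0
    clv3_amplitude: float = 1000.0
    clv3_sigma: float = 8.0  # µm, geodesic
    dr5_base: float = 500.0
    dr5_wedge_amplitude: float = 400.0
    dr5_central_min_radius: float = 15.0  # µm, axis distance
    dr5_central_min_depth: float = 0.1  # center level as fraction of base
    dr5_transition_width: float = 2.0  # µm, logistic width
    wedge_sigma_azimuth: float = 15.0  # degrees
    wedge_sigma_colat: float = 10.0  # degrees
    noise_mult_sigma: float = 0.2  # lognormal sigma
    noise_add_sigma: float = 5.0  # additive Gaussian sigma, a.u.
    position_jitter: float = 0.0  # µm radial jitter, truncated at cell_diameter/4
    grid_pixel_size: float = 1.0  # µm
    grid_channel: str = "DR5"
    center: tuple = (0.0, 0.0, 0.0)  # true sphere center, µm
    seed: int = 0

    def validate(self) -> None:
        if not self.dome_radius > self.cell_diameter > 0:
            raise ValidationError(
                f"need dome_radius > cell_diameter > 0, got dome_radius={self.dome_radius}, "
                f"cell_diameter={self.cell_diameter}"
            )
        if self.n_layers < 0:
            raise ValidationError(f"n_layers must be >= 0, got {self.n_layers}")
        if not 0 < self.summit_colatitude <= 90:
            raise ValidationError(
                f"summit_colatitude must be in (0, 90], got {self.summit_colatitude}"
            )
        for name in ("primordium_colatitude",):
            v = getattr(self, name)
            if not 0 <= v < 360:
                raise ValidationError(f"{name} must be in [0, 360), got {v}")
        for az in self.primordium_azimuths:
            if not 0 <= az < 360:
                raise ValidationError(f"primordium_azimuths must be in [0, 360), got {az}")
        for name in (
            "clv3_amplitude",
            "clv3_sigma",
            "dr5_base",
            "dr5_central_min_radius",
            "dr5_transition_width",
            "wedge_sigma_azimuth",
            "wedge_sigma_colat",
            "grid_pixel_size",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("dr5_wedge_amplitude", "noise_mult_sigma", "noise_add_sigma", "position_jitter"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 < self.dr5_central_min_depth < 1:
            raise ValidationError(
                f"dr5_central_min_depth must be in (0, 1), got {self.dr5_central_min_depth}"
            )


@dataclass(frozen=True)
class SamGroundTruth:
    """Planted truth written alongside every generated meristem."""

    sphere_center: tuple
    dome_radius: float
    apex: tuple  # true meristem center on the dome surface
    axis_direction: tuple
    primordium_seeds: tuple  # 3 x (x, y, z)
    spec: SamSpec

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = asdict(self.spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SamGroundTruth":
        spec_d = dict(d["spec"])
        spec_d["primordium_azimuths"] = tuple(spec_d["primordium_azimuths"])
        spec_d["center"] = tuple(spec_d["center"])
        return cls(
            sphere_center=tuple(d["sphere_center"]),
            dome_radius=d["dome_radius"],
            apex=tuple(d["apex"]),
            axis_direction=tuple(d["axis_direction"]),
            primordium_seeds=tuple(tuple(p) for p in d["primordium_seeds"]),
            spec=SamSpec(**spec_d),
        )


def _cap_lattice(radius: float, colatitude_deg: float, spacing: float) -> np.ndarray:
    """Near-uniform Fibonacci lattice on a spherical cap (unit sphere scaled).

    The point count follows from hexagonal packing of the cap area at the
    requested spacing, so emitted nuclei counts are fully determined by the
    spec (no silent drops).
    """
    theta_c = math.radians(colatitude_deg)
    cap_area = 2 * math.pi * radius**2 * (1 - math.cos(theta_c))
    per_point = (math.sqrt(3) / 2) * spacing**2
    n = max(4, int(round(cap_area / per_point)))
    i = np.arange(n)
    z = 1 - (1 - math.cos(theta_c)) * (i + 0.5) / n  # cos(theta), apex downward sweep
    phi = i * _GOLDEN_ANGLE
    sin_t = np.sqrt(np.clip(1 - z**2, 0, None))
    pts = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), z])
    return radius * pts


def _dr5_logistic_offset(spec: SamSpec) -> float:
    """Logistic midpoint such that the clean field crosses 120% of its
    central value exactly at ``dr5_central_min_radius``."""
    depth = spec.dr5_central_min_depth
    target = 0.2 * depth / (1 - depth)  # sigmoid value at the crossing
    if not 0 < target < 1:
        raise ValidationError("dr5_central_min_depth incompatible with the 120% readout")
    return spec.dr5_central_min_radius - spec.dr5_transition_width * math.log(
        target / (1 - target)
    )


def _clean_fields(xyz: np.ndarray, spec: SamSpec) -> dict[str, np.ndarray]:
    """Noise-free CLV3 / DR5 intensities at 3D positions."""
    center = np.asarray(spec.center, dtype=float)
    rel = xyz - center
    rho = np.hypot(rel[:, 0], rel[:, 1])  # axis distance
    r3 = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        cos_t = np.where(r3 > 0, rel[:, 2] / np.maximum(r3, 1e-300), 1.0)
    theta = np.arccos(np.clip(cos_t, -1, 1))
    geo = spec.dome_radius * theta  # geodesic distance from the apex
    clv3 = spec.clv3_amplitude * np.exp(-(geo**2) / (2 * spec.clv3_sigma**2))

    depth = spec.dr5_central_min_depth
    rho0 = _dr5_logistic_offset(spec)
    sig = 1.0 / (1.0 + np.exp(-(rho - rho0) / spec.dr5_transition_width))
    dr5 = spec.dr5_base * (depth + (1 - depth) * sig)

    if spec.dr5_wedge_amplitude > 0:
        az = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
        colat = np.degrees(theta)
        for p_az in spec.primordium_azimuths:
            d_az = (az - p_az + 180.0) % 360.0 - 180.0
            d_co = colat - spec.primordium_colatitude
            dr5 = dr5 + spec.dr5_wedge_amplitude * np.exp(
                -(d_az**2) / (2 * spec.wedge_sigma_azimuth**2)
                - (d_co**2) / (2 * spec.wedge_sigma_colat**2)
            )
    return {"CLV3": clv3, "DR5": dr5}


def _apply_noise(clean: np.ndarray, spec: SamSpec, rng: np.random.Generator) -> np.ndarray:
    mult = rng.lognormal(mean=0.0, sigma=spec.noise_mult_sigma, size=clean.shape)
    add = rng.normal(0.0, spec.noise_add_sigma, size=clean.shape)
    return np.clip(clean * mult + add, 0.0, None)


def _primordium_seeds(spec: SamSpec) -> np.ndarray:
    center = np.asarray(spec.center, dtype=float)
    theta = math.radians(spec.primordium_colatitude)
    seeds = []
    for az in spec.primordium_azimuths:
        phi = math.radians(az)
        seeds.append(
            center
            + spec.dome_radius
            * np.array(
                [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
            )
        )
    return np.array(seeds)


def generate_sam(spec: SamSpec) -> tuple[pd.DataFrame, SurfaceGrid, SamGroundTruth]:
    """Generate one synthetic meristem.

    Returns the per-nucleus table (``cell_id, x_um, y_um, z_um, layer,
    CLV3, DR5``), the top-view surface grid of the ``spec.grid_channel``
    intensities, and the planted ground truth.  Identical spec (including
    seed) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.center, dtype=float)

    frames = []
    for layer_idx in range(spec.n_layers + 1):
        radius = spec.dome_radius - layer_idx * spec.cell_diameter
        if radius <= spec.cell_diameter:
            break
        pts = _cap_lattice(radius, spec.summit_colatitude, spec.cell_diameter) + center
        if spec.position_jitter > 0:
            # Radial jitter truncated so L1 nuclei stay within cell_diameter/4
            # of the true sphere.
            jit = rng.normal(0.0, spec.position_jitter, size=len(pts))
            jit = np.clip(jit, -spec.cell_diameter / 4, spec.cell_diameter / 4)
            units = (pts - center) / np.linalg.norm(pts - center, axis=1)[:, None]
            pts = pts + units * jit[:, None]
        label = "L1" if layer_idx == 0 else ("L2" if layer_idx == 1 else "inner")
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{label}_{layer_idx}_{i:04d}" for i in range(len(pts))],
                    "x_um": pts[:, 0],
                    "y_um": pts[:, 1],
                    "z_um": pts[:, 2],
                    "layer": label,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    xyz = table[["x_um", "y_um", "z_um"]].to_numpy()
    clean = _clean_fields(xyz, spec)
    for channel in ("CLV3", "DR5"):
        table[channel] = _apply_noise(clean[channel], spec, rng)

    grid = _rasterize_surface(table, spec)

    truth = SamGroundTruth(
        sphere_center=tuple(center),
        dome_radius=spec.dome_radius,
        apex=tuple(center + np.array([0.0, 0.0, spec.dome_radius])),
        axis_direction=(0.0, 0.0, 1.0),
        primordium_seeds=tuple(tuple(s) for s in _primordium_seeds(spec)),
        spec=spec,
    )
    return table, grid, truth


def _rasterize_surface(table: pd.DataFrame, spec: SamSpec) -> SurfaceGrid:
    """Top-view rasterisation: each pixel takes the intensity of the nearest
    L1 nucleus (radial max-projection of the L1 mosaic); pixels farther than
    one cell diameter from any L1 nucleus are background (0)."""
    if spec.grid_channel not in table.columns:
        raise ValidationError(f"grid_channel {spec.grid_channel!r} not generated")
    l1 = table[table["layer"] == "L1"]
    xy = l1[["x_um", "y_um"]].to_numpy()
    values = l1[spec.grid_channel].to_numpy()
    cx, cy = spec.center[0], spec.center[1]
    extent = spec.dome_radius + spec.cell_diameter
    px = spec.grid_pixel_size
    n = int(math.ceil(2 * extent / px)) + 1
    x0, y0 = cx - extent, cy - extent
    xs = x0 + np.arange(n) * px
    ys = y0 + np.arange(n) * px
    gx, gy = np.meshgrid(xs, ys)  # gy varies along rows
    tree = cKDTree(xy)
    dist, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), k=1)
    vals = np.where(dist <= spec.cell_diameter, values[idx], 0.0)
    return SurfaceGrid(data=vals.reshape(n, n), pixel_size=px, origin=(x0, y0))


# ---------------------------------------------------------------------------
# Toy genomic-interval world
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalWorldSpec:
    """Parameters of the toy genome (single chromosome, bp units).

    Binding-site midpoints are drawn Normal(TSS, ``binding_offset_sigma``)
    in the gene's strand orientation; each binding site spawns a linked
    "acetylation-decrease" interval nearby with probability ``p_link``.
    Independent background intervals model unrelated chromatin changes.
    Posterior scores come from a Beta distribution skewed toward 1, so the
    0.9 posterior filter has work to do.
    """

    genome_length: int = 2_000_000
    chrom: str = "chr1"
    n_genes: int = 300
    gene_length_mean: float = 2000.0  # lognormal, bp
    gene_length_sigma: float = 0.5
    n_binding_sites: int = 300
    binding_offset_sigma: float = 500.0  # bp from TSS
    binding_width_mean: float = 200.0
    binding_width_sd: float = 30.0
    p_link: float = 0.6
    linked_offset_sigma: float = 300.0  # bp between site and linked interval
    acet_width_mean: float = 500.0
    acet_width_sd: float = 100.0
    n_acet_background_up: int = 120
    n_acet_background_down: int = 80
    posterior_alpha: float = 9.0
    posterior_beta: float = 1.0
    open_chrom_prob: float = 0.7
    open_chrom_upstream: int = 1000
    open_chrom_downstream: int = 500
    seed: int = 0

    def validate(self) -> None:
        for name in ("genome_length", "n_genes", "n_binding_sites"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("n_acet_background_up", "n_acet_background_down"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.p_link <= 1:
            raise ValidationError(f"p_link must be in [0, 1], got {self.p_link}")
        if not 0 <= self.open_chrom_prob <= 1:
            raise ValidationError(f"open_chrom_prob must be in [0, 1], got {self.open_chrom_prob}")
        for name in (
            "gene_length_mean",
            "binding_offset_sigma",
            "binding_width_mean",
            "acet_width_mean",
            "posterior_alpha",
            "posterior_beta",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class IntervalGroundTruth:
    """Planted truth of the toy genome."""

    spec: IntervalWorldSpec
    binding_parent_gene: tuple  # gene index per binding site
    binding_tss_offset: tuple  # signed strand-aware offset drawn per site
    linked_parent_site: tuple  # binding-site index per linked acetylation interval
    open_genes: tuple  # gene ids with an open-chromatin promoter
    bound_genes: tuple  # gene ids that received >= 1 binding site

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = asdict(self.spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalGroundTruth":
        return cls(
            spec=IntervalWorldSpec(**d["spec"]),
            binding_parent_gene=tuple(d["binding_parent_gene"]),
            binding_tss_offset=tuple(d["binding_tss_offset"]),
            linked_parent_site=tuple(d["linked_parent_site"]),
            open_genes=tuple(d["open_genes"]),
            bound_genes=tuple(d["bound_genes"]),
        )


def _make_interval(
    chrom: str, mid: float, width: float, genome_length: int, name: str, score: float
) -> tuple:
    half = max(1, int(round(width / 2)))
    start = int(round(mid)) - half
    end = int(round(mid)) + half
    start = max(0, min(start, genome_length - 2))
    end = max(start + 1, min(end, genome_length - 1))
    return (chrom, start, end, name, score)


def generate_interval_world(
    spec: IntervalWorldSpec,
) -> tuple[list[GeneModel], IntervalSet, IntervalSet, IntervalSet, IntervalSet, IntervalGroundTruth]:
    """Generate the toy genome.

    Returns ``(genes, binding, acet_up, acet_down, open_chromatin, truth)``.
    All intervals are 0-based half-open, sorted, within the genome; posterior
    scores are attached to binding and acetylation intervals.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length

    lengths = rng.lognormal(math.log(spec.gene_length_mean), spec.gene_length_sigma, spec.n_genes)
    lengths = np.clip(lengths, 200, 20_000).astype(np.int64)
    slack = L - int(lengths.sum())
    if slack <= spec.n_genes:
        raise ValidationError(
            f"genome_length {L} too short for {spec.n_genes} genes totalling {lengths.sum()} bp"
        )
    gaps = rng.exponential(slack / (spec.n_genes + 1), spec.n_genes + 1)
    gaps = np.floor(gaps * (slack / gaps.sum())).astype(np.int64)
    strands = rng.choice(["+", "-"], size=spec.n_genes)

    genes: list[GeneModel] = []
    pos = 0
    for i in range(spec.n_genes):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        if end >= L:
            raise ValidationError("genome_length too short for the requested gene layout")
        n_ex = int(rng.integers(1, 5))
        exons = _split_exons(start, end, n_ex, rng)
        genes.append(
            GeneModel(
                chrom=spec.chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
                gene_id=f"g{i:04d}",
                exons=exons,
            )
        )
        pos = end

    tss = np.array([g.tss for g in genes])
    sign = np.array([1 if g.strand == "+" else -1 for g in genes])

    parent = rng.integers(0, spec.n_genes, size=spec.n_binding_sites)
    offsets = rng.normal(0.0, spec.binding_offset_sigma, size=spec.n_binding_sites)
    widths = np.clip(
        rng.normal(spec.binding_width_mean, spec.binding_width_sd, spec.n_binding_sites), 50, None
    )
    posteriors = rng.beta(spec.posterior_alpha, spec.posterior_beta, spec.n_binding_sites)
    binding_rows = []
    for k in range(spec.n_binding_sites):
        mid = tss[parent[k]] + sign[parent[k]] * offsets[k]
        binding_rows.append(
            _make_interval(spec.chrom, mid, widths[k], L, "binding", posteriors[k])
        )
    binding = IntervalSet(pd.DataFrame(binding_rows, columns=["chrom", "start", "end", "name", "score"]))

    # Linked acetylation-decrease intervals near binding sites.
    link_draws = rng.random(spec.n_binding_sites)
    linked_rows, linked_parents = [], []
    for k in range(spec.n_binding_sites):
        off = rng.normal(0.0, spec.linked_offset_sigma)
        w = max(100.0, rng.normal(spec.acet_width_mean, spec.acet_width_sd))
        post = rng.beta(spec.posterior_alpha, spec.posterior_beta)
        if link_draws[k] < spec.p_link:
            mid = tss[parent[k]] + sign[parent[k]] * offsets[k] + off
            linked_rows.append(_make_interval(spec.chrom, mid, w, L, "down", post))
            linked_parents.append(k)

    def _background(n: int, label: str) -> list[tuple]:
        mids = rng.uniform(0, L, size=n)
        ws = np.maximum(100.0, rng.normal(spec.acet_width_mean, spec.acet_width_sd, n))
        posts = rng.beta(spec.posterior_alpha, spec.posterior_beta, n)
        return [_make_interval(spec.chrom, m, w, L, label, p) for m, w, p in zip(mids, ws, posts)]

    down_rows = linked_rows + _background(spec.n_acet_background_down, "down")
    up_rows = _background(spec.n_acet_background_up, "up")
    cols = ["chrom", "start", "end", "name", "score"]
    acet_down = IntervalSet(pd.DataFrame(down_rows, columns=cols))
    acet_up = IntervalSet(pd.DataFrame(up_rows, columns=cols))

    open_flags = rng.random(spec.n_genes) < spec.open_chrom_prob
    open_rows = []
    open_genes = []
    for i, g in enumerate(genes):
        if not open_flags[i]:
            continue
        if g.strand == "+":
            s, e = g.tss - spec.open_chrom_upstream, g.tss + spec.open_chrom_downstream
        else:
            s, e = g.tss - spec.open_chrom_downstream, g.tss + spec.open_chrom_upstream
        s, e = max(0, s), min(L - 1, e)
        if e > s:
            open_rows.append((spec.chrom, s, e, g.gene_id, np.nan))
            open_genes.append(g.gene_id)
    open_chromatin = IntervalSet(pd.DataFrame(open_rows, columns=cols))

    truth = IntervalGroundTruth(
        spec=spec,
        binding_parent_gene=tuple(int(p) for p in parent),
        binding_tss_offset=tuple(float(o) for o in offsets),
        linked_parent_site=tuple(linked_parents),
        open_genes=tuple(open_genes),
        bound_genes=tuple(sorted({genes[p].gene_id for p in parent})),
    )
    return genes, binding, acet_up, acet_down, open_chromatin, truth


def _split_exons(start: int, end: int, n_ex: int, rng: np.random.Generator) -> tuple:
    """Partition a gene span into alternating exons/introns (>= 50 bp each
    where the span allows)."""
    span = end - start
    if n_ex == 1 or span < (2 * n_ex - 1) * 50:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_ex - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [span]])
    exons = []
    for j in range(0, len(bounds) - 1, 2):
        s, e = start + int(bounds[j]), start + int(bounds[j + 1])
        if e > s:
            exons.append((s, e))
    return tuple(exons) if exons else ((start, end),)
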