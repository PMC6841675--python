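"""Reproducibility benchmarks: planted-truth recovery and statistical
calibration of the whole pipeline, computed from scratch on synthetic data.

Each function runs one self-contained study — exactness of the sphere fit,
equidistance of the spherical circumcenter, center-recovery accuracy
against the reporter-derived reference, calibration of the central-window
t-test and the kernel-regression bootstrap, agreement of the exact tests
with enumeration oracles, and interval-algebra correctness against
per-base oracles — and returns plain numbers.  The test suite asserts on
them; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import math
import tempfile

import numpy as np
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from . import intervals as iv
from .geometry import clv3_center, estimate_center, fit_sphere, geodesic_distance
from .groupstats import ContingencyTable2x2, chi_square, fisher_exact
from .pipeline import PipelineConfig, run_pipeline
from .radial import (
    ProfileConfig,
    SurfaceGrid,
    central_window_test,
    cross_section_profiles,
    kernel_profile,
    threshold_distance,
)
from .synthetic import IntervalWorldSpec, SamSpec, generate_interval_world, generate_sam

# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def sphere_fit_exactness(seed: int, n_poses: int = 20) -> dict:
    """Noise-free sphere recovery and rigid-motion equivariance errors (µm)."""
    rng = np.random.default_rng(seed)
    max_center = max_radius = max_equiv = 0.0
    for k in range(n_poses):
        center = rng.uniform(-100, 100, 3)
        radius = rng.uniform(5, 80)
        v = rng.normal(size=(16, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = center + radius * v
        fit = fit_sphere(pts)
        max_center = max(max_center, float(np.linalg.norm(fit.center - center)))
        max_radius = max(max_radius, abs(fit.radius - radius))

        rot = Rotation.random(random_state=(seed * 1000 + k) % (2**31)).as_matrix()
        shift = rng.uniform(-100, 100, 3)
        fit2 = fit_sphere(pts @ rot.T + shift)
        max_equiv = max(
            max_equiv, float(np.linalg.norm(fit2.center - (rot @ fit.center + shift)))
        )
        max_equiv = max(max_equiv, abs(fit2.radius - fit.radius))
    return {
        "max_center_error_um": max_center,
        "max_radius_error_um": max_radius,
        "max_equivariance_error_um": max_equiv,
        "n": n_poses,
    }


def circumcenter_equidistance(seed: int, n_triples: int = 1000, n_bruteforce: int = 20) -> dict:
    """Equidistance of P_center to its three projected seeds over random
    seed triples, plus a 0.1°-grid brute-force cross-check on a subset."""
    from .geometry import spherical_center

    rng = np.random.default_rng(seed)
    radius = 40.0
    v = rng.normal(size=(16, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    fit = fit_sphere(radius * v)

    max_rel = 0.0
    centers = []
    triples = []
    for _ in range(n_triples):
        while True:
            seeds = rng.normal(size=(3, 3))
            seeds = radius * seeds / np.linalg.norm(seeds, axis=1)[:, None]
            seeds = seeds + rng.normal(0, 2.0, (3, 3))
            try:
                mc = spherical_center(seeds, fit, summit_hint=rng.normal(size=3) * radius)
                break
            except Exception:
                continue
        d = [geodesic_distance(mc.p_center, s, fit) for s in mc.seeds_projected]
        max_rel = max(max_rel, (max(d) - min(d)) / radius)
        centers.append(mc.p_center)
        triples.append(mc.seeds_projected)

    # brute force: 0.1-degree sphere grid, minimize the equidistance spread
    th = np.radians(np.arange(0.05, 180, 0.1))
    ph = np.radians(np.arange(0.05, 360, 0.1))
    cos_t, sin_t = np.cos(th), np.sin(th)
    max_gap = 0.0
    for i in range(n_bruteforce):
        seeds_u = triples[i] / radius
        # angular distance on the sphere, factorized over the lat/lon grid
        best = (np.inf, None)
        # evaluate in latitude stripes to bound memory
        for j0 in range(0, len(th), 300):
            sl = slice(j0, j0 + 300)
            x = sin_t[sl][:, None] * np.cos(ph)[None, :]
            y = sin_t[sl][:, None] * np.sin(ph)[None, :]
            z = np.broadcast_to(cos_t[sl][:, None], x.shape)
            ang = [
                np.arccos(np.clip(x * s[0] + y * s[1] + z * s[2], -1, 1)) for s in seeds_u
            ]
            spread = np.maximum(np.maximum(ang[0], ang[1]), ang[2]) - np.minimum(
                np.minimum(ang[0], ang[1]), ang[2]
            )
            k = np.unravel_index(np.argmin(spread), spread.shape)
            if spread[k] < best[0]:
                best = (float(spread[k]), np.array([x[k], y[k], z[k]]) * radius)
        cand = best[1]
        if cand @ centers[i] < 0:
            cand = -cand  # grid minimum may land on the antipodal solution
        max_gap = max(max_gap, geodesic_distance(cand, centers[i], fit))
    return {
        "max_equidistance_spread_rel": max_rel,
        "max_bruteforce_gap_um": max_gap,
        "grid_step_um": radius * math.radians(0.1),
        "n": n_triples,
    }


def center_accuracy(seed: int, n_meristems: int = 100) -> dict:
    """Geodesic distance between the geometric center estimate and the
    reporter-derived center on synthetic meristems at default noise."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_meristems)
    within = 0
    errors = []
    for s in sub_seeds:
        spec = SamSpec(seed=int(s))
        table, _, truth = generate_sam(spec)
        fit, mc = estimate_center(table, np.array(truth.primordium_seeds))
        cc = clv3_center(table, "CLV3", fit)
        err = geodesic_distance(cc, mc.p_center, fit)
        errors.append(err)
        within += err < spec.cell_diameter
    nine = sum(
        1
        for s in range(9)
        if _one_center_error(s) < SamSpec().cell_diameter
    )
    return {
        "fraction_within_cell_diameter": within / n_meristems,
        "median_error_um": float(np.median(errors)),
        "nine_seed_successes": nine,
        "n": n_meristems,
    }


def _one_center_error(seed: int) -> float:
    table, _, truth = generate_sam(SamSpec(seed=seed))
    fit, mc = estimate_center(table, np.array(truth.primordium_seeds))
    cc = clv3_center(table, "CLV3", fit)
    return geodesic_distance(cc, mc.p_center, fit)


# ---------------------------------------------------------------------------
# radial profiling
# ---------------------------------------------------------------------------


def _radial_grid(func, extent=40.0, px=0.5):
    n = int(2 * extent / px) + 1
    xs = -extent + np.arange(n) * px
    gx, gy = np.meshgrid(xs, xs)
    return SurfaceGrid(data=func(np.hypot(gx, gy)), pixel_size=px, origin=(-extent, -extent))


def profiling_closed_forms() -> dict:
    """Rotation invariance on a symmetric grid and the two closed-form
    threshold distances (linear ramp, inverted-Gaussian well)."""
    grid = _radial_grid(lambda r: 100.0 * np.exp(-(r**2) / (2 * 100.0**2)), px=0.1)
    p = cross_section_profiles(grid, np.array([0.0, 0.0]))
    inner = p.distances <= 35
    spread = np.nanmax(p.per_section[:, inner], axis=0) - np.nanmin(
        p.per_section[:, inner], axis=0
    )
    invariance = float(np.max(spread) / 100.0)

    ramp = _radial_grid(lambda r: 10.0 * (1 + r / 100.0), extent=40.0, px=0.5)
    t_ramp = threshold_distance(cross_section_profiles(ramp, np.array([0.0, 0.0])))

    well = _radial_grid(
        lambda r: 50.0 * (2 - np.exp(-(r**2) / (2 * 20.0**2))), extent=40.0, px=0.5
    )
    t_well = threshold_distance(cross_section_profiles(well, np.array([0.0, 0.0])))
    return {
        "rotation_invariance_max_rel": invariance,
        "threshold_linear_ramp_um": t_ramp.distance,
        "threshold_gaussian_well_um": t_well.distance,
        "threshold_gaussian_well_expected_um": 20.0 * math.sqrt(2 * math.log(1.25)),
    }


def threshold_recovery(seed: int, n_seeds: int = 51) -> dict:
    """Median 120%-threshold distance across synthetic meristems at default
    noise vs. the planted central-minimum radius.

    Uses the noise-robust background option (mean over the central 2.5 µm
    rather than the single distance-0 bin), since the central bin rests on
    one cell patch whose multiplicative noise would otherwise dominate.
    """
    cfg = ProfileConfig(background_halfwidth=2.5)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_seeds)
    vals = []
    for s in sub:
        spec = SamSpec(seed=int(s))
        _, grid, _ = generate_sam(spec)
        p = cross_section_profiles(grid, np.array([0.0, 0.0]), cfg)
        vals.append(threshold_distance(p, cfg).distance)
    return {
        "median_threshold_um": float(np.median(vals)),
        "planted_radius_um": SamSpec().dr5_central_min_radius,
        "pixel_size_um": SamSpec().grid_pixel_size,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# statistical calibration
# ---------------------------------------------------------------------------


def window_test_type1(seed: int, n_sim: int = 2000, group_size: int = 3) -> dict:
    """Type-I error of the central-window t-test on null synthetic groups
    (same generator, different seeds)."""
    rng = np.random.default_rng(seed)

    def one_profile(s):
        _, grid, _ = generate_sam(SamSpec(seed=int(s)))
        return cross_section_profiles(grid, np.array([0.0, 0.0]))

    rejections = 0
    for _ in range(n_sim):
        seeds = rng.integers(0, 2**31 - 1, size=2 * group_size)
        a = [one_profile(s) for s in seeds[:group_size]]
        b = [one_profile(s) for s in seeds[group_size:]]
        rejections += central_window_test(a, b).p < 0.05
    return {"rejection_rate": rejections / n_sim, "n": n_sim}


def kernel_ci_coverage(seed: int, n_mc: int = 200, B: int = 2000, n_cells: int = 200) -> dict:
    """Pointwise bootstrap CI coverage of a known linear signal, at interior
    evaluation points, across Monte-Carlo replicates.  The record count
    matches the pooled four-meristem scale of the per-cell analyses."""
    rng = np.random.default_rng(seed)
    ev = np.array([5.0, 10.0, 15.0])
    cfg = ProfileConfig(kernel_bandwidth=2.0, bootstrap_iterations=B)
    cover = np.zeros(len(ev))
    for _ in range(n_mc):
        x = rng.uniform(0, 20, n_cells)
        y = 2 * x + rng.normal(0, 1.0, n_cells)
        res = kernel_profile(x, y, ev, cfg, seed=int(rng.integers(2**31)))
        cover += (res.lower <= 2 * ev) & (2 * ev <= res.upper)
    return {"coverage": float(np.mean(cover / n_mc)), "n": n_mc, "bootstrap_B": B}


def _enumeration_fisher_p(a, b, c, d):
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    probs = [math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


def fisher_vs_enumeration(max_total: int = 30) -> dict:
    """Exhaustive sweep: Fisher p equals the brute-force enumeration over
    every 2x2 table with grand total (hence every margin) <= max_total."""
    max_diff = 0.0
    n_tables = 0
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    _, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
                    p_ref = _enumeration_fisher_p(a, b, c, d)
                    max_diff = max(max_diff, abs(p - min(1.0, p_ref)))
                    n_tables += 1
    return {"max_abs_diff": max_diff, "n": n_tables}


def chi_square_vs_hand() -> dict:
    """Pearson statistic against hand-computed expected tables."""
    tables = [(42, 678, 82, 535), (3, 51, 2, 367), (10, 20, 30, 40), (1, 1, 1, 1)]
    max_diff = 0.0
    for a, b, c, d in tables:
        stat, _ = chi_square(ContingencyTable2x2(a, b, c, d))
        n = a + b + c + d
        hand = 0.0
        for obs, r, col in ((a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c),
                            (d, c + d, b + d)):
            e = r * col / n
            hand += (obs - e) ** 2 / e
        max_diff = max(max_diff, abs(stat - hand))
    return {"max_abs_diff": max_diff, "n": len(tables)}


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def interval_algebra(seed: int, n_instances: int = 1000) -> dict:
    """Reduction vs per-base boolean oracle; conflict-filter minimum gap by
    brute force; Venn conservation on the toy genome."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, 30))
        starts = rng.integers(0, 960, n)
        ends = starts + rng.integers(1, 40, n)
        df = pd.DataFrame({"chrom": "c", "start": starts, "end": ends})
        s = iv.IntervalSet(df)
        out = iv.reduce_intervals(s)
        mask = np.zeros(1000, bool)
        for a, b in zip(starts, ends):
            mask[a:b] = True
        ok_cover = out.covered_bases() == int(mask.sum())
        padded = np.concatenate([[False], mask, [False]])
        ok_count = len(out) == int(np.sum(np.diff(padded.astype(int)) == 1))
        mismatches += not (ok_cover and ok_count and out.is_reduced)

    genes, binding, up, down, oc, truth = generate_interval_world(IntervalWorldSpec(seed=seed))
    up_r = iv.reduce_intervals(iv.filter_posterior(up))
    down_r = iv.reduce_intervals(iv.filter_posterior(down))
    up_k, down_k, _ = iv.conflict_filter(up_r, down_r)
    min_gap = math.inf
    for ru in up_k:
        for rd in down_k:
            min_gap = min(min_gap, max(0, max(rd.start - ru.end, ru.start - rd.end)))
    if not np.isfinite(min_gap):
        min_gap = -1.0  # one side empty: no constraint to violate

    binding_r = iv.reduce_intervals(binding)
    counts = iv.overlap_sets(binding_r, up_k, down_k)
    venn_violations = sum(
        sum(c.values()) != len(s)
        for c, s in zip(counts.values(), (binding_r, up_k, down_k))
    )
    return {
        "reduce_mismatches": mismatches,
        "conflict_min_gap_bp": float(min_gap),
        "venn_conservation_violations": venn_violations,
        "n": n_instances,
    }


def metaprofile_mass(seed: int) -> dict:
    """Fraction of binding midpoints in the promoter window vs. the
    analytic Normal mass implied by the planted TSS-offset distribution."""
    genes, binding, *_, truth = generate_interval_world(IntervalWorldSpec(seed=seed))
    sigma = truth.spec.binding_offset_sigma
    d = iv.signed_tss_distances(binding, genes)
    frac = float(np.mean((d >= -2500) & (d <= 1000)))
    mass = float(sps.norm.cdf(1000, 0, sigma) - sps.norm.cdf(-2500, 0, sigma))
    n = len(d)
    return {
        "window_fraction": frac,
        "analytic_mass": mass,
        "abs_error": abs(frac - mass),
        "binomial_3sigma": 3 * math.sqrt(mass * (1 - mass) / n),
        "n": n,
    }


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def pipeline_determinism(seed: int) -> dict:
    """Two full pipeline runs with the same config must hash identically."""
    seeds = {"sam": seed, "intervals": seed + 1, "bootstrap": seed + 2}
    with tempfile.TemporaryDirectory() as tmp:
        m1 = run_pipeline(PipelineConfig(out_dir=f"{tmp}/r1", seeds=seeds, log_level="WARNING"))
        m2 = run_pipeline(PipelineConfig(out_dir=f"{tmp}/r2", seeds=seeds, log_level="WARNING"))
    return {
        "identical": int(m1["stages"] == m2["stages"]),
        "n": sum(len(v) for v in m1["stages"].values()),
    }
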