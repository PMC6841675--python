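"""Genomic-interval post-processing for ChIP-derived regions.

Implements the interval rules applied downstream of the domain caller:
posterior filtering (keep score > 0.9), reduction (merge overlapping or
adjacent regions), removal of opposite-direction conflicts closer than a
minimum gap (default 73 bp, about half a nucleosome), promoter-window
annotation (2500 bp upstream / 1000 bp downstream of the TSS), three-set
Venn overlaps, strand-aware TSS metaprofiles with bootstrap confidence
bands, and Fisher-exact enrichment of a gene class against a background
universe (e.g. open-chromatin genes).

All coordinates are BED-style: 0-based, half-open, per chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import groupstats
from .errors import ValidationError

__all__ = [
    "IntervalSet",
    "GeneModel",
    "AnnotationConfig",
    "filter_posterior",
    "reduce_intervals",
    "conflict_filter",
    "annotate",
    "overlap_sets",
    "tss_metaprofile",
    "enrichment_2x2",
    "MetaprofileResult",
]

_COLUMNS = ["chrom", "start", "end", "name", "score"]


class IntervalSet:
    """A sorted set of strand-free genomic intervals.

    Backed by a DataFrame with columns ``chrom, start, end, name, score``;
    ``score`` carries the caller's posterior probability (NaN if absent) and
    ``name`` a free label (e.g. the direction of a histone-mark change).
    Intervals are 0-based half-open and kept sorted by (chrom, start, end).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("name", "score"):
            if col not in df.columns:
                df[col] = "." if col == "name" else np.nan
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValidationError(f"interval table missing columns {missing}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValidationError(
                f"malformed interval {row['chrom']}:{row['start']}-{row['end']} "
                "(need 0 <= start < end)"
            )
        df = df[_COLUMNS].sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        return cls(pd.DataFrame(records, columns=_COLUMNS[: len(records[0])] if records else _COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    @property
    def is_reduced(self) -> bool:
        """True if intervals are pairwise disjoint and non-adjacent per chromosome."""
        for _, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if len(starts) > 1 and np.any(starts[1:] <= ends[:-1]):
                return False
        return True

    def covered_bases(self) -> int:
        total = 0
        for _, sub in self.df.groupby("chrom", sort=False):
            pos = 0
            cur = -1
            for s, e in zip(sub["start"], sub["end"]):
                s = max(s, cur)
                if e > s:
                    pos += e - s
                    cur = e
                else:
                    cur = max(cur, e)
            total += pos
        return total


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand and optional sub-features (half-open bp).

    TSS is ``start`` on the + strand, ``end`` on the - strand.  Exon/UTR
    sub-spans, when present, must nest within the gene span; introns are the
    gaps between exons.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exons: tuple = ()
    five_utr: tuple | None = None
    three_utr: tuple | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: need 0 <= start < end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class AnnotationConfig:
    """Promoter-window annotation parameters (bp).

    ``upstream_bp``/``downstream_bp`` extend the gene span strand-aware;
    ``priority`` resolves overlapping categories, highest first.
    """

    upstream_bp: int = 2500
    downstream_bp: int = 1000
    priority: tuple = ("upstream", "5utr", "exon", "intron", "3utr", "downstream", "intergenic")

    def __post_init__(self):
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValidationError("annotation windows must be >= 0")


def filter_posterior(s: IntervalSet, threshold: float = 0.9) -> IntervalSet:
    """Keep intervals with posterior probability strictly greater than
    ``threshold`` (the caller's "higher than 0.9" rule)."""
    if s.df["score"].isna().any():
        raise ValidationError("posterior scores missing for some intervals")
    return IntervalSet(s.df[s.df["score"] > threshold])


def reduce_intervals(s: IntervalSet) -> IntervalSet:
    """Merge overlapping or adjacent (zero-gap abutting) intervals.

    The output is disjoint, sorted and non-adjacent; per-interval scores and
    labels do not survive merging (score NaN, name '.').
    """
    rows = []
    for chrom, sub in s.df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for st, en in zip(starts[1:], ends[1:]):
            if st <= cur_e:  # overlap or abutment
                cur_e = max(cur_e, en)
            else:
                rows.append((chrom, cur_s, cur_e, ".", np.nan))
                cur_s, cur_e = st, en
        rows.append((chrom, cur_s, cur_e, ".", np.nan))
    return IntervalSet(pd.DataFrame(rows, columns=_COLUMNS))


def _pairwise_gaps(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Gap matrix between interval sets on one chromosome; 0 when overlapping."""
    a_s = a["start"].to_numpy()[:, None]
    a_e = a["end"].to_numpy()[:, None]
    b_s = b["start"].to_numpy()[None, :]
    b_e = b["end"].to_numpy()[None, :]
    return np.maximum(0, np.maximum(b_s - a_e, a_s - b_e))


def conflict_filter(
    up: IntervalSet, down: IntervalSet, min_gap: int = 73
) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    """Remove opposite-direction conflicts: any up/down pair of intervals
    whose gap is strictly less than ``min_gap`` bp has BOTH members removed.

    The gap between overlapping intervals is 0; otherwise it is the distance
    between the nearest interval ends.  A pair at exactly ``min_gap`` is
    kept (strict "closer than" reading).  Both inputs must be reduced.

    Returns ``(up_kept, down_kept, removed)`` where ``removed`` carries the
    direction in its ``name`` column.
    """
    for label, s in (("up", up), ("down", down)):
        if not s.is_reduced:
            raise ValidationError(f"{label} set must be reduced before conflict filtering")
    drop_up = np.zeros(len(up), dtype=bool)
    drop_down = np.zeros(len(down), dtype=bool)
    up_idx = {c: g for c, g in up.df.groupby("chrom", sort=False)}
    down_idx = {c: g for c, g in down.df.groupby("chrom", sort=False)}
    for chrom in set(up_idx) & set(down_idx):
        ga, gb = up_idx[chrom], down_idx[chrom]
        gaps = _pairwise_gaps(ga, gb)
        conflict = gaps < min_gap
        drop_up[ga.index[conflict.any(axis=1)]] = True
        drop_down[gb.index[conflict.any(axis=0)]] = True
    removed_up = up.df[drop_up].assign(name="up")
    removed_down = down.df[drop_down].assign(name="down")
    removed = pd.concat([removed_up, removed_down], ignore_index=True)
    if removed.empty:
        removed = pd.DataFrame(columns=_COLUMNS)
    return (
        IntervalSet(up.df[~drop_up]),
        IntervalSet(down.df[~drop_down]),
        IntervalSet(removed),
    )


def _gene_category(mid: int, gene: GeneModel, cfg: AnnotationConfig) -> str | None:
    """Category of a midpoint with respect to one gene, or None if outside
    the gene's extended window."""
    if gene.strand == "+":
        up_lo, up_hi = gene.start - cfg.upstream_bp, gene.start
        dn_lo, dn_hi = gene.end, gene.end + cfg.downstream_bp
    else:
        up_lo, up_hi = gene.end, gene.end + cfg.upstream_bp
        dn_lo, dn_hi = gene.start - cfg.downstream_bp, gene.start
    if up_lo <= mid < up_hi:
        return "upstream"
    if dn_lo <= mid < dn_hi:
        return "downstream"
    if not (gene.start <= mid < gene.end):
        return None
    if gene.five_utr and gene.five_utr[0] <= mid < gene.five_utr[1]:
        return "5utr"
    if gene.three_utr and gene.three_utr[0] <= mid < gene.three_utr[1]:
        return "3utr"
    if gene.exons:
        for s, e in gene.exons:
            if s <= mid < e:
                return "exon"
        return "intron"
    return "exon"  # no sub-features annotated: gene body counts as exonic


def _signed_tss_distance(mid: int, gene: GeneModel) -> int:
    """Signed bp distance of a position to a gene's TSS; negative = upstream."""
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def annotate(
    s: IntervalSet, genes: list[GeneModel], cfg: AnnotationConfig = AnnotationConfig()
) -> pd.DataFrame:
    """Assign one category and a nearest gene to every interval.

    The interval midpoint decides membership; overlapping candidate
    categories resolve by priority (upstream > 5'UTR > exon > intron >
    3'UTR > downstream > intergenic) with nearest-TSS tie-break.  Intervals
    on chromosomes absent from the gene list are intergenic (with a
    warning).  The signed TSS distance is negative upstream of the TSS.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    prio = {cat: i for i, cat in enumerate(cfg.priority)}
    rows = []
    warned: set[str] = set()
    for rec in s.df.itertuples(index=False):
        mid = (rec.start + rec.end) // 2
        cands = by_chrom.get(rec.chrom)
        if not cands:
            if rec.chrom not in warned:
                warnings.warn(f"chromosome {rec.chrom!r} absent from gene models; intergenic")
                warned.add(rec.chrom)
            rows.append((rec.chrom, rec.start, rec.end, mid, "intergenic", None, None))
            continue
        best: tuple[int, int, str, GeneModel] | None = None
        for g in cands:
            cat = _gene_category(mid, g, cfg)
            if cat is None:
                continue
            key = (prio[cat], abs(_signed_tss_distance(mid, g)))
            if best is None or key < (best[0], best[1]):
                best = (*key, cat, g)
        if best is None:
            nearest = min(cands, key=lambda g: abs(_signed_tss_distance(mid, g)))
            rows.append(
                (rec.chrom, rec.start, rec.end, mid, "intergenic", nearest.gene_id,
                 _signed_tss_distance(mid, nearest))
            )
        else:
            _, _, cat, g = best
            rows.append(
                (rec.chrom, rec.start, rec.end, mid, cat, g.gene_id,
                 _signed_tss_distance(mid, g))
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "midpoint", "category", "gene_id", "tss_distance"],
    )


def _overlaps_any(df: pd.DataFrame, other: IntervalSet) -> np.ndarray:
    """For each interval in df, True if it overlaps (>= 1 bp) any interval
    of the reduced set ``other``."""
    out = np.zeros(len(df), dtype=bool)
    other_by_chrom = {c: g for c, g in other.df.groupby("chrom", sort=False)}
    for chrom, sub in df.groupby("chrom", sort=False):
        og = other_by_chrom.get(chrom)
        if og is None:
            continue
        o_starts = og["start"].to_numpy()
        o_ends = og["end"].to_numpy()
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        # reduced => disjoint & sorted: only the last interval starting before e can overlap
        j = np.searchsorted(o_starts, e, side="left") - 1
        valid = j >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[valid] = o_ends[j[valid]] > s[valid]
        out[_positions(df, sub.index)] = hit
    return out


def _positions(df: pd.DataFrame, index) -> np.ndarray:
    locator = pd.Series(np.arange(len(df)), index=df.index)
    return locator.loc[index].to_numpy()


def overlap_sets(
    a: IntervalSet, b: IntervalSet, c: IntervalSet, names: tuple[str, str, str] = ("A", "B", "C")
) -> dict[str, dict[str, int]]:
    """Three-set Venn overlap counts by membership pattern.

    Each set's elements are classified by which other sets they overlap
    (>= 1 bp); counts are element counts per set, so within each set the
    pattern counts sum to the set size.  All sets must be reduced.
    Returns ``{set_name: {pattern: count}}`` with patterns like ``"A"``,
    ``"AB"``, ``"ABC"`` (sorted concatenation of member names).
    """
    sets = dict(zip(names, (a, b, c)))
    for name, s in sets.items():
        if not s.is_reduced:
            raise ValidationError(f"set {name!r} must be reduced before Venn overlap")
    result: dict[str, dict[str, int]] = {}
    for name, s in sets.items():
        flags = {name: np.ones(len(s), dtype=bool)}
        for other_name, other in sets.items():
            if other_name != name:
                flags[other_name] = _overlaps_any(s.df, other)
        patterns = []
        for i in range(len(s)):
            members = "".join(sorted(n for n, f in flags.items() if f[i]))
            patterns.append(members)
        counts: dict[str, int] = {}
        for p in patterns:
            counts[p] = counts.get(p, 0) + 1
        result[name] = counts
    return result


@dataclass(frozen=True)
class MetaprofileResult:
    """TSS-relative density of interval midpoints with bootstrap CI."""

    bin_centers: np.ndarray
    density: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    distances: np.ndarray = field(repr=False, default=None)


def signed_tss_distances(s: IntervalSet, genes: list[GeneModel]) -> np.ndarray:
    """Signed distance of each interval midpoint to its nearest TSS
    (strand-aware; negative = upstream).  Intervals on chromosomes without
    genes yield NaN."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arrays = {
        c: (np.array([g.tss for g in gs]), np.array([1 if g.strand == "+" else -1 for g in gs]))
        for c, gs in by_chrom.items()
    }
    out = np.full(len(s), np.nan)
    for i, rec in enumerate(s.df.itertuples(index=False)):
        if rec.chrom not in tss_arrays:
            continue
        tss, sign = tss_arrays[rec.chrom]
        mid = (rec.start + rec.end) // 2
        d = (mid - tss) * sign
        out[i] = d[np.argmin(np.abs(d))]
    return out


def tss_metaprofile(
    s: IntervalSet,
    genes: list[GeneModel],
    window: int = 3000,
    bins: int = 60,
    bootstrap_B: int = 1000,
    seed: int | None = None,
) -> MetaprofileResult:
    """Density of interval midpoints by signed distance to the nearest TSS.

    Midpoints within ``±window`` bp of a TSS are histogrammed (density
    normalised so the integral over the window is 1); the 95% band is the
    pointwise 2.5/97.5 percentile over ``bootstrap_B`` resamples of the
    contributing intervals.
    """
    d = signed_tss_distances(s, genes)
    d = d[np.isfinite(d)]
    d = d[np.abs(d) <= window]
    if len(d) == 0:
        raise ValidationError("no intervals within the window of any TSS")
    edges = np.linspace(-window, window, bins + 1)
    density, _ = np.histogram(d, bins=edges, density=True)
    n = len(d)
    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_B, bins))
    for bi in range(bootstrap_B):
        sample = d[rng.integers(0, n, size=n)]
        boot[bi], _ = np.histogram(sample, bins=edges, density=True)
    lower = np.percentile(boot, 2.5, axis=0)
    upper = np.percentile(boot, 97.5, axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return MetaprofileResult(
        bin_centers=centers, density=density, lower=lower, upper=upper, distances=d
    )


def enrichment_2x2(
    targets: set, class_members: set, background: set
) -> tuple[groupstats.ContingencyTable2x2, float, float]:
    """Fisher-exact enrichment of a target gene set within a class, against
    a background universe (e.g. open-chromatin genes).

    Builds the 2x2 table (in class / not) x (target / not) restricted to the
    background and delegates to :func:`samquant.groupstats.fisher_exact`.
    Returns ``(table, odds_ratio, p_two_sided)``.
    """
    targets, class_members, background = set(targets), set(class_members), set(background)
    if not targets <= background:
        raise ValidationError("targets must be a subset of the background universe")
    if not class_members <= background:
        raise ValidationError("class members must be a subset of the background universe")
    a = len(class_members & targets)
    b = len(class_members - targets)
    c = len(targets - class_members)
    d = len(background - class_members - targets)
    table = groupstats.ContingencyTable2x2(a=a, b=b, c=c, d=d)
    odds, p = groupstats.fisher_exact(table)
    return table, odds, p
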