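"""Interval algebra: filtering, reduction, conflict removal, annotation,
overlaps, metaprofiles and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from samquant.errors import ValidationError
from samquant.intervals import (
    AnnotationConfig,
    GeneModel,
    IntervalSet,
    annotate,
    conflict_filter,
    enrichment_2x2,
    filter_posterior,
    overlap_sets,
    reduce_intervals,
    signed_tss_distances,
    tss_metaprofile,
)


def iset(rows):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]))


def per_base_mask(s: IntervalSet, length=1000):
    mask = np.zeros(length, bool)
    for rec in s:
        mask[rec.start : rec.end] = True
    return mask


def mask_components(mask):
    padded = np.concatenate([[False], mask, [False]])
    return int(np.sum(np.diff(padded.astype(int)) == 1))


class TestFilterPosterior:
    def test_strictly_greater_than(self):
        s = iset([("c", 0, 10, ".", 0.89), ("c", 20, 30, ".", 0.90), ("c", 40, 50, ".", 0.91)])
        out = filter_posterior(s, 0.9)
        assert len(out) == 1 and out.df.iloc[0]["start"] == 40

    def test_empty_set(self):
        out = filter_posterior(iset([]), 0.9)
        assert len(out) == 0

    def test_threshold_zero_keeps_positive_scores(self):
        s = iset([("c", 0, 5, ".", 0.0), ("c", 10, 15, ".", 0.01)])
        assert len(filter_posterior(s, 0.0)) == 1

    def test_missing_scores_rejected(self):
        s = iset([("c", 0, 5, ".", np.nan)])
        with pytest.raises(ValidationError):
            filter_posterior(s, 0.9)


class TestReduce:
    def test_abutting_merge(self):
        out = reduce_intervals(iset([("c", 0, 10, ".", 1.0), ("c", 10, 20, ".", 1.0)]))
        assert [(r.start, r.end) for r in out] == [(0, 20)]

    def test_one_bp_gap_not_merged(self):
        out = reduce_intervals(iset([("c", 0, 10, ".", 1.0), ("c", 11, 20, ".", 1.0)]))
        assert [(r.start, r.end) for r in out] == [(0, 10), (11, 20)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        starts = rng.integers(0, 950, n)
        ends = starts + rng.integers(1, 50, n)
        s = iset([("c", int(a), int(b), ".", 1.0) for a, b in zip(starts, ends)])
        out = reduce_intervals(s)
        mask = per_base_mask(s)
        assert np.array_equal(per_base_mask(out), mask)
        assert len(out) == mask_components(mask)
        assert out.covered_bases() == int(mask.sum())
        assert out.is_reduced
        again = reduce_intervals(out)
        assert again.df.equals(out.df)  # idempotent


class TestConflictFilter:
    def test_close_pair_removed(self):
        up = iset([("c", 1000, 1100, "up", 1.0)])
        down = iset([("c", 1150, 1200, "down", 1.0)])
        u, d, removed = conflict_filter(up, down)
        assert len(u) == 0 and len(d) == 0 and len(removed) == 2

    def test_gap_exactly_73_kept(self):
        up = iset([("c", 1000, 1100, "up", 1.0)])
        down = iset([("c", 1173, 1200, "down", 1.0)])
        u, d, removed = conflict_filter(up, down)
        assert len(u) == 1 and len(d) == 1 and len(removed) == 0

    def test_overlapping_pair_removed(self):
        up = iset([("c", 1000, 1100, "up", 1.0)])
        down = iset([("c", 1050, 1200, "down", 1.0)])
        u, d, removed = conflict_filter(up, down)
        assert len(u) == 0 and len(d) == 0

    def test_unreduced_input_rejected(self):
        up = iset([("c", 0, 10, "up", 1.0), ("c", 5, 20, "up", 1.0)])
        with pytest.raises(ValidationError):
            conflict_filter(up, iset([("c", 500, 600, "down", 1.0)]))

    def test_output_min_gap_by_brute_force(self, rng):
        up = reduce_intervals(
            iset([("c", int(s), int(s) + int(w), "up", 1.0)
                  for s, w in zip(rng.integers(0, 20000, 60), rng.integers(10, 300, 60))])
        )
        down = reduce_intervals(
            iset([("c", int(s), int(s) + int(w), "down", 1.0)
                  for s, w in zip(rng.integers(0, 20000, 60), rng.integers(10, 300, 60))])
        )
        u, d, _ = conflict_filter(up, down)
        for ru in u:
            for rd in d:
                gap = max(0, max(rd.start - ru.end, ru.start - rd.end))
                assert gap >= 73


def plus_gene(start=5000, end=8000, **kw):
    return GeneModel(chrom="c", start=start, end=end, strand="+", gene_id="g1", **kw)


class TestAnnotate:
    def test_upstream_window(self):
        ann = annotate(iset([("c", 2550, 2650, ".", 1.0)]), [plus_gene()])
        assert ann.iloc[0]["category"] == "upstream"
        assert ann.iloc[0]["tss_distance"] == 2600 - 5000

    def test_downstream_window(self):
        ann = annotate(iset([("c", 8050, 8150, ".", 1.0)]), [plus_gene()])
        assert ann.iloc[0]["category"] == "downstream"

    def test_exon_containment(self):
        g = plus_gene(exons=((5000, 5500), (6000, 8000)))
        ann = annotate(iset([("c", 6100, 6200, ".", 1.0)]), [g])
        assert ann.iloc[0]["category"] == "exon"
        ann2 = annotate(iset([("c", 5600, 5700, ".", 1.0)]), [g])
        assert ann2.iloc[0]["category"] == "intron"

    def test_minus_strand_upstream_extends_rightward(self):
        g = GeneModel(chrom="c", start=5000, end=8000, strand="-", gene_id="g2")
        ann = annotate(iset([("c", 8500, 8600, ".", 1.0)]), [g])
        assert ann.iloc[0]["category"] == "upstream"
        assert ann.iloc[0]["tss_distance"] == 8000 - 8550  # negative = upstream

    def test_absent_chromosome_is_intergenic_with_warning(self):
        with pytest.warns(UserWarning):
            ann = annotate(iset([("chrX", 100, 200, ".", 1.0)]), [plus_gene()])
        assert ann.iloc[0]["category"] == "intergenic"

    def test_categories_partition(self, interval_world):
        genes, binding, *_ = interval_world
        ann = annotate(reduce_intervals(binding), genes)
        assert len(ann) == len(reduce_intervals(binding))
        assert ann["category"].isin(
            ["upstream", "5utr", "exon", "intron", "3utr", "downstream", "intergenic"]
        ).all()


class TestOverlapSets:
    def test_identical_sets_triple_overlap(self):
        s = reduce_intervals(iset([("c", 0, 10, ".", 1.0), ("c", 100, 130, ".", 1.0)]))
        counts = overlap_sets(s, s, s)
        assert counts["A"] == {"ABC": 2}
        assert counts["B"] == {"ABC": 2} and counts["C"] == {"ABC": 2}

    def test_disjoint_sets_exclusive_cells(self):
        a = reduce_intervals(iset([("c", 0, 10, ".", 1.0)]))
        b = reduce_intervals(iset([("c", 50, 60, ".", 1.0)]))
        c = reduce_intervals(iset([("c", 100, 110, ".", 1.0), ("c", 200, 220, ".", 1.0)]))
        counts = overlap_sets(a, b, c)
        assert counts == {"A": {"A": 1}, "B": {"B": 1}, "C": {"C": 2}}

    def test_matches_all_pairs_oracle_and_conservation(self, rng):
        def rand_set(n):
            starts = rng.integers(0, 5000, n)
            return reduce_intervals(
                iset([("c", int(s), int(s + w), ".", 1.0)
                      for s, w in zip(starts, rng.integers(5, 120, n))])
            )

        a, b, c = rand_set(30), rand_set(25), rand_set(35)
        counts = overlap_sets(a, b, c)
        for name, s, others in (("A", a, {"B": b, "C": c}), ("B", b, {"A": a, "C": c}),
                                ("C", c, {"A": a, "B": b})):
            assert sum(counts[name].values()) == len(s)
            for rec in s:
                pattern = {name}
                for oname, o in others.items():
                    if any(orc.start < rec.end and orc.end > rec.start for orc in o):
                        pattern.add(oname)
                key = "".join(sorted(pattern))
                assert counts[name][key] >= 1  # pattern observed by brute force exists
        # full brute-force recount
        for name, s, others in (("A", a, {"B": b, "C": c}), ("B", b, {"A": a, "C": c}),
                                ("C", c, {"A": a, "B": b})):
            brute: dict[str, int] = {}
            for rec in s:
                pattern = {name}
                for oname, o in others.items():
                    if any(orc.start < rec.end and orc.end > rec.start for orc in o):
                        pattern.add(oname)
                key = "".join(sorted(pattern))
                brute[key] = brute.get(key, 0) + 1
            assert brute == counts[name]


class TestMetaprofile:
    def test_midpoints_at_tss_concentrate_in_zero_bin(self):
        genes = [plus_gene(start=5000, end=8000)]
        s = iset([("c", 4995, 5005, ".", 1.0)] * 1)
        res = tss_metaprofile(s, genes, window=1000, bins=10, bootstrap_B=50, seed=0)
        near_zero = np.abs(res.bin_centers) <= 200
        width = 2000 / 10
        assert res.density[near_zero].sum() * width == pytest.approx(1.0)
        assert res.density.sum() * width == pytest.approx(1.0)

    def test_planted_normal_offsets_recovered(self, interval_world):
        genes, binding, *_ = interval_world
        truth = interval_world[-1]
        sigma = truth.spec.binding_offset_sigma
        d = signed_tss_distances(binding, genes)
        frac = np.mean((d >= -2500) & (d <= 1000))
        mass = sps.norm.cdf(1000, 0, sigma) - sps.norm.cdf(-2500, 0, sigma)
        n = len(d)
        assert abs(frac - mass) < 3 * np.sqrt(mass * (1 - mass) / n) + 0.01

    def test_bootstrap_size_leaves_point_estimate_unchanged(self):
        genes = [plus_gene()]
        rng = np.random.default_rng(0)
        rows = [("c", int(5000 + o), int(5000 + o + 10), ".", 1.0)
                for o in rng.integers(-900, 900, 50)]
        s = iset(rows)
        r1 = tss_metaprofile(s, genes, window=1000, bins=10, bootstrap_B=100, seed=1)
        r2 = tss_metaprofile(s, genes, window=1000, bins=10, bootstrap_B=200, seed=1)
        assert np.array_equal(r1.density, r2.density)

    def test_no_intervals_near_tss_rejected(self):
        with pytest.raises(ValidationError):
            tss_metaprofile(iset([("c", 500_000, 500_100, ".", 1.0)]), [plus_gene()],
                            window=1000, bins=10, bootstrap_B=10, seed=0)


class TestEnrichment:
    def test_degenerate_full_overlap(self):
        g = {"a", "b", "c"}
        table, odds, p = enrichment_2x2(g, g, g)
        assert odds == np.inf
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_subset_precondition(self):
        with pytest.raises(ValidationError):
            enrichment_2x2({"x"}, {"a"}, {"a", "b"})

    def test_planted_enrichment_detected(self, rng):
        detected = 0
        for _ in range(50):
            background = {f"g{i}" for i in range(200)}
            class_members = {f"g{i}" for i in range(60)}
            # targets drawn preferentially from the class
            targets = {f"g{i}" for i in range(200) if rng.random() < (0.6 if i < 60 else 0.1)}
            _, odds, p = enrichment_2x2(targets, class_members, background)
            detected += (odds > 1) and (p < 0.05)
        assert detected >= 48  # planted effect found in >= 95% of worlds

    def test_null_rejection_rate_bounded(self, rng):
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            background = {f"g{i}" for i in range(150)}
            class_members = {g for g in background if rng.random() < 0.3}
            targets = {g for g in background if rng.random() < 0.2}
            _, _, p = enrichment_2x2(targets, class_members, background)
            rejections += p < 0.05
        assert rejections / n_sim <= 0.05 + 0.025
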