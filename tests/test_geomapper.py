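"""Two-step geomapping: transform, segment assignment, screen, region calls."""

import numpy as np
import pandas as pd
import pytest

from atcmap.geomapper import (
    AtcGeomapper,
    assign_gene_copynumber,
    call_atc_regions,
    correlate_gene,
    log2_transform,
    screen_atc_genes,
)
from conftest import as_cohort, interval_jaccard, small_config


class TestLog2Transform:
    @pytest.mark.parametrize("raw, expected", [(0.0, 0.0), (1.0, 1.0), (1023.0, 10.0), (3.0, 2.0)])
    def test_pointwise(self, raw, expected):
        assert log2_transform(np.array([raw]))[0] == pytest.approx(expected, abs=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(np.array([-0.5]))

    def test_dataframe_preserves_labels(self):
        df = pd.DataFrame([[0.0, 3.0]], index=["g"], columns=["s1", "s2"])
        out = log2_transform(df)
        assert list(out.columns) == ["s1", "s2"] and out.loc["g", "s2"] == 2.0


class TestSegmentAssignment:
    def grid(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 100_000, 200_000],
                "end": [100_000, 200_000, 300_000],
                "s1": [0.0, 1.0, 2.0],
                "s2": [5.0, 6.0, 7.0],
            }
        )

    def test_containment(self):
        gene = {"chrom": "chr1", "start": 150_000, "end": 160_000}
        np.testing.assert_allclose(assign_gene_copynumber(gene, self.grid()), [1.0, 6.0])

    def test_midpoint_rule_on_boundary_spanning_gene(self):
        gene = {"chrom": "chr1", "start": 195_000, "end": 204_980}  # midpoint 199,990
        np.testing.assert_allclose(assign_gene_copynumber(gene, self.grid()), [1.0, 6.0])

    def test_gap_falls_back_to_nearest_segment(self):
        grid = self.grid().drop(index=1).reset_index(drop=True)
        gene = {"chrom": "chr1", "start": 130_000, "end": 140_000}  # midpoint in the gap
        np.testing.assert_allclose(assign_gene_copynumber(gene, grid), [0.0, 5.0])

    def test_absent_chromosome_raises(self):
        with pytest.raises(KeyError):
            assign_gene_copynumber({"chrom": "chrX", "start": 0, "end": 10}, self.grid())

    def test_planted_gene_vector_matches_generator_segments(self, small_bundle):
        cohort = as_cohort(small_bundle)
        gene_id = small_bundle.manifest["planted_regions"][0]["member_genes"][3]
        gene = small_bundle.annotation.set_index("gene_id").loc[gene_id]
        vec = assign_gene_copynumber(
            {"chrom": gene.chrom, "start": gene.start, "end": gene.end},
            small_bundle.copy_number,
            cohort.samples,
        )
        mid = (gene.start + gene.end) // 2
        cn = small_bundle.copy_number
        row = cn[(cn.chrom == gene.chrom) & (cn.start <= mid) & (cn.end > mid)]
        np.testing.assert_array_equal(vec, row[cohort.samples].to_numpy(dtype=float)[0])


class TestCorrelateGene:
    def test_perfect_positive_and_negative(self):
        assert correlate_gene([1, 2, 3, 4], [0, 1, 2, 3]) == pytest.approx(1.0)
        assert correlate_gene([1, 2, 3, 4], [3, 2, 1, 0]) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        assert np.isnan(correlate_gene([2, 2, 2, 2], [1, 2, 3, 4]))

    def test_too_few_pairs_undefined(self):
        assert np.isnan(correlate_gene([1, 2], [1, 2]))
        # pairwise deletion leaves only 2 complete pairs
        assert np.isnan(correlate_gene([1, 2, np.nan, np.nan], [1, 2, 3, 4]))

    def test_pairwise_deletion_uses_complete_pairs(self):
        r = correlate_gene([1, 2, 3, 4, np.nan], [0, 1, 2, 3, 100])
        assert r == pytest.approx(1.0)


class TestScreen:
    def build_cohort(self, r_targets):
        """Cohort whose genes have exactly the requested correlations."""
        from atcmap.cohort import Cohort

        n = 50
        rng = np.random.default_rng(0)
        z1 = rng.standard_normal(n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = rng.standard_normal(n)
        z2 -= z2.mean() + z1 * (z1 @ z2) / (z1 @ z1)  # orthogonalize
        z2 /= z2.std()
        samples = [f"S{i}" for i in range(n)]
        genes, rows = [], []
        for i, r in enumerate(r_targets):
            genes.append(f"g{i}")
            rows.append(5.0 + r * z1 + np.sqrt(1 - r * r) * z2)
        expr = pd.DataFrame(rows, index=genes, columns=samples)
        cn = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        cn = pd.concat([cn, pd.DataFrame([2.0 + z1], columns=samples)], axis=1)
        meta = pd.DataFrame(
            {"er_status": "positive", "subtype": "LumA", "os_days": 100.0, "os_event": 1},
            index=pd.Index(samples, name="sample"),
        )
        ann = pd.DataFrame(
            {
                "gene_id": genes,
                "chrom": "chr1",
                "start": np.arange(len(genes)) * 1000,
                "end": np.arange(len(genes)) * 1000 + 500,
                "strand": "+",
            }
        )
        return Cohort(expression=expr, copy_number=cn, metadata=meta), ann

    def test_threshold_is_inclusive(self):
        cohort, ann = self.build_cohort([0.9, 0.3])
        atc = screen_atc_genes(cohort, ann, r_threshold=0.9)
        # the r = 0.9 gene is constructed to hit its target exactly
        r_obs = atc.r.iloc[0] if len(atc) else None
        assert len(atc) == 1 and atc.gene_id.iloc[0] == "g0"
        # exactly at the observed value: retained (>= is inclusive) ...
        assert len(screen_atc_genes(cohort, ann, r_threshold=r_obs)) == 1
        # ... and the next representable float above it: dropped
        assert len(screen_atc_genes(cohort, ann, r_threshold=np.nextafter(r_obs, 1.0))) == 0

    def test_raising_threshold_never_grows_the_set(self):
        cohort, ann = self.build_cohort([0.95, 0.7, 0.5, 0.2, -0.4])
        sizes = [len(screen_atc_genes(cohort, ann, r_threshold=t)) for t in (0.0, 0.4, 0.6, 0.8, 0.99)]
        assert sizes == sorted(sizes, reverse=True)

    def test_output_sorted_by_position(self):
        cohort, ann = self.build_cohort([0.9, 0.8, 0.85])
        atc = screen_atc_genes(cohort, ann, r_threshold=0.5)
        assert list(atc.start) == sorted(atc.start)


def _atc_frame(chrom, starts, width=10_000, r=0.9):
    starts = np.asarray(starts, dtype=int)
    return pd.DataFrame(
        {
            "gene_id": [f"g{chrom}_{i}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
            "end": starts + width,
            "strand": "+",
            "r": r,
        }
    )


class TestCallRegions:
    def test_gene_count_criterion_excludes_small_clusters(self):
        rng = np.random.default_rng(0)
        atc = _atc_frame("chr1", rng.uniform(5e6, 9e6, 14).astype(int))
        assert call_atc_regions(atc, min_genes=15) == []
        atc16 = _atc_frame("chr1", rng.uniform(5e6, 9e6, 16).astype(int))
        assert len(call_atc_regions(atc16, min_genes=15)) == 1

    def test_span_criterion_excludes_wide_clusters(self):
        rng = np.random.default_rng(1)
        atc = _atc_frame("chr1", rng.uniform(0, 25e6, 30).astype(int))  # ~25 Mb spread
        assert call_atc_regions(atc, max_span_mb=20.0) == []

    def test_emitted_regions_satisfy_all_criteria(self):
        rng = np.random.default_rng(2)
        pos = np.r_[rng.uniform(5e6, 11e6, 25), rng.uniform(60e6, 67e6, 30)].astype(int)
        regions = call_atc_regions(_atc_frame("chr1", pos))
        assert len(regions) == 2
        for reg in regions:
            assert reg.gene_count == len(reg.members) >= 15
            assert reg.span_mb == pytest.approx((reg.end - reg.start) / 1e6)
            assert reg.span_mb < 20.0
            assert reg.density > 1e-8

    def test_same_chromosome_regions_never_overlap(self):
        rng = np.random.default_rng(3)
        pos = np.r_[rng.uniform(5e6, 11e6, 20), rng.uniform(30e6, 37e6, 25), rng.uniform(60e6, 66e6, 22)]
        regions = call_atc_regions(_atc_frame("chr1", pos.astype(int)))
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start

    def test_k_range_clamped_with_warning(self):
        atc = _atc_frame("chr1", np.arange(16) * 1000 + 5_000_000)
        with pytest.warns(UserWarning, match="clamping"):
            regions = call_atc_regions(atc, k_range=(1, 50))
        assert len(regions) == 1

    def test_empty_input(self):
        assert call_atc_regions(_atc_frame("chr1", []).iloc[0:0]) == []


class TestModelInterface:
    def test_fit_recovers_planted_region(self, small_bundle):
        res = AtcGeomapper(as_cohort(small_bundle), small_bundle.annotation).fit()
        truth = small_bundle.manifest["planted_regions"][0]
        assert len(res.regions) == 1
        reg = res.regions[0]
        assert reg.chrom == truth["chrom"]
        assert interval_jaccard((reg.start, reg.end), tuple(truth["member_span"])) >= 0.8

    def test_summary_mentions_counts(self, small_bundle):
        res = AtcGeomapper(as_cohort(small_bundle), small_bundle.annotation).fit()
        text = res.summary()
        assert "ATC regions retained: 1" in text
        assert res.regions[0].name == "A" and "A" in text

    def test_regions_frame_roundtrip(self, small_bundle):
        res = AtcGeomapper(as_cohort(small_bundle), small_bundle.annotation).fit()
        rf = res.regions_frame()
        assert list(rf.columns[:4]) == ["name", "chrom", "start", "end"]
        assert rf.gene_count.iloc[0] == res.regions[0].gene_count
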