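"""Positional classification: category definitions, precedence,
strand-awareness, mirroring invariance, probe resolution and summaries."""

import numpy as np
import pandas as pd
import pytest

import eqtmscan as eq
from eqtmscan.classify import CANONICAL


def cpg(pos, chrom="chr1"):
    return eq.CpGSite(f"cg_{chrom}_{pos}", chrom, pos)


class TestBroadCategories:
    def test_promoter_window(self, plus_gene):
        c = eq.classify_pair(cpg(9_000), plus_gene, [plus_gene])
        assert (c.broad, c.detailed, c.canonical) == ("cis", "near_promoter", True)

    def test_gene_body(self, plus_gene):
        c = eq.classify_pair(cpg(15_000), plus_gene, [plus_gene])
        assert (c.broad, c.detailed, c.canonical) == ("cis", "in_gene_body", True)
        assert c.signed_distance == 0

    def test_trans(self, plus_gene):
        c = eq.classify_pair(cpg(15_000, "chr2"), plus_gene, [plus_gene])
        assert (c.broad, c.detailed, c.canonical) == ("trans", "trans", False)

    def test_distal_beyond_50kb(self, plus_gene):
        c = eq.classify_pair(cpg(75_000), plus_gene, [plus_gene])
        assert (c.broad, c.detailed) == ("distal", "distal")
        assert c.signed_distance == 55_000

    def test_promoter_beats_body_in_overlap_zone(self, plus_gene):
        """Within 2500 bp downstream of the TSS both definitions apply;
        promoter wins."""
        c = eq.classify_pair(cpg(11_000), plus_gene, [plus_gene])
        assert c.detailed == "near_promoter"

    def test_minus_strand_promoter_is_at_high_coordinate(self):
        g = eq.GeneModel("gm", "chr1", "-", 10_000, 20_000)
        c = eq.classify_pair(cpg(21_000), g, [g])
        assert c.detailed == "near_promoter"
        c2 = eq.classify_pair(cpg(11_000), g, [g])
        assert c2.detailed == "in_gene_body"

    def test_malformed_gene_raises(self):
        with pytest.raises(eq.AnnotationError):
            eq.GeneModel("bad", "chr1", "+", 5_000, 5_000)


class TestNeighborCategories:
    def setup_method(self):
        self.gene = eq.GeneModel("g", "chr1", "+", 100_000, 110_000)

    def test_closest_downstream_when_gene_is_nearest(self):
        other = eq.GeneModel("o", "chr1", "+", 200_000, 210_000)
        c = eq.classify_pair(cpg(90_000), self.gene, [self.gene, other])
        assert c.detailed == "closest_downstream_gene" and c.canonical
        assert c.signed_distance == -10_000

    def test_closest_upstream_when_gene_is_nearest(self):
        other = eq.GeneModel("o", "chr1", "+", 200_000, 210_000)
        c = eq.classify_pair(cpg(120_000), self.gene, [self.gene, other])
        assert c.detailed == "closest_upstream_gene" and c.canonical
        assert c.signed_distance == 10_000

    def test_gene_between(self):
        # an intervening gene's TSS sits between the CpG and the associated
        # TSS; its span overlaps the associated gene so no other condition
        # fires
        mid = eq.GeneModel("mid", "chr1", "+", 98_000, 120_000)  # TSS 98,000
        c = eq.classify_pair(cpg(90_000), self.gene, [self.gene, mid])
        assert c.detailed == "gene_between"

    def test_multiple_closer_between(self):
        # the same intervening TSS plus the CpG inside another gene
        mid = eq.GeneModel("mid", "chr1", "+", 98_000, 120_000)
        host = eq.GeneModel("host", "chr1", "+", 88_000, 93_000)
        c = eq.classify_pair(cpg(90_000), self.gene, [self.gene, mid, host])
        assert c.detailed == "multiple_closer_between"

    def test_closer_5prime(self):
        # a nearer TSS on the opposite side of the CpG ('-' gene ending
        # just left of it)
        opp = eq.GeneModel("opp", "chr1", "-", 70_000, 91_000)  # TSS 91,000
        c = eq.classify_pair(cpg(93_000), self.gene, [self.gene, opp])
        assert c.detailed == "closer_5prime"
        assert not c.canonical

    def test_closer_3prime(self):
        # another gene's TES closer than both ends of the associated gene
        opp = eq.GeneModel("opp", "chr1", "+", 70_000, 91_000)  # TES 91,000
        c = eq.classify_pair(cpg(93_000), self.gene, [self.gene, opp])
        assert c.detailed == "closer_3prime"

    def test_in_different_gene_pure(self, fixture_genome):
        """The nested-gene fixture yields a pure in_different_gene pair."""
        anchor = fixture_genome.genes[0]
        nested = fixture_genome.genes[1]
        c = eq.classify_pair(
            cpg(anchor.start + 15_000), nested, fixture_genome.genes
        )
        assert c.detailed == "in_different_gene"


class TestClassificationProperties:
    def test_exhaustive_and_mutually_exclusive(self, fixture_genome):
        """Every pair gets exactly one label from the fixed vocabulary and
        cis pairs get exactly one detailed cis label."""
        for c in fixture_genome.cpgs:
            for g in fixture_genome.genes:
                cls = eq.classify_pair(c, g, fixture_genome.genes)
                assert cls.detailed in eq.DETAILED_CATEGORIES
                assert (cls.broad == "trans") == (cls.detailed == "trans")
                assert (cls.broad == "distal") == (cls.detailed == "distal")
                assert cls.canonical == (cls.detailed in CANONICAL)
                if cls.canonical:
                    assert cls.broad == "cis"
                if cls.signed_distance == 0 and cls.broad == "cis":
                    assert cls.detailed in ("in_gene_body", "near_promoter",
                                            "in_different_gene",
                                            "multiple_closer_between")

    def test_mirror_invariance(self, fixture_genome):
        """Flipping coordinates and strands leaves every classification
        unchanged (strand symmetry)."""
        mirror = fixture_genome.mirrored()
        genes_m = {g.gene_id: g for g in mirror.genes}
        cpgs_m = {c.cpg_id: c for c in mirror.cpgs}
        for c in fixture_genome.cpgs:
            for g in fixture_genome.genes:
                a = eq.classify_pair(c, g, fixture_genome.genes)
                b = eq.classify_pair(cpgs_m[c.cpg_id], genes_m[g.gene_id],
                                     mirror.genes)
                assert (a.broad, a.detailed, a.canonical) == \
                       (b.broad, b.detailed, b.canonical)
                assert a.signed_distance == b.signed_distance


class TestGeneBodySubcategory:
    def test_first_exon_plus_strand(self, plus_gene):
        s = eq.genebody_subcategory(cpg(12_800), plus_gene)
        assert s.sub == "exonic" and s.first_exon and not s.last_exon

    def test_intronic(self, plus_gene):
        s = eq.genebody_subcategory(cpg(13_500), plus_gene)
        assert s.sub == "intronic"

    def test_minus_strand_first_exon_is_highest_coordinate(self):
        g = eq.GeneModel("gm", "chr1", "-", 10_000, 20_000,
                         exons=((10_000, 12_000), (17_000, 20_000)))
        s = eq.genebody_subcategory(cpg(11_000), g)  # body: 10k < pos < 17.5k
        assert s.sub == "exonic" and s.last_exon and not s.first_exon

    def test_outside_body_raises(self, plus_gene):
        with pytest.raises(ValueError, match="not in the body"):
            eq.genebody_subcategory(cpg(10_500), plus_gene)


class TestResolveProbeLocation:
    def test_singleton(self):
        p = eq.ProbeLocation("p", ((("chr1"), 100, 200, "other", None),))
        assert eq.resolve_probe_location(p, cpg(5_000)) == ("chr1", 100, 200)

    def test_proximity_wins(self):
        p = eq.ProbeLocation("p", (
            ("chr1", 100_000, 100_100, "primary", "gA"),
            ("chr1", 6_000, 6_100, "secondary", "gB"),
        ))
        assert eq.resolve_probe_location(p, cpg(5_000))[1] == 6_000

    def test_rank_breaks_distance_ties(self):
        p = eq.ProbeLocation("p", (
            ("chr1", 6_000, 6_100, "secondary", "gA"),
            ("chr1", 3_900, 4_000, "primary", "gB"),
        ))
        # both candidates 1000 bp from the CpG at 5,000
        assert eq.resolve_probe_location(p, cpg(5_000))[1] == 3_900

    def test_annotatable_preferred(self):
        p = eq.ProbeLocation("p", (
            ("chr1", 5_000, 5_100, "primary", None),
            ("chr1", 50_000, 50_100, "other", "gB"),
        ))
        assert eq.resolve_probe_location(p, cpg(5_000))[1] == 50_000

    def test_no_annotatable_falls_back(self):
        p = eq.ProbeLocation("p", (
            ("chr1", 9_000, 9_100, "other", None),
            ("chr1", 5_000, 5_100, "primary", None),
        ))
        assert eq.resolve_probe_location(p, cpg(5_000))[1] == 5_000


class TestRelativeProportion:
    def test_direct_arithmetic(self):
        r = eq.relative_proportion_by_distance(
            [5, 5, 50, 50], [5] * 10 + [50] * 90, bins=[0, 10, 100]
        )
        assert r[0] == pytest.approx((2 / 4) / (10 / 100))

    def test_identical_distributions_give_unity(self, rng):
        d = rng.uniform(0, 100, 500)
        r = eq.relative_proportion_by_distance(d, d, bins=[0, 25, 50, 75, 100])
        np.testing.assert_allclose(r, 1.0)

    def test_empty_array_bin_is_nan(self):
        r = eq.relative_proportion_by_distance([5.0], [50.0], bins=[0, 10, 100])
        assert np.isnan(r[0]) and not np.isnan(r[1])

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            eq.relative_proportion_by_distance([], [1.0], bins=[0, 10])


class TestOverlappingGenePairs:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["cpg_id", "gene_id", "detailed", "sign"])

    def test_promoter_body_pair_found(self):
        df = self._frame([
            ("cg1", "inner", "near_promoter", "-"),
            ("cg1", "outer", "in_gene_body", "+"),
        ])
        assert eq.find_overlapping_gene_pairs(df) == \
            [("cg1", "inner", "outer", "-", "+")]

    def test_requires_both_associations(self):
        df = self._frame([("cg1", "inner", "near_promoter", "-")])
        assert eq.find_overlapping_gene_pairs(df) == []

    def test_no_overlap_empty(self):
        df = self._frame([
            ("cg1", "a", "near_promoter", "-"),
            ("cg2", "b", "in_gene_body", "+"),
        ])
        assert eq.find_overlapping_gene_pairs(df) == []

    def test_pipeline_fixture_detects_nested_pair(self, fixture_genome):
        """A CpG in the nested gene's promoter and the anchor's body,
        significant for both, is reported."""
        anchor, nested = fixture_genome.genes[0], fixture_genome.genes[1]
        pos = anchor.start + 5_100
        site = cpg(pos)
        cls_a = eq.classify_pair(site, anchor, fixture_genome.genes)
        cls_n = eq.classify_pair(site, nested, fixture_genome.genes)
        assert {cls_a.detailed, cls_n.detailed} == {"in_gene_body", "near_promoter"}
        df = self._frame([
            (site.cpg_id, nested.gene_id, cls_n.detailed, "-"),
            (site.cpg_id, anchor.gene_id, cls_a.detailed, "+"),
        ])
        out = eq.find_overlapping_gene_pairs(df)
        assert len(out) == 1 and out[0][1] == nested.gene_id
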