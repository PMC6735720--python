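"""Quartiles, occupancy, zone dNPS, repeat families and strain comparison."""
import numpy as np
import pytest

from nucpattern.classify import NCPFragment
from nucpattern.genomic_io import GeneRecord, RepeatElement
from nucpattern.profiles import (
    NucleosomeZone,
    ZONES_YEAST,
    assign_quartiles,
    compare_strains,
    occupancy_profile,
    repeat_overlap,
    validate_zones,
    zone_dnps,
    zone_preset,
)
from nucpattern.synth import synth_fragment


def gene(gid, tss, strand="+", expr=1.0, chrom="chr1"):
    return GeneRecord(gid, chrom, tss, strand, expr)


def type_fragment(pattern_type, chrom, start, seed=0):
    f = synth_fragment(pattern_type, 1.0, seed=seed)
    return NCPFragment(chrom=chrom, start=start, sequence=f.sequence)


class TestQuartiles:
    def test_four_genes(self):
        genes = [gene(f"g{i}", 100 * i, expr=e) for i, e in enumerate((0, 1, 10, 100))]
        q = assign_quartiles(genes)
        assert [q[f"g{i}"] for i in range(4)] == [1, 2, 3, 4]

    def test_eight_genes_two_per_group(self):
        genes = [gene(f"g{i}", 100 * i, expr=float(i)) for i in range(8)]
        q = assign_quartiles(genes)
        counts = np.bincount(list(q.values()))[1:]
        assert list(counts) == [2, 2, 2, 2]

    def test_ties_broken_stably_by_gene_id(self):
        genes = [gene("b", 0, expr=5.0), gene("a", 10, expr=5.0), gene("c", 20, expr=1.0), gene("d", 30, expr=9.0)]
        q = assign_quartiles(genes)
        # rank order: c(1) < a(5,'a') < b(5,'b') < d(9)
        assert (q["c"], q["a"], q["b"], q["d"]) == (1, 2, 3, 4)

    def test_identical_expression_rejected(self):
        genes = [gene(f"g{i}", i, expr=3.0) for i in range(4)]
        with pytest.raises(ValueError, match="identical"):
            assign_quartiles(genes)

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="at least 4"):
            assign_quartiles([gene("g", 0)])


class TestOccupancy:
    genes4 = [gene(f"g{i}", 5000, expr=float(i)) for i in range(4)]

    def test_single_fragment_covers_its_body(self):
        frag = type_fragment(1, "chr1", 5000 - 50)
        genes = [gene("g0", 5000, expr=0.0)] + [gene(f"g{i}", 20000, expr=float(i)) for i in range(1, 4)]
        prof = occupancy_profile([frag], genes, window=200)
        g0 = prof.occupancy["1"]  # least-expressed quartile holds g0
        covered = prof.offsets[(g0 > 0)]
        assert covered.min() == -50 and covered.max() == 96
        assert np.all(g0[(prof.offsets >= -50) & (prof.offsets <= 96)] == 1)

    def test_minus_strand_gene_mirrors_offsets(self):
        frag = type_fragment(1, "chr1", 5000)  # body [5000, 5147), downstream of tss
        plus = occupancy_profile([frag], [gene("gp", 5000, "+", 0.0)] + self.genes4[1:], window=200)
        minus = occupancy_profile([frag], [gene("gm", 5000, "-", 0.0)] + self.genes4[1:], window=200)
        assert np.array_equal(plus.occupancy["1"], minus.occupancy["1"][::-1])

    def test_quartile_pooling_identity(self):
        rng = np.random.default_rng(3)
        frags = [type_fragment(1, "chr1", int(p), seed=i) for i, p in enumerate(rng.integers(0, 30000, 60))]
        genes = [gene(f"g{i}", int(t), expr=float(i)) for i, t in enumerate(rng.integers(2000, 28000, 12))]
        prof = occupancy_profile(frags, genes, window=500)
        pooled = sum(prof.occupancy[q] * prof.n_genes[q] for q in "1234") / len(genes)
        assert np.allclose(pooled, prof.occupancy["all"])


class TestZones:
    zones = ZONES_YEAST

    def make_genes(self):
        return [gene(f"g{i}", 10000 + 5000 * i, expr=float(i)) for i in range(4)]

    def test_presets_are_valid_partitions(self):
        for name in ("yeast", "mammal"):
            validate_zones(zone_preset(name))

    def test_overlapping_zones_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            validate_zones([NucleosomeZone("-1", -300, 0), NucleosomeZone("+1", -80, 120)])

    def test_all_type1_everywhere(self, gbs_map):
        genes = self.make_genes()
        frags = []
        for g in genes:
            for z in self.zones:
                dyad = g.tss + (z.lo + z.hi) // 2
                frags.append(type_fragment(1, "chr1", dyad - 73))
        res = zone_dnps(frags, genes, self.zones, gbs_map)
        for z in self.zones:
            assert res.zone_dnps(z.label) == 100.0
        assert res.mean_zone_deviation == pytest.approx(0.0)
        assert res.genomic.dnps == 100.0

    def test_boundary_dyad_is_half_open(self, gbs_map):
        genes = self.make_genes()
        # dyad exactly at +1 zone's lo boundary (offset -80) -> in +1, not -1
        frag = type_fragment(1, "chr1", genes[0].tss - 80 - 73)
        res = zone_dnps([frag], genes, self.zones, gbs_map)
        assert res.summaries["+1"]["all"] is not None
        assert res.summaries["-1"]["all"] is None

    def test_zone_partition_no_double_assignment(self, gbs_map):
        genes = self.make_genes()
        rng = np.random.default_rng(0)
        frags = [type_fragment(1, "chr1", int(p), seed=i) for i, p in enumerate(rng.integers(9000, 26000, 200))]
        res = zone_dnps(frags, genes, self.zones, gbs_map)
        total_assigned = sum(
            res.summaries[z.label]["all"].n_fragments
            for z in self.zones
            if res.summaries[z.label]["all"] is not None
        )
        # oracle: direct offset arithmetic over (gene, fragment) pairs
        expected = 0
        for g in genes:
            for f in frags:
                off = f.dyad - g.tss
                expected += sum(1 for z in self.zones if z.lo <= off < z.hi)
        assert total_assigned == expected

    def test_minus_strand_offsets(self, gbs_map):
        genes = [gene("gm", 10000, "-", 0.0)] + [gene(f"g{i}", 30000 + 5000 * i, expr=float(i)) for i in range(1, 4)]
        # dyad at tss - 60 -> strand-corrected offset +60 -> zone +1
        frag = type_fragment(4, "chr1", 10000 - 60 - 73)
        res = zone_dnps([frag], genes, self.zones, gbs_map)
        assert res.summaries["+1"]["all"].n_fragments == 1
        assert res.zone_dnps("+1") == -100.0


class TestRepeatOverlap:
    def test_midpoint_assignment_and_min_len(self, gbs_map):
        repeats = [
            RepeatElement("chr1", 1000, 1400, "SINE", "Alu"),
            RepeatElement("chr1", 5000, 5140, "LINE", "L1"),  # 140 bp: filtered out
        ]
        frags = [
            type_fragment(1, "chr1", 1100),  # dyad 1173 in the Alu
            type_fragment(1, "chr1", 5000),  # dyad in the short LINE -> unassigned
            type_fragment(4, "chr1", 9000),
        ]
        res = repeat_overlap(frags, repeats, gbs_map)
        assert res.summaries["SINE"].n_fragments == 1
        assert res.summaries["LINE"] is None
        assert res.summaries["genic/other"].n_fragments == 2
        assert res.fractions["SINE"] == pytest.approx(1 / 3)

    def test_nested_elements_resolved_by_priority(self, gbs_map):
        repeats = [
            RepeatElement("chr1", 1000, 3000, "LINE", "L1"),
            RepeatElement("chr1", 1500, 1900, "SINE", "Alu"),  # nested in the LINE
        ]
        frag = type_fragment(1, "chr1", 1600)  # dyad 1673 inside both
        res = repeat_overlap([frag], repeats, gbs_map)
        assert res.summaries["SINE"].n_fragments == 1

    def test_fractions_sum_to_one(self, gbs_map, rng):
        repeats = [RepeatElement("chr1", int(s), int(s) + 400, "LTR") for s in range(1000, 20000, 3000)]
        frags = [type_fragment(1, "chr1", int(p), seed=i) for i, p in enumerate(rng.integers(0, 25000, 100))]
        res = repeat_overlap(frags, repeats, gbs_map)
        assert sum(res.fractions.values()) == pytest.approx(1.0)


class TestCompareStrains:
    def chrom_fragments(self, spec):
        """spec: {chrom: (n_type1, n_type4)} -> fragment list."""
        frags = []
        for chrom, (n1, n4) in spec.items():
            for i in range(n1):
                frags.append(type_fragment(1, chrom, 200 * i, seed=i))
            for i in range(n4):
                frags.append(type_fragment(4, chrom, 200 * (i + n1), seed=i))
        return frags

    def test_identical_strains(self, gbs_map):
        frags = self.chrom_fragments({"chr1": (3, 1), "chr2": (1, 3), "chr3": (2, 2)})
        res = compare_strains({"WT": frags, "same": list(frags)}, gbs_map)
        t, p = res.tests["same"]
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert res.mean_abs_deviation == pytest.approx(0.0)

    def test_opposite_extremes(self, gbs_map):
        wt = self.chrom_fragments({"chr1": (4, 0), "chr2": (5, 0), "chr3": (3, 0)})
        mut = self.chrom_fragments({"chr1": (0, 4), "chr2": (0, 5), "chr3": (0, 3)})
        res = compare_strains({"WT": wt, "mut": mut}, gbs_map)
        assert res.genomic_dnps["WT"] == 100.0
        assert res.genomic_dnps["mut"] == -100.0
        # all per-chromosome values are +/-100 exactly; zero within-group
        # variance makes the t statistic infinite and p underflows to 0
        t, p = res.tests["mut"]
        assert p < 0.05

    def test_matches_textbook_t_statistic(self, gbs_map):
        # per-chromosome dNPS: WT (100, 0, -100), mut (100, 100, 0)
        wt = self.chrom_fragments({"chr1": (2, 0), "chr2": (1, 1), "chr3": (0, 2)})
        mut = self.chrom_fragments({"chr1": (2, 0), "chr2": (2, 0), "chr3": (1, 1)})
        res = compare_strains({"WT": wt, "mut": mut}, gbs_map)
        a, b = np.array([100.0, 100.0, 0.0]), np.array([100.0, 0.0, -100.0])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res.tests["mut"][0] == pytest.approx(t_hand)
        assert res.mean_abs_deviation == pytest.approx(abs(a.mean() - b.mean()))

    def test_single_chromosome_strain_skipped(self, gbs_map):
        wt = self.chrom_fragments({"chr1": (2, 0), "chr2": (1, 1)})
        solo = self.chrom_fragments({"chr1": (1, 1)})
        res = compare_strains({"WT": wt, "solo": solo}, gbs_map)
        assert "solo" not in res.tests
        assert res.genomic_dnps["solo"] == 0.0

    def test_missing_reference(self, gbs_map):
        with pytest.raises(ValueError, match="reference"):
            compare_strains({"a": []}, gbs_map, reference="WT")
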