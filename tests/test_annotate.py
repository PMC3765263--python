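"""Genome mapping and priority-annotation tests."""

import numpy as np
import pytest

from mircycle.annotate import (
    AnnotationSummary,
    Feature,
    GenomeIndex,
    annotate_tags,
    load_bed,
    load_gff3,
    map_tags,
    revcomp,
    rrna_quality_check,
    write_bed,
)


def random_genome(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMapTags:
    def test_plus_and_minus_strand_hits(self):
        rng = np.random.default_rng(3)
        core = random_genome(rng, 500)
        tag = core[100:122]
        genome = {"c": core}
        hits, flagged, skipped = map_tags([tag, revcomp(tag)], genome)
        plus = [h for h in hits[tag] if h.strand == "+"]
        minus = [h for h in hits[revcomp(tag)] if h.strand == "-"]
        assert plus[0].start == 100 and plus[0].end == 122
        assert minus[0].start == 100 and minus[0].end == 122
        assert not flagged and not skipped

    def test_absent_tag_has_no_hits(self):
        rng = np.random.default_rng(4)
        genome = {"c": random_genome(rng, 1000)}
        tag = "ACGT" * 6  # repetitive, vanishingly unlikely by chance
        hits, _, _ = map_tags([tag], genome)
        assert tag not in hits

    def test_non_acgt_tag_skipped(self):
        genome = {"c": "ACGT" * 100}
        hits, _, skipped = map_tags(["ACGTNACGTACGTACGTACGT"], genome)
        assert skipped == 1 and not hits

    def test_high_copy_tag_flagged(self):
        tag = "ACGTTGCAACGTTGCAAGGCC"
        spacer = "TTTTTTTTTT"
        genome = {"c": spacer + (tag + spacer) * 25}
        hits, flagged, _ = map_tags([tag], genome, max_loci=20)
        assert flagged[tag] == 25
        assert len(hits[tag]) == 25

    def test_agrees_with_naive_scan(self):
        """Seed-and-verify mapping equals a naive substring scan of both
        strands on a small genome."""
        rng = np.random.default_rng(5)
        genome_seq = random_genome(rng, 5000)
        genome = {"c": genome_seq}
        tags = [genome_seq[i : i + 20] for i in (0, 77, 1234, 4980)]
        tags += [revcomp(genome_seq[500:522])]
        hits, _, _ = map_tags(tags, genome)
        rc = revcomp(genome_seq)
        for tag in tags:
            naive = []
            for strand, hay in (("+", genome_seq), ("-", rc)):
                start = hay.find(tag)
                while start >= 0:
                    if strand == "+":
                        naive.append((start, start + len(tag), "+"))
                    else:
                        s = len(hay) - start - len(tag)
                        naive.append((s, s + len(tag), "-"))
                    start = hay.find(tag, start + 1)
            got = sorted((h.start, h.end, h.strand) for h in hits.get(tag, []))
            assert got == sorted(naive)


def make_hits(tag, start, end, strand="+", chrom="c"):
    from mircycle.annotate import TagHit

    return {tag: [TagHit(tag, chrom, start, end, strand)]}


class TestAnnotateTags:
    TAG = "A" * 22

    def test_rrna_beats_mirna(self):
        feats = [
            Feature("c", 0, 100, "+", "rRNA", "genbank"),
            Feature("c", 0, 100, "+", "miRNA", "genbank"),
        ]
        classes, _ = annotate_tags({self.TAG: 1}, make_hits(self.TAG, 10, 32), feats)
        assert classes[self.TAG] == "rRNA"

    def test_repeat_beats_exon(self):
        feats = [
            Feature("c", 0, 100, "+", "repeat", "genbank"),
            Feature("c", 0, 100, "+", "exon", "genbank"),
        ]
        classes, _ = annotate_tags({self.TAG: 1}, make_hits(self.TAG, 10, 32), feats)
        assert classes[self.TAG] == "repeat"

    def test_genbank_outranks_rfam_within_ncrna_tier(self):
        feats = [
            Feature("c", 0, 100, "+", "rRNA", "rfam"),
            Feature("c", 0, 100, "+", "tRNA", "genbank"),
        ]
        classes, _ = annotate_tags({self.TAG: 1}, make_hits(self.TAG, 10, 32), feats)
        assert classes[self.TAG] == "tRNA"

    def test_exon_antisense_by_strand_disagreement(self):
        feats = [Feature("c", 0, 100, "+", "exon", "genbank")]
        classes, _ = annotate_tags(
            {self.TAG: 1}, make_hits(self.TAG, 10, 32, strand="-"), feats
        )
        assert classes[self.TAG] == "exon_antisense"

    def test_unmapped_tag_is_unan(self):
        classes, summary = annotate_tags({self.TAG: 3}, {}, [])
        assert classes[self.TAG] == "unan"
        assert summary.read_counts["unan"] == 3

    def test_unknown_feature_class_rejected(self):
        with pytest.raises(ValueError, match="lncRNA"):
            Feature("c", 0, 10, "+", "lncRNA", "genbank")

    def test_every_tag_gets_exactly_one_class(self, sim_annotation):
        """Partition property on the full simulated tag set."""
        classes = sim_annotation["classes"]
        summary = sim_annotation["summary"]
        all_tags = sim_annotation["all_tags"]
        assert set(classes) == set(all_tags)
        assert sum(summary.unique_counts.values()) == len(all_tags)
        assert sum(summary.read_counts.values()) == sum(all_tags.values())

    def test_planted_features_annotated_as_planted(self, sim, sim_annotation):
        truth, classes = sim["truth"], sim_annotation["classes"]
        for p in truth.conserved():
            assert classes[p.mature_seq] == "miRNA"
        for p in truth.novel():
            assert classes[p.mature_seq] == "unan"


class TestRrnaQuality:
    def test_fraction_below_threshold_passes(self):
        s = AnnotationSummary(read_counts={"rRNA": 2801, "exon_sense": 7199},
                              total_reads=10000)
        verdict, frac = rrna_quality_check(s)
        assert verdict == "PASS" and frac == pytest.approx(28.01)

    def test_boundary_is_warn(self):
        s = AnnotationSummary(read_counts={"rRNA": 40}, total_reads=100)
        assert rrna_quality_check(s)[0] == "WARN"

    def test_empty_library_passes(self):
        verdict, frac = rrna_quality_check(AnnotationSummary())
        assert verdict == "PASS" and frac == 0.0


class TestIO:
    def test_bed_roundtrip(self, tmp_path):
        feats = [
            Feature("c1", 5, 50, "+", "rRNA", "rfam"),
            Feature("c1", 80, 120, "-", "exon", "genbank"),
        ]
        path = tmp_path / "f.bed"
        write_bed(feats, path)
        assert load_bed(path) == feats

    def test_gff3_coordinates_converted(self, tmp_path):
        path = tmp_path / "f.gff3"
        path.write_text("c1\tgenbank\texon\t6\t50\t.\t+\t.\tID=x\n")
        feats = load_gff3(path)
        assert feats[0].start == 5 and feats[0].end == 50
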