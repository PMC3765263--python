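"""Read-filtering, tag-collapsing and length-distribution tests."""

import numpy as np
import pytest

from mircycle.preprocess import (
    CleanLibrary,
    FilterPolicy,
    FilterStats,
    collapse_tags,
    filter_reads,
    length_distribution,
)

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{qual}\n")


def hq(seq):
    return (seq, "I" * len(seq))


class TestFilterReads:
    def test_each_category_lands_once(self, tmp_path):
        insert22 = "ACGTACGTACGTACGTACGTAC"
        reads = [
            hq(insert22 + ADAPTER3),                      # clean
            hq("CCGTCCGTCCGTCCGTCCGTCCGTCCGTCCGTCCGTCCGT"),  # no 3' adapter
            hq(ADAPTER3),                                  # empty insert
            hq(ADAPTER5 + "ACGTACGT" + ADAPTER3),          # 5' contamination
            hq("ACGTACGTACGTACGT" + ADAPTER3),             # 16 nt insert
            hq("A" * 22 + ADAPTER3),                       # polyA
            hq(insert22 + "N" * 4 + ADAPTER3),             # low quality (Ns)
            (insert22 + ADAPTER3, "#" * (22 + len(ADAPTER3))),  # low quality (phred)
            hq("ACGT" * 9 + ADAPTER3),                     # 36 nt: over the cap
        ]
        path = tmp_path / "mix.fastq"
        write_fastq(path, reads)
        lib, stats = filter_reads(path, ADAPTER3, ADAPTER5)
        assert stats.total_reads == 9
        assert stats.high_quality == 7
        assert stats.low_quality == 2
        assert stats.adapter3_null == 1
        assert stats.insert_null == 1
        assert stats.adapter5_contaminants == 1
        assert stats.smaller_than_18nt == 1
        assert stats.polyA == 1
        assert stats.longer_than_max == 1
        assert stats.clean_reads == 1
        assert lib.tags == {insert22: 1}
        stats.check_partition()

    def test_insert_shorter_than_18_is_not_a_tag(self, tmp_path):
        path = tmp_path / "short.fastq"
        write_fastq(path, [hq("ACGTACGTACGTACGT" + ADAPTER3)])
        lib, stats = filter_reads(path, ADAPTER3, ADAPTER5)
        assert stats.smaller_than_18nt == 1
        assert lib.tags == {}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        lib, stats = filter_reads(path, ADAPTER3, ADAPTER5)
        assert stats.total_reads == 0 and lib.tags == {}

    def test_malformed_record_reports_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nIIII\n")
        with pytest.raises(ValueError, match="index 1"):
            filter_reads(path, ADAPTER3, ADAPTER5)

    def test_empty_adapter_rejected(self, tmp_path):
        path = tmp_path / "x.fastq"
        write_fastq(path, [hq("ACGT")])
        with pytest.raises(ValueError, match="adapters"):
            filter_reads(path, "", ADAPTER5)

    def test_generator_injection_recovered_exactly(self, sim):
        """The per-category injected counts of the simulator are recovered
        verbatim by the filter (the accounting round-trip)."""
        for stage, stats in sim["stats"].items():
            injected = sim["truth"].injected[stage]
            assert stats.low_quality == injected["low_quality"]
            for cat in (
                "adapter3_null",
                "insert_null",
                "adapter5_contaminants",
                "smaller_than_18nt",
                "polyA",
            ):
                assert getattr(stats, cat) == injected[cat], cat
            stats.check_partition()

    def test_filtering_is_idempotent(self, sim, tmp_path):
        """Re-filtering the cleaned output changes nothing."""
        lib = sim["clean"]["anagen"]
        path = tmp_path / "refilter.fastq"
        with open(path, "w") as fh:
            i = 0
            for tag, count in list(lib.tags.items())[:500]:
                for _ in range(min(count, 3)):
                    seq = tag + ADAPTER3
                    fh.write(f"@t{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                    i += 1
        relib, restats = filter_reads(path, ADAPTER3, ADAPTER5)
        assert restats.clean_reads == restats.high_quality == restats.total_reads
        assert set(relib.tags) == set(list(lib.tags)[:500])

    def test_partition_invariant_on_random_reads(self, tmp_path):
        """Fuzz: category counts always partition high-quality reads."""
        rng = np.random.default_rng(0)
        reads = []
        for _ in range(400):
            n = int(rng.integers(5, 60))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            qual = "".join(rng.choice(list("#5I"), size=n))
            reads.append((seq, qual))
        path = tmp_path / "fuzz.fastq"
        write_fastq(path, reads)
        lib, stats = filter_reads(path, ADAPTER3, ADAPTER5)
        stats.check_partition()
        assert stats.total_reads == 400
        assert sum(lib.tags.values()) == stats.clean_reads


class TestCollapseAndLengths:
    def test_collapse_merges_identical_inserts(self):
        reads = ["ACGTACGTACGTACGTAC"] * 3 + ["TTGACCGTACGTACGTCA"] * 2
        lib = collapse_tags(reads)
        assert lib.tags == {
            "ACGTACGTACGTACGTAC": 3,
            "TTGACCGTACGTACGTCA": 2,
        }
        assert lib.total_clean == 5

    def test_all_distinct(self):
        reads = [f"ACGTACGTACGTACGTA{b}" for b in "ACGT"]
        lib = collapse_tags(reads)
        assert lib.n_unique == 4 and lib.total_clean == 4

    def test_lexicographic_tag_order(self):
        lib = collapse_tags(["TTTTTTTTTTTTTTTTTT", "AAAAAAAAAAAAAAAAAC"])
        assert list(lib.tags) == sorted(lib.tags)

    def test_single_tag_histograms(self):
        lib = CleanLibrary(stage="s", tags={"A" * 22: 10})
        dists = length_distribution([lib])["s"]
        assert dists["total"] == {22: 10}
        assert dists["distinct"] == {22: 1}

    def test_empty_library(self):
        dists = length_distribution([CleanLibrary(stage="s")])["s"]
        assert dists["total"] == {} and dists["distinct"] == {}

    def test_modal_insert_length_is_22(self, sim):
        """The simulated libraries peak at the canonical 22-nt length."""
        dists = length_distribution(sim["clean"].values())
        for stage, hists in dists.items():
            assert max(hists["total"], key=hists["total"].get) == 22

    def test_zero_noise_tag_counts_match_planted(self, tmp_path):
        from mircycle import synthetic as syn

        cfg = syn.default_config(seed=5, reads_per_library=30_000, count_noise="exact")
        genome, truth = syn.generate_genome(cfg)
        libs = syn.simulate_reads(genome, truth, cfg)
        path = tmp_path / "a.fastq"
        syn.write_fastq(libs["anagen"], "anagen", path)
        lib, _ = filter_reads(path, cfg.adapter3, cfg.adapter5)
        matures = {p.mirna_id: p.mature_seq for p in truth.precursors}
        for mid, want in truth.realized_counts["anagen"].items():
            assert lib.tags.get(matures[mid], 0) == want


class TestStatsArithmetic:
    def test_percentages_relative_to_high_quality(self):
        stats = FilterStats.from_category_counts(
            total_reads=110,
            high_quality=100,
            adapter3_null=5,
            insert_null=5,
            adapter5_contaminants=0,
            smaller_than_18nt=10,
            polyA=0,
        )
        assert stats.clean_reads == 80
        assert stats.percentages["clean_reads"] == pytest.approx(80.0)
        assert stats.percentages["smaller_than_18nt"] == pytest.approx(10.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(AssertionError):
            FilterStats(
                total_reads=10, high_quality=10, clean_reads=5
            ).check_partition()
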