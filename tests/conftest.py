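"""Shared fixtures: one default synthetic study per test session."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from mircycle import preprocess as pre
from mircycle import synthetic as syn

STAGES = ("anagen", "catagen", "telogen")


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """The default simulated study, written to disk and pre-filtered.

    Returns a dict with the config, genome, ground truth, artifact
    directory, clean libraries and filter stats per stage.
    """
    outdir = tmp_path_factory.mktemp("sim")
    cfg = syn.default_config(seed=7)
    genome, truth = syn.write_outputs(outdir, cfg)
    clean, stats = {}, {}
    for stage in STAGES:
        clean[stage], stats[stage] = pre.filter_reads(
            outdir / f"{stage}.fastq", cfg.adapter3, cfg.adapter5, stage=stage
        )
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "dir": outdir,
        "clean": clean,
        "stats": stats,
    }


@pytest.fixture(scope="session")
def sim_annotation(sim):
    """Mapping + annotation of the pooled unique tags of the default study."""
    from mircycle import annotate as ann

    all_tags = {}
    for lib in sim["clean"].values():
        for tag, c in lib.tags.items():
            all_tags[tag] = all_tags.get(tag, 0) + c
    hits, flagged, skipped = ann.map_tags(sorted(all_tags), sim["genome"])
    classes, summary = ann.annotate_tags(all_tags, hits, sim["truth"].features)
    return {
        "all_tags": all_tags,
        "hits": hits,
        "flagged": flagged,
        "classes": classes,
        "summary": summary,
    }
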