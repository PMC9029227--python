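"""Shared fixtures: a small fully ground-truthed synthetic study.

The small study (10 compliant hairpins, 10 decoys, 5k reads/sample,
error-free reads) is generated once per session; most stage-level tests
read from it.  The large discovery benchmark (50 hairpins / 200 decoys)
lives in the acceptance tests.
"""

from __future__ import annotations

from collections import Counter

import pytest

from sexmir.read_processing import filter_reads
from sexmir.synthetic_data import (
    ExpressionModel,
    SyntheticSpec,
    generate_genome,
    generate_reads,
)

SMALL_KW = dict(
    seed=3,
    chromosomes=(("chr1", 30000), ("chr2", 30000), ("chr3", 30000), ("chr4", 30000)),
    n_planted_hairpins=10,
    n_decoy_loci=10,
    n_known=4,
    depth=5000,
    category_counts={
        "low_quality": 100, "adapter3_null": 80, "adapter5_contaminant": 50,
        "insert_null": 50, "polyA": 100, "shorter_than_min": 200,
    },
    ncrna_fragment_reads=300,
    degradation_fragment_reads=200,
    repeat_fragment_reads=100,
    expression_model=ExpressionModel(
        n_female_biased=2, n_male_biased=2, n_female_specific=1, n_male_specific=1),
    error_rate=0.0,
    n_transcripts=20,
)


def small_spec() -> SyntheticSpec:
    return SyntheticSpec(**SMALL_KW)


@pytest.fixture(scope="session")
def small_study():
    """(spec, genome, gff, repeats, references, truth) for the small config."""
    spec = small_spec()
    genome, gff, repeats, refs, truth = generate_genome(spec)
    return spec, genome, gff, repeats, refs, truth


@pytest.fixture(scope="session")
def small_reads(small_study):
    """In-memory reads for every sample of the small study (error-free)."""
    spec, genome, _gff, _repeats, _refs, truth = small_study
    truth, reads = generate_reads(spec, truth, out_dir=None, genome=genome)
    return truth, reads


@pytest.fixture(scope="session")
def small_tags(small_study, small_reads):
    """Filtered and collapsed tag counts {tag: {sample: count}}."""
    spec = small_study[0]
    _truth, reads = small_reads
    fp = spec.filter_params()
    tag_counts: dict[str, dict[str, int]] = {}
    reports = {}
    for sample, _sex in spec.samples:
        inserts, report = filter_reads(reads[sample], fp)
        reports[sample] = report
        for seq, c in Counter(inserts).items():
            tag_counts.setdefault(seq, {})[sample] = c
    return tag_counts, reports
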