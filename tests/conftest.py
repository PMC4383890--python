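import numpy as np
import pytest

import coexmap as cm


@pytest.fixture(scope="session")
def toy_layout():
    """Two overlapping genes and six hand-placed reads.

    Gene A: exons [101,200] + [301,400] (1-based inclusive), intron (200,300].
    Gene B: exon [151,250]; A and B overlap on [151,200].
    Hand tally (max_overlap, gene level):
      r1 [100,150)  A=50 B=0            -> feature A
      r2 [160,210)  A=40 B=50           -> feature B
      r3 [170,200)  A=30 B=30           -> ambiguous (tie)
      r4 [210,240)  A exon 0, B exon 30 -> feature B (exon beats intron)
      r5 [260,290)  exon 0, A intron 30 -> intron A
      r6 [900,950)  nothing             -> no_feature
    HTSeq union mode: r1 A, r2 ambiguous, r3 ambiguous, r4 B,
    r5 no_feature, r6 no_feature.
    """
    return {
        "chromosomes": {"chr1": 10_000},
        "genes": [
            {
                "gene_id": "GA",
                "chrom": "chr1",
                "strand": "+",
                "biotype": "protein_coding",
                "transcripts": [
                    {"transcript_id": "GA.t1", "exons": [[101, 200], [301, 400]]}
                ],
            },
            {
                "gene_id": "GB",
                "chrom": "chr1",
                "strand": "-",
                "biotype": "lincRNA",
                "transcripts": [{"transcript_id": "GB.t1", "exons": [[151, 250]]}],
            },
        ],
        "reads": [
            {"read_id": "r1", "chrom": "chr1", "pos": 101, "cigar": "50M"},
            {"read_id": "r2", "chrom": "chr1", "pos": 161, "cigar": "50M"},
            {"read_id": "r3", "chrom": "chr1", "pos": 171, "cigar": "30M"},
            {"read_id": "r4", "chrom": "chr1", "pos": 211, "cigar": "30M"},
            {"read_id": "r5", "chrom": "chr1", "pos": 261, "cigar": "30M"},
            {"read_id": "r6", "chrom": "chr1", "pos": 901, "cigar": "50M"},
        ],
    }


@pytest.fixture(scope="session")
def module_data():
    """Planted-module count matrix at the study conditions
    (5 modules x 20 genes, 100 background, 60 samples)."""
    spec = cm.ModuleSpec(seed=11)
    table, truth = cm.gen_module_matrix(spec)
    return table, truth


@pytest.fixture(scope="session")
def module_map(module_data):
    table, truth = module_data
    expr = cm.normalize(table)
    weights = cm.redundancy_weights(
        cm.sample_similarity(expr), 0.95, expr.sample_ids
    )
    return cm.build_map(expr, weights), truth, expr, weights
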