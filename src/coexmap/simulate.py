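"""Seeded generators for synthetic test inputs.

Three families: (1) toy GTF + SAM layouts whose expected counts are
computed by an embedded straight-line assigner kept deliberately
independent of :mod:`coexmap.counting`; (2) count matrices with planted
latent-factor co-expression modules, optional anti-correlated gene
pairs and duplicated samples; (3) matrices with an exact number of
features passing / failing the expression filter.

All generators are pure functions of their arguments: the same spec and
seed give byte-identical output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import SPECIAL_COUNTERS, CountTable

# ---------------------------------------------------------------------------
# Toy alignments


def _layout_gtf(layout: dict) -> str:
    lines = []
    for gene in layout["genes"]:
        for tx in gene["transcripts"]:
            for start, end in tx["exons"]:  # 1-based inclusive
                attrs = (
                    f'gene_id "{gene["gene_id"]}"; '
                    f'transcript_id "{tx["transcript_id"]}"; '
                    f'gene_biotype "{gene.get("biotype", "protein_coding")}";'
                )
                lines.append(
                    "\t".join(
                        [
                            gene["chrom"],
                            "sim",
                            "exon",
                            str(start),
                            str(end),
                            ".",
                            gene.get("strand", "+"),
                            ".",
                            attrs,
                        ]
                    )
                )
    return "\n".join(lines) + "\n"


def _layout_sam(layout: dict) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in sorted(layout["chromosomes"].items()):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for read in layout["reads"]:
        fields = [
            read["read_id"],
            str(read.get("flag", 0)),
            read["chrom"],
            str(read["pos"]),
            str(read.get("mapq", 60)),
            read["cigar"],
            "*",
            "0",
            "0",
            "*",
            "*",
        ]
        nh = read.get("nh", 1)
        fields.append(f"NH:i:{nh}")
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def _ref_bases(pos1: int, cigar: str) -> set[int]:
    """0-based reference positions consumed by a CIGAR (brute force)."""
    bases: set[int] = set()
    ref = pos1 - 1
    for n_str, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n_str)
        if op in "M=XD":
            for p in range(ref, ref + n):
                bases.add(p)
            ref += n
        elif op == "N":
            ref += n
    return bases


def brute_force_counts(
    layout: dict,
    mode: str = "max_overlap",
    level: str = "gene",
    multicount: bool = False,
    min_mapq: int = 0,
    sample_id: str = "sample",
) -> CountTable:
    """Expected counts by literal base-set arithmetic over the layout.

    This is a second, independent implementation of the assignment rules
    (sets of integer base positions instead of interval arithmetic) used
    as the counting oracle.
    """
    # exonic / intronic base sets per feature
    features: list[tuple[str, set[int], set[int], str]] = []  # id, exonic, intronic, chrom
    for gene in layout["genes"]:
        chrom = gene["chrom"]
        if level == "gene":
            exonic: set[int] = set()
            for tx in gene["transcripts"]:
                for start, end in tx["exons"]:
                    exonic |= set(range(start - 1, end))
            span = set(range(min(exonic), max(exonic) + 1))
            features.append((gene["gene_id"], exonic, span - exonic, chrom))
        else:
            for tx in gene["transcripts"]:
                exonic = set()
                for start, end in tx["exons"]:
                    exonic |= set(range(start - 1, end))
                features.append((tx["transcript_id"], exonic, set(), chrom))

    feature_ids = [f[0] for f in features]
    fcounts = dict.fromkeys(feature_ids, 0)
    gene_ids = [g["gene_id"] for g in layout["genes"]]
    icounts = dict.fromkeys(gene_ids, 0)
    special = dict.fromkeys(SPECIAL_COUNTERS, 0)

    for read in layout["reads"]:
        flag = read.get("flag", 0)
        if flag & 0x4 or flag & 0x100 or flag & 0x800:
            continue
        if read.get("nh", 1) > 1:
            special["not_unique"] += 1
            continue
        if read.get("mapq", 60) < min_mapq:
            special["low_quality"] += 1
            continue
        bases = _ref_bases(read["pos"], read["cigar"])
        ex_ov = {
            fid: len(bases & exonic)
            for fid, exonic, _intr, chrom in features
            if chrom == read["chrom"]
        }
        positive = {fid: ov for fid, ov in ex_ov.items() if ov > 0}
        if level == "transcript" and multicount:
            if positive:
                for fid in positive:
                    fcounts[fid] += 1
            else:
                special["no_feature"] += 1
            continue
        if mode == "htseq_union":
            if len(positive) == 1:
                fcounts[next(iter(positive))] += 1
            elif len(positive) >= 2:
                special["ambiguous"] += 1
            else:
                special["no_feature"] += 1
            continue
        if positive:
            best = max(positive.values())
            winners = [fid for fid, ov in positive.items() if ov == best]
            if len(winners) == 1:
                fcounts[winners[0]] += 1
            else:
                special["ambiguous"] += 1
            continue
        if level == "gene":
            in_ov = {
                fid: len(bases & intr)
                for fid, _ex, intr, chrom in features
                if chrom == read["chrom"] and len(bases & intr) > 0
            }
            if in_ov:
                best = max(in_ov.values())
                winners = [fid for fid, ov in in_ov.items() if ov == best]
                if len(winners) == 1:
                    icounts[winners[0]] += 1
                else:
                    special["ambiguous"] += 1
                continue
        special["no_feature"] += 1

    intron = level == "gene"
    return CountTable(
        feature_ids=feature_ids,
        sample_ids=[sample_id],
        counts=np.array([[fcounts[f]] for f in feature_ids]),
        intron_gene_ids=gene_ids if intron else [],
        intron_counts=(
            np.array([[icounts[g]] for g in gene_ids]) if intron else None
        ),
        special_counts={k: np.array([v]) for k, v in special.items()},
    )


def gen_toy_alignments(
    layout: dict,
    seed: int = 0,
    mode: str = "max_overlap",
    level: str = "gene",
) -> tuple[str, str, CountTable]:
    """(GTF text, SAM text, expected CountTable) for a hand-written layout."""
    for read in layout["reads"]:
        length = layout["chromosomes"].get(read["chrom"])
        if length is None:
            raise ValueError(f"read {read['read_id']} on undeclared chromosome")
        last = max(_ref_bases(read["pos"], read["cigar"]), default=read["pos"] - 1)
        if last >= length:
            raise ValueError(
                f"read {read['read_id']} extends past chromosome end"
            )
    return (
        _layout_gtf(layout),
        _layout_sam(layout),
        brute_force_counts(layout, mode=mode, level=level),
    )


def random_alignment_layout(
    seed: int, max_reads: int = 50, max_genes: int = 4
) -> dict:
    """A random layout of up to ``max_genes`` overlapping genes and up to
    ``max_reads`` reads, including spliced, deleted, unmapped, secondary,
    multi-hit and low-MAPQ records."""
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    chrom_len = 6000
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    for g in range(n_genes):
        start = int(rng.integers(1, 2500))
        n_exons = int(rng.integers(1, 4))
        exons = []
        cursor = start
        for _ in range(n_exons):
            length = int(rng.integers(20, 120))
            exons.append([cursor, cursor + length - 1])  # 1-based inclusive
            cursor += length + int(rng.integers(10, 200))
        genes.append(
            {
                "gene_id": f"G{g:02d}",
                "chrom": chrom,
                "strand": "+" if rng.random() < 0.5 else "-",
                "biotype": "protein_coding",
                "transcripts": [
                    {"transcript_id": f"G{g:02d}.t1", "exons": exons}
                ],
            }
        )
    n_reads = int(rng.integers(0, max_reads + 1))
    reads = []
    for i in range(n_reads):
        pos = int(rng.integers(1, 3500))
        style = rng.random()
        if style < 0.6:
            cigar = f"{int(rng.integers(20, 80))}M"
        elif style < 0.85:
            cigar = (
                f"{int(rng.integers(10, 40))}M"
                f"{int(rng.integers(20, 300))}N"
                f"{int(rng.integers(10, 40))}M"
            )
        else:
            cigar = (
                f"{int(rng.integers(10, 30))}M"
                f"{int(rng.integers(1, 10))}D"
                f"{int(rng.integers(10, 30))}M"
            )
        flag = 0
        if rng.random() < 0.05:
            flag = 4
        elif rng.random() < 0.05:
            flag = 256
        reads.append(
            {
                "read_id": f"r{i:04d}",
                "chrom": chrom,
                "pos": pos,
                "cigar": cigar,
                "flag": flag,
                "mapq": int(rng.integers(0, 61)),
                "nh": 2 if rng.random() < 0.08 else 1,
            }
        )
    return {"chromosomes": {chrom: chrom_len}, "genes": genes, "reads": reads}


# ---------------------------------------------------------------------------
# Planted-module count matrices


@dataclass
class ModuleSpec:
    """Latent-factor design for planted co-expression modules.

    Genes in module m share a per-sample factor f_ms ~ N(0, factor_sd)
    on the log-intensity scale with gene noise N(0, noise_sd); counts
    are multinomial per sample at ``library_size``, which couples genes
    through the total-count constraint exactly where the normalization
    operates.
    """

    n_modules: int = 5
    genes_per_module: int = 20
    n_background_genes: int = 100
    n_samples: int = 60
    factor_sd: float = 1.0
    noise_sd: float = 0.5
    negative_gene_pairs: int = 0
    duplicate_samples: int = 0
    library_size: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_modules > 0 and self.genes_per_module < 2:
            raise ValueError("genes_per_module must be >= 2")
        if self.negative_gene_pairs > 0 and self.n_modules < 1:
            raise ValueError("negative pairs require at least one module")
        for name in ("n_samples", "library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModuleTruth:
    """Ground-truth labels: module id per gene (-1 = background) and the
    anti-correlated pairs."""

    modules: dict[str, int]
    negative_pairs: list[tuple[str, str]] = field(default_factory=list)

    def is_within(self, a: str, b: str) -> bool:
        ma, mb = self.modules[a], self.modules[b]
        return ma >= 0 and ma == mb

    def pair_labels(self, feature_ids: list[str]) -> dict[tuple[str, str], str]:
        """'within' / 'between' for every unordered pair."""
        out = {}
        for i, a in enumerate(feature_ids):
            for b in feature_ids[i + 1:]:
                out[(a, b)] = "within" if self.is_within(a, b) else "between"
        return out


def gen_module_matrix(spec: ModuleSpec) -> tuple[CountTable, ModuleTruth]:
    """Draw a count matrix with planted modules (see :class:`ModuleSpec`)."""
    seed = spec.seed
    for _attempt in range(10):
        table, truth, ok = _draw_module_matrix(spec, seed)
        if ok:
            return table, truth
        seed += 1  # deterministic retry on a zero-variance row
    raise RuntimeError("could not draw a matrix without zero-variance rows")


def _draw_module_matrix(spec: ModuleSpec, seed: int):
    rng = np.random.default_rng(seed)
    n_module_genes = spec.n_modules * spec.genes_per_module
    n_neg = 2 * spec.negative_gene_pairs
    n_genes = n_module_genes + n_neg + spec.n_background_genes
    s = spec.n_samples

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    modules = {}
    loadings = np.zeros((n_genes, max(spec.n_modules, 1)))
    idx = 0
    for m in range(spec.n_modules):
        for _ in range(spec.genes_per_module):
            modules[gene_ids[idx]] = m
            loadings[idx, m] = 1.0
            idx += 1
    negative_pairs = []
    for p in range(spec.negative_gene_pairs):
        m = p % spec.n_modules
        a, b = gene_ids[idx], gene_ids[idx + 1]
        modules[a] = m
        modules[b] = -1  # anti-member: not 'within' the module
        loadings[idx, m] = 1.0
        loadings[idx + 1, m] = -1.0
        negative_pairs.append((a, b))
        idx += 2
    for _ in range(spec.n_background_genes):
        modules[gene_ids[idx]] = -1
        idx += 1

    mu = rng.normal(0.0, 1.0, size=n_genes)
    factors = rng.normal(0.0, spec.factor_sd, size=(max(spec.n_modules, 1), s))
    eps = rng.normal(0.0, spec.noise_sd, size=(n_genes, s))
    log_intensity = mu[:, None] + loadings @ factors + eps
    # per-sample softmax -> multinomial at the library size
    z = log_intensity - log_intensity.max(axis=0, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.empty((n_genes, s), dtype=np.int64)
    for j in range(s):
        counts[:, j] = rng.multinomial(spec.library_size, probs[:, j])

    sample_ids = [f"s{j:03d}" for j in range(s)]
    if spec.duplicate_samples > 0:
        d = min(spec.duplicate_samples, s)
        counts = np.hstack([counts, counts[:, :d]])
        sample_ids = sample_ids + [f"s{j:03d}_dup" for j in range(d)]

    ok = bool((counts.std(axis=1) > 0).all())
    table = CountTable(
        feature_ids=gene_ids, sample_ids=sample_ids, counts=counts
    )
    return table, ModuleTruth(modules, negative_pairs), ok


# ---------------------------------------------------------------------------
# Filter-boundary matrices


def gen_filter_matrix(
    n_pass: int,
    n_fail: int,
    n_samples: int,
    seed: int = 0,
    min_reads: int = 10,
    min_sample_fraction: float = 0.10,
) -> CountTable:
    """A matrix in which exactly ``n_pass`` features survive the expression
    filter and exactly ``n_fail`` do not."""
    if n_samples < 10:
        raise ValueError("need at least 10 samples for fraction granularity")
    rng = np.random.default_rng(seed)
    n = n_pass + n_fail
    need = int(np.ceil(min_sample_fraction * n_samples))
    # baseline: everything below the read threshold
    counts = rng.integers(0, min_reads, size=(n, n_samples), dtype=np.int64)
    which_pass = np.zeros(n, dtype=bool)
    which_pass[rng.permutation(n)[:n_pass]] = True
    pass_rows = np.flatnonzero(which_pass)
    if pass_rows.size:
        # give each passing feature >= min_reads in exactly `need` samples
        cols = np.argsort(rng.random((pass_rows.size, n_samples)), axis=1)[:, :need]
        boost = rng.integers(min_reads, 5 * min_reads, size=cols.shape, dtype=np.int64)
        counts[pass_rows[:, None], cols] = boost
    feature_ids = [f"f{i:06d}" for i in range(n)]
    sample_ids = [f"s{j:03d}" for j in range(n_samples)]
    return CountTable(feature_ids=feature_ids, sample_ids=sample_ids, counts=counts)
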