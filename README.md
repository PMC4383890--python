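# coexmap

RNA-seq co-expression maps for genes and transcripts, with
guilt-by-association queries.

Co-expression analysis infers what a poorly studied gene or transcript
does from the company it keeps: genes whose expression rises and falls
together across many heterogeneous samples tend to share regulation and
function. `coexmap` builds such a map from bulk RNA-seq counts and lets
you query it — for a single gene, a transcript, or a seed list of
disease genes — returning the strongest co-expressed partners, the
transcription factors among them, locally computed functional
enrichment, and the most anti-correlated genes. Because RNA-seq
measures non-coding RNAs and individual splice variants, the same
machinery applies to lincRNAs, miRNAs and per-transcript maps, not just
protein-coding genes.

## What it computes

Starting from SAM alignments and a GTF annotation:

1. **Read counting with overlap-size disambiguation.** A read aligned
   where genes overlap is assigned to the gene covering the most of its
   aligned reference bases; exact ties are ambiguous. Intronic reads
   are tallied per gene, and ambiguous / unassigned / multi-mapping /
   low-quality reads are reported in separate counters. An
   HTSeq-count union-mode compatibility switch reproduces the standard
   behavior (any read touching two genes is discarded as ambiguous).
2. **QC, normalization, filtering.** Samples need ≥ 10 million reads
   with ≥ 60% mapped. Expression is the fraction of the sample's total
   feature count (reads not assigned to a feature are excluded from the
   denominator). Features without ≥ 10 reads in at least 10% of
   samples are dropped.
3. **Weighted correlation and mutual rank.** Samples that are
   near-duplicates (inter-sample Pearson r ≥ τ, default 0.95) get
   weight `w_i = 1/n_i` where `n_i` counts the samples similar to *i*.
   For every feature pair the weighted Pearson correlation

       r_w(x, y) = Σ w (x−x̄_w)(y−ȳ_w) / √(Σ w (x−x̄_w)² · Σ w (y−ȳ_w)²)

   is computed, each feature's partners are ranked by `r_w`, and the
   **mutual rank** of a pair is `MR(A,B) = (rank_A(B) + rank_B(A)) / 2`
   — low when both genes place each other near the top of their lists,
   which de-prioritizes promiscuous hubs such as ribosomal genes.
4. **Scrambled-null calibration.** Each expression row is permuted
   across samples; correlations from the scrambled matrix are the
   negatives of an ROC sweep that reports the AUC and the FDR and
   correlation threshold at a chosen sensitivity (default 95%).
5. **Queries.** Reports follow the classic layout: 50 strongest
   co-expressed genes, 25 strongest transcription factors, top 20
   hypergeometric enrichment terms over the top 1500 significantly
   co-expressed partners (significance cutoff α/N, Bonferroni), and the
   negatively correlated list. Seed lists are aggregated by mean
   forward rank or by top-5% vote counting; partner-list overlap
   compares two features' top-5% lists (a 114,936-feature map gives
   5,747-entry lists).

## Worked example

`examples/02_build_and_query.py` simulates counts with five planted
20-gene modules plus 100 background genes over 60 samples, builds the
map and queries it:

```
query gene: g0000 (module 0)
top 5 partners by mutual rank:
  g0015  r=+0.840  MR=  1.0  (same module)
  g0003  r=+0.725  MR=  2.5  (same module)
  g0004  r=+0.701  MR=  3.0  (same module)
  g0014  r=+0.690  MR=  3.5  (same module)
  g0008  r=+0.688  MR=  3.5  (same module)

seed list = 5 module-0 genes; of the top 15 candidates, 15 are the
remaining module members
```

`MR = 1.0` means the query and `g0015` are each other's strongest
partner. Seeding with five module members recovers the other fifteen
exactly — the guilt-by-association use case. The other examples cover
read counting against overlapping genes (`01`), FDR calibration against
the scrambled null (`03`) and the full shell pipeline (`04`).

The same steps are available as subcommands of one CLI:

```bash
coexmap simulate --preset modules --seed 4 --out-dir sim/
coexmap preprocess --counts sim/modules.counts.tsv --out expr.tsv
coexmap build --expr expr.tsv --out-prefix map --edge-list edges.tsv
coexmap query --map-prefix map --id g0000
```

`edges.tsv` is a three-column edge list importable into BioLayout or
Cytoscape.

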