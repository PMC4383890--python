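#!/usr/bin/env bash
# Full shell pipeline on simulated inputs:
#   simulate -> preprocess -> build -> query / overlap / calibrate
set -euo pipefail
dir=$(mktemp -d)

coexmap simulate --preset modules --seed 4 --out-dir "$dir" \
    --n-modules 2 --genes-per-module 8 --n-background-genes 30 --n-samples 40

coexmap preprocess --counts "$dir/modules.counts.tsv" \
    --out "$dir/expr.tsv" --min-reads 10 --min-sample-fraction 0.10

coexmap build --expr "$dir/expr.tsv" --out-prefix "$dir/map" \
    --tau 0.95 --edge-list "$dir/edges.tsv" --edge-k 5

echo "--- single-gene query ---"
coexmap query --map-prefix "$dir/map" --id g0000 | head -n 8

echo "--- partner-list overlap of two module mates ---"
coexmap overlap --map-prefix "$dir/map" --a g0000 --b g0001 --fraction 0.2

echo "--- scrambled-null calibration ---"
coexmap calibrate --expr "$dir/expr.tsv" --seed 1 --n-pairs 500

rm -rf "$dir"
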