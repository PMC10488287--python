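# sctiger

Inference of signed, directed, time-delayed gene regulatory networks (GRNs)
from **paired case-versus-control scRNA-seq datasets**.

The pipeline combines four ideas:

1. **Pseudotime ordering** — cells of each condition are ordered along an
   inferred trajectory (kNN graph + partition-based graph abstraction +
   diffusion pseudotime), turning snapshot data into per-gene series.
2. **Co-differential expression** — after cell-count matching, each gene
   contributes one series `Δe_g[t] = case_g[t] − control_g[t]`. Gene pairs
   that co-vary within a condition but have unrelated co-differential
   series carry no signal here, which filters classic co-expression false
   positives.
3. **Attention-based dilated causal convolutions** — one small network per
   target series (learnable per-channel attention, depthwise dilated causal
   convolutions with PReLU and residual connections, pointwise output) is
   trained to predict the target from the past of all series; attention
   scores are gap-thresholded into potential causes, each validated by
   permutation importance (time-shuffling the candidate must destroy the
   learned fit), with the pseudotime delay read from the first-layer kernel
   and the regulation sign from the correlation of the two series. The
   networks are implemented in pure NumPy with a small reverse-mode
   autodiff engine (`sctiger.causal.autograd`) and Adam — no deep-learning
   framework required.
4. **Permutation significance testing** — the whole discovery is repeated
   over random cell subsamples; a background built from gene-wise shuffled
   matrices parameterizes a negative-binomial null from which the minimum
   detection count for significance is derived.

Outputs per gene of interest: GraphML networks (per-goi + merged), a
Cytoscape-style edge table, raw per-run edge TSVs, and detection-frequency
histograms.

## CLI

```bash
# full pipeline
sctiger run --case case.csv --control control.csv --genes AR,PTEN \
    --permutations 100 --top-k 100 --max-dropout 0.9 --alpha 0.05 \
    --seed 1 -o results/

# benchmark a dataset directory (ExpressionData.csv + refNetwork.csv);
# direction, sign and self-loops are disregarded in the metrics
sctiger benchmark path/to/dataset --runs 10 -o metrics.tsv

# synthetic fixtures (paired case/control or trajectory benchmark data)
sctiger synth --kind case-control --genes 40 --cells 120 -o fixture/
sctiger synth --kind trajectory --topology HSC -o hsc_surrogate/

# dropout-injection robustness protocol
sctiger robustness --case case.csv --control control.csv --genes AR \
    --levels 0.01,0.02,0.05 --runs 10 -o robustness.json
```

Inputs: dense CSV/TSV (genes in rows, header = cell ids) or 10x-style MTX
directories (`matrix.mtx` + `genes.tsv`/`features.tsv` + `barcodes.tsv`).

## Package layout

| module | role |
| --- | --- |
| `sctiger.matrix` | expression-matrix container, CSV/TSV/MTX readers |
| `sctiger.preprocess` | QC filters, normalization, Leiden clustering, subsampling |
| `sctiger.pseudotime` | trajectory ordering (graph abstraction + diffusion pseudotime) |
| `sctiger.codiff` | co-differential matrix, dropout filter, candidate screening, signs |
| `sctiger.causal` | autodiff engine, per-target networks, attention thresholding, permutation importance, delay estimation |
| `sctiger.significance` | repeated-run edge frequencies, NB null, significant edges |
| `sctiger.grn_io` | GraphML / Cytoscape-table serialization, network merging |
| `sctiger.benchmark` | reference-network scoring protocol (precision/recall/F1/specificity) |
| `sctiger.synth` | synthetic generators with known ground truth, dropout injection |
| `sctiger.pipeline` | end-to-end orchestration, robustness & condition-flip protocols |
| `sctiger.cli` | `sctiger` command group |
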