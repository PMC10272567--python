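# osmonet

A tested, reusable pipeline for leaf/root osmotic-stress transcriptomics:
from a probe-level microarray intensity matrix to gene co-expression
networks, transcription-factor hubs and switch-gene calls, with a synthetic
data generator that plants ground truth for every stage.

## What it does

1. **Probe → gene consolidation** (`osmonet.probe_mapping`): best-hit
   resolution of a BLAST-tabular probe map (identity ≥ 90%, highest bit
   score, documented tie-breaks), averaging of probes that share a gene,
   and a conflict filter that discards genes whose probes show opposite
   fold changes (≤ −1 and ≥ +1 log2) within a single contrast.
2. **Differential expression** (`osmonet.diffexpr`): per-contrast two-group
   fits on log2 intensities, empirical-Bayes variance moderation
   (digamma/trigamma moment matching, Newton-inverted trigamma equation),
   moderated t-statistics, Benjamini–Hochberg adjustment, and DET calls at
   adjusted p < 0.05 and |log2 FC| ≥ 1.
3. **Clustering** (`osmonet.clustering`): condition means of the DET union
   → log2(x+1) → row standardization → Euclidean k-means (equivalent
   ordering to centered-Pearson distance), k selected where the
   Calinski–Harabasz argmax meets the SSE elbow, and per-gene cluster
   scores (correlation with the assigned centroid).
4. **Co-expression networks** (`osmonet.network`): cluster-score-filtered
   genes (score ≥ 0.8), Pearson correlations across the context's samples,
   edges at |r| ≥ 0.9 and p ≤ 0.05 (anti-correlations retained, signed),
   and TF hubs as the top 20% of TF nodes by degree — a single rule that
   reproduces the published 16/79, 27/136 and 12/61 hub counts.
5. **Switch genes** (`osmonet.switch_genes`): expression filtering (zeros,
   IQR percentile, linear FC ≥ 2, FDR ≤ 0.05), an |r|-percentile-thresholded
   network (85th percentile), k-means modules, heat cartography (K_π, z_g),
   APCC, and party/date/fight-club hub roles; switch genes are
   high-K_π, low-z_g nodes with negative APCC.
6. **Physiology** (`osmonet.physiology`): RWC, electrolyte leakage,
   2^−ΔΔCt and pooled-variance t-tests.
7. **Synthetic data** (`osmonet.synthetic`): a latent-factor generator for
   the 2 genotypes × 2 organs × 2 treatments × 3 replicates design with
   eight planted expression archetypes, module co-expression, hubs,
   anti-hubs (fight-club mechanism), probe redundancy and sign-conflicting
   probes — fully reproducible from a seed.
8. **Orchestration** (`osmonet.pipeline`, `osmonet.cli`): end-to-end runs,
   cluster→archetype matching for the three context networks (common,
   root-specific, leaf-specific), and DET count bookkeeping whose
   common/specific identities hold by construction.

## CLI

```bash
# generate synthetic inputs with planted truth
osmonet simulate --seed 1 --out scratch/sim

# full pipeline on those inputs (or --simulate to do both at once)
osmonet run-all --in scratch/sim --out scratch/run --seed 1

# individual stages
osmonet map   --in scratch/sim --out scratch/map
osmonet de    --in scratch/map --out scratch/de
osmonet swim  --in scratch/map --out scratch/swim --seed 1
osmonet report --de scratch/run/de_results.tsv --out scratch/counts.tsv
osmonet physio --seed 1 --out scratch/physio.tsv
```

`run-all` writes DE tables, cluster assignments/scores, k diagnostics,
GraphML + edge-list exports per context network, hub tables, the TF class
summary, the switch-gene table, and versioned JSON run metadata.

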