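# acst

Analysis of Consistent Signal Transduction (ACST): a topology-aware test
for signaling-pathway deregulation from two-group gene-expression data.

Instead of asking whether a pathway's genes are enriched for differential
expression, ACST asks whether the pathway contains **consistent
cascades** — transcription-factor → target edges whose expression changes
agree with the edge's sign (up–up or down–down across an activation,
opposite directions across a repression). The method:

1. computes a signed Welch *t* per gene (test group minus control);
2. squares it and standardizes the squares across all genes of the
   pathway catalog (the local statistic *z*), so observed and permuted
   scores live on one scale;
3. finds the **maximal consistent subgraphs** of each pathway — the
   weakly-connected components of the consistent-edge subgraph, using
   non-standardized *t* signs;
4. scores each component `w(d) · Σz`, where `d` is the directed distance
   (node count of the shortest directed path) from the component to the
   pathway's leaves and `w(d) = 1/d` by default — cascades near the
   pathway's terminal effectors count more;
5. sums component scores into a per-pathway global statistic, assessed by
   a **subject-sampling permutation null** (class labels shuffled over
   subjects, preserving gene–gene correlation; every permutation
   recomputes *t* and re-standardizes), with empirical p-values
   `(1 + #{null ≥ observed}) / (B + 1)` and a resampling-based FDR point
   estimate (null-expected exceedances over observed exceedances, capped
   at 1 and monotonized).

Pathways can come from KGML documents (only gene entries and `GErel`
relations are used; `expression` → +1, `repression` → −1, other → 0) or
from a plain signed TSV edge-list. A seeded synthetic-data module
generates pathway catalogs and expression matrices with planted
consistent cascades, plus a brute-force subgraph oracle, so the whole
pipeline is testable offline.

## Command line

```sh
# generate a synthetic benchmark (catalog + expression + labels + truth)
acst simulate --out-dir sim --n-pathways 20 --plant-chain 4 --effect 2 --seed 1

# run the analysis
acst run --pathway-dir sim/pathways --pathway-format edgelist \
         --expression sim/expression.tsv --labels sim/labels.tsv \
         --test-label test -B 1000 --seed 1 --out-dir out

# per-gene t / t² / z export
acst stats --pathway-dir sim/pathways --expression sim/expression.tsv \
           --labels sim/labels.tsv --test-label test --out stats.tsv

# repeatability between two result sets (Spearman rho + F-test)
acst compare out_a/results.tsv out_b/results.tsv
```

`acst run` writes `results.tsv` (pathway_id, name, n_genes_measured,
n_subgraphs, global_stat, pvalue, adj_pvalue, significant,
top_subgraph_nodes), `results.json` (full subgraph detail),
`subgraphs.tsv` / `subgraph_edges.tsv` (per-component node and edge
tables) and `manifest.json` (seed, B, input digests — enough to
reproduce the run exactly). Runs with identical configuration are
byte-identical. Sign convention: *t* > 0 means higher expression in the
`--test-label` group. `--weight` selects the position weight
(`reciprocal` or `exponential:<lam>`); `--alpha-adj` (default 0.25) is
the significance cut on adjusted values.

## Layout

- `src/acst/pathway_io.py` — KGML / edge-list parsing, measured-gene restriction
- `src/acst/expression_io.py` — expression matrix + labels loading/validation
- `src/acst/core_stats.py` — Welch t (scalar and batched), standardization
- `src/acst/consistency_engine.py` — consistency predicate, component
  enumeration, leaf distances, subgraph/pathway scores, fast compiled scorer
- `src/acst/inference.py` — permutation null, p-values, FDR, repeatability
- `src/acst/synthetic_fixtures.py` — seeded generators and the brute-force oracle
- `src/acst/cli.py` — `acst run | simulate | stats | compare`
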