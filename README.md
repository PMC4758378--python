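# uprhd

Tools for detecting activation of the **unfolded protein response (UPR)** in
Huntington's disease (HD) expression data, and for prioritizing genes that
connect the UPR to HD biology.

HD is caused by an expanded CAG repeat in the huntingtin gene (*HTT*); the
mutant protein is suspected of provoking endoplasmic-reticulum stress, whose
adaptive transcriptional program — the UPR, driven by the sensors IRE1
(ERN1), PERK (EIF2AK3) and ATF6 — can turn pro-apoptotic when stress
persists. Testing that hypothesis on transcriptomic data requires a chain of
analyses, each of which this package implements as a reusable, tested
library with a thin CLI:

- **`gsea_core`** — gene-set enrichment from scratch: a ranking metric
  (signal-to-noise or log2 fold change), the weighted Kolmogorov–Smirnov
  running-sum enrichment score *ES*, a permutation null (phenotype-label or
  random-gene-set), the normalized score *NES = ES / mean |ES_null, same
  sign|*, empirical p-values and a pooled permutation FDR, plus extraction
  of the **leading edge** (the set members at or before the running-sum
  peak — the genes that carry the signal). A comparison is called
  **up** when fdr ≤ 0.05 and NES ≥ +1.4, **down** when fdr ≤ 0.05 and
  NES ≤ −1.4.
- **`consensus`** — intersection of leading edges across models at
  configurable stringency (required comparisons + minimum support) to build
  consensus signatures of conserved UPR dysregulation.
- **`motif_scan`** — both-strand scanning of TSS-relative promoter windows
  ([−1000, +500) nt) for the stress response elements
  UPRE (`TGACGTGR`), ERSE-I (`CCAATN{9}CCACG`) and ERSE-II (`ATTGGNCCACG`),
  with per-gene presence calls and element-combination counts.
- **`enrichment_stats`** — hypergeometric tail test, Fisher exact test,
  Benjamini–Hochberg adjustment and flat-annotation over-representation
  analysis, shared by the motif and functional enrichment steps.
- **`cag_correlation`** — per-gene Spearman correlation of expression
  (FPKM) with CAG repeat length across an allelic series, with an empirical
  permutation FDR estimated separately for the positive and negative tails:
  `fdr(t) = mean_perm #{ρ_perm ≥ t} / #{ρ_obs ≥ t}`, clamped to [0, 1] and
  monotonized in |ρ|.
- **`network_prioritize`** — assembly of a seed-centred protein-interaction
  network around the UPR core components (ATF6, ATF4, DDIT3, EIF2AK3, ERN1,
  XBP1), overlay of annotation lists (apoptosis, HTT interactors with
  direct/indirect type), and tri-set prioritization that intersects the
  differential-UPR consensus, an HD therapeutic-target list and the HTT
  interactome into one evidence table per candidate gene.
- **`synthetic_data`** — seeded generators that emulate the statistical
  structure of every input (two-group expression with a planted
  coordinately shifted gene set, promoters with planted elements, a CAG
  allelic series with planted monotone responders, an interactome with
  planted annotation overlaps), each returning its ground truth so recovery
  is measurable.
- **`pipeline`** / **`uprhd` CLI** — end-to-end orchestration from a TOML
  config with deterministic seeding, per-stage TSV outputs and a manifest
  of input hashes.

## Worked example

Plant a 50-gene set shifted up by 1.5 noise-SD in the cases of a simulated
10 vs 10 comparison, then test it:

```python
from uprhd.synthetic_data import simulate_expression
from uprhd.io_gene_sets import GeneSet
from uprhd.gsea_core import gsea, results_to_frame

dataset, truth = simulate_expression(n_genes=1000, n_case=10, n_control=10,
                                     planted_set_size=50, effect=1.5, seed=7)
results = gsea(dataset, [GeneSet("UPR_SYNTH", "planted set", truth.planted_set)],
               n_perm=500, seed=1)
print(results_to_frame(results)[["set", "size", "es", "nes", "p", "fdr", "direction"]]
      .to_string(index=False))
```

prints

```
      set  size       es      nes     p  fdr direction
UPR_SYNTH    50 0.955717 2.146872 0.004  0.0        up
```

The planted set reaches ES ≈ 0.96 (the running sum climbs almost to its
maximum before any miss), NES ≈ 2.1 against 500 phenotype-permutation
nulls, an add-one-smoothed permutation p of 0.004, and is classified "up";
49 of its 50 genes fall in the leading edge.

The full synthetic pipeline runs from a config file:

```sh
uprhd run --config examples/pipeline.toml
```

and writes per-stage TSVs (per-comparison enrichment, consensus signature,
motif hits and enrichment, CAG correlation with permutation FDR, the
interactome in SIF, and the final prioritization table), a run log and a
manifest; re-running the same config reproduces every file byte for byte.

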