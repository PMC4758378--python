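# Methods

This note documents the statistical machinery, the defaults and their
rationale, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.

## Gene-set enrichment

Genes are ranked by a signed two-group differential metric. The default,
signal-to-noise, is

    s2n = (mu_case - mu_ctrl) / (s_case + s_ctrl)

with each group's sample SD floored at `0.2 * |group mean|` (and at 0.2
when both SD and mean are zero) — the convention of the widely used
enrichment tool, which keeps low-variance genes from dominating the
ranking. Signal-to-noise needs at least 3 samples per group; below that the
metric falls back, with a warning, to the difference of group means
(`log2fc`, appropriate because inputs are assumed to be on a log-like
scale). Ties are broken lexicographically by gene symbol so rankings are
exactly reproducible.

The enrichment score of a gene set walks the ranking: a hit at rank *i*
adds `|score_i|^p / sum_hits |score|^p`, a miss subtracts `1/(N - N_hits)`;
ES is the running-sum value of maximal absolute deviation from zero (first
such position on the rare exact tie). The weight exponent defaults to
`p = 1`, the classic choice that emphasizes genes with strong scores
without squaring away the rest. If every hit carries zero score (a fully
degenerate ranking), hits fall back to equal weights rather than dividing
by zero. ES is clamped to [−1, 1] against accumulated float error; a set
covering the whole ranking scores exactly 1.

Two permutation nulls are available. *Phenotype* permutation shuffles
sample labels and re-ranks — the stricter null, preserving gene-gene
correlation — and is chosen automatically when both groups have ≥ 7
samples, below which the label-permutation space is too small; otherwise
*gene-set* permutation draws random same-size sets on the fixed ranking.
`n_perm` defaults to 1000; values below 100 warn and below 10 raise. NES
divides ES by the mean |ES| of same-sign null values; if the null is
entirely one-sided the result is flagged (`UndefinedNESError` /
`note` field) rather than silently NaN. The permutation p-value is the
add-one-smoothed same-sign tail fraction. FDR is pooled over the sets
tested in a run, as the cited enrichment methodology does: for an observed
NES, the fraction of pooled same-sign null NES at least as extreme divided
by the fraction of observed NES at least as extreme, clamped to [0, 1].
With the handful of sets typical here this estimate is coarse but honest;
it is not a BH adjustment.

A comparison is classified **up** at fdr ≤ 0.05 and NES ≥ +1.4, **down** at
fdr ≤ 0.05 and NES ≤ −1.4, else **ns**. The asymmetric-looking pair of
bounds is deliberately symmetric; both are exposed via `Thresholds`.

The leading edge ("core enrichment") is the set members at ranks up to and
including the peak for positive ES, from the peak onward for negative ES.

## Consensus signatures

Per-comparison leading edges are intersected under a two-part rule: a gene
must occur in every *required* comparison (e.g. the human iPSC model) and
in at least `min_support` of the remaining ones (e.g. 4 of 6 murine
models). Up- and down-signatures are built independently from up- and
down-classified comparisons; time-series datasets contribute one comparison
per time point. The rule is monotone: relaxing support or removing a
required comparison never removes a gene.

## Promoter stress elements

The three consensus elements are compiled to fixed-width matchers: UPRE
`TGACGTGR` (8 nt, R = G/A), ERSE-I `CCAATN{9}CCACG` (19 nt), ERSE-II
`ATTGGNCCACG` (11 nt). Windows are TSS-relative, `[-1000, +500)` half-open,
0-based, with the TSS at offset 0; promoters arrive pre-cut in FASTA
(headers `>GENE` or `>GENE|window=-1000:+500`). Both strands are scanned by
default (strandedness of the original element mapping is not knowable from
the inputs, so it is a flag); a reverse-strand hit is reported at the
forward coordinate of its match start. All overlapping occurrences are
reported, but enrichment uses per-gene *presence*, counting a gene once per
element. The sequence letter N never matches, even against a pattern
spacer, so masked bases cannot create hits. Element-combination counts use
"at least these" semantics: a gene with all three elements contributes to
every pairwise count.

On uniform background the chance-hit rate is analytic — per position and
strand `2·(1/4)^8` for UPRE and `(1/4)^10` for each ERSE — which the test
suite uses to calibrate the scanner.

## Over-representation statistics

The hypergeometric upper tail `P(X >= k)` (scipy, log-space internally),
the 2×2 Fisher exact test (one-sided "greater" everywhere
over-representation is asked; it equals the hypergeometric tail on cell a),
and Benjamini–Hochberg step-up adjustment back both the motif enrichment
and the flat-annotation ORA. ORA restricts terms to the supplied universe,
drops (and logs) list genes outside it, and adjusts across all tested
terms. The promoter-enrichment universe is every gene with a promoter
record; target genes without one are excluded from both sides and logged,
since no presence call exists for them. GO-DAG propagation is the
annotation provider's responsibility — annotations are consumed flat.

## CAG-repeat correlation

Expression (FPKM) across an allelic series of CAG lengths (defaults 20, 80,
92, 111, 140, 175 — the repeat lengths of the knock-in series this emulates)
is correlated per gene with the repeat number using Spearman's rho
(mid-ranks for ties). The empirical FDR permutes the CAG labels
independently per gene in every round and, for a threshold t > 0, takes

    fdr_pos(t) = mean over rounds of #{rho_perm >= t} / #{rho_obs >= t}

clamped to [0, 1], mirrored for the negative tail. Each gene is assigned
the estimate at its own |rho|, then monotonized q-value-style (cumulative
minimum walking from weak to strong |rho|), so FDR never increases with
|rho|. Positive and negative tails are separate: a gene has one finite tail
FDR and 1 for the other, and at most one significance flag. Genes with zero
expression variance have no defined rank correlation; they are excluded
from both the observed and null tallies, flagged with rho = NaN, and
logged. Significance defaults to fdr < 0.01 (exposed as a flag). Replicates
within a CAG genotype are treated as independent observations.
Over-representation of a gene set among the significant genes is a
one-sided Fisher test; the expected-by-chance overlap is simply
`set size × genome-wide significant fraction`, reported to one decimal.

## Network prioritization

The interactome is the seed proteins (defaults: ATF6, ATF4, DDIT3, EIF2AK3,
ERN1, XBP1) plus their direct interaction partners; edges among included
nodes are retained by default (induced subgraph — the natural reading of a
database extract; `induced=False` restricts to seed–neighbor edges).
Self-loops and duplicate edges are dropped; an edge list containing no seed
is an error. Annotation overlays are exact set intersections; direct/
indirect HTT-interaction types are consumed from input, never inferred, and
conflicting types for one gene are an error. Tri-set prioritization emits
one record per gene in the intersection of the differential consensus,
therapeutic-target and HTT-interactor lists, joins motif flags and
correlation statistics where available (NA otherwise), and sorts by
correlation significance then gene.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its arguments including the seed, and
serializes its ground truth, so downstream recovery is scorable without
reaching into generator internals.

- *Expression*: background Normal(baseline 7, sd 1) in both groups — a
  log-intensity-like scale with light tails — with the planted set shifted
  by `effect × sd` in cases only. Defaults (1000 genes, 10 vs 10, 50-gene
  set, effect 1.5) are the conditions under which enrichment recovery is
  asserted. Not modeled: probe effects, batch structure, count
  overdispersion, gene-gene correlation; the enrichment stage consumes only
  rank structure, so these omissions chiefly flatter the phenotype-
  permutation null, and passing recovery tests bounds behavior on clean
  signal, not on confounded designs.
- *Promoters*: i.i.d. uniform A/C/G/T background — chosen because it makes
  chance-hit rates closed-form for scanner calibration — with each motif
  planted independently at its rate, uniform offset and strand, degenerate
  positions spelled at random. Real promoters are GC-biased and repetitive;
  absolute hit rates on real sequence will differ from the calibrated
  chance rates, the scanner itself is sequence-agnostic. An optional
  per-gene rate boost lets the pipeline plant motif enrichment in a target
  set.
- *CAG series*: the association is planted on rank(CAG), not raw CAG,
  making the truth exactly monotone for a rank-based statistic; values are
  clamped at 0 (FPKM are non-negative), which can flatten strongly
  repressed genes — a real censoring phenomenon, and the reason repression
  effects should stay within `baseline/effect` of the rank range. The
  replicate count per genotype (default 4) is a free parameter of the
  emulated design.
- *Network*: edge endpoints pick a seed with probability 0.15, else a
  uniform node, making seeds hubs — the degree structure of a database
  extract queried around those seeds. Annotation lists intersect the
  seed neighborhood exactly as planted and are padded with off-graph
  decoys, so overlay counts have a known truth. No degree-corrected null or
  community structure is modeled.

## Numerical and interface choices

- Gene symbols are canonicalized to upper case everywhere (human, mouse,
  rat and yeast conventions differ mostly in case). Ortholog collapse
  defaults to max-mean-probe, the common microarray convention; `first` and
  `error-on-collision` are available, and unmapped ids are counted and
  logged, never silently dropped.
- Expression I/O accepts plain TSV and GCT v1.2; phenotypes CLS or
  two-column TSV; gene sets GMT; networks edge-list TSV with SIF export.
- All permutation machinery takes an explicit seed; the pipeline derives
  per-stage seeds deterministically from one root seed (kept below 2^31)
  and records them in the manifest, making full runs hash-stable.
- Pipeline configs are flat TOML — diffable, no code execution. Exit
  codes: 0 ok, 2 validation failure (before any stage runs), 3 stage
  failure (partial outputs retained, failing stage named).

## Test problem sizes

The suite checks oracle equivalence (enrichment score vs brute-force
enumeration on 200 random instances; motif scanner vs a naive sliding
window on 100; hypergeometric tail vs exact combinatorics at N ≤ 60),
null calibration (200-repeat uniformity of enrichment p-values at 200
genes / 6 vs 6; 20-seed null CAG series at 200 genes; 100-repeat ORA false
positive rate), and recovery at the study conditions above (50 seeded
enrichment runs with and without effect; 20 planted CAG genes at
effect/noise = 10; exact (40, 6) network overlaps). These sizes make the
full suite run in well under two minutes while leaving the binomial
uncertainty of each asserted rate far from its bound.

## Known limitations

- The run-level enrichment FDR pools few sets, so its resolution is limited
  by `n_perm` and the set count; single-set runs reduce it to a p-like
  quantity.
- Continuous-phenotype and multi-class enrichment are out of scope, as are
  PWM/log-odds motif scoring and motif discovery.
- The permutation FDR for correlation assumes exchangeable samples;
  replicate structure within a genotype is not modeled in the null.
- Interactome assembly is 1-hop by design; deeper closures change the
  overlay counts and are intentionally not the default.
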