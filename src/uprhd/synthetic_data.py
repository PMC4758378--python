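"""Generators for synthetic inputs with recorded ground truth.

Each generator emulates the statistical structure of one class of input the
pipeline consumes — two-group expression with a coordinately shifted gene
set, TSS-anchored promoter windows with planted stress elements, an allelic
series of CAG repeat lengths with a planted monotone expression response,
and an interaction network with designed annotation overlaps. Every
generator is a pure function of its arguments including ``seed``, and the
returned :class:`SimulationTruth` suffices to score recovery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io_gene_sets import CASE, CONTROL, ExpressionDataset

DEFAULT_CAG_VALUES = (20, 80, 92, 111, 140, 175)
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a generated dataset."""

    planted_set: frozenset[str] = frozenset()
    effect_size: float = 0.0
    planted_motif_positions: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    planted_correlated: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    planted_overlaps: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        rows: list[dict] = []
        for g in sorted(self.planted_set):
            rows.append({"kind": "planted_set", "gene": g, "detail": f"{self.effect_size:g}"})
        for g, hits in sorted(self.planted_motif_positions.items()):
            for name, off, strand in hits:
                rows.append({"kind": "planted_motif", "gene": g, "detail": f"{name}@{off}{strand}"})
        for g, sign in sorted(self.planted_correlated.items()):
            rows.append({"kind": "planted_correlated", "gene": g, "detail": f"{sign:+d}"})
        for listname, genes in sorted(self.planted_overlaps.items()):
            for g in sorted(genes):
                rows.append({"kind": "planted_overlap", "gene": g, "detail": listname})
        return rows


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# two-group expression
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int = 1000,
    n_case: int = 10,
    n_control: int = 10,
    planted_set_size: int = 50,
    effect: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline: float = 7.0,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Two-group expression with a coordinately shifted gene set.

    Background genes are Normal(baseline, noise_sd) in both groups (a
    log-like scale with light tails); the first ``planted_set_size`` genes
    are shifted by ``effect * noise_sd`` in case samples only. ``effect``
    may be negative to plant repression.
    """
    if n_genes <= 0 or n_case <= 0 or n_control <= 0:
        raise ValueError("n_genes, n_case and n_control must be positive")
    if planted_set_size > n_genes:
        raise ValueError("planted_set_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    n_samples = n_case + n_control
    values = baseline + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    values[:planted_set_size, :n_case] += effect * noise_sd
    phenotype = [CASE] * n_case + [CONTROL] * n_control
    samples = [f"case_{i+1}" for i in range(n_case)] + [f"ctrl_{i+1}" for i in range(n_control)]
    dataset = ExpressionDataset(genes, samples, values, phenotype)
    truth = SimulationTruth(planted_set=frozenset(genes[:planted_set_size]), effect_size=effect)
    return dataset, truth


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------

def _spell_consensus(expanded: Sequence[str], rng: np.random.Generator) -> str:
    """Draw one concrete spelling of an expanded consensus (list of allowed bases)."""
    return "".join(choices[rng.integers(len(choices))] for choices in expanded)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def simulate_promoters(
    n_genes: int = 200,
    window: tuple[int, int] = (-1000, 500),
    motif_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    boosted_genes: Iterable[str] | None = None,
    boosted_rates: Mapping[str, float] | None = None,
) -> tuple[list["PromoterRecord"], SimulationTruth]:
    """TSS-relative promoter windows with planted stress elements.

    Background is i.i.d. uniform A/C/G/T. Each gene independently receives
    each motif with its rate, at a uniform random offset and strand, spelled
    from the consensus with degenerate positions drawn at random.
    ``boosted_genes``/``boosted_rates`` optionally override the rates for a
    subset of genes (used to plant motif enrichment in a target set).
    """
    from .motif_scan import DEFAULT_PATTERNS, PromoterRecord, compile_pattern

    if motif_rates is None:
        motif_rates = {name: 0.0 for name in DEFAULT_PATTERNS}
    patterns = {name: compile_pattern(DEFAULT_PATTERNS.get(name, name), name=name) for name in motif_rates}
    length = window[1] - window[0]
    for name, pat in patterns.items():
        if pat.length > length:
            raise ValueError(f"motif {name} ({pat.length} nt) longer than window ({length} nt)")
    for name, rate in motif_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {name} outside [0,1]")
    boosted = frozenset(str(g).upper() for g in boosted_genes) if boosted_genes else frozenset()

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records: list[PromoterRecord] = []
    truth = SimulationTruth()
    for gene in _gene_names(n_genes):
        seq = rng.integers(0, 4, size=length)
        seq_list = list(bases[seq])
        planted: list[tuple[str, int, str]] = []
        rates = dict(motif_rates)
        if gene in boosted and boosted_rates:
            rates.update(boosted_rates)
        for name, rate in rates.items():
            if rng.random() >= rate:
                continue
            pat = patterns[name]
            start = int(rng.integers(0, length - pat.length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            instance = _spell_consensus(pat.expanded, rng)
            if strand == "-":
                instance = reverse_complement(instance)
            seq_list[start:start + pat.length] = list(instance)
            planted.append((name, start + window[0], strand))
        records.append(PromoterRecord(gene=gene, sequence="".join(seq_list), window=window))
        if planted:
            truth.planted_motif_positions[gene] = planted
    return records, truth


# ---------------------------------------------------------------------------
# CAG allelic series
# ---------------------------------------------------------------------------

@dataclass
class CAGSeries:
    """Per-sample CAG repeat number plus a genes x samples FPKM matrix."""

    cag: np.ndarray
    gene_ids: list[str]
    fpkm: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cag = np.asarray(self.cag, dtype=float)
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if not self.sample_ids:
            self.sample_ids = [f"s{i+1}" for i in range(self.cag.size)]
        if self.fpkm.shape != (len(self.gene_ids), self.cag.size):
            raise ValueError("FPKM matrix shape does not match gene/sample lists")
        if len(np.unique(self.cag)) < 3:
            raise ValueError("at least 3 distinct CAG values required")
        if (self.fpkm < 0).any():
            raise ValueError("FPKM values must be non-negative")


def simulate_cag_series(
    cag_values: Sequence[int] = DEFAULT_CAG_VALUES,
    replicates: int = 4,
    n_genes: int = 200,
    frac_pos: float = 0.10,
    frac_neg: float = 0.08,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline: float = 10.0,
    gene_ids: Sequence[str] | None = None,
    planted_pos: Iterable[str] | None = None,
    planted_neg: Iterable[str] | None = None,
) -> tuple[CAGSeries, SimulationTruth]:
    """FPKM allelic series with a planted fraction of CAG-responsive genes.

    Correlated genes get ``baseline ± effect * rank(CAG)`` plus noise — the
    association is planted on the rank of the repeat length, so the truth is
    exactly monotone for the rank-based correlation downstream. Values are
    clamped at 0 (FPKM are non-negative). Planted gene identities can be
    given explicitly; by default the first/last fractions of the gene list
    are used.
    """
    if len(set(cag_values)) < 3:
        raise ValueError("at least 3 distinct CAG values required")
    if frac_pos + frac_neg > 1:
        raise ValueError("frac_pos + frac_neg must be <= 1")
    if replicates <= 0 or n_genes <= 0:
        raise ValueError("replicates and n_genes must be positive")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_names(n_genes)
    n_genes = len(genes)
    cag = np.repeat(np.asarray(sorted(cag_values), dtype=float), replicates)
    ranks = np.repeat(np.arange(1, len(set(cag_values)) + 1, dtype=float), replicates)
    n_samples = cag.size

    if planted_pos is not None or planted_neg is not None:
        pos = [g for g in genes if g in frozenset(planted_pos or ())]
        neg = [g for g in genes if g in frozenset(planted_neg or ())]
    else:
        n_pos = int(round(frac_pos * n_genes))
        n_neg = int(round(frac_neg * n_genes))
        pos = genes[:n_pos]
        neg = genes[n_pos:n_pos + n_neg]
    pos_set, neg_set = frozenset(pos), frozenset(neg)

    fpkm = baseline + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    for i, g in enumerate(genes):
        if g in pos_set:
            fpkm[i] += effect * ranks
        elif g in neg_set:
            fpkm[i] -= effect * ranks
    fpkm = np.clip(fpkm, 0.0, None)

    samples = [f"cag{int(c)}_r{r+1}" for c in sorted(cag_values) for r in range(replicates)]
    series = CAGSeries(cag=cag, gene_ids=genes, fpkm=fpkm, sample_ids=samples)
    truth = SimulationTruth(
        planted_correlated={**{g: +1 for g in pos_set}, **{g: -1 for g in neg_set}},
        effect_size=effect,
    )
    return series, truth


# ---------------------------------------------------------------------------
# interaction network with annotated overlaps
# ---------------------------------------------------------------------------

def simulate_network(
    n_nodes: int = 300,
    n_edges: int = 900,
    seed_nodes: Sequence[str] = ("ATF6", "ATF4", "DDIT3", "EIF2AK3", "ERN1", "XBP1"),
    planted_apoptosis_overlap: int = 40,
    planted_htt_overlap: int = 6,
    seed: int = 0,
    n_decoy_annotations: int = 20,
    seed_bias: float = 0.15,
) -> tuple[list[tuple[str, str]], dict[str, frozenset[str]], SimulationTruth]:
    """Random simple graph whose seed 1-hop neighborhood carries planted overlaps.

    Edge endpoints pick a seed node with probability ``seed_bias`` and a
    uniform node otherwise, making the seeds hubs — the structure of a
    database extract queried around those seeds, where each query protein
    returns tens of interaction partners.

    Returns (edge list, annotation lists, truth). The apoptosis list
    intersects the seed-centred interactome in exactly
    ``planted_apoptosis_overlap`` nodes; the HTT-interactor list intersects
    those apoptosis nodes in exactly ``planted_htt_overlap``. Both lists are
    padded with decoy symbols absent from the graph, so overlaps with the
    interactome are exactly as planted.
    """
    if planted_apoptosis_overlap > n_nodes or planted_htt_overlap > n_nodes:
        raise ValueError("planted overlaps exceed n_nodes")
    if planted_htt_overlap > planted_apoptosis_overlap:
        raise ValueError("HTT overlap must be <= apoptosis overlap (nested by design)")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds simple-graph maximum {max_edges}")
    seeds = [str(s).upper() for s in seed_nodes]
    if len(seeds) > n_nodes:
        raise ValueError("more seed nodes than nodes")

    rng = np.random.default_rng(seed)
    others = _gene_names(n_nodes - len(seeds), prefix="N")
    all_nodes = seeds + others
    graph = nx.Graph()
    graph.add_nodes_from(all_nodes)

    def draw_endpoint() -> str:
        if rng.random() < seed_bias:
            return seeds[int(rng.integers(len(seeds)))]
        return all_nodes[int(rng.integers(n_nodes))]

    while graph.number_of_edges() < n_edges:
        a, b = draw_endpoint(), draw_endpoint()
        if a != b:
            graph.add_edge(a, b)
    # every seed must participate in at least one interaction
    non_seed = [n for n in all_nodes if n not in seeds]
    for s in seeds:
        if graph.degree(s) == 0:
            graph.add_edge(s, non_seed[int(rng.integers(len(non_seed)))])

    neighborhood = set(seeds)
    for s in seeds:
        neighborhood.update(graph.neighbors(s))
    pool = sorted(neighborhood)
    if planted_apoptosis_overlap > len(pool):
        raise ValueError(
            f"seed neighborhood has only {len(pool)} nodes; cannot plant overlap "
            f"{planted_apoptosis_overlap} (increase n_edges)"
        )
    apop_in = list(rng.choice(pool, size=planted_apoptosis_overlap, replace=False))
    htt_in = list(rng.choice(apop_in, size=planted_htt_overlap, replace=False)) if planted_htt_overlap else []
    decoys_a = _gene_names(n_decoy_annotations, prefix="APOPX")
    decoys_h = _gene_names(n_decoy_annotations, prefix="HTTX")
    annotations = {
        "apoptosis": frozenset(apop_in) | frozenset(decoys_a),
        "htt_interactors": frozenset(htt_in) | frozenset(decoys_h),
    }
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    truth = SimulationTruth(planted_overlaps={
        "apoptosis_in_interactome": frozenset(apop_in),
        "htt_in_apoptosis": frozenset(htt_in),
    })
    return edges, annotations, truth
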