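"""Gene-set enrichment from scratch: weighted running sum, NES, permutation FDR.

The statistic is the classic weighted Kolmogorov-Smirnov running sum: genes
are ranked by a differential metric, walking down the ranking a hit (gene in
the set) adds its weighted score mass and a miss subtracts ``1/(N - Nh)``;
the enrichment score (ES) is the running-sum value of maximal absolute
deviation from zero. ES is normalized against a permutation null (phenotype
label permutation with re-ranking, or random same-size gene sets on the
fixed ranking) to give NES, an empirical p-value and an FDR pooled over the
sets tested in a run. The leading edge — the set members at or before the
peak for positive ES, at or after it for negative ES — names the genes that
carry the signal ("core enrichment").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_gene_sets import CASE, CONTROL, ExpressionDataset, GeneSet

VARIANCE_FLOOR_FRACTION = 0.2


class UndefinedNESError(ValueError):
    """Raised when the permutation null contains no value with the sign of ES."""


@dataclass
class RankedList:
    """Genes ordered best-to-worst by a signed differential metric."""

    genes: list[str]
    scores: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if (np.diff(self.scores) > 0).any():
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Thresholds:
    """Direction-call thresholds: significant if fdr <= fdr_max and |NES| clears its bound."""

    fdr_max: float = 0.05
    nes_up_min: float = 1.4
    nes_down_max: float = -1.4

    def __post_init__(self) -> None:
        if not (self.nes_up_min > 0 > self.nes_down_max):
            raise ValueError("require nes_up_min > 0 > nes_down_max")


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    es: float
    peak_index: int
    nes: float = float("nan")
    p_perm: float = float("nan")
    fdr: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)
    direction: str = "ns"
    note: str = ""


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _signal2noise(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    mu_c, mu_k = case.mean(axis=1), ctrl.mean(axis=1)
    s_c = case.std(axis=1, ddof=1)
    s_k = ctrl.std(axis=1, ddof=1)
    s_c = np.maximum(s_c, VARIANCE_FLOOR_FRACTION * np.abs(mu_c))
    s_k = np.maximum(s_k, VARIANCE_FLOOR_FRACTION * np.abs(mu_k))
    # constant zero-mean genes would otherwise divide by zero
    s_c = np.where(s_c == 0, VARIANCE_FLOOR_FRACTION, s_c)
    s_k = np.where(s_k == 0, VARIANCE_FLOOR_FRACTION, s_k)
    return (mu_c - mu_k) / (s_c + s_k)


def _log2fc(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    # input assumed on a log-like scale; difference of group means
    return case.mean(axis=1) - ctrl.mean(axis=1)


def _order(genes: Sequence[str], scores: np.ndarray) -> np.ndarray:
    """Descending by score, ties broken lexicographically by gene symbol."""
    return np.lexsort((np.asarray(genes, dtype=object), -scores))


def rank_genes(dataset: ExpressionDataset, metric: str = "signal2noise") -> RankedList:
    """Rank genes by a two-group differential metric.

    ``signal2noise`` = (mu_case - mu_ctrl) / (s_case + s_ctrl) with each
    group SD floored at 0.2*|group mean|; it needs >= 3 samples per group
    and falls back to ``log2fc`` (difference of group means) otherwise.
    """
    if metric not in ("signal2noise", "log2fc"):
        raise ValueError(f"unknown metric {metric!r}")
    case = dataset.group_matrix(CASE)
    ctrl = dataset.group_matrix(CONTROL)
    if case.shape[1] < 1 or ctrl.shape[1] < 1:
        raise ValueError("each phenotype group needs at least one sample")
    if metric == "signal2noise" and min(case.shape[1], ctrl.shape[1]) < 3:
        warnings.warn("signal2noise needs >=3 samples per group; falling back to log2fc")
        metric = "log2fc"
    scores = _signal2noise(case, ctrl) if metric == "signal2noise" else _log2fc(case, ctrl)
    order = _order(dataset.gene_ids, scores)
    return RankedList(
        genes=[dataset.gene_ids[i] for i in order],
        scores=scores[order],
        metric=metric,
    )


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _running_sum(weights: np.ndarray, hit_mask: np.ndarray) -> tuple[float, int, np.ndarray]:
    """ES, peak index and full running sum for precomputed |score|^p weights."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set not represented in the ranked list")
    hit_weight = weights[hit_mask].sum()
    if hit_weight > 0:
        steps = np.where(hit_mask, weights / hit_weight, 0.0)
    else:  # all hit scores zero: fall back to unweighted hits
        steps = np.where(hit_mask, 1.0 / n_hits, 0.0)
    if n > n_hits:
        steps[~hit_mask] = -1.0 / (n - n_hits)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    # cumulative float error can push the extreme a hair past +-1
    return float(np.clip(running[peak], -1.0, 1.0)), peak, running


def enrichment_score(
    ranked: RankedList,
    gene_set: GeneSet | Iterable[str],
    exponent: float = 1.0,
    min_set_size: int = 5,
) -> tuple[float, int, np.ndarray]:
    """Weighted-KS enrichment score of a gene set on a ranking.

    Returns ``(ES, peak_index, running_sum)``; ES is in [-1, 1] and equals
    exactly 1 when the set covers the whole ranking (no miss steps).
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(str(g).upper() for g in gene_set)
    hit_mask = np.array([g in members for g in ranked.genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set not represented in the ranked list")
    if n_hits < min_set_size:
        raise ValueError(f"only {n_hits} set genes in ranking (< min_set_size={min_set_size})")
    weights = np.abs(ranked.scores) ** exponent
    return _running_sum(weights, hit_mask)


def leading_edge(
    ranked: RankedList,
    gene_set: GeneSet | Iterable[str],
    es: float,
    peak_index: int,
) -> list[str]:
    """Set members driving the enrichment: ranks <= peak for ES > 0, >= peak for ES < 0."""
    if es == 0:
        raise ValueError("leading edge undefined for ES = 0")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(str(g).upper() for g in gene_set)
    if es > 0:
        return [g for g in ranked.genes[: peak_index + 1] if g in members]
    return [g for g in ranked.genes[peak_index:] if g in members]


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _check_n_perm(n_perm: int) -> None:
    if n_perm < 10:
        raise ValueError("n_perm < 10 gives no usable null")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values and FDR will be coarse")


def _phenotype_null_weights(
    dataset: ExpressionDataset,
    metric: str,
    n_perm: int,
    rng: np.random.Generator,
    exponent: float,
) -> tuple[list[np.ndarray], list[list[str]]]:
    """Per-permutation (ordered weights, ordered genes) under label shuffling."""
    values = dataset.values
    genes = np.asarray(dataset.gene_ids, dtype=object)
    n_case = int(dataset.case_mask.sum())
    n_samples = values.shape[1]
    use_s2n = metric == "signal2noise" and min(n_case, n_samples - n_case) >= 3
    weights_list: list[np.ndarray] = []
    genes_list: list[list[str]] = []
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        case = values[:, perm[:n_case]]
        ctrl = values[:, perm[n_case:]]
        scores = _signal2noise(case, ctrl) if use_s2n else _log2fc(case, ctrl)
        order = _order(genes, scores)
        weights_list.append(np.abs(scores[order]) ** exponent)
        genes_list.append(list(genes[order]))
    return weights_list, genes_list


def permutation_null(
    dataset: ExpressionDataset,
    gene_set: GeneSet | Iterable[str],
    mode: str = "gene_set",
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "signal2noise",
    exponent: float = 1.0,
) -> np.ndarray:
    """Null ES sample for one gene set.

    ``phenotype`` permutes sample labels and re-ranks; ``gene_set`` draws
    random same-size gene sets on the fixed ranking.
    """
    if mode not in ("phenotype", "gene_set"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    _check_n_perm(n_perm)
    rng = np.random.default_rng(seed)
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(str(g).upper() for g in gene_set)
    ranked = rank_genes(dataset, metric=metric)
    hit_mask = np.array([g in members for g in ranked.genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set not represented in the ranked list")

    null = np.empty(n_perm)
    if mode == "gene_set":
        weights = np.abs(ranked.scores) ** exponent
        n = len(ranked)
        for i in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_hits, replace=False)] = True
            null[i], _, _ = _running_sum(weights, mask)
    else:
        w_list, g_list = _phenotype_null_weights(dataset, ranked.metric, n_perm, rng, exponent)
        for i, (w, gs) in enumerate(zip(w_list, g_list)):
            mask = np.array([g in members for g in gs])
            null[i], _, _ = _running_sum(w, mask)
    return null


# ---------------------------------------------------------------------------
# normalization, p, FDR
# ---------------------------------------------------------------------------

def _normalize_null(null_es: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Null NES (each sign scaled by its own mean |ES|) plus the two sign means."""
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    pos_mean = float(np.abs(pos).mean()) if pos.size else float("nan")
    neg_mean = float(np.abs(neg).mean()) if neg.size else float("nan")
    nes = np.empty_like(null_es)
    nes[null_es > 0] = pos / pos_mean if pos.size else 0.0
    nes[null_es < 0] = neg / neg_mean if neg.size else 0.0
    nes[null_es == 0] = 0.0
    return nes, pos_mean, neg_mean


def normalize_and_test(es: float, null_es: np.ndarray) -> tuple[float, float, float]:
    """NES, permutation p and single-set FDR for an observed ES.

    NES divides ES by the mean magnitude of same-sign null values; the
    p-value is the add-one-smoothed same-sign tail fraction. The FDR here
    treats this set as the whole run (see :func:`gsea` for pooled FDR over
    several sets). Raises :class:`UndefinedNESError` if no null value shares
    the sign of ES, so undefined normalizations are flagged rather than
    propagated as NaN.
    """
    null_es = np.asarray(null_es, dtype=float)
    if es == 0:
        return 0.0, 1.0, 1.0
    same = null_es[np.sign(null_es) == np.sign(es)]
    if same.size == 0:
        raise UndefinedNESError("no same-sign null ES values; NES undefined")
    nes = es / float(np.abs(same).mean())
    p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
    null_nes, _, _ = _normalize_null(null_es)
    same_nes = null_nes[np.sign(null_nes) == np.sign(nes)]
    tail = int((np.abs(same_nes) >= abs(nes)).sum())
    fdr = min(1.0, tail / same_nes.size) if same_nes.size else 1.0
    return float(nes), float(p), float(fdr)


def _pooled_fdr(observed_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """FDR per observed NES from a pooled null, same-sign tails, clamped to [0,1]."""
    fdr = np.ones_like(observed_nes)
    for sign in (1, -1):
        obs_idx = np.where(np.sign(observed_nes) == sign)[0]
        if obs_idx.size == 0:
            continue
        null_side = null_nes[np.sign(null_nes) == sign]
        obs_side = observed_nes[obs_idx]
        for i, nes in zip(obs_idx, obs_side):
            num = (np.abs(null_side) >= abs(nes)).mean() if null_side.size else 1.0
            den = (np.abs(obs_side) >= abs(nes)).mean()
            fdr[i] = min(1.0, num / den)
    return fdr


def classify_regulation(result: EnrichmentResult, thresholds: Thresholds | None = None) -> str:
    """'up' / 'down' / 'ns' from NES and FDR thresholds."""
    th = thresholds or Thresholds()
    if np.isnan(result.nes) or np.isnan(result.fdr):
        return "ns"
    if result.fdr <= th.fdr_max and result.nes >= th.nes_up_min:
        return "up"
    if result.fdr <= th.fdr_max and result.nes <= th.nes_down_max:
        return "down"
    return "ns"


# ---------------------------------------------------------------------------
# run-level driver
# ---------------------------------------------------------------------------

def gsea(
    dataset: ExpressionDataset,
    gene_sets: Sequence[GeneSet],
    metric: str = "signal2noise",
    mode: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
    min_set_size: int = 5,
    thresholds: Thresholds | None = None,
) -> list[EnrichmentResult]:
    """Run enrichment for several gene sets against one comparison.

    ``mode=None`` picks phenotype permutation when both groups have >= 7
    samples (labels then support a rich null) and random gene sets
    otherwise. FDR is pooled across all sets in the run: the same-sign null
    NES tail fraction over the observed tail fraction, clamped to [0, 1].
    """
    if mode is None:
        n_case = int(dataset.case_mask.sum())
        n_ctrl = len(dataset.sample_ids) - n_case
        mode = "phenotype" if min(n_case, n_ctrl) >= 7 else "gene_set"
    _check_n_perm(n_perm)
    rng = np.random.default_rng(seed)
    ranked = rank_genes(dataset, metric=metric)
    weights = np.abs(ranked.scores) ** exponent
    n = len(ranked)

    # share phenotype permutations across sets
    perm_masks: list[tuple[np.ndarray, list[str]]] | None = None
    if mode == "phenotype":
        w_list, g_list = _phenotype_null_weights(dataset, ranked.metric, n_perm, rng, exponent)
        perm_masks = list(zip(w_list, g_list))

    results: list[EnrichmentResult] = []
    null_nes_pool: list[np.ndarray] = []
    for gs in gene_sets:
        hit_mask = np.array([g in gs.members for g in ranked.genes])
        n_hits = int(hit_mask.sum())
        if n_hits < max(min_set_size, 1):
            results.append(EnrichmentResult(gs.name, n_hits, float("nan"), -1, note="set too small in ranking"))
            continue
        es, peak, _ = _running_sum(weights, hit_mask)
        null = np.empty(n_perm)
        if mode == "gene_set":
            for i in range(n_perm):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=n_hits, replace=False)] = True
                null[i], _, _ = _running_sum(weights, mask)
        else:
            members = gs.members
            for i, (w, genes_i) in enumerate(perm_masks):
                mask = np.array([g in members for g in genes_i])
                null[i], _, _ = _running_sum(w, mask)
        try:
            nes, p, _ = normalize_and_test(es, null)
        except UndefinedNESError:
            results.append(EnrichmentResult(gs.name, n_hits, es, peak, note="undefined NES (one-sided null)"))
            continue
        null_nes, _, _ = _normalize_null(null)
        null_nes_pool.append(null_nes)
        le = leading_edge(ranked, gs, es, peak) if es != 0 else []
        results.append(EnrichmentResult(gs.name, n_hits, es, peak, nes=nes, p_perm=p, leading_edge=le))

    defined = [r for r in results if not np.isnan(r.nes)]
    if defined and null_nes_pool:
        observed = np.array([r.nes for r in defined])
        pooled = np.concatenate(null_nes_pool)
        fdrs = _pooled_fdr(observed, pooled)
        for r, f in zip(defined, fdrs):
            r.fdr = float(f)
    for r in results:
        r.direction = classify_regulation(r, thresholds)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "size": [r.set_size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p_perm for r in results],
            "fdr": [r.fdr for r in results],
            "direction": [r.direction for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
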