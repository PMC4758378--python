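"""Per-gene Spearman correlation with CAG repeat length and permutation FDR.

Expression across an allelic series of CAG repeat lengths is correlated
gene-by-gene with the repeat number (Spearman, mid-ranks for ties). The
empirical FDR comes from gene-wise permutation: for each gene the CAG
labels are shuffled independently in every round, the permuted correlations
pooled, and at any threshold t > 0

    fdr_pos(t) = mean over rounds of #{permuted rho >= t} / #{observed rho >= t}

clamped to [0, 1] (mirrored for the negative tail). Each gene's FDR is the
estimate at its own |rho|, then monotonized so FDR never increases with
|rho|. Positive and negative tails are estimated separately, so a gene has
one finite tail FDR and 1 for the other. Genes with zero expression
variance have no defined rank correlation; they are flagged and excluded
from both the observed and the null tallies.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_stats import ContingencyTable2x2, fisher_exact_2x2
from .io_gene_sets import GeneSet
from .synthetic_data import CAGSeries

logger = logging.getLogger(__name__)

SIGNIFICANCE_FDR = 0.01


def spearman_rho(x: Iterable[float], y: Iterable[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties); NaN if either side is constant."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("equal-length vectors of at least 3 values required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _row_pearson(rows: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; ``other`` is one vector or one row per gene."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    if other.ndim == 1:
        oc = other - other.mean()
        num = rc @ oc
        den = np.sqrt((rc**2).sum(axis=1) * (oc**2).sum())
    else:
        oc = other - other.mean(axis=1, keepdims=True)
        num = (rc * oc).sum(axis=1)
        den = np.sqrt((rc**2).sum(axis=1) * (oc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def correlate(series: CAGSeries) -> np.ndarray:
    """Observed per-gene Spearman rho vs CAG number (NaN for constant genes)."""
    expr_ranks = stats.rankdata(series.fpkm, axis=1)
    cag_ranks = stats.rankdata(series.cag)
    rho = _row_pearson(expr_ranks, cag_ranks)
    rho[np.ptp(series.fpkm, axis=1) == 0] = np.nan
    return rho


def permutation_fdr(
    series: CAGSeries,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = SIGNIFICANCE_FDR,
) -> pd.DataFrame:
    """Per-gene rho with empirical positive/negative-tail FDRs.

    CAG labels are permuted independently per gene in every round;
    reproducible under ``seed``. Returns a frame with columns gene, rho,
    fdr_pos, fdr_neg, fdr_cor (the FDR of the gene's own tail),
    significant_pos, significant_neg at ``fdr_threshold``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    rng = np.random.default_rng(seed)
    active = np.ptp(series.fpkm, axis=1) > 0
    n_dropped = int((~active).sum())
    if n_dropped:
        logger.warning("permutation_fdr: %d constant genes excluded from tallies", n_dropped)

    genes = np.asarray(series.gene_ids, dtype=object)
    expr_ranks = stats.rankdata(series.fpkm[active], axis=1)
    cag_ranks = stats.rankdata(series.cag)
    obs = _row_pearson(expr_ranks, cag_ranks)
    g_act, n_samp = expr_ranks.shape

    pos_idx = np.where(obs > 0)[0]
    neg_idx = np.where(obs < 0)[0]
    pos_null_count = np.zeros(pos_idx.size)
    neg_null_count = np.zeros(neg_idx.size)
    for _ in range(n_perm):
        perm = np.argsort(rng.random((g_act, n_samp)), axis=1)
        null_rho = _row_pearson(expr_ranks, cag_ranks[perm])
        sorted_null = np.sort(null_rho)
        if pos_idx.size:
            pos_null_count += g_act - np.searchsorted(sorted_null, obs[pos_idx], side="left")
        if neg_idx.size:
            neg_null_count += np.searchsorted(sorted_null, obs[neg_idx], side="right")

    fdr_pos = np.ones(g_act)
    fdr_neg = np.ones(g_act)
    if pos_idx.size:
        fdr_pos = _tail_fdr_from_counts(obs, pos_idx, pos_null_count, n_perm, positive=True)
    if neg_idx.size:
        fdr_neg = _tail_fdr_from_counts(obs, neg_idx, neg_null_count, n_perm, positive=False)

    out = pd.DataFrame({"gene": genes[active], "rho": obs, "fdr_pos": fdr_pos, "fdr_neg": fdr_neg})
    dropped = pd.DataFrame(
        {"gene": genes[~active], "rho": np.nan, "fdr_pos": 1.0, "fdr_neg": 1.0}
    )
    out = pd.concat([out, dropped], ignore_index=True)
    out["fdr_cor"] = np.where(out["rho"] > 0, out["fdr_pos"], np.where(out["rho"] < 0, out["fdr_neg"], 1.0))
    out.loc[out["rho"].isna(), "fdr_cor"] = 1.0
    out["significant_pos"] = (out["rho"] > 0) & (out["fdr_pos"] < fdr_threshold)
    out["significant_neg"] = (out["rho"] < 0) & (out["fdr_neg"] < fdr_threshold)
    order = {g: i for i, g in enumerate(series.gene_ids)}
    return out.sort_values("gene", key=lambda s: s.map(order)).reset_index(drop=True)


def _tail_fdr_from_counts(
    obs: np.ndarray,
    idx: np.ndarray,
    null_counts: np.ndarray,
    n_perm: int,
    positive: bool,
) -> np.ndarray:
    fdr = np.ones(obs.size)
    tvals = obs[idx]
    sorted_obs = np.sort(obs)
    if positive:
        obs_count = obs.size - np.searchsorted(sorted_obs, tvals, side="left")
    else:
        obs_count = np.searchsorted(sorted_obs, tvals, side="right")
    raw = np.clip((null_counts / n_perm) / np.maximum(obs_count, 1), 0.0, 1.0)
    # q-value-style monotonization: a gene's fdr is the best (smallest) estimate
    # over all thresholds that would still call it, i.e. cumulative min walking
    # from the weakest |rho| upward; fdr is then non-increasing in |rho|
    order = np.argsort(np.abs(tvals), kind="mergesort")
    mono = np.minimum.accumulate(raw[order])
    out = np.empty_like(raw)
    out[order] = mono
    fdr[idx] = out
    return fdr


def set_overrepresentation(
    significant: Iterable[str],
    target: GeneSet | Iterable[str],
    universe: Iterable[str],
) -> float:
    """One-sided Fisher p for over-representation of a target set among significant genes."""
    uni = frozenset(str(g).upper() for g in universe)
    if not uni:
        raise ValueError("empty universe")
    sig = frozenset(str(g).upper() for g in significant) & uni
    tgt = (target.members if isinstance(target, GeneSet) else frozenset(str(g).upper() for g in target)) & uni
    a = len(sig & tgt)
    b = len(sig - tgt)
    c = len(tgt - sig)
    d = len(uni) - a - b - c
    return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), alternative="greater")


def expected_overlap(set_size: int, genomewide_fraction: float) -> float:
    """Expected-by-chance overlap count, reported to one decimal."""
    if not 0.0 <= genomewide_fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return round(set_size * genomewide_fraction, 1)
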