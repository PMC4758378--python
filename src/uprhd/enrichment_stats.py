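"""Shared over-representation statistics.

Hypergeometric tail test, 2x2 Fisher exact test, Benjamini-Hochberg
adjustment, and a flat-annotation over-representation analysis (ORA) used
both for stress-element promoter enrichment and for functional/pathway
enrichment. One-sided 'greater' is the default alternative throughout,
since the question is always over-representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SIGNIFICANCE_FDR = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = in/out of the gene list, columns = with/without the property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("negative cell count")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf is evaluated in log-space internally; exact for these small counts
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_2x2(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Fisher exact p for a 2x2 table; 'greater' is the hypergeometric upper tail on cell a."""
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"alternative must be 'greater' or 'two_sided', got {alternative!r}")
    alt = "two-sided" if alternative == "two_sided" else alternative
    arr = [[table.a, table.b], [table.c, table.d]]
    return float(stats.fisher_exact(arr, alternative=alt)[1])


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDRs, returned in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    gene_list: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Flat-annotation over-representation analysis.

    One hypergeometric upper-tail test per term (terms restricted to the
    universe), BH-adjusted across all tested terms, sorted by fdr then p.
    List genes outside the universe are dropped with a warning. Columns:
    term, k, K, n, N, p, fdr.
    """
    uni = frozenset(str(g).upper() for g in universe)
    if not uni:
        raise ValueError("empty universe")
    lst = frozenset(str(g).upper() for g in gene_list)
    outside = lst - uni
    if outside:
        logger.warning("ora: %d list genes outside the universe dropped", len(outside))
        lst = lst & uni

    rows = []
    for term, members in annotations.items():
        term_set = frozenset(str(g).upper() for g in members) & uni
        if not term_set:
            continue
        k = len(lst & term_set)
        rows.append((str(term), k, len(term_set), len(lst), len(uni)))
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "fdr"])
    frame = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N"])
    frame["p"] = [hypergeom_tail(k, K, n, N) for k, K, n, N in frame[["k", "K", "n", "N"]].itertuples(index=False)]
    frame["fdr"] = bh_adjust(frame["p"])
    return frame.sort_values(["fdr", "p", "term"], kind="mergesort").reset_index(drop=True)


def motif_enrichment(
    presence: pd.DataFrame,
    targets: Iterable[str],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Stress-element enrichment of a target gene list against a promoter universe.

    ``presence`` is the boolean gene x pattern frame from the scanner; the
    universe defaults to every gene with a promoter record. Target genes
    lacking a promoter are excluded from both sides (and logged), since no
    presence call exists for them. Columns: pattern, k, K, n, N, p.
    """
    uni = frozenset(str(g).upper() for g in universe) if universe is not None else frozenset(presence.index)
    uni = uni & frozenset(presence.index)
    if not uni:
        raise ValueError("no universe gene has a promoter record")
    tgt = frozenset(str(g).upper() for g in targets)
    missing = tgt - uni
    if missing:
        logger.warning("motif_enrichment: %d target genes lack promoter records", len(missing))
    tgt = tgt & uni

    rows = []
    sub = presence.loc[sorted(uni)]
    for pattern in presence.columns:
        with_motif = frozenset(sub.index[sub[pattern]])
        k = len(tgt & with_motif)
        K = len(with_motif)
        rows.append((pattern, k, K, len(tgt), len(uni), hypergeom_tail(k, K, len(tgt), len(uni))))
    return pd.DataFrame(rows, columns=["pattern", "k", "K", "n", "N", "p"])
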