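"""Cross-model consensus signatures from leading-edge gene sets.

A consensus signature collects genes that recur in the leading edges
("enrichment cores") of several independent comparisons, at configurable
stringency: a gene qualifies iff it appears in *every* required comparison
and in at least ``min_support`` of the remaining (optional) comparisons.
With no required comparisons and ``min_support`` equal to the number of
inputs this is the plain intersection; lowering ``min_support`` or
shrinking the required list can only add genes (monotonicity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class ConsensusRule:
    required: tuple[str, ...] = ()
    min_support: int = 0


@dataclass
class ConsensusSignature:
    direction: str
    genes: frozenset[str]
    support: dict[str, int] = field(default_factory=dict)
    rule: ConsensusRule = field(default_factory=ConsensusRule)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": sorted(self.genes),
                "support": [self.support[g] for g in sorted(self.genes)],
                "direction": self.direction,
            }
        )


def consensus_signature(
    leading_edges: Mapping[str, Iterable[str]],
    required: Iterable[str] = (),
    min_support: int | None = None,
    direction: str = "up",
) -> ConsensusSignature:
    """Intersect leading-edge sets at configurable stringency.

    ``leading_edges`` maps comparison id -> leading-edge genes. A gene is
    included iff it is present in every ``required`` comparison and in at
    least ``min_support`` of the optional (non-required) ones.
    ``min_support=None`` defaults to all optional comparisons (strict
    intersection). The per-gene support count over optional comparisons is
    recorded.
    """
    sets = {str(k): frozenset(str(g).upper() for g in v) for k, v in leading_edges.items()}
    required = tuple(str(r) for r in required)
    unknown = [r for r in required if r not in sets]
    if unknown:
        raise ValueError(f"unknown comparison id(s) in required: {unknown}")
    optional = [k for k in sets if k not in required]
    if min_support is None:
        min_support = len(optional)
    if not 0 <= min_support <= len(optional):
        raise ValueError(f"min_support={min_support} outside [0, {len(optional)}]")

    universe = frozenset().union(*sets.values()) if sets else frozenset()
    genes: set[str] = set()
    support: dict[str, int] = {}
    for gene in universe:
        if any(gene not in sets[r] for r in required):
            continue
        n = sum(gene in sets[k] for k in optional)
        if n >= min_support:
            genes.add(gene)
            support[gene] = n
    return ConsensusSignature(
        direction=direction,
        genes=frozenset(genes),
        support=support,
        rule=ConsensusRule(required=required, min_support=min_support),
    )
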