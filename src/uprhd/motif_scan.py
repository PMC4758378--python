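"""Consensus-pattern scanning of promoter windows for ER stress elements.

Three short degenerate consensus elements recruit the UPR transcription
factors ATF6 and XBP1:

* UPRE    — ``TGACGTGR``      (R = G/A; 8 nt)
* ERSE-I  — ``CCAATN{9}CCACG`` (9-nt spacer; 19 nt)
* ERSE-II — ``ATTGGNCCACG``   (1-nt spacer; 11 nt)

Promoter windows are TSS-relative, by default ``[-1000, +500)`` half-open
with the TSS at offset 0. Both strands are scanned by default; a
reverse-strand hit is reported at the forward coordinate of the match
start. All overlapping occurrences are reported, but per-gene *presence*
(>= 1 hit) is the unit used for enrichment. The masked base ``N`` in a
sequence never matches, not even against a pattern spacer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_PATTERNS: dict[str, str] = {
    "UPRE": "TGACGTGR",
    "ERSE-I": "CCAATN{9}CCACG",
    "ERSE-II": "ATTGGNCCACG",
}

_SYMBOL_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "GA",
    "N": "ACGT",  # any base; sequence letter N is excluded on purpose
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    consensus: str
    length: int
    expanded: tuple[str, ...]  # allowed bases per position
    regex: re.Pattern = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class MotifHit:
    gene: str
    pattern: str
    offset: int  # TSS-relative coordinate of the forward-strand match start
    strand: str
    matched: str


@dataclass
class PromoterRecord:
    """One TSS-relative promoter window."""

    gene: str
    sequence: str
    window: tuple[int, int] = (-1000, 500)
    strand: str = "+"

    def __post_init__(self) -> None:
        self.gene = str(self.gene).upper()
        self.sequence = str(self.sequence).upper()
        span = self.window[1] - self.window[0]
        if len(self.sequence) != span:
            raise ValueError(
                f"{self.gene}: sequence length {len(self.sequence)} != window span {span}"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene}: unexpected letters {sorted(bad)}")


def compile_pattern(consensus: str, name: str | None = None) -> MotifPattern:
    """Compile a degenerate consensus (A/C/G/T/R/N with optional ``{k}`` repeats).

    The compiled matcher accepts exactly the strings the consensus denotes;
    ``R`` matches G or A, ``N`` matches any of A/C/G/T.
    """
    consensus = consensus.strip().upper()
    expanded: list[str] = []
    i = 0
    while i < len(consensus):
        sym = consensus[i]
        if sym not in _SYMBOL_BASES:
            raise ValueError(f"unknown consensus symbol {sym!r} in {consensus!r}")
        i += 1
        repeat = 1
        if i < len(consensus) and consensus[i] == "{":
            j = consensus.index("}", i)
            repeat = int(consensus[i + 1 : j])
            if repeat < 1:
                raise ValueError(f"non-positive repeat in {consensus!r}")
            i = j + 1
        expanded.extend([_SYMBOL_BASES[sym]] * repeat)
    # lookahead so overlapping occurrences are all found
    rx = re.compile("(?=(" + "".join(f"[{b}]" for b in expanded) + "))")
    return MotifPattern(
        name=name or consensus,
        consensus=consensus,
        length=len(expanded),
        expanded=tuple(expanded),
        regex=rx,
    )


def scan_promoter(
    rec: PromoterRecord,
    pattern: MotifPattern,
    strands: str = "both",
) -> list[MotifHit]:
    """All (overlapping) occurrences of a pattern in one promoter window."""
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    if len(rec.sequence) < pattern.length:
        raise ValueError(f"{rec.gene}: sequence shorter than pattern {pattern.name}")
    hits: list[MotifHit] = []
    start0 = rec.window[0]
    for m in pattern.regex.finditer(rec.sequence):
        hits.append(MotifHit(rec.gene, pattern.name, m.start() + start0, "+", m.group(1)))
    if strands == "both":
        rc = reverse_complement(rec.sequence)
        L = len(rec.sequence)
        for m in pattern.regex.finditer(rc):
            fwd_start = L - m.start() - pattern.length
            hits.append(MotifHit(rec.gene, pattern.name, fwd_start + start0, "-", m.group(1)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass
class MotifHitTable:
    """Per gene x pattern hit counts, presence calls and individual hits."""

    counts: pd.DataFrame  # genes x patterns, int
    hits: pd.DataFrame    # columns gene, pattern, offset, strand, matched

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    @classmethod
    def from_flags(cls, flags: pd.DataFrame) -> "MotifHitTable":
        """Build a presence-only table from a boolean gene x pattern frame."""
        counts = flags.astype(int)
        empty = pd.DataFrame(columns=["gene", "pattern", "offset", "strand", "matched"])
        return cls(counts=counts, hits=empty)


def presence_table(
    promoters: Sequence[PromoterRecord],
    patterns: Mapping[str, str] | Sequence[MotifPattern] | None = None,
    strands: str = "both",
) -> MotifHitTable:
    """Scan every promoter with every pattern; presence = at least one hit."""
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    if isinstance(patterns, Mapping):
        compiled = [compile_pattern(c, name=n) for n, c in patterns.items()]
    else:
        compiled = list(patterns)
    if not promoters or not compiled:
        raise ValueError("presence_table needs promoters and patterns")
    genes = [p.gene for p in promoters]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene ids in promoter input: {dupes[:5]}")

    counts = pd.DataFrame(0, index=genes, columns=[p.name for p in compiled], dtype=int)
    all_hits: list[MotifHit] = []
    for rec in promoters:
        for pat in compiled:
            hits = scan_promoter(rec, pat, strands=strands)
            counts.loc[rec.gene, pat.name] = len(hits)
            all_hits.extend(hits)
    hits_frame = pd.DataFrame(
        [(h.gene, h.pattern, h.offset, h.strand, h.matched) for h in all_hits],
        columns=["gene", "pattern", "offset", "strand", "matched"],
    )
    return MotifHitTable(counts=counts, hits=hits_frame)


def combination_counts(table: MotifHitTable) -> dict[str, int]:
    """Counts of genes carrying at least each pattern combination, plus 'none'.

    Combinations are 'at least these': a gene with all three elements
    contributes to every pairwise 'both' count and to each single count.
    """
    import itertools

    presence = table.presence
    names = sorted(presence.columns)
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            mask = presence[list(combo)].all(axis=1)
            out["+".join(combo)] = int(mask.sum())
    out["none"] = int((~presence.any(axis=1)).sum()) if len(presence) else 0
    return out


# ---------------------------------------------------------------------------
# FASTA I/O (header ``>GENE`` or ``>GENE|window=-1000:+500``)
# ---------------------------------------------------------------------------

_WINDOW_RX = re.compile(r"window=([+-]?\d+):([+-]?\d+)")


def read_promoters_fasta(path: str | Path, window: tuple[int, int] = (-1000, 500)) -> list[PromoterRecord]:
    records: list[PromoterRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, rest = rec.id.partition("|")
        win = window
        m = _WINDOW_RX.search(rest) if rest else None
        if m:
            win = (int(m.group(1)), int(m.group(2)))
        records.append(PromoterRecord(gene=gene, sequence=str(rec.seq), window=win))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_promoters_fasta(promoters: Sequence[PromoterRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(
            Seq(p.sequence),
            id=f"{p.gene}|window={p.window[0]}:{p.window[1]:+d}",
            description="",
        )
        for p in promoters
    ]
    SeqIO.write(recs, str(path), "fasta")
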