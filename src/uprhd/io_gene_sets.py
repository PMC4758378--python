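"""Readers, writers and identifier handling for gene sets and expression data.

Gene identifiers are canonicalized to upper-case symbols throughout, since
human, mouse, rat and yeast symbol conventions differ only in case for most
orthologous pairs and mixed-case input is the norm when several model
organisms are compared against human annotation.

Supported formats:

* GMT — one gene set per line: ``name<TAB>description<TAB>member...``
* GCT v1.2 and plain TSV (header row = sample ids, first column = gene id)
  for expression matrices
* CLS (``n k 1`` / ``# class0 class1`` / per-sample labels) or a two-column
  TSV for phenotype labels
* two-column TSV for ortholog maps (source id -> human symbol)
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols.

    Members are stored as an upper-case, de-duplicated frozenset.
    """

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)
    source: str = ""

    def __post_init__(self) -> None:
        canon = frozenset(str(m).strip().upper() for m in self.members if str(m).strip())
        object.__setattr__(self, "members", canon)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self.members


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with a two-group phenotype.

    ``phenotype`` holds one of ``{"case", "control"}`` per sample; at least
    one sample of each group is required.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phenotype: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if any(not g for g in self.gene_ids):
            raise ValueError("missing gene id")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")
        if len(self.phenotype) != len(self.sample_ids):
            raise ValueError("one phenotype label per sample required")
        bad = set(self.phenotype) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        for grp in (CASE, CONTROL):
            if self.phenotype.count(grp) < 1:
                raise ValueError(f"phenotype group {grp!r} has no samples")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([p == CASE for p in self.phenotype])

    def group_matrix(self, group: str) -> np.ndarray:
        mask = np.array([p == group for p in self.phenotype])
        return self.values[:, mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, phenotype: Sequence[str]) -> "ExpressionDataset":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            phenotype=list(phenotype),
        )


@dataclass
class OrthologMap:
    """Deterministic source-species-id -> human-symbol map (many-to-one allowed)."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        self.pairs = {str(k).upper(): str(v).upper() for k, v in self.pairs.items()}
        if not self.pairs:
            raise ValueError("empty ortholog map")

    def get(self, gene: str) -> str | None:
        return self.pairs.get(str(gene).upper())


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file into a list of gene sets.

    Raises ValueError on an empty file, a line with fewer than three fields,
    or a duplicated set name.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members), source=str(path)))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# expression matrices and phenotypes
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix from GCT v1.2 or plain TSV.

    GCT is detected by its ``#1.2`` magic line. Gene ids are upper-cased.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if first.startswith("#1.2"):
        frame = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in frame.columns:
            frame = frame.drop(columns=["Description"])
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = [str(g).upper() for g in frame.index]
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    return frame.astype(float)


def write_expression(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene")


def read_phenotype(path: str | Path, case_label: str | None = None) -> list[str]:
    """Read phenotype labels from CLS or a two-column TSV.

    Returns per-sample ``case``/``control`` labels. In CLS input the first
    class named on the ``#`` line is taken as case unless ``case_label``
    says otherwise; in TSV input the second column must already be
    ``case``/``control`` (or ``case_label`` names the case class).
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) >= 3 and lines[1].startswith("#"):
        class_names = lines[1].lstrip("#").split()
        labels = lines[2].split()
        if len(class_names) != 2:
            raise ValueError(f"{path}: exactly two phenotype classes required, got {class_names}")
        case_name = case_label if case_label is not None else class_names[0]
        if case_name not in class_names:
            raise ValueError(f"{path}: case label {case_name!r} not among classes {class_names}")
        # numeric CLS variant uses 0/1 referring to class order
        out = []
        for lab in labels:
            if lab in class_names:
                out.append(CASE if lab == case_name else CONTROL)
            elif lab.isdigit() and int(lab) < len(class_names):
                out.append(CASE if class_names[int(lab)] == case_name else CONTROL)
            else:
                raise ValueError(f"{path}: unknown sample label {lab!r}")
        return out
    # two-column TSV: sample_id <TAB> label
    out = []
    for ln in lines:
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        lab = fields[1]
        if case_label is not None:
            out.append(CASE if lab == case_label else CONTROL)
        elif lab in (CASE, CONTROL):
            out.append(lab)
        else:
            raise ValueError(f"{path}: label {lab!r} is not case/control and no case_label given")
    return out


def write_cls(phenotype: Sequence[str], path: str | Path) -> None:
    labels = list(phenotype)
    classes = [CASE, CONTROL]
    with Path(path).open("w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One symbol per line, upper-cased, blank lines and '#' comments skipped."""
    out = set()
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.add(ln.split("\t")[0].upper())
    return frozenset(out)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    pairs: dict[str, str] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        pairs[fields[0]] = fields[1]
    return OrthologMap(pairs)


# ---------------------------------------------------------------------------
# ortholog collapse
# ---------------------------------------------------------------------------

COLLAPSE_RULES = ("max-mean-probe", "first", "error-on-collision")


def apply_ortholog_map(
    dataset: ExpressionDataset,
    ortholog_map: OrthologMap,
    collapse: str = "max-mean-probe",
) -> ExpressionDataset:
    """Translate gene ids to human symbols, collapsing many-to-one hits.

    Collapse rules: ``max-mean-probe`` keeps the row with the largest row
    mean (the usual microarray probe-collapse convention), ``first`` keeps
    the first row encountered, ``error-on-collision`` refuses collisions.
    Unmapped ids are dropped and their count logged.
    """
    if collapse not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {collapse!r}; expected one of {COLLAPSE_RULES}")
    by_human: dict[str, list[int]] = {}
    unmapped: list[str] = []
    for i, gene in enumerate(dataset.gene_ids):
        human = ortholog_map.get(gene)
        if human is None:
            unmapped.append(gene)
            continue
        by_human.setdefault(human, []).append(i)
    if unmapped:
        logger.warning(
            "apply_ortholog_map: %d/%d ids unmapped and dropped (e.g. %s)",
            len(unmapped), len(dataset.gene_ids), ", ".join(unmapped[:5]),
        )
    if not by_human:
        raise ValueError("no gene mapped to a human symbol")

    rows: list[int] = []
    genes: list[str] = []
    for human, idxs in by_human.items():
        if len(idxs) > 1:
            if collapse == "error-on-collision":
                raise ValueError(f"ortholog collision on {human!r}: {len(idxs)} source rows")
            if collapse == "max-mean-probe":
                means = dataset.values[idxs].mean(axis=1)
                idxs = [idxs[int(np.argmax(means))]]
            else:  # first
                idxs = [idxs[0]]
        rows.append(idxs[0])
        genes.append(human)
    return ExpressionDataset(
        gene_ids=genes,
        sample_ids=list(dataset.sample_ids),
        values=dataset.values[rows],
        phenotype=list(dataset.phenotype),
    )


# ---------------------------------------------------------------------------
# venn region counts
# ---------------------------------------------------------------------------

def venn_counts(sets: Sequence[GeneSet] | Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for 2-7 gene sets.

    Returns ``{(names of sets containing the region): count}`` over all
    2^k - 1 regions; every element of the union lands in exactly one region,
    so the counts sum to the union size.
    """
    if isinstance(sets, Mapping):
        named = {str(k): frozenset(str(g).upper() for g in v) for k, v in sets.items()}
    else:
        named = {gs.name: gs.members for gs in sets}
    if not (2 <= len(named) <= 7):
        raise ValueError(f"venn_counts supports 2-7 sets, got {len(named)}")
    names = sorted(named)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            counts[combo] = 0
    for gene in frozenset().union(*named.values()):
        region = tuple(n for n in names if gene in named[n])
        counts[region] += 1
    return counts
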