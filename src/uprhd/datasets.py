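"""Small reference tables shipped with the package.

The prioritization reference table lists 13 differentially regulated UPR
genes that physically interact with HTT and are curated HD therapeutic-
target candidates, together with published promoter stress-element flags
(UPRE, ERSE-I, ERSE-II), the HTT interaction type (direct/indirect), and
the Spearman correlation of striatal expression with CAG repeat length in
an allelic series of HD mice plus its estimated permutation FDR. It serves
as a fixed, hand-checkable input for the prioritization and significance-
filter logic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

MOTIF_COLUMNS = ("UPRE", "ERSE-I", "ERSE-II")


def _data_path(name: str):
    return resources.files("uprhd").joinpath("data", name)


def load_prioritization_table() -> pd.DataFrame:
    """13-gene prioritization reference table.

    Columns: gene, UPRE/ERSE-I/ERSE-II (bool), interaction_type
    ('direct'/'indirect'), rho, fdr_cor.
    """
    with resources.as_file(_data_path("prioritization_reference.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    for col in MOTIF_COLUMNS:
        frame[col] = frame[col].map({"+": True, "-": False}).astype(bool)
    frame["rho"] = frame["rho"].astype(float)
    frame["fdr_cor"] = frame["fdr_cor"].astype(float)
    return frame


def load_motif_flags() -> pd.DataFrame:
    """Boolean gene x pattern presence flags from the prioritization table."""
    frame = load_prioritization_table()
    return frame.set_index("gene")[list(MOTIF_COLUMNS)]
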