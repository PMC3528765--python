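"""Packaged reference tables.

Two small published reference tables ship with the package as plain TSV:
the 66-gene BRCA2 expression signature (moderated t statistics, BH-adjusted
p-values and cytogenetic band per gene) and the two-color FISH screen of 9
BRCA2-mutant plus 9 BRCAX tumors (per-chromosome deletion percentages).
They are the standard worked inputs for the FISH contingency analysis and
for positional bookkeeping of the signature.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_signature_genes", "load_fish_screen"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("brcadel.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"sample_id": str})


def load_signature_genes() -> pd.DataFrame:
    """The 66-gene BRCA2 signature: probeset_id, gene, band, t, p_adjusted.

    Positive t means higher expression in BRCA2-mutant tumors; the genes
    with negative t include the cluster on 13q/14q whose expression is
    reduced by hemizygous deletion.
    """
    return _read("brca2_signature_genes.tsv")


def load_fish_screen() -> pd.DataFrame:
    """Two-color FISH screen percentages: sample_id, brca_status, chr13, chr14.

    Each percentage is the share of modal-green nuclei with fewer red
    (deletion-probe) spots than the modal count on that chromosome.
    """
    return _read("fish_deletion_percentages.tsv")
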