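"""Packaged reference data.

* The 18-condition vocabulary of the pea-aphid expression panel (adult
  morphs, embryo stages, head/leg/gut/salivary-gland/bacteriocyte tissues).
* The published table of 15 duplications in which the positively selected
  copy is expressed in at least one condition where the non-selected copy
  is not (binary profiles with PS and BS+MNM flags and putative functions).
* The 9-taxon Sternorrhyncha reference species tree used by the synthetic
  generators, with *Acyrthosiphon pisum* as the focal species.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: The 18 reference expression conditions.
CONDITIONS: tuple[str, ...] = (
    "AM", "AP", "AO", "E0", "E1A", "E1K", "E2A", "E2K", "E3A", "E3K",
    "H", "HP", "HR2", "HR4", "LP", "G", "SG", "B",
)

#: 9-taxon reference species tree (focal species last, ladderized).
SPECIES_TREE_NEWICK = (
    "(Dcitri,(Btabaci,(Dvitifoliae,(Ccedri,((Rpadi,Aglycines),"
    "(Dnoxia,(Mpersicae,Apisum)))))));"
)

FOCAL_SPECIES = "Apisum"

#: The three most distant outgroup species (orthology least reliable).
DISTANT_SPECIES: frozenset[str] = frozenset({"Dcitri", "Btabaci", "Dvitifoliae"})

SPECIES: tuple[str, ...] = (
    "Dcitri", "Btabaci", "Dvitifoliae", "Ccedri", "Rpadi",
    "Aglycines", "Dnoxia", "Mpersicae", "Apisum",
)


def load_gain_table() -> pd.DataFrame:
    """The packaged gain-case table (30 genes in 15 duplications).

    Columns: duplication, gene, putative_function, ps, bs_mnm, and the 18
    condition columns with values 0 / 1 / NA.
    """
    with resources.files("dupfate.data").joinpath("gain_case_profiles.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("ps", "bs_mnm"):
        df[col] = df[col].astype(int)
    for cond in CONDITIONS:
        df[cond] = pd.to_numeric(df[cond].replace("NA", None))
    return df


def gain_table_profiles(df: pd.DataFrame | None = None) -> dict[str, pd.Series]:
    """Per-gene binary profiles (condition-indexed Series) from the table."""
    df = load_gain_table() if df is None else df
    return {
        row["gene"]: pd.Series(
            [row[c] for c in CONDITIONS], index=list(CONDITIONS), dtype=float
        )
        for _, row in df.iterrows()
    }
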