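"""Bundled study table for *Crepis* s.l. karyotypes and genome sizes.

One row per analysed accession: chromosome counts (2n, base number x,
ploidy), the karyotype formula and asymmetry index from the morphometric
analysis, and the flow-cytometric 1C value (pg) with its SD and internal
standard where available.  Clade labels follow the plastid phylogeny
(clades I-III, subclades IVa-IVc, and the *Lagoseris* lineage); accessions
whose subclade is not resolved in the source carry the generic label
``IV``.  The polyploid *C. biennis* enters with its literature base number
x = 5.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .karyo_metrics import BaseNumberRecord

_TABLE = "crepis_table2.tsv"


def load_study_table() -> pd.DataFrame:
    """The per-accession study table as a DataFrame (NaN for missing)."""
    with resources.files("karyoevol.data").joinpath(_TABLE).open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["-"])
    df["genus"] = df["species"].str.split().str[0]
    return df


def base_number_records(
    df: pd.DataFrame | None = None,
    genus: str | None = "Crepis",
    diploid_only: bool = True,
) -> list[BaseNumberRecord]:
    """Records for :func:`karyoevol.karyo_metrics.tally_base_numbers`."""
    if df is None:
        df = load_study_table()
    if genus is not None:
        df = df[df["genus"] == genus]
    if diploid_only:
        df = df[df["ploidy"] == 2]
    return [
        BaseNumberRecord(
            species=row.species,
            base_number=int(row.x),
            infraspecific="" if pd.isna(row.infraspecific) else str(row.infraspecific),
            ploidy=int(row.ploidy),
        )
        for row in df.itertuples()
    ]


def one_c_values(
    df: pd.DataFrame | None = None,
    genus: str | None = "Crepis",
    diploid_only: bool = False,
) -> dict[str, float]:
    """Measured 1C values (pg), keyed by species (+accession if several).

    Each species has at most one measured accession per cytotype in the
    table, so keys are effectively species names.
    """
    if df is None:
        df = load_study_table()
    if genus is not None:
        df = df[df["genus"] == genus]
    if diploid_only:
        df = df[df["ploidy"] == 2]
    df = df[np.isfinite(df["one_c_pg"])]
    out: dict[str, float] = {}
    for row in df.itertuples():
        key = row.species
        if key in out:  # disambiguate repeated cytotypes
            key = f"{row.species} ({row.accession})"
        out[key] = float(row.one_c_pg)
    return out


def clade_groups(
    df: pd.DataFrame | None = None, genus: str | None = "Crepis"
) -> dict[str, str]:
    """taxon -> clade label mapping aligned with :func:`one_c_values`."""
    if df is None:
        df = load_study_table()
    if genus is not None:
        df = df[df["genus"] == genus]
    groups: dict[str, str] = {}
    for row in df.itertuples():
        groups.setdefault(row.species, row.clade)
    return groups
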