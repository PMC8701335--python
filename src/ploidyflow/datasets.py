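"""Packaged karyological and endopolyploidy survey tables.

Three curated tables for 25 wild populations of 23 *Echeveria* species:

``karyology``
    Chromosome number 2n, basic number x, ploidy decomposition, the
    internal standard used, replicate-averaged 2C content (pg, mean +/-
    SE) and the published monoploid genome size in Mbp.  The
    ``mbp_off_by_one`` flag marks three rows whose published Mbp value
    differs by one unit from recomputation off the rounded 2C mean (the
    source rounded from unrounded replicate means).  For *E. helmutiana*
    x is recorded as 21 (2n = 42, diploid).
``endopolyploidy_populations``
    Per-population leaf-parenchyma nuclei percentages over 2C..64C with
    the published endocycle label and cycle value.  ``two_level`` marks
    populations whose individuals split into two endopolyploidy patterns;
    ``aggregate_discordant`` marks the three whose published aggregate
    cycle value is not the mean of their per-individual values.
``endopolyploidy_individuals``
    The per-individual rows behind the two-level populations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PCT_COLUMNS = ["pct_2c", "pct_4c", "pct_8c", "pct_16c", "pct_32c", "pct_64c"]
LEVEL_BY_COLUMN = dict(
    zip(PCT_COLUMNS, ["2C", "4C", "8C", "16C", "32C", "64C"])
)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("ploidyflow.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"accession": str})


def load_karyology() -> pd.DataFrame:
    """Karyology and genome-size table, one row per population (25)."""
    return _read("karyology.csv")


def load_endopolyploidy_populations() -> pd.DataFrame:
    """Per-population C-level percentage table (25 rows)."""
    return _read("endopolyploidy_populations.csv")


def load_endopolyploidy_individuals() -> pd.DataFrame:
    """Per-individual C-level percentages for two-level populations."""
    return _read("endopolyploidy_individuals.csv")


def percentages_from_row(row) -> dict[str, float]:
    """C-level percentage dict from one table row (NaN levels -> absent)."""
    out = {}
    for col, level in LEVEL_BY_COLUMN.items():
        v = row[col]
        if pd.notna(v):
            out[level] = float(v)
    return out
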