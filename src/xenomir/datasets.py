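"""Bundled reference tables from the milk-feeding validation dataset.

Small published summary tables shipped as CSV so the sequencing-evidence
arm can be exercised without re-downloading raw data:

* per-run mapping statistics for the four pooled plasma small-RNA
  libraries of SRA BioProject PRJNA307561 (time points T0/T3/T6/T9,
  mapped-read counts under three quantification tools);
* raw counts of the 17 bovine-specific (no human sequence homolog)
  miRNAs detected in those libraries;
* the top plasma increasers T0→T3 with their milk-abundance ranks, and
  the top milk miRNAs with their plasma fold changes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "pooled_mapping_stats",
    "bovine_unique_counts",
    "plasma_increasers_vs_milk",
    "milk_top_vs_plasma",
]


def _path(name: str):
    return resources.files("xenomir.data").joinpath(name)


def pooled_mapping_stats() -> pd.DataFrame:
    """Total and mapped read counts per pooled plasma library.

    Index: SRA run accession.  Columns: timepoint, total_reads, and
    mapped-read counts for the miRge, Chimira and Bowtie/miRBase routes.
    """
    with resources.as_file(_path("plasma_pool_mapping.csv")) as p:
        return pd.read_csv(p, index_col=0)


def bovine_unique_counts() -> pd.DataFrame:
    """Raw counts of bovine-specific miRNAs per time point (blank = 0)."""
    with resources.as_file(_path("bovine_unique_counts.csv")) as p:
        df = pd.read_csv(p, index_col=0)
    return df.fillna(0).astype(int)


def plasma_increasers_vs_milk() -> pd.DataFrame:
    """Top T0→T3 plasma increasers with milk abundance rank (NaN = ND)."""
    with resources.as_file(_path("plasma_increase_milk_rank.csv")) as p:
        return pd.read_csv(p, index_col=0)


def milk_top_vs_plasma() -> pd.DataFrame:
    """Most abundant milk miRNAs with plasma fold change (NaN = ND)."""
    with resources.as_file(_path("milk_top_plasma_fc.csv")) as p:
        return pd.read_csv(p, index_col=0)
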