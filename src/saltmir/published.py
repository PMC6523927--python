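"""Loaders for the published summary tables bundled with the package.

These are the printed sequencing summary (per-library raw/clean/mapped
counts), the sRNA category abundances, and the two novel-miRNA differential
expression tables (control/stress counts, TPMs, log2 ratios, p-values, FDR
and up/down labels).  They serve as verifiable arithmetic inputs: the
package's own TPM, log2-ratio, percentage and regulation-call routines are
checked against the printed columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1", "load_table2", "load_table5", "load_table6"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("saltmir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """Per-library sequencing summary: raw, clean and mapped tag counts."""
    return _load("table1_sequencing_summary.tsv")


def load_table2() -> pd.DataFrame:
    """Read abundance of each sRNA category per library."""
    return _load("table2_category_abundance.tsv")


def load_table5() -> pd.DataFrame:
    """Novel-miRNA differential expression, sensitive genotype (control vs stress)."""
    return _load("table5_novel_mirna_de_hc4_vs_hsa.tsv")


def load_table6() -> pd.DataFrame:
    """Novel-miRNA differential expression, tolerant genotype (control vs stress)."""
    return _load("table6_novel_mirna_de_ic1_vs_is4.tsv")
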