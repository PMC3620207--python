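"""Published summary tables from the blood small-RNA profiling study of
bone-metastatic vs non-metastatic lung adenocarcinoma.

These are inputs, not outputs: the differential-expression summary (28
miRNAs with log2 fold change, p-value and status) lets the threshold rules
be checked against every printed status label, and the KEGG enrichment
table (pathway, reported gene count, Entrez gene IDs, adjusted p) supports
the self-consistency check that re-counting the printed IDs reproduces
each row's gene count.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data(name: str) -> pd.DataFrame:
    with resources.files("mirmet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reported_de_table() -> pd.DataFrame:
    """The study's 28-row differential-expression summary.

    Columns: mir_name, fold_change (log2), p_value, status.
    """
    return _data("de_mirnas.tsv")


def load_reported_kegg_table() -> pd.DataFrame:
    """The study's KEGG enrichment table.

    Columns: pathway, number_of_genes, gene_ids (space-separated Entrez
    IDs), p_value (adjusted, hypergeometric).
    """
    return _data("kegg_pathways.tsv")
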