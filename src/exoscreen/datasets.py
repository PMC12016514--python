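"""Small bundled reference tables.

``load_go_term_rows`` returns the published GO-term enrichment rows for
the Pdr1/Yap1 acetic-acid ChIP-exo screen (terms over-represented among
genes targeted only under acid stress), with the printed gene lists, term
sizes and the 7,166-gene universe denominator.  Useful as a worked
fixture for the enrichment machinery and for cross-TF gene comparisons.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_go_term_rows", "go_rows_as_map"]


def load_go_term_rows() -> pd.DataFrame:
    """GO rows: term, tf, published adjusted p, n, K, N and gene list."""
    ref = resources.files("exoscreen.data").joinpath("go_term_rows.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["genes"] = df["genes"].str.split(",")
    return df


def go_rows_as_map(df: pd.DataFrame | None = None) -> dict[str, frozenset[str]]:
    """The rows as a term -> gene-set mapping (Pdr1 and Yap1 rows mixed)."""
    if df is None:
        df = load_go_term_rows()
    return {row.term: frozenset(row.genes) for row in df.itertuples(index=False)}
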