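"""The glycogen-metabolism gene panel and published worked-example tables.

The panel covers genes encoding proteins of glycogen synthesis or
breakdown.  Each entry carries the gene symbol, cytoband locus,
chromosome, and a regulatory role: ``de_novo`` (direct de novo
synthesis), ``positive`` / ``negative`` regulator of glycogen synthesis,
or ``dual`` (both production and breakdown).

Only the 22 differentially expressed genes (plus GAA) have published
panel annotations; the remaining 44 entries in the packaged 67-gene
default are a curated synthetic completion of standard glycogen-pathway
genes (flagged ``published=0``) so the full-panel screen is exercised
end to end.  A user-supplied panel TSV with the same columns replaces it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "PanelEntry",
    "load_panel",
    "load_reference_differential",
    "load_reference_clinical_counts",
    "ROLES",
]

ROLES = ("de_novo", "positive", "negative", "dual")


@dataclass(frozen=True)
class PanelEntry:
    symbol: str
    locus: str
    chrom: str
    role: str


def _data_path(name: str):
    return resources.files("umglyco.data").joinpath(name)


def load_panel(path=None) -> pd.DataFrame:
    """Load the gene panel (packaged 67-gene default or a user TSV).

    Returns a DataFrame with columns symbol, locus, chrom, role
    (and, for the packaged panel, a ``published`` flag).
    """
    src = _data_path("gene_panel.tsv") if path is None else path
    panel = pd.read_csv(src, sep="\t", dtype=str)
    required = {"symbol", "locus", "chrom", "role"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    if panel["symbol"].duplicated().any():
        dups = panel.loc[panel["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate panel symbols: {dups}")
    bad = set(panel["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown panel roles: {sorted(bad)}")
    return panel


def load_reference_differential() -> pd.DataFrame:
    """Published per-gene fold changes of the 22-gene differential set.

    The signed median fold changes and two-decimal adjusted p displays for
    the all-patients run and the copy-number-omission rerun ("n.a." for
    chromosome-3 genes, parsed to NaN).  Serves as a worked-example input
    for the fold-change summary statistics.
    """
    df = pd.read_csv(_data_path("table1_reference.tsv"), sep="\t")
    for col in ("fc_all", "p_all", "fc_filtered", "p_filtered"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_reference_clinical_counts() -> pd.DataFrame:
    """Published clinical 2x2 counts by glycogen group (high vs low).

    One row per variable level with the counts in the high- and
    low-glycogen columns; worked-example input for the chi-square
    association report.
    """
    return pd.read_csv(_data_path("table2_counts.tsv"), sep="\t")
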