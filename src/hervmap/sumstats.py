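"""Per-variant summary statistics (beta, se, p, z) and allele harmonization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class SummaryStats:
    """GWAS/eQTL summary statistics for one trait over a set of variants.

    ``a1`` is the effect allele.  z = beta / se is materialised as a column.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"summary stats missing columns: {sorted(missing)}")
        if (self.table["se"] <= 0).any():
            raise ValueError("all standard errors must be positive")
        self.table = self.table.reset_index(drop=True).copy()
        self.table["z"] = self.table["beta"] / self.table["se"]

    def __len__(self) -> int:
        return len(self.table)

    def top_variant(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]

    def lookup(self, variant_id: str) -> pd.Series | None:
        hit = self.table[self.table["variant_id"] == variant_id]
        return None if hit.empty else hit.iloc[0]


def harmonize(
    exposure: SummaryStats, outcome: SummaryStats, drop_ambiguous: bool = True
) -> tuple[SummaryStats, SummaryStats]:
    """Align the two datasets on shared variants and effect alleles.

    Outcome betas are flipped where its a1/a2 are swapped relative to the
    exposure; strand-ambiguous palindromic variants (A/T, C/G) are dropped
    (allele frequency is not trusted to resolve them).  Variants whose
    alleles cannot be reconciled are dropped.
    """
    e = exposure.table.set_index("variant_id")
    o = outcome.table.set_index("variant_id")
    shared = e.index.intersection(o.index)
    e, o = e.loc[shared].copy(), o.loc[shared].copy()
    keep = []
    for vid in shared:
        ea1, ea2 = e.at[vid, "a1"].upper(), e.at[vid, "a2"].upper()
        oa1, oa2 = o.at[vid, "a1"].upper(), o.at[vid, "a2"].upper()
        if drop_ambiguous and (_is_ambiguous(ea1, ea2) or _is_ambiguous(oa1, oa2)):
            continue
        if (oa1, oa2) == (ea1, ea2):
            keep.append(vid)
        elif (oa1, oa2) == (ea2, ea1):
            o.at[vid, "beta"] = -o.at[vid, "beta"]
            o.at[vid, "a1"], o.at[vid, "a2"] = ea1, ea2
            o.at[vid, "freq"] = 1 - o.at[vid, "freq"]
            keep.append(vid)
        # else: irreconcilable alleles, drop
    e, o = e.loc[keep].reset_index(), o.loc[keep].reset_index()
    return SummaryStats(e.drop(columns="z")), SummaryStats(o.drop(columns="z"))


def read_summary_stats(path) -> SummaryStats:
    return SummaryStats(pd.read_csv(path, sep="\t"))
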