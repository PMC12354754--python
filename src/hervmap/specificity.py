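"""Cell-type-specific HERV calling and chromatin-state enrichment.

A locus counts as specific to a cell type when a Wilcoxon rank-sum test of
that group against all other cells survives Bonferroni correction at
p < 1e-5 with log2 fold change > 2.  Specific loci are then tested for
enrichment in each of the 15 ChromHMM chromatin states of the matching
cell type with two-sided Fisher exact tests and BH-FDR at 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from intervaltree import IntervalTree
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

STATE_VOCAB = [
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
]

ENHANCER_STATES = ("EnhG", "Enh")
PROMOTER_STATES = ("TssA", "TssAFlnk")


@dataclass
class ChromatinStateTrack:
    """One cell type's 15-state segmentation: non-overlapping labeled intervals."""

    celltype: str
    intervals: pd.DataFrame  # columns chrom, start, end, state

    def __post_init__(self) -> None:
        unknown = set(self.intervals["state"]) - set(STATE_VOCAB)
        if unknown:
            raise ValueError(f"unknown chromatin state labels: {sorted(unknown)}")

    def trees(self, states: tuple[str, ...] | None = None) -> dict[str, IntervalTree]:
        df = self.intervals
        if states is not None:
            df = df[df["state"].isin(states)]
        trees: dict[str, IntervalTree] = {}
        for row in df.itertuples(index=False):
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.state)
        return trees


def read_bed9(path, celltype: str) -> ChromatinStateTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
    )
    return ChromatinStateTrack(celltype=celltype, intervals=df)


# ---------------------------------------------------------------------------
# Differential expression / marker calling
# ---------------------------------------------------------------------------


def call_celltype_markers(
    adata: ad.AnnData,
    groupby: str = "celltype",
    alpha: float = 1e-5,
    min_log2fc: float = 2.0,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum per (feature, cell type).

    Runs on the log1p-normalized cell matrix; the fold change compares
    expm1 group means.  Bonferroni family = features x groups tested.
    Returns a tidy frame with raw and adjusted p, log2FC, and the specific
    flag (adjusted p < alpha and log2FC > min_log2fc).
    """
    labels = adata.obs[groupby]
    groups = [g for g, n in labels.value_counts().items() if n >= 2]
    skipped = sorted(set(labels.unique()) - set(groups))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 cells each")
    X = sparse.csr_matrix(adata.X, dtype=float).toarray()
    expm1 = np.expm1(X)
    n_tests = len(groups) * adata.n_vars
    rows = []
    for g in groups:
        mask = (labels == g).to_numpy()
        a, b = X[mask], X[~mask]
        stat, p = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                     method="asymptotic")
        mean_in = expm1[mask].mean(axis=0)
        mean_out = expm1[~mask].mean(axis=0)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        p_adj = np.minimum(p * n_tests, 1.0)
        for j, feat in enumerate(adata.var_names):
            rows.append(
                {
                    "feature": feat,
                    "celltype": g,
                    "statistic": stat[j],
                    "p": p[j],
                    "p_bonferroni": p_adj[j],
                    "log2fc": log2fc[j],
                    "specific": bool(p_adj[j] < alpha and log2fc[j] > min_log2fc),
                }
            )
    result = pd.DataFrame(rows)
    result.attrs["skipped_groups"] = skipped
    return result


# ---------------------------------------------------------------------------
# Chromatin-state enrichment
# ---------------------------------------------------------------------------


def _features_in_states(
    features: pd.DataFrame, track: ChromatinStateTrack, states: tuple[str, ...]
) -> pd.Series:
    """Boolean per feature: interval overlaps any interval of the given
    states by >= 1 bp.  ``features`` needs chrom/start/end columns."""
    trees = track.trees(states)
    hits = []
    for row in features.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits.append(bool(tree and tree.overlap(row.start, row.end)))
    return pd.Series(hits, index=features.index)


def fisher_state_enrichment(
    specific_ids: dict[str, list[str]],
    tracks: dict[str, ChromatinStateTrack],
    background: pd.DataFrame,
    states: list[str] | None = None,
) -> pd.DataFrame:
    """Specific-vs-background Fisher enrichment per (cell type, state).

    ``background`` indexes every feature entering the differential test with
    chrom/start/end columns.  For each cell type and state S the 2x2 table
    is {specific, non-specific} x {overlaps S, does not}; BH-FDR spans all
    cell types x states tested.  An empty specific set yields NaN results.
    """
    states = states or STATE_VOCAB
    rows = []
    for ct, track in tracks.items():
        spec = set(specific_ids.get(ct, []))
        is_spec = background.index.isin(spec)
        for state in states:
            in_state = _features_in_states(background, track, (state,)).to_numpy()
            a = int((is_spec & in_state).sum())
            b = int((is_spec & ~in_state).sum())
            c = int((~is_spec & in_state).sum())
            d = int((~is_spec & ~in_state).sum())
            if a + b == 0:
                orr, p = np.nan, np.nan
            else:
                orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"celltype": ct, "state": state, "a": a, "b": b,
                         "c": c, "d": d, "odds_ratio": orr, "p": p})
    result = pd.DataFrame(rows)
    ok = result["p"].notna()
    result["q"] = np.nan
    if ok.any():
        result.loc[ok, "q"] = multipletests(result.loc[ok, "p"], method="fdr_bh")[1]
    return result


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s, cur_e = None, None
        for row in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = row.start, row.end
            elif row.start <= cur_e:
                cur_e = max(cur_e, row.end)
            else:
                out.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                cur_s, cur_e = row.start, row.end
        if cur_s is not None:
            out.append({"chrom": chrom, "start": cur_s, "end": cur_e})
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def extract_enhancer_promoter_sets(
    track: ChromatinStateTrack,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(enhancers, promoters): merged unions of EnhG+Enh and TssA+TssAFlnk."""
    df = track.intervals
    enh = _merge_intervals(df[df["state"].isin(ENHANCER_STATES)][["chrom", "start", "end"]])
    pro = _merge_intervals(df[df["state"].isin(PROMOTER_STATES)][["chrom", "start", "end"]])
    return enh, pro
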