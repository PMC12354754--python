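"""Per-cell and pseudobulk normalization, variable-locus selection, and
HERV-to-nearest-gene correlation.

Cell-level normalization scales each cell to 1e4 total counts then log1p;
pseudobulk aggregates raw UMIs per (individual, cell type), scales each
individual to 1e6 within the cell type, then log1p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats


def normalize_per_cell(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log1p(count * scale / cell_total); zero counts stay exactly zero."""
    X = sparse.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cells with zero total counts present; run QC first")
    inv = sparse.diags(scale / totals)
    norm = inv @ X
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.X = norm
    out.uns["normalized"] = {"scale": scale, "log1p": True}
    return out


@dataclass
class PseudobulkMatrix:
    """Per-cell-type pseudobulk expression across individuals.

    ``expression``: dict celltype -> DataFrame (individuals x features) of
    log1p CPM-like values.  ``raw``: same layout, aggregate UMI counts.
    ``cells_per_individual``: dict celltype -> Series of cell counts.
    Individuals with zero cells of a type are absent from that frame.
    """

    expression: dict[str, pd.DataFrame]
    raw: dict[str, pd.DataFrame]
    cells_per_individual: dict[str, pd.Series]
    scale: float = 1e6

    @property
    def celltypes(self) -> list[str]:
        return list(self.expression)


def make_pseudobulk(adata: ad.AnnData, scale: float = 1e6) -> PseudobulkMatrix:
    """Aggregate raw UMIs per (individual, cell type), normalize, log1p."""
    if "individual" not in adata.obs or "celltype" not in adata.obs:
        raise ValueError("cell metadata must carry 'individual' and 'celltype'")
    X = sparse.csr_matrix(adata.X, dtype=float)
    expression, raw, ncells = {}, {}, {}
    for ct, obs_ct in adata.obs.groupby("celltype", observed=True):
        idx = adata.obs.index.get_indexer(obs_ct.index)
        sub = X[idx]
        groups = obs_ct["individual"].to_numpy()
        indivs = sorted(pd.unique(groups))
        agg = np.zeros((len(indivs), adata.n_vars))
        counts = []
        for i, ind in enumerate(indivs):
            rows = np.nonzero(groups == ind)[0]
            agg[i] = np.asarray(sub[rows].sum(axis=0)).ravel()
            counts.append(len(rows))
        raw_df = pd.DataFrame(agg, index=indivs, columns=adata.var_names)
        totals = raw_df.sum(axis=1)
        norm = np.log1p(raw_df.div(totals, axis=0) * scale)
        expression[ct] = norm
        raw[ct] = raw_df
        ncells[ct] = pd.Series(counts, index=indivs, name="n_cells")
    return PseudobulkMatrix(expression=expression, raw=raw,
                            cells_per_individual=ncells, scale=scale)


@dataclass
class HvgResult:
    """Mean / normalized-dispersion table with the selected flag."""

    table: pd.DataFrame  # index feature; columns mean, dispersion, dispersion_norm, selected

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def select_highly_variable(
    adata: ad.AnnData,
    min_disp: float = 0.5,
    min_mean: float = 0.1,
    max_mean: float = 4.0,
    n_bins: int = 20,
) -> HvgResult:
    """Mean-binned dispersion selection on a log1p-normalized matrix.

    Statistics are computed on the expm1 scale: dispersion = var/mean;
    features fall into ``n_bins`` equal-frequency mean bins; the normalized
    dispersion subtracts the bin median and divides by the bin MAD (bin
    mean/SD when the MAD is zero).  Selected features satisfy
    dispersion_norm > min_disp and min_mean < mean < max_mean.
    """
    X = sparse.csr_matrix(adata.X, dtype=float)
    Y = X.copy()
    Y.data = np.expm1(Y.data)
    n = Y.shape[0]
    mean = np.asarray(Y.mean(axis=0)).ravel()
    sq = Y.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    var *= n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)

    df = pd.DataFrame({"mean": mean, "dispersion": disp}, index=adata.var_names)
    ok = df["dispersion"].notna()
    try:
        bins = pd.qcut(df.loc[ok, "mean"], q=min(n_bins, ok.sum()), duplicates="drop")
    except ValueError:
        bins = pd.Series("all", index=df.index[ok])
    dnorm = pd.Series(np.nan, index=df.index)
    for _, idx in df.loc[ok].groupby(bins, observed=True).groups.items():
        d = df.loc[idx, "dispersion"]
        med = d.median()
        mad = (d - med).abs().median()
        if mad > 0:
            dnorm.loc[idx] = (d - med) / mad
        else:
            sd = d.std()
            dnorm.loc[idx] = 0.0 if (not sd or np.isnan(sd) or sd == 0) else (d - d.mean()) / sd
    df["dispersion_norm"] = dnorm
    df["selected"] = (
        (df["dispersion_norm"] > min_disp)
        & (df["mean"] > min_mean)
        & (df["mean"] < max_mean)
    ).fillna(False)
    return HvgResult(table=df)


def correlate_nearest_gene(
    pseudobulk: PseudobulkMatrix,
    herv_to_gene: dict[str, str],
    min_individuals: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of each HERV with its nearest gene, per cell type.

    Computed across individuals of the per-cell-type pseudobulk with
    mid-rank ties.  Pairs with a constant vector are reported with NaN rho
    and excluded from summaries.
    """
    rows = []
    for ct, expr in pseudobulk.expression.items():
        for herv, gene in herv_to_gene.items():
            if herv not in expr.columns or gene not in expr.columns:
                continue
            x, y = expr[herv], expr[gene]
            if len(expr) < min_individuals:
                continue
            if x.nunique() <= 1 or y.nunique() <= 1:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append({"celltype": ct, "herv_id": herv, "gene_id": gene,
                         "rho": rho, "p": p, "n": len(expr)})
    return pd.DataFrame(rows, columns=["celltype", "herv_id", "gene_id", "rho", "p", "n"])


def write_phenotype_bed(
    pseudobulk: PseudobulkMatrix,
    celltype: str,
    feature_meta: pd.DataFrame,
    path,
) -> None:
    """BED-like phenotype table: chrom, start, end, feature, one column per
    individual — the standard cis-QTL phenotype layout."""
    expr = pseudobulk.expression[celltype]
    feats = [f for f in expr.columns if f in feature_meta.index]
    out = feature_meta.loc[feats, ["chrom", "start", "end"]].copy()
    out["feature_id"] = feats
    for ind in expr.index:
        out[ind] = expr.loc[ind, feats].to_numpy()
    out.to_csv(path, sep="\t", index=False)
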