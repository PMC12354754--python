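"""Covariate-adjusted cis-eQTL mapping per cell type.

The scan follows the standard permutation-based cis-QTL design: for each
phenotype, variants within a 1 Mb window of its TSS are tested by
correlating covariate-residualized phenotype and dosage (equivalent to the
OLS t-test with covariates included, by Frisch-Waugh-Lovell); a permutation
pass re-scans phenotype permutations to get an empirical p for the top
association and fits a Beta distribution to the permutation minima so the
empirical p can be interpolated smoothly; BH-FDR across phenotypes gives
q-values; and a forward-backward stepwise pass conditioning on accepted
dosages yields ranked conditionally independent signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeSet


# ---------------------------------------------------------------------------
# Phenotype / covariate preparation
# ---------------------------------------------------------------------------


def prepare_phenotypes_covariates(
    expression: pd.DataFrame,
    genotypes: GenotypeSet,
    base_covariates: pd.DataFrame,
    min_fraction: float = 0.10,
    n_pcs: int = 6,
    n_factors: int = 2,
    n_hvg_for_factors: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict phenotypes and assemble the covariate matrix.

    Phenotypes are features expressed (non-zero) in strictly more than
    ``min_fraction`` of shared individuals.  Covariates are sex and age,
    the top ``n_pcs`` genotype principal-component scores, and
    ``n_factors`` latent expression factors — principal components of the
    ``n_hvg_for_factors`` most variable phenotype columns (a PCA stand-in
    for PEER-style latent confounders).
    """
    shared = expression.index.intersection(genotypes.dosages.index).intersection(
        base_covariates.index
    )
    n_cov_total = 2 + n_pcs + n_factors
    if len(shared) < n_cov_total + 10:
        raise ValueError(
            f"only {len(shared)} shared individuals; need >= {n_cov_total + 10}"
        )
    expr = expression.loc[shared]
    present = (expr > 0).mean(axis=0) > min_fraction
    phenotypes = expr.loc[:, present]

    dos = genotypes.dosages.loc[shared].to_numpy(dtype=float)
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        dos = np.where(nan_mask, col_mean[None, :], dos)
    dos = dos - dos.mean(axis=0)
    u, s, _ = np.linalg.svd(dos, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    pcs = (pcs - pcs.mean(axis=0)) / pcs.std(axis=0)

    variances = phenotypes.var(axis=0)
    top = variances.sort_values(ascending=False).index[:n_hvg_for_factors]
    sub = phenotypes[top].to_numpy()
    sub = sub - sub.mean(axis=0)
    uf, sf, _ = np.linalg.svd(sub, full_matrices=False)
    k = min(n_factors, uf.shape[1])
    factors = uf[:, :k] * sf[:k]
    factors = (factors - factors.mean(axis=0)) / factors.std(axis=0)

    cov = pd.DataFrame(index=shared)
    cov["sex"] = base_covariates.loc[shared, "sex"].to_numpy(dtype=float)
    cov["age"] = base_covariates.loc[shared, "age"].to_numpy(dtype=float)
    for i in range(n_pcs):
        cov[f"PC{i + 1}"] = pcs[:, i]
    for i in range(k):
        cov[f"factor{i + 1}"] = factors[:, i]
    return phenotypes, cov


# ---------------------------------------------------------------------------
# Residualization machinery
# ---------------------------------------------------------------------------


def _design_q(covariates: pd.DataFrame) -> np.ndarray:
    """Orthonormal basis of [intercept | covariates]."""
    C = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    q, _ = np.linalg.qr(C)
    return q


def _residualize(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    return x - q @ (q.T @ x)


def _p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df)


# ---------------------------------------------------------------------------
# Nominal scan
# ---------------------------------------------------------------------------


def cis_window_variants(
    variants: pd.DataFrame, chrom: str, tss: int, window: int = 1_000_000
) -> pd.Index:
    """Variant ids with |pos - tss| <= window on the phenotype's chromosome."""
    sel = (variants["chrom"] == chrom) & ((variants["pos"] - tss).abs() <= window)
    return variants.index[sel]


def nominal_cis_scan(
    phenotypes: pd.DataFrame,
    phenotype_meta: pd.DataFrame,
    genotypes: GenotypeSet,
    covariates: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """All (phenotype, cis-variant) association records.

    ``phenotype_meta`` indexes each phenotype with chrom and tss columns.
    Association = correlation of covariate-residualized phenotype and
    dosage; t with df = n - 2 - n_covariates; two-sided p.  Monomorphic
    variants are skipped.
    """
    individuals = phenotypes.index
    q = _design_q(covariates.loc[individuals])
    n = len(individuals)
    df = n - 2 - covariates.shape[1]
    if df < 1:
        raise ValueError("not enough individuals for the covariate model")
    dos_all = genotypes.dosages.loc[individuals]
    records = []
    for pheno in phenotypes.columns:
        chrom = phenotype_meta.at[pheno, "chrom"]
        tss = int(phenotype_meta.at[pheno, "tss"])
        cis = cis_window_variants(genotypes.variants, chrom, tss, window)
        if len(cis) == 0:
            continue
        G = dos_all[cis].to_numpy(dtype=float)
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
        Gr = _residualize(G, q)
        gsd = Gr.std(axis=0)
        poly = gsd > 0
        y = phenotypes[pheno].to_numpy(dtype=float)
        yr = _residualize(y, q)
        ysd = yr.std()
        if ysd == 0:
            continue
        r = (yr @ Gr[:, poly]) / (n * ysd * gsd[poly])
        p = _p_from_r(r, df)
        beta = r * ysd / gsd[poly]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = (ysd / gsd[poly]) * np.sqrt((1 - np.clip(r, -1, 1) ** 2) / df)
        t = r * np.sqrt(df / (1 - np.clip(r, -1 + 1e-15, 1 - 1e-15) ** 2))
        for j, vid in enumerate(np.asarray(cis)[poly]):
            records.append(
                {
                    "phenotype_id": pheno,
                    "variant_id": vid,
                    "beta": beta[j],
                    "se": se[j],
                    "t": t[j],
                    "p_nominal": p[j],
                }
            )
    return pd.DataFrame(
        records, columns=["phenotype_id", "variant_id", "beta", "se", "t", "p_nominal"]
    )


# ---------------------------------------------------------------------------
# Permutation pass with Beta approximation
# ---------------------------------------------------------------------------


def _fit_beta(pvals: np.ndarray) -> tuple[float, float, bool]:
    """Beta(a, b) by MLE with a method-of-moments fallback."""
    pvals = np.clip(pvals, 1e-12, 1 - 1e-12)
    m, v = pvals.mean(), pvals.var()
    if v == 0:
        return 1.0, 1.0, True
    common = m * (1 - m) / v - 1
    a_mom, b_mom = max(m * common, 1e-6), max((1 - m) * common, 1e-6)
    try:
        a, b, _, _ = stats.beta.fit(pvals, a_mom, b_mom, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError
        return float(a), float(b), False
    except Exception:
        return float(a_mom), float(b_mom), True


def permutation_pass(
    phenotypes: pd.DataFrame,
    phenotype_meta: pd.DataFrame,
    genotypes: GenotypeSet,
    covariates: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Phenotype-level records with empirical and Beta-approximated p.

    Permutes phenotype values across individuals (genotypes and covariates
    fixed), rescans the cis window, and records the permutation minimum p.
    ``p_empirical = (1 + #{perm min p <= observed}) / (1 + n_perm)``;
    ``p_beta`` evaluates the fitted Beta CDF at the observed minimum.
    """
    rng = np.random.default_rng(seed)
    individuals = phenotypes.index
    q = _design_q(covariates.loc[individuals])
    n = len(individuals)
    df = n - 2 - covariates.shape[1]
    dos_all = genotypes.dosages.loc[individuals]
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    records = []
    for pheno in phenotypes.columns:
        chrom = phenotype_meta.at[pheno, "chrom"]
        tss = int(phenotype_meta.at[pheno, "tss"])
        cis = cis_window_variants(genotypes.variants, chrom, tss, window)
        if len(cis) == 0:
            continue
        G = dos_all[cis].to_numpy(dtype=float)
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
        Gr = _residualize(G, q)
        gsd = Gr.std(axis=0)
        poly = gsd > 0
        if not poly.any():
            continue
        Gn = Gr[:, poly] / (gsd[poly] * n)  # so yn @ Gn = r when yn standardized
        y = phenotypes[pheno].to_numpy(dtype=float)
        yr = _residualize(y, q)
        ysd = yr.std()
        if ysd == 0:
            continue
        r_obs = (yr / ysd) @ Gn
        j_top = int(np.argmax(np.abs(r_obs)))
        rmax_obs = float(np.abs(r_obs[j_top]))

        Yp = y[perm_idx]  # (n_perm, n)
        Yr = Yp - (Yp @ q) @ q.T
        sd = Yr.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf
        R = (Yr / sd) @ Gn
        rmax_perm = np.abs(R).max(axis=1)

        p_obs = float(_p_from_r(np.array([rmax_obs]), df)[0])
        p_perm = _p_from_r(rmax_perm, df)
        p_emp = (1 + int((p_perm <= p_obs).sum())) / (1 + n_perm)
        a, b, mom = _fit_beta(p_perm)
        p_beta = float(stats.beta.cdf(p_obs, a, b))

        top_vid = np.asarray(cis)[poly][j_top]
        r_top = r_obs[j_top]
        beta = r_top * ysd / gsd[poly][j_top]
        se = (ysd / gsd[poly][j_top]) * np.sqrt((1 - r_top**2) / df)
        records.append(
            {
                "phenotype_id": pheno,
                "n_variants": int(poly.sum()),
                "variant_id": top_vid,
                "beta": beta,
                "se": se,
                "p_nominal": p_obs,
                "p_empirical": p_emp,
                "beta_shape1": a,
                "beta_shape2": b,
                "beta_fit_mom": mom,
                "p_beta": p_beta,
            }
        )
    return pd.DataFrame(records)


def phenotype_fdr(perm_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH q-values on p_beta across phenotypes (one cell type = one family)."""
    from statsmodels.stats.multitest import multipletests

    out = perm_results.copy()
    if len(out):
        out["q_value"] = multipletests(out["p_beta"], method="fdr_bh")[1]
        out["significant"] = out["q_value"] < alpha
    else:
        out["q_value"] = []
        out["significant"] = []
    return out


def pbeta_significance_cutoff(perm_results: pd.DataFrame, alpha: float = 0.05) -> float | None:
    """Global p_beta cutoff implied by the q < alpha boundary.

    Midpoint between the largest significant and smallest non-significant
    p_beta (the usual threshold-propagation convention for conditional
    passes).  None when nothing is significant.
    """
    with_q = phenotype_fdr(perm_results, alpha)
    sig = with_q[with_q["significant"]]
    if sig.empty:
        return None
    lb = sig["p_beta"].max()
    nonsig = with_q[~with_q["significant"]]
    ub = nonsig["p_beta"].min() if not nonsig.empty else 1.0
    return float((lb + ub) / 2)


# ---------------------------------------------------------------------------
# Conditionally independent signals
# ---------------------------------------------------------------------------


@dataclass
class IndependentSignal:
    rank: int
    variant_id: str
    beta: float
    se: float
    p_nominal: float


def conditional_independent_scan(
    phenotype: pd.Series,
    chrom: str,
    tss: int,
    genotypes: GenotypeSet,
    covariates: pd.DataFrame,
    beta_shape1: float,
    beta_shape2: float,
    pbeta_cutoff: float,
    window: int = 1_000_000,
    r2_collinear: float = 0.95,
) -> pd.DataFrame:
    """Forward-backward stepwise scan for one significant phenotype.

    The phenotype's nominal significance threshold is the Beta quantile of
    the global p_beta cutoff; forward rounds add the best cis variant while
    it passes the threshold (conditioning on all accepted dosages), skipping
    candidates collinear (r^2 > ``r2_collinear``) with an accepted variant;
    the backward pass keeps each accepted variant only if it stays below
    threshold conditioned on all the others.  Ranked by final p.
    """
    p_threshold = float(stats.beta.ppf(pbeta_cutoff, beta_shape1, beta_shape2))
    individuals = phenotype.index
    cis = cis_window_variants(genotypes.variants, chrom, tss, window)
    if len(cis) == 0:
        return pd.DataFrame(columns=["rank", "variant_id", "beta", "se", "p_nominal"])
    dos = genotypes.dosages.loc[individuals, cis].to_numpy(dtype=float)
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean[None, :], dos)
    pos = genotypes.variants.loc[cis, "pos"].to_numpy()
    vids = np.asarray(cis)
    y = phenotype.to_numpy(dtype=float)
    n = len(y)

    def scan(extra: list[int], exclude: set[int]):
        """Best (p, |t|, pos)-ordered variant conditioning on accepted dosages."""
        cov = covariates.loc[individuals].copy()
        for k, j in enumerate(extra):
            cov[f"__cond{k}"] = dos[:, j]
        q = _design_q(cov)
        df = n - 2 - cov.shape[1]
        if df < 1:
            return None
        Gr = _residualize(dos, q)
        gsd = Gr.std(axis=0)
        yr = _residualize(y, q)
        ysd = yr.std()
        if ysd == 0:
            return None
        ok = gsd > 0
        for j in exclude | set(extra):
            ok[j] = False
        if not ok.any():
            return None
        r = (yr @ Gr[:, ok]) / (n * ysd * gsd[ok])
        p = _p_from_r(r, df)
        t = np.abs(r) * np.sqrt(df / (1 - np.clip(r, -1 + 1e-15, 1 - 1e-15) ** 2))
        idx_ok = np.nonzero(ok)[0]
        order = np.lexsort((pos[idx_ok], -t, p))
        jbest = idx_ok[order[0]]
        kbest = order[0]
        beta = r[kbest] * ysd / gsd[jbest]
        se = (ysd / gsd[jbest]) * np.sqrt((1 - r[kbest] ** 2) / df)
        return jbest, float(p[kbest]), float(beta), float(se)

    accepted: list[int] = []
    excluded: set[int] = set()
    while True:
        res = scan(accepted, excluded)
        if res is None:
            break
        j, p, _, _ = res
        if p >= p_threshold:
            break
        collinear = False
        for ja in accepted:
            r = np.corrcoef(dos[:, j], dos[:, ja])[0, 1]
            if r**2 > r2_collinear:
                collinear = True
                break
        if collinear:
            excluded.add(j)
            continue
        accepted.append(j)

    # backward: each accepted must survive conditioning on all the others
    final = []
    for j in accepted:
        others = [k for k in accepted if k != j]
        cov = covariates.loc[individuals].copy()
        for k, jo in enumerate(others):
            cov[f"__cond{k}"] = dos[:, jo]
        q = _design_q(cov)
        df = n - 2 - cov.shape[1]
        Gr = _residualize(dos[:, [j]], q)
        gsd = Gr[:, 0].std()
        yr = _residualize(y, q)
        ysd = yr.std()
        if gsd == 0 or ysd == 0 or df < 1:
            continue
        r = float(yr @ Gr[:, 0] / (n * ysd * gsd))
        p = float(_p_from_r(np.array([r]), df)[0])
        if p < p_threshold:
            beta = r * ysd / gsd
            se = (ysd / gsd) * np.sqrt((1 - r**2) / df)
            final.append({"variant_id": vids[j], "beta": beta, "se": se, "p_nominal": p})
    final.sort(key=lambda d: d["p_nominal"])
    for rank, rec in enumerate(final, start=1):
        rec["rank"] = rank
    return pd.DataFrame(final, columns=["rank", "variant_id", "beta", "se", "p_nominal"])
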