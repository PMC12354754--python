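"""Summary-level triangulation: SMR, HEIDI, colocalization, mediation triads.

SMR tests whether an exposure's strongest cis instrument also carries the
outcome association: at that variant, b_xy = b_out / b_exp and
T_SMR = z_exp^2 z_out^2 / (z_exp^2 + z_out^2) ~ chi^2(1) under the null of
no pleiotropy.  HEIDI asks whether b_xy is homogeneous across linked SNPs
(one shared causal variant) or heterogeneous (linkage of distinct
variants).  Colocalization evaluates the five standard hypotheses with
Wakefield approximate Bayes factors.  The mediation intersection collects
(HERV, gene, disease) triads whose three pairwise associations are all
significant within one cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .sumstats import SummaryStats, harmonize


# ---------------------------------------------------------------------------
# SMR
# ---------------------------------------------------------------------------


@dataclass
class SmrOutcome:
    top_variant: str
    b_xy: float
    se_xy: float
    p_smr: float
    z_exposure: float
    z_outcome: float


def smr_test(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instrument_p: float = 5e-8,
) -> SmrOutcome | None:
    """Single-instrument SMR at the exposure's top cis variant.

    Returns None when no exposure variant reaches ``instrument_p`` or the
    instrument (and every fallback below threshold) is absent from the
    outcome.  ``se_xy = |b_xy| / sqrt(T_SMR)``.
    """
    e = exposure.table.sort_values("p")
    candidates = e[e["p"] < instrument_p]
    if candidates.empty:
        return None
    o = outcome.table.set_index("variant_id")
    row = None
    for _, cand in candidates.iterrows():
        if cand["variant_id"] in o.index:
            row = cand
            break
    if row is None:
        return None
    out = o.loc[row["variant_id"]]
    z_e = row["beta"] / row["se"]
    z_o = out["beta"] / out["se"]
    if row["beta"] == 0:
        return None
    b_xy = out["beta"] / row["beta"]
    denom = z_e**2 + z_o**2
    t_smr = (z_e**2 * z_o**2) / denom if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    se_xy = abs(b_xy) / np.sqrt(t_smr) if t_smr > 0 else np.inf
    return SmrOutcome(
        top_variant=row["variant_id"], b_xy=float(b_xy), se_xy=float(se_xy),
        p_smr=p_smr, z_exposure=float(z_e), z_outcome=float(z_o),
    )


# ---------------------------------------------------------------------------
# HEIDI
# ---------------------------------------------------------------------------


def heidi_test(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld_r: np.ndarray,
    top_variant: str | None = None,
    min_p_include: float = 1.57e-3,
    r2_hi: float = 0.9,
    r2_lo: float = 0.05,
    max_snps: int = 20,
    min_snps: int = 3,
    method: str = "satterthwaite",
) -> tuple[float, int]:
    """Heterogeneity-in-dependent-instruments test.

    Eligible SNPs have exposure p < ``min_p_include`` and r^2 with the top
    instrument in [r2_lo, r2_hi], capped at the ``max_snps`` strongest.
    d_i = b_xy(i) - b_xy(top); the covariance of d follows from the delta
    method with the LD correlations; T = sum (d_i / sd_i)^2 is referred to
    a moment-matched scaled chi^2 (``satterthwaite``) or the exact
    eigenvalue mixture (``imhof``).  Returns (p_heidi, n_snps_used);
    (nan, n) when fewer than ``min_snps`` SNPs are eligible.
    """
    e = exposure.table.reset_index(drop=True)
    o = outcome.table.set_index("variant_id").loc[e["variant_id"]].reset_index()
    if top_variant is None:
        top_variant = e.loc[e["p"].idxmin(), "variant_id"]
    i_top = int(e.index[e["variant_id"] == top_variant][0])

    r_top = ld_r[i_top]
    r2 = r_top**2
    eligible = (
        (e["p"].to_numpy() < min_p_include)
        & (r2 >= r2_lo)
        & (r2 <= r2_hi)
        & (np.arange(len(e)) != i_top)
    )
    idx = np.nonzero(eligible)[0]
    if len(idx) > max_snps:
        idx = idx[np.argsort(e["p"].to_numpy()[idx])[:max_snps]]
    if len(idx) < min_snps:
        return float("nan"), int(len(idx))

    sel = np.concatenate([[i_top], idx])
    be = e["beta"].to_numpy()[sel]
    se_e = e["se"].to_numpy()[sel]
    bo = o["beta"].to_numpy()[sel]
    se_o = o["se"].to_numpy()[sel]
    R = ld_r[np.ix_(sel, sel)]
    bxy = bo / be

    m = len(sel)
    # delta-method covariance of bxy over the selected SNPs; exposure and
    # outcome samples are independent
    cov_b = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            cov_b[i, j] = (
                R[i, j] * se_o[i] * se_o[j] / (be[i] * be[j])
                + bxy[i] * bxy[j] * R[i, j] * se_e[i] * se_e[j] / (be[i] * be[j])
            )
    # d_i = bxy[i] - bxy[0] for i = 1..m-1
    k = m - 1
    cov_d = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            cov_d[i, j] = (
                cov_b[i + 1, j + 1] - cov_b[i + 1, 0] - cov_b[j + 1, 0] + cov_b[0, 0]
            )
    sd = np.sqrt(np.diag(cov_d))
    if (sd == 0).any():
        return float("nan"), k
    d = bxy[1:] - bxy[0]
    z = d / sd
    T = float(np.sum(z**2))
    corr_d = cov_d / np.outer(sd, sd)
    eig = np.linalg.eigvalsh(corr_d)
    eig = eig[eig > 1e-10]
    if method == "imhof":
        p = _imhof_p(T, eig)
    else:
        mu = eig.sum()
        var = 2 * (eig**2).sum()
        scale = var / (2 * mu)
        dof = 2 * mu**2 / var
        p = float(stats.chi2.sf(T / scale, dof))
    return p, k


def _imhof_p(t: float, eig: np.ndarray) -> float:
    """P(Q > t) for Q = sum eig_i chi^2_1 by numerical inversion (Imhof)."""
    from scipy.integrate import quad

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(eig * u)) - 0.5 * t * u
        rho = np.prod((1 + (eig * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _ = quad(integrand, 1e-8, np.inf, limit=500)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Screening with multiple-testing policy
# ---------------------------------------------------------------------------


def smr_screen(
    pairs: list[dict],
    q_threshold: float = 0.05,
    p_heidi_threshold: float = 0.01,
    instrument_p: float = 5e-8,
) -> pd.DataFrame:
    """Run SMR + HEIDI over (exposure, outcome) pairs and apply the policy.

    Each pair dict needs: exposure_id, outcome_id, celltype, assoc_type
    (herv-gene / herv-disease / gene-disease), exposure, outcome
    (SummaryStats), ld (correlation matrix, optional).  Bonferroni is
    applied within (celltype, assoc_type); significant = q < 0.05 and
    p_heidi > 0.01 (HEIDI-untestable associations are flagged, not
    significant).
    """
    rows = []
    for pair in pairs:
        exp_h, out_h = harmonize(pair["exposure"], pair["outcome"])
        res = smr_test(exp_h, out_h, instrument_p=instrument_p)
        if res is None:
            continue
        ld = pair.get("ld")
        if ld is not None:
            sub = np.isin(pair["exposure"].table["variant_id"], exp_h.table["variant_id"])
            ld_h = ld[np.ix_(np.nonzero(sub)[0], np.nonzero(sub)[0])]
            p_heidi, n_heidi = heidi_test(exp_h, out_h, ld_h, top_variant=res.top_variant)
        else:
            p_heidi, n_heidi = float("nan"), 0
        rows.append(
            {
                "exposure_id": pair["exposure_id"],
                "outcome_id": pair["outcome_id"],
                "celltype": pair["celltype"],
                "assoc_type": pair.get("assoc_type", "herv-disease"),
                "top_variant": res.top_variant,
                "b_xy": res.b_xy,
                "se_xy": res.se_xy,
                "p_smr": res.p_smr,
                "p_heidi": p_heidi,
                "n_heidi_snps": n_heidi,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["exposure_id", "outcome_id", "celltype", "assoc_type", "top_variant",
                 "b_xy", "se_xy", "p_smr", "p_heidi", "n_heidi_snps"],
    )
    if out.empty:
        out["q_smr"] = []
        out["heidi_untested"] = []
        out["significant"] = []
        return out
    out["q_smr"] = np.nan
    for _, idx in out.groupby(["celltype", "assoc_type"]).groups.items():
        n_tests = len(idx)
        out.loc[idx, "q_smr"] = np.minimum(out.loc[idx, "p_smr"] * n_tests, 1.0)
    out["heidi_untested"] = out["p_heidi"].isna()
    out["significant"] = (
        (out["q_smr"] < q_threshold)
        & out["p_heidi"].notna()
        & (out["p_heidi"] > p_heidi_threshold)
    )
    return out


# ---------------------------------------------------------------------------
# Colocalization (approximate Bayes factors)
# ---------------------------------------------------------------------------


@dataclass
class ColocResult:
    pp: dict[str, float]
    n_variants: int
    top_shared_variant: str

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]


def _wakefield_labf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    z2 = (beta / se) ** 2
    r = w**2 / (w**2 + se**2)
    return 0.5 * (np.log(1 - r) + r * z2)


def coloc_abf(
    stats1: SummaryStats,
    stats2: SummaryStats,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    min_variants: int = 10,
    sd_prior1: float = 0.15,
    sd_prior2: float = 0.15,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Per-variant Wakefield log-ABFs from (beta, se) with prior effect s.d.
    0.15 for quantitative traits (0.2 for case-control); hypothesis sums
    combined in log space with priors p1, p2, p12.  Requires at least
    ``min_variants`` shared harmonized variants.
    """
    s1, s2 = harmonize(stats1, stats2)
    m = len(s1)
    if m < min_variants:
        raise ValueError(f"only {m} shared variants; need >= {min_variants}")
    l1 = _wakefield_labf(s1.table["beta"].to_numpy(), s1.table["se"].to_numpy(), sd_prior1)
    l2 = _wakefield_labf(s2.table["beta"].to_numpy(), s2.table["se"].to_numpy(), sd_prior2)
    lsum = l1 + l2
    lH0 = 0.0
    lH1 = np.log(p1) + logsumexp(l1)
    lH2 = np.log(p2) + logsumexp(l2)
    # H3: different causal variants i != j
    both = logsumexp(l1) + logsumexp(l2)
    same = logsumexp(lsum)
    # log(sum_{i!=j} exp(l1_i + l2_j)) = log(exp(both) - exp(same))
    if both > same:
        lH3 = np.log(p1) + np.log(p2) + both + np.log1p(-np.exp(same - both))
    else:
        lH3 = -np.inf
    lH4 = np.log(p12) + same
    ls = np.array([lH0, lH1, lH2, lH3, lH4])
    pp = np.exp(ls - logsumexp(ls))
    top_idx = int(np.argmax(lsum))
    return ColocResult(
        pp={f"H{i}": float(pp[i]) for i in range(5)},
        n_variants=m,
        top_shared_variant=s1.table["variant_id"].iloc[top_idx],
    )


# ---------------------------------------------------------------------------
# Mediation triads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediationTriad:
    herv_id: str
    gene_id: str
    disease_id: str
    celltype: str


def mediation_intersect(
    herv_gene: pd.DataFrame,
    herv_disease: pd.DataFrame,
    gene_disease: pd.DataFrame,
) -> list[MediationTriad]:
    """Triads (HERV, gene, disease, cell type) whose three pairwise
    associations are all flagged significant.  Pure set intersection."""
    def sig(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["significant"]] if "significant" in df else df

    hg = sig(herv_gene)
    hd = sig(herv_disease)
    gd = sig(gene_disease)
    hg_set = set(zip(hg["exposure_id"], hg["outcome_id"], hg["celltype"]))
    hd_set = set(zip(hd["exposure_id"], hd["outcome_id"], hd["celltype"]))
    gd_set = set(zip(gd["exposure_id"], gd["outcome_id"], gd["celltype"]))
    triads = []
    for h, g, ct in sorted(hg_set):
        for (h2, d, ct2) in hd_set:
            if h2 != h or ct2 != ct:
                continue
            if (g, d, ct) in gd_set:
                triads.append(MediationTriad(h, g, d, ct))
    return triads


def plot_region(stats_list: list[tuple[str, SummaryStats]], path=None):
    """Minimal regional association scatter (-log10 p vs position)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(stats_list), 1, sharex=True,
                             figsize=(7, 2.2 * len(stats_list)), squeeze=False)
    for ax, (label, ss) in zip(axes[:, 0], stats_list):
        ax.scatter(ss.table["pos"], -np.log10(ss.table["p"]), s=8)
        ax.set_ylabel(f"{label}\n-log10 p")
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
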