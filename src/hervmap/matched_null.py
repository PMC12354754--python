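"""Matched-null functional enrichment of eSNPs.

For every eQTL variant we draw up to 100 non-eQTL variants matched on
distance to the nearest phenotype TSS (within 2.5 kb) and minor allele
frequency (within 2%), excluding any variant that is nominally associated
(p <= 0.05) with any phenotype.  Category enrichment compares the eSNP hit
rate against the pooled null with a ratio statistic and Fisher exact test,
BH-FDR corrected across categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MatchedNullDraw:
    esnp_id: str
    matched: list[str]
    shortfall: int = 0
    dropped: bool = False


def draw_matched_null(
    esnps: list[str],
    pool: pd.DataFrame,
    nominal_p: pd.Series,
    k: int = 100,
    dist_tol: float = 2500.0,
    maf_tol: float = 0.02,
    p_exclude: float = 0.05,
    min_keep: int = 20,
    seed: int = 0,
) -> list[MatchedNullDraw]:
    """Sample matched non-eQTL variants for each eSNP.

    ``pool`` indexes every candidate variant with columns ``distance_to_tss``
    (bp to the nearest phenotype TSS; compared in absolute value) and
    ``maf``.  ``nominal_p`` gives each variant's best (smallest) nominal
    eQTL p over all phenotypes; only variants with p > ``p_exclude`` (or
    absent from the scan) are eligible.  Sampling is uniform without
    replacement within an eSNP; draws shorter than ``min_keep`` drop the
    eSNP.
    """
    rng = np.random.default_rng(seed)
    dist = pool["distance_to_tss"].abs()
    maf = pool["maf"]
    best_p = nominal_p.reindex(pool.index)
    non_eqtl = best_p.isna() | (best_p > p_exclude)
    draws = []
    for esnp in esnps:
        if esnp not in pool.index:
            draws.append(MatchedNullDraw(esnp, [], shortfall=k, dropped=True))
            continue
        d0, m0 = abs(pool.at[esnp, "distance_to_tss"]), pool.at[esnp, "maf"]
        eligible = (
            ((dist - d0).abs() <= dist_tol)
            & ((maf - m0).abs() <= maf_tol)
            & non_eqtl
            & (pool.index != esnp)
        )
        ids = pool.index[eligible].to_numpy()
        take = min(k, len(ids))
        chosen = list(rng.choice(ids, size=take, replace=False)) if take else []
        shortfall = k - take
        draws.append(
            MatchedNullDraw(esnp, chosen, shortfall=shortfall,
                            dropped=(take < min_keep))
        )
    return draws


def functional_enrichment(
    esnps: list[str],
    draws: list[MatchedNullDraw],
    categories: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-category enrichment of eSNPs over their matched null.

    ratio = (share of eSNPs in C) / (share of null variants in C); Fisher
    on {eSNP, null} x {in C, not in C}; BH-FDR across categories.  eSNPs
    whose draw was dropped are excluded together with their null.
    """
    kept = [d for d in draws if not d.dropped]
    used_esnps = [d.esnp_id for d in kept if d.esnp_id in set(esnps)]
    null_ids = [v for d in kept for v in d.matched]
    n_e, n_n = len(used_esnps), len(null_ids)
    rows = []
    for cat, members in categories.items():
        a = sum(1 for v in used_esnps if v in members)
        c = sum(1 for v in null_ids if v in members)
        b, d = n_e - a, n_n - c
        if n_e == 0 or n_n == 0:
            ratio, orr, p = np.nan, np.nan, np.nan
        elif c == 0:
            ratio = np.nan
            orr, p = stats.fisher_exact([[a, b], [c, d]])
        else:
            ratio = (a / n_e) / (c / n_n)
            orr, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append(
            {"category": cat, "n_esnp_in": a, "n_esnp": n_e,
             "n_null_in": c, "n_null": n_n, "ratio": ratio,
             "odds_ratio": orr, "p": p}
        )
    result = pd.DataFrame(rows)
    ok = result["p"].notna()
    result["q"] = np.nan
    if ok.any():
        result.loc[ok, "q"] = multipletests(result.loc[ok, "p"], method="fdr_bh")[1]
    result["significant"] = result["q"] < fdr
    return result


def verify_draws(
    draws: list[MatchedNullDraw],
    pool: pd.DataFrame,
    nominal_p: pd.Series,
    dist_tol: float = 2500.0,
    maf_tol: float = 0.02,
    p_exclude: float = 0.05,
) -> bool:
    """Post-hoc check that every matched variant satisfies both tolerances
    and the non-eQTL exclusion.  Returns True when all draws are valid."""
    for d in draws:
        if d.esnp_id not in pool.index:
            continue
        d0 = abs(pool.at[d.esnp_id, "distance_to_tss"])
        m0 = pool.at[d.esnp_id, "maf"]
        for v in d.matched:
            if abs(abs(pool.at[v, "distance_to_tss"]) - d0) > dist_tol:
                return False
            if abs(pool.at[v, "maf"] - m0) > maf_tol:
                return False
            pv = nominal_p.get(v, np.nan)
            if not (np.isnan(pv) or pv > p_exclude):
                return False
            if v == d.esnp_id:
                return False
    return True
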