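"""End-to-end orchestration of the synthetic demo and staged runs.

``run(config)`` executes the stages in dependency order — annotation,
read quantification, QC, normalization, pseudobulk, marker calling,
chromatin enrichment, eQTL mapping, matched-null enrichment, and
summary-level SMR/colocalization — and writes a manifest recording the
config hash, per-stage child seeds and record counts.  With
``simulate=True`` every input is generated with planted ground truth and
the manifest reports planted-vs-recovered eQTLs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation, eqtl, matched_null, normalize, quantify, simulate, smr, specificity
from .simulate import CausalPlan, PlantedEffect, SimConfig, child_seed


@dataclass
class PipelineConfig:
    """All stage thresholds in one place.

    The analysis defaults are the published ones: HERV expression filter at
    >20 cells, HVG (0.5, 0.1, 4), markers Bonferroni p<1e-5 & log2FC>2,
    1 Mb cis window with 10,000 permutations, >10% sample-presence filter,
    matched null k=100 within 2.5 kb and 2% MAF, SMR instrument p<5e-8 with
    q<0.05 and pHEIDI>0.01, coloc default priors with >=10 variants.  Any
    override is echoed into the run manifest.
    """

    seed: int = 0
    outdir: str = "hervmap_run"
    simulate: bool = True
    min_cells: int = 20
    hvg_min_disp: float = 0.5
    hvg_min_mean: float = 0.1
    hvg_max_mean: float = 4.0
    de_alpha: float = 1e-5
    de_min_log2fc: float = 2.0
    eqtl_window: int = 1_000_000
    n_perm: int = 10_000
    min_fraction: float = 0.10
    null_k: int = 100
    null_dist_tol: float = 2500.0
    null_maf_tol: float = 0.02
    instrument_p: float = 5e-8
    q_threshold: float = 0.05
    p_heidi_threshold: float = 0.01
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_min_variants: int = 10
    # QC gates (desk-scale synthetic cells are far shallower than real
    # droplets, so the demo config overrides these; overrides land in the
    # manifest)
    qc_min_genes: int = 500
    qc_max_genes: int = 6000
    qc_min_counts: int = 1000
    qc_max_counts: int = 25_000
    qc_max_mito_pct: float = 10.0
    sim: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def demo_config(seed: int = 0, outdir: str = "hervmap_demo") -> PipelineConfig:
    """Desk-scale demo: shallow synthetic cells, reduced permutations."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        simulate=True,
        n_perm=1000,
        # a 2 Mb toy genome with a few hundred variants is too sparse for
        # 2.5 kb / 2% matching; widen both tolerances at demo scale
        null_dist_tol=100_000.0,
        null_maf_tol=0.10,
        qc_min_genes=5,
        qc_max_genes=6000,
        qc_min_counts=50,
        sim={
            "n_genes": 12,
            "n_hervs": 36,
            "n_individuals": 80,
            "n_variants_per_locus": 25,
            "n_cells_per_type": {"CD4-T": 250, "CD8-T": 180, "B": 120},
            "mean_umis_per_cell": 400.0,
        },
    )


def run(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the manifest dict (also written to
    ``outdir/manifest.json`` together with the stage outputs)."""
    if not config.simulate:
        raise NotImplementedError(
            "file-driven runs go through the stage CLIs; run() orchestrates "
            "the synthetic demo"
        )
    os.makedirs(config.outdir, exist_ok=True)
    simcfg = SimConfig(seed=config.seed, **config.sim)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {name: child_seed(config.seed, name)
                  for name in ["annotation", "cells", "reads", "genotypes",
                               "expression", "chromatin"]},
        "stages": {},
    }

    # --- annotation -------------------------------------------------------
    genes, hervs_all, strata_truth = simulate.simulate_annotation(simcfg)
    annot = annotation.build_annotation(hervs_all, genes)
    annotation.write_combined_reference(genes, annot.hervs, os.path.join(config.outdir, "combined.gtf"))
    strata_truth.to_csv(os.path.join(config.outdir, "strata_truth.tsv"), sep="\t", index=False)
    manifest["stages"]["annotation"] = {
        "n_genes": len(genes),
        "n_hervs_input": len(hervs_all),
        "n_hervs_retained": len(annot.hervs),
        "n_hervs_removed": len(annot.removed),
    }

    # --- quantification ---------------------------------------------------
    cells = simulate.simulate_cells(simcfg)
    reads, counts_truth = simulate.simulate_read_table(simcfg, genes, annot.hervs, cells)
    kinds = {g.gene_id: "gene" for g in genes}
    kinds.update({h.herv_id: "herv" for h in annot.hervs})
    feature_ids = list(kinds)
    adata, discarded = quantify.assign_unique_reads(reads, feature_ids, kinds, cells)
    adata_qc, qc_report = quantify.qc_filter_cells(
        adata,
        min_genes=config.qc_min_genes,
        max_genes=config.qc_max_genes,
        min_counts=config.qc_min_counts,
        max_counts=config.qc_max_counts,
        max_mito_pct=config.qc_max_mito_pct,
    )
    retained_hervs = quantify.filter_expressed_hervs(adata_qc, min_cells=config.min_cells)
    quantify.write_mtx(adata_qc, os.path.join(config.outdir, "matrix"))
    manifest["stages"]["quantify"] = {
        "n_reads": len(reads),
        "n_discarded_multimapping": discarded,
        "n_cells_qc": qc_report.n_cells_out,
        "n_features_qc": qc_report.n_features_out,
        "n_expressed_hervs": len(retained_hervs),
    }

    # --- normalization / pseudobulk / markers -----------------------------
    norm = normalize.normalize_per_cell(adata_qc)
    pb = normalize.make_pseudobulk(adata_qc)
    hvg = normalize.select_highly_variable(
        norm, min_disp=config.hvg_min_disp, min_mean=config.hvg_min_mean,
        max_mean=config.hvg_max_mean,
    )
    markers = specificity.call_celltype_markers(
        norm, alpha=config.de_alpha, min_log2fc=config.de_min_log2fc
    )
    herv_markers = markers[markers["feature"].isin(retained_hervs)]
    specific_sets = {
        ct: list(sub.loc[sub["specific"], "feature"])
        for ct, sub in herv_markers.groupby("celltype")
    }
    manifest["stages"]["normalize"] = {
        "n_hvg": len(hvg.selected),
        "n_specific_hervs": int(sum(len(v) for v in specific_sets.values())),
    }

    # --- chromatin enrichment --------------------------------------------
    tracks = simulate.simulate_chromatin_states(simcfg, annot.hervs, specific_sets)
    herv_meta = pd.DataFrame(
        {
            "chrom": [h.chrom for h in annot.hervs],
            "start": [h.interval.start for h in annot.hervs],
            "end": [h.interval.end for h in annot.hervs],
        },
        index=[h.herv_id for h in annot.hervs],
    )
    background = herv_meta.loc[herv_meta.index.intersection(herv_markers["feature"].unique())]
    enrich = specificity.fisher_state_enrichment(specific_sets, tracks, background)
    enrich.to_csv(os.path.join(config.outdir, "state_enrichment.tsv"), sep="\t", index=False)
    manifest["stages"]["chromatin"] = {"n_enrichment_tests": int(enrich["p"].notna().sum())}

    # --- eQTL -------------------------------------------------------------
    genotypes = simulate.simulate_genotypes(simcfg, hervs=annot.hervs[:12])
    planted_hervs = [h.herv_id for h in annot.hervs[:4]]
    target_ct = simcfg.celltypes[0]
    plan = []
    for i, hid in enumerate(planted_hervs[:2]):
        h = next(x for x in annot.hervs if x.herv_id == hid)
        cis = eqtl.cis_window_variants(genotypes.variants, h.chrom, h.tss, config.eqtl_window)
        vid = cis[len(cis) // (2 + i)]
        plan.append(PlantedEffect(hid, vid, target_ct, beta_true=0.8))
    simcfg.eqtl_plan = plan
    pheno_ids = planted_hervs + [h.herv_id for h in annot.hervs[4:10]]
    phenos, covars, eqtl_truth = simulate.simulate_expression_with_eqtl(
        simcfg, genotypes, herv_ids=pheno_ids
    )
    herv_tss = {h.herv_id: (h.chrom, h.tss) for h in annot.hervs}
    pheno_meta = pd.DataFrame(
        {"chrom": [herv_tss[p][0] for p in pheno_ids],
         "tss": [herv_tss[p][1] for p in pheno_ids]},
        index=pheno_ids,
    )
    eqtl_results = {}
    nominal_all = []
    for ct, frame in phenos.items():
        # few phenotypes at demo scale: a latent expression factor would just
        # re-learn the strongest planted effect, so none is fit here
        ph, cov = eqtl.prepare_phenotypes_covariates(
            frame, genotypes, covars, min_fraction=0.0, n_pcs=3, n_factors=0
        )
        perm = eqtl.permutation_pass(
            ph, pheno_meta, genotypes, cov,
            n_perm=config.n_perm, seed=child_seed(config.seed, f"perm-{ct}"),
            window=config.eqtl_window,
        )
        perm = eqtl.phenotype_fdr(perm, alpha=config.q_threshold)
        perm["celltype"] = ct
        eqtl_results[ct] = perm
        nom = eqtl.nominal_cis_scan(ph, pheno_meta, genotypes, cov, window=config.eqtl_window)
        nom["celltype"] = ct
        nominal_all.append(nom)
    eqtl_table = pd.concat(eqtl_results.values(), ignore_index=True)
    eqtl_table.to_csv(os.path.join(config.outdir, "eqtl_phenotype_level.tsv"), sep="\t", index=False)
    planted_vs_recovered = []
    for rec in plan:
        for ct, perm in eqtl_results.items():
            row = perm[perm["phenotype_id"] == rec.herv_id]
            if row.empty:
                continue
            planted_vs_recovered.append(
                {
                    "herv_id": rec.herv_id,
                    "celltype": ct,
                    "planted_here": ct == rec.celltype,
                    "planted_variant": rec.variant_id,
                    "top_variant": row["variant_id"].iloc[0],
                    "q_value": float(row["q_value"].iloc[0]),
                    "significant": bool(row["significant"].iloc[0]),
                }
            )
    pv = pd.DataFrame(planted_vs_recovered)
    pv.to_csv(os.path.join(config.outdir, "planted_vs_recovered.tsv"), sep="\t", index=False)
    manifest["stages"]["eqtl"] = {
        "n_phenotypes": int(len(pheno_ids)),
        "n_planted": len(plan),
        "n_recovered_in_target": int(pv[pv["planted_here"]]["significant"].sum()) if len(pv) else 0,
        "n_false_celltype_hits": int(pv[~pv["planted_here"]]["significant"].sum()) if len(pv) else 0,
    }

    # --- matched-null enrichment -----------------------------------------
    nominal = pd.concat(nominal_all, ignore_index=True)
    best_p = nominal.groupby("variant_id")["p_nominal"].min()
    tss_positions = pheno_meta["tss"].to_numpy()
    vpos = genotypes.variants["pos"].to_numpy()
    d2tss = np.abs(vpos[:, None] - tss_positions[None, :]).min(axis=1)
    pool = pd.DataFrame(
        {"distance_to_tss": d2tss, "maf": genotypes.variants["maf"].to_numpy()},
        index=genotypes.variants.index,
    )
    target_perm = eqtl_results[target_ct]
    esnps = list(target_perm.loc[target_perm["significant"], "variant_id"].unique())
    draws = matched_null.draw_matched_null(
        esnps, pool, best_p, k=config.null_k, dist_tol=config.null_dist_tol,
        maf_tol=config.null_maf_tol, seed=child_seed(config.seed, "matched-null"),
    )
    enh_variants = set()
    enh, _pro = specificity.extract_enhancer_promoter_sets(tracks[target_ct])
    for row in enh.itertuples(index=False):
        hit = (genotypes.variants["chrom"] == row.chrom) & \
              (genotypes.variants["pos"] >= row.start) & (genotypes.variants["pos"] < row.end)
        enh_variants |= set(genotypes.variants.index[hit])
    null_enrich = matched_null.functional_enrichment(esnps, draws, {"enhancer": enh_variants})
    null_enrich.to_csv(os.path.join(config.outdir, "esnp_enrichment.tsv"), sep="\t", index=False)
    manifest["stages"]["matched_null"] = {
        "n_esnps": len(esnps),
        "n_draws_kept": int(sum(not d.dropped for d in draws)),
    }

    # --- SMR / coloc ------------------------------------------------------
    m = 40
    ld = simulate_block_ld(m, rho=0.6, block=10)
    exp_ss, out_ss = simulate.simulate_summary_stats(
        simcfg, ld, CausalPlan(mode="shared", index_exposure=12, lam_exposure=9, lam_outcome=7)
    )
    smr_res = smr.smr_test(exp_ss, out_ss, instrument_p=config.instrument_p)
    coloc_res = smr.coloc_abf(
        exp_ss, out_ss, p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12,
        min_variants=config.coloc_min_variants,
    )
    manifest["stages"]["smr_coloc"] = {
        "smr_ran": smr_res is not None,
        "p_smr": None if smr_res is None else smr_res.p_smr,
        "pp_h4": coloc_res.pp_h4,
    }

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def simulate_block_ld(m: int, rho: float = 0.6, block: int = 10) -> np.ndarray:
    """Block-equicorrelated LD correlation matrix (PSD by construction)."""
    R = np.eye(m)
    for b0 in range(0, m, block):
        b1 = min(b0 + block, m)
        R[b0:b1, b0:b1] = rho
    np.fill_diagonal(R, 1.0)
    return R


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
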