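"""Synthetic data with planted ground truth.

Every generator is a pure function of its config and derives its own child
seed from the global seed, so a fixed config reproduces byte-identical
outputs.  The generators emulate, at desk scale, the inputs of a
population-scale single-cell HERV study: an annotation with known genomic
strata, UMI read tables with a controllable multi-mapping fraction,
Hardy-Weinberg genotypes over block LD, pseudobulk phenotypes with additive
cis effects planted in chosen cell types, chromatin-state tracks correlated
with planted cell-type-specific loci, and GWAS/eQTL summary statistics drawn
at the z-score level under shared or distinct causal variants.

Machine-readable truth tables accompany every planted object.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, GeneModel, HervLocus
from .genotypes import GenotypeSet
from .sumstats import SummaryStats

CELLTYPES_DEFAULT = {"CD4-T": 400, "CD8-T": 250, "NK": 150, "B": 120, "Myeloid": 80}

REP_NAMES = ["LTR2B", "LTR7", "MER21B", "THE1C", "MLT1H2", "LTR9", "THE1D", "MLT1D"]
FAMILIES = ["ERV1", "ERVK", "ERVL", "ERVL-MaLR"]

CHROMATIN_STATES = [
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
]


def child_seed(seed: int, name: str) -> int:
    """Stable per-operation child seed, below 2**31."""
    return zlib.crc32(f"{seed}:{name}".encode()) & 0x7FFFFFFF


@dataclass
class PlantedEffect:
    """An additive cis-eQTL effect planted in one cell type."""

    herv_id: str
    variant_id: str
    celltype: str
    beta_true: float
    noise_sd: float = 1.0


@dataclass
class SimConfig:
    """Study-condition knobs for the whole synthetic cohort.

    Defaults describe a desk-scale PBMC-like cohort: five immune cell types
    at roughly PBMC proportions, 100 genotyped donors, common variants
    (MAF 0.05-0.5) in 10-variant LD blocks.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 20
    n_hervs: int = 60
    exon_overlap_fraction: float = 0.25
    n_cells_per_type: dict = field(default_factory=lambda: dict(CELLTYPES_DEFAULT))
    n_individuals: int = 100
    multimap_fraction: float = 0.10
    mean_umis_per_cell: float = 500.0
    n_variants_per_locus: int = 50
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    eqtl_plan: list = field(default_factory=list)
    gwas_plan: str = "shared"
    n_gwas: int = 50_000
    n_eqtl_sample: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.multimap_fraction < 1):
            raise ValueError("multimap_fraction must be in [0, 1)")
        if self.n_genes < 1 or self.n_hervs < 1:
            raise ValueError("need at least one gene and one HERV")

    @property
    def celltypes(self) -> list[str]:
        return list(self.n_cells_per_type)


class PlacementError(ValueError):
    """Requested feature density does not fit on the simulated genome."""


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

_GENE_LEN = 20_000
_EXON_OFFSETS = [(0, 1_000), (8_000, 9_000), (16_000, 17_000)]
_HERV_LEN = 400


def simulate_annotation(
    config: SimConfig,
) -> tuple[list[GeneModel], list[HervLocus], pd.DataFrame]:
    """Place genes and HERV loci in four known strata.

    ``round(n_hervs * exon_overlap_fraction)`` loci overlap an exon by >=1 bp;
    the rest are split as evenly as possible between intronic-sense,
    intronic-antisense and intergenic placements.  Returns (genes, hervs,
    truth) where truth maps herv_id -> planted stratum.
    """
    rng = np.random.default_rng(child_seed(config.seed, "annotation"))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    slots_per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    slot_w = config.chrom_length // slots_per_chrom
    if slot_w < _GENE_LEN + 10_000:
        raise PlacementError(
            f"chrom_length {config.chrom_length} too short for "
            f"{slots_per_chrom} genes per chromosome"
        )

    genes: list[GeneModel] = []
    for gi in range(config.n_genes):
        chrom = chroms[gi % config.n_chromosomes]
        slot = gi // config.n_chromosomes
        gstart = slot * slot_w + 2_000
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, gstart, gstart + _GENE_LEN, strand)
        exons = [
            GenomicInterval(chrom, gstart + a, gstart + b, strand)
            for a, b in _EXON_OFFSETS
        ]
        genes.append(GeneModel(f"GENE{gi:04d}", iv, exons))

    n_exonic = int(round(config.n_hervs * config.exon_overlap_fraction))
    n_rest = config.n_hervs - n_exonic
    n_sense = n_rest // 3
    n_anti = n_rest // 3
    n_inter = n_rest - n_sense - n_anti
    plan = (
        ["exonic_removed"] * n_exonic
        + ["intron_sense"] * n_sense
        + ["intron_antisense"] * n_anti
        + ["intergenic"] * n_inter
    )

    # sub-slot bookkeeping so loci never overlap each other
    intron1 = (_EXON_OFFSETS[0][1], _EXON_OFFSETS[1][0])  # [1000, 8000)
    intron2 = (_EXON_OFFSETS[1][1], _EXON_OFFSETS[2][0])  # [9000, 16000)
    intron_slots = []
    for lo, hi in (intron1, intron2):
        step = _HERV_LEN + 300
        intron_slots += list(range(lo + 100, hi - _HERV_LEN - 100, step))
    per_gene_capacity = len(intron_slots)

    usage: dict[tuple[str, int], int] = {}  # (kind, gene index or slot) -> next sub-slot
    hervs: list[HervLocus] = []
    truth_rows = []
    counters: dict[tuple[str, str], int] = {}

    def make_id(chrom: str) -> str:
        rep = REP_NAMES[rng.integers(len(REP_NAMES))]
        n = counters.get((rep, chrom), 0)
        counters[(rep, chrom)] = n + 1
        suffix = f"_dup{n}" if n else ""
        return f"{rep}{suffix}-{chrom}"

    gene_cycle = 0
    inter_cycle = 0
    n_slots_total = config.n_chromosomes * slots_per_chrom
    for stratum in plan:
        if stratum == "exonic_removed":
            gene = genes[gene_cycle % len(genes)]
            k = usage.get(("ex", gene_cycle % len(genes)), 0)
            usage[("ex", gene_cycle % len(genes))] = k + 1
            if k >= 2:
                raise PlacementError("too many exon-overlapping loci requested")
            exon = gene.exons[1 + k % 2]
            # straddle the exon boundary: guaranteed >=1 bp overlap
            start = exon.start - _HERV_LEN // 2
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(gene.chrom, start, start + _HERV_LEN, strand)
            gene_cycle += 1
        elif stratum in ("intron_sense", "intron_antisense"):
            gene = genes[gene_cycle % len(genes)]
            k = usage.get(("in", gene_cycle % len(genes)), 0)
            usage[("in", gene_cycle % len(genes))] = k + 1
            if k >= per_gene_capacity:
                raise PlacementError("too many intronic loci requested per gene")
            rel = intron_slots[k] + int(rng.integers(0, 100))
            start = gene.interval.start + rel
            strand = gene.strand if stratum == "intron_sense" else (
                "-" if gene.strand == "+" else "+"
            )
            iv = GenomicInterval(gene.chrom, start, start + _HERV_LEN, strand)
            gene_cycle += 1
        else:  # intergenic: tail of a gene slot, outside every gene body
            slot = inter_cycle % n_slots_total
            chrom = chroms[slot % config.n_chromosomes]
            slot_idx = slot // config.n_chromosomes
            k = usage.get(("ig", slot), 0)
            usage[("ig", slot)] = k + 1
            base = slot_idx * slot_w + 2_000 + _GENE_LEN + 2_000
            start = base + k * (_HERV_LEN + 300) + int(rng.integers(0, 100))
            if start + _HERV_LEN > (slot_idx + 1) * slot_w - 500:
                raise PlacementError("too many intergenic loci requested per slot")
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, start + _HERV_LEN, strand)
            inter_cycle += 1
        herv = HervLocus(make_id(iv.chrom), iv, family=FAMILIES[rng.integers(len(FAMILIES))])
        hervs.append(herv)
        truth_rows.append({"herv_id": herv.herv_id, "stratum": stratum})

    truth = pd.DataFrame(truth_rows)
    return genes, hervs, truth


# ---------------------------------------------------------------------------
# Reads / counts
# ---------------------------------------------------------------------------


def simulate_cells(config: SimConfig) -> pd.DataFrame:
    """Cell metadata: barcode, individual, celltype (individuals cycled)."""
    rng = np.random.default_rng(child_seed(config.seed, "cells"))
    rows = []
    for ct, n in config.n_cells_per_type.items():
        indivs = rng.integers(0, config.n_individuals, size=n)
        for i in range(n):
            rows.append(
                {
                    "barcode": f"{ct.replace('-', '')}_{i:05d}",
                    "individual": f"IND{indivs[i]:04d}",
                    "celltype": ct,
                }
            )
    return pd.DataFrame(rows)


def simulate_read_table(
    config: SimConfig,
    genes: list[GeneModel],
    hervs: list[HervLocus],
    cells: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """UMI-level read table over genes + HERVs with planted ambiguity.

    Per-(cell, feature) molecule counts are Poisson around cell-type-specific
    rates; each molecule yields one read row; a ``multimap_fraction`` of
    reads acquires a second candidate feature.  Returns (reads, truth_counts)
    where truth_counts holds the planted molecule count per (barcode,
    feature).  Reads carry no sequence, only feature candidacy.
    """
    rng = np.random.default_rng(child_seed(config.seed, "reads"))
    if cells is None:
        cells = simulate_cells(config)
    feat_ids = [g.gene_id for g in genes] + [h.herv_id for h in hervs]
    n_feat = len(feat_ids)
    celltypes = config.celltypes

    # cell-type-structured rates: lognormal baseline x per-celltype multiplier
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_feat)
    mult = np.ones((len(celltypes), n_feat))
    specific = rng.random((len(celltypes), n_feat)) < 0.10
    mult[specific] = rng.lognormal(1.0, 0.5, size=int(specific.sum()))
    rates = base[None, :] * mult
    rates = rates / rates.sum(axis=1, keepdims=True) * config.mean_umis_per_cell

    ct_index = {ct: i for i, ct in enumerate(celltypes)}
    read_rows = []
    truth_rows = []
    for bc, ct in zip(cells["barcode"], cells["celltype"]):
        lam = rates[ct_index[ct]]
        counts = rng.poisson(lam)
        nz = np.nonzero(counts)[0]
        for fi in nz:
            truth_rows.append({"barcode": bc, "feature": feat_ids[fi], "count": int(counts[fi])})
        total = int(counts.sum())
        feats = np.repeat(nz, counts[nz])
        ambig = rng.random(total) < config.multimap_fraction
        partners = rng.integers(0, n_feat, size=total)
        for j in range(total):
            fid = feat_ids[feats[j]]
            if ambig[j]:
                partner = feat_ids[partners[j]]
                if partner == fid:
                    partner = feat_ids[(partners[j] + 1) % n_feat]
                cand = (fid, partner)
            else:
                cand = (fid,)
            read_rows.append(
                {
                    "read_id": f"r{len(read_rows):08d}",
                    "cell_barcode": bc,
                    "umi": f"u{j:06d}",
                    "feature_ids": cand,
                }
            )
    reads = pd.DataFrame(read_rows, columns=["read_id", "cell_barcode", "umi", "feature_ids"])
    truth = pd.DataFrame(truth_rows, columns=["barcode", "feature", "count"])
    return reads, truth


def harlequin_example_reads() -> pd.DataFrame:
    """The worked single-cell read-filtering example.

    Two Harlequin loci: 4 reads initially map to *Harlequin-int_dup64-chr1*,
    5 to *Harlequin-int-chr17*, and exactly one read maps to both, giving an
    8-row table (7 unique + 1 ambiguous).
    """
    a = "Harlequin-int_dup64-chr1"
    b = "Harlequin-int-chr17"
    rows = []
    for i in range(3):
        rows.append(("rA%d" % i, "CELL1", "u%02d" % i, (a,)))
    for i in range(4):
        rows.append(("rB%d" % i, "CELL1", "u%02d" % (10 + i), (b,)))
    rows.append(("rShared", "CELL1", "u99", (a, b)))
    return pd.DataFrame(rows, columns=["read_id", "cell_barcode", "umi", "feature_ids"])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _latent_to_dosage(z: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Threshold standard-normal latents into HWE genotype dosages (minor-
    allele counts).  Column j uses maf[j]."""
    u = stats.norm.cdf(z)
    p2 = maf**2
    p1 = 2 * maf * (1 - maf)
    g = np.zeros_like(z, dtype=np.int8)
    g[u < (p2 + p1)] = 1
    g[u < p2] = 2
    return g


def simulate_genotypes(
    config: SimConfig,
    hervs: list[HervLocus] | None = None,
    n_variants: int | None = None,
) -> GenotypeSet:
    """Hardy-Weinberg dosages over block-equicorrelated latent Gaussians.

    Within each block of ``ld_block_size`` consecutive variants the latent
    correlation is ``ld_rho``; across blocks it is zero.  Variants are placed
    around each HERV TSS when loci are given (``n_variants_per_locus`` each,
    within the 1 Mb cis window), else uniformly per chromosome.
    """
    if config.n_individuals < 30:
        raise ValueError("need >= 30 individuals for genotype simulation")
    lo, hi = config.maf_range
    rng = np.random.default_rng(child_seed(config.seed, "genotypes"))

    positions: list[tuple[str, int]] = []
    if hervs is not None:
        for h in hervs:
            span = min(1_000_000, config.chrom_length // 2)
            left = max(1, h.tss - span)
            right = min(config.chrom_length - 1, h.tss + span)
            pos = np.sort(rng.integers(left, right, size=config.n_variants_per_locus))
            positions += [(h.chrom, int(p)) for p in pos]
    else:
        nv = n_variants or config.n_variants_per_locus
        for c in range(config.n_chromosomes):
            pos = np.sort(rng.integers(1, config.chrom_length, size=nv))
            positions += [(f"chr{c + 1}", int(p)) for p in pos]
    # dedupe, keep sorted per chromosome
    positions = sorted(set(positions))
    m = len(positions)

    maf = rng.uniform(lo, hi, size=m)
    n = config.n_individuals
    rho = config.ld_rho
    z = np.empty((n, m))
    bs = config.ld_block_size
    block_ids = np.arange(m) // bs
    for b in np.unique(block_ids):
        idx = np.nonzero(block_ids == b)[0]
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, idx.size))
        z[:, idx] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    dos = _latent_to_dosage(z, maf[None, :])

    individuals = [f"IND{i:04d}" for i in range(n)]
    var_ids = [f"rs{i + 1:06d}" for i in range(m)]
    dosages = pd.DataFrame(dos, index=individuals, columns=var_ids)
    freq = dosages.mean(axis=0).to_numpy() / 2
    variants = pd.DataFrame(
        {
            "variant_id": var_ids,
            "chrom": [c for c, _ in positions],
            "pos": [p for _, p in positions],
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(freq, 1 - freq),
            "maf_target": maf,
            "ld_block": block_ids,
        }
    ).set_index("variant_id")
    return GenotypeSet(dosages=dosages, variants=variants)


def expected_dosage_correlation(
    rho: float, maf_i: float, maf_j: float, n: int = 200_000, seed: int = 12345
) -> float:
    """Monte-Carlo mapping from latent correlation to dosage correlation."""
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, 2))
    z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    g = _latent_to_dosage(z, np.array([maf_i, maf_j])[None, :])
    return float(np.corrcoef(g[:, 0], g[:, 1])[0, 1])


# ---------------------------------------------------------------------------
# Expression with planted eQTLs
# ---------------------------------------------------------------------------


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Per-individual sex (0/1) and age (years, 20-90)."""
    rng = np.random.default_rng(child_seed(config.seed, "covariates"))
    individuals = [f"IND{i:04d}" for i in range(config.n_individuals)]
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=config.n_individuals),
            "age": rng.uniform(20, 90, size=config.n_individuals),
        },
        index=individuals,
    )


def simulate_expression_with_eqtl(
    config: SimConfig,
    genotypes: GenotypeSet,
    herv_ids: list[str] | None = None,
    covariates: pd.DataFrame | None = None,
    sex_effect: float = 0.2,
    age_effect: float = 0.3,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Pseudobulk-style phenotypes with additive cis effects.

    For every planted effect, in its named cell type only:
    ``y = beta_true * standardized(dosage) + covariates + N(0, noise_sd)``;
    other cell types get the same covariate structure without the genetic
    term.  Returns (per-celltype phenotype frames, covariates, truth table).
    """
    rng = np.random.default_rng(child_seed(config.seed, "expression"))
    if covariates is None:
        covariates = simulate_covariates(config)
    if herv_ids is None:
        herv_ids = sorted({e.herv_id for e in config.eqtl_plan})
    plan_by_ct: dict[str, list[PlantedEffect]] = {}
    for eff in config.eqtl_plan:
        if eff.celltype not in config.n_cells_per_type:
            raise KeyError(f"unknown celltype {eff.celltype!r} in eqtl_plan")
        if eff.variant_id not in genotypes.dosages.columns:
            raise KeyError(f"unknown variant {eff.variant_id!r} in eqtl_plan")
        if eff.herv_id not in herv_ids:
            raise KeyError(f"unknown herv {eff.herv_id!r} in eqtl_plan")
        plan_by_ct.setdefault(eff.celltype, []).append(eff)

    individuals = genotypes.dosages.index
    age_std = (covariates["age"] - covariates["age"].mean()) / covariates["age"].std()
    cov_part = (
        sex_effect * covariates["sex"].to_numpy()
        + age_effect * age_std.to_numpy()
    )
    phenotypes: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for ct in config.celltypes:
        mat = rng.standard_normal((len(individuals), len(herv_ids)))
        frame = pd.DataFrame(mat, index=individuals, columns=herv_ids)
        frame = frame.add(cov_part, axis=0)
        for eff in plan_by_ct.get(ct, []):
            g = genotypes.dosages[eff.variant_id].to_numpy().astype(float)
            sd = g.std()
            if sd == 0:
                raise ValueError(f"monomorphic planted variant {eff.variant_id}")
            gz = (g - g.mean()) / sd
            frame[eff.herv_id] = (
                eff.beta_true * gz
                + cov_part
                + rng.standard_normal(len(individuals)) * eff.noise_sd
            )
            truth_rows.append(
                {
                    "herv_id": eff.herv_id,
                    "variant_id": eff.variant_id,
                    "celltype": ct,
                    "beta_true": eff.beta_true,
                    "noise_sd": eff.noise_sd,
                }
            )
        phenotypes[ct] = frame
    truth = pd.DataFrame(
        truth_rows, columns=["herv_id", "variant_id", "celltype", "beta_true", "noise_sd"]
    )
    return phenotypes, covariates, truth


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class CausalPlan:
    """Shared vs distinct causal-variant design for a summary-stat pair."""

    mode: str = "shared"  # "shared" | "distinct" | "null"
    index_exposure: int = 0
    index_outcome: int = 0
    # non-centralities on the z scale: a strong cis-eQTL instrument (z ~ 9)
    # and a genome-wide-significant GWAS locus (z ~ 8)
    lam_exposure: float = 9.0
    lam_outcome: float = 8.0


def simulate_summary_stats(
    config: SimConfig,
    ld: np.ndarray,
    plan: CausalPlan,
    maf: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    chrom: str = "chr1",
    seed_offset: int = 0,
) -> tuple[SummaryStats, SummaryStats]:
    """Draw an (exposure, outcome) z-score pair under LD.

    z ~ MVN(R @ lam, R) where lam is zero except at the causal index; betas
    recovered as z * se with se = 1/sqrt(2 maf (1-maf) n).
    """
    rng = np.random.default_rng(child_seed(config.seed, f"sumstats{seed_offset}"))
    m = ld.shape[0]
    try:
        chol = np.linalg.cholesky(ld + 1e-10 * np.eye(m))
    except np.linalg.LinAlgError as exc:
        raise ValueError("LD matrix is not positive semi-definite") from exc
    if maf is None:
        maf = np.full(m, 0.3)
    if positions is None:
        positions = np.arange(m) * 1_000 + 10_000

    def draw(index: int, lam: float, n: int) -> SummaryStats:
        mean = np.zeros(m)
        if plan.mode != "null" and lam != 0:
            lvec = np.zeros(m)
            lvec[index] = lam
            mean = ld @ lvec
        z = mean + chol @ rng.standard_normal(m)
        se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
        beta = z * se
        df = pd.DataFrame(
            {
                "variant_id": [f"rs{i + 1:06d}" for i in range(m)],
                "chrom": chrom,
                "pos": positions,
                "a1": "G",
                "a2": "A",
                "freq": maf,
                "beta": beta,
                "se": se,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "n": n,
            }
        )
        return SummaryStats(df)

    idx_out = plan.index_outcome if plan.mode == "distinct" else plan.index_exposure
    exposure = draw(plan.index_exposure, plan.lam_exposure, config.n_eqtl_sample)
    outcome = draw(idx_out, plan.lam_outcome, config.n_gwas)
    return exposure, outcome


# ---------------------------------------------------------------------------
# Chromatin states
# ---------------------------------------------------------------------------


def simulate_chromatin_states(
    config: SimConfig,
    hervs: list[HervLocus],
    specific_loci: dict[str, list[str]] | None = None,
    active_fraction: float = 0.8,
    background_active: float = 0.10,
    bin_size: int = 1_000,
):
    """Per-cell-type 15-state tracks tiling the genome without gaps.

    Background bins draw mostly quiescent/weak states with a small active
    fraction; for each cell type, ``active_fraction`` of its planted
    specific loci get their bins relabelled to an active state (Enh/TssA) in
    that cell type's track only, so enrichment is recoverable by design.
    """
    from .specificity import ChromatinStateTrack

    rng = np.random.default_rng(child_seed(config.seed, "chromatin"))
    specific_loci = specific_loci or {}
    herv_by_id = {h.herv_id: h for h in hervs}
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    n_bins = int(np.ceil(config.chrom_length / bin_size))

    background_states = ["Quies", "TxWk", "Tx", "Het", "ReprPCWk"]
    active_states = ["Enh", "EnhG", "TssA", "TssAFlnk"]
    tracks: dict[str, ChromatinStateTrack] = {}
    for ct in config.celltypes:
        rows = []
        labels = {}
        for chrom in chroms:
            lab = np.array(
                rng.choice(background_states, size=n_bins, p=[0.6, 0.15, 0.1, 0.1, 0.05])
            )
            active_mask = rng.random(n_bins) < background_active
            lab[active_mask] = rng.choice(active_states, size=int(active_mask.sum()))
            labels[chrom] = lab
        for hid in specific_loci.get(ct, []):
            h = herv_by_id[hid]
            if rng.random() < active_fraction:
                state = active_states[rng.integers(0, 2)]  # Enh or EnhG
                b0 = h.interval.start // bin_size
                b1 = (h.interval.end - 1) // bin_size
                labels[h.chrom][b0 : b1 + 1] = state
        for chrom in chroms:
            lab = labels[chrom]
            run_start = 0
            for i in range(1, n_bins + 1):
                if i == n_bins or lab[i] != lab[run_start]:
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": run_start * bin_size,
                            "end": min(i * bin_size, config.chrom_length),
                            "state": lab[run_start],
                        }
                    )
                    run_start = i
        tracks[ct] = ChromatinStateTrack(celltype=ct, intervals=pd.DataFrame(rows))
    return tracks


# ---------------------------------------------------------------------------
# Writers (plain-text interchange formats)
# ---------------------------------------------------------------------------


def write_read_table(reads: pd.DataFrame, path) -> None:
    out = reads.copy()
    out["feature_ids"] = out["feature_ids"].map(lambda c: ";".join(c))
    out.to_csv(path, sep="\t", index=False)


def read_read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["feature_ids"] = df["feature_ids"].map(lambda s: tuple(s.split(";")))
    return df


def write_dosage_tsv(genotypes: GenotypeSet, path) -> None:
    genotypes.dosages.T.rename_axis("variant_id").to_csv(path, sep="\t")


def write_vcf(genotypes: GenotypeSet, path) -> None:
    """Minimal VCF 4.2 with GT fields (dosage = count of ALT allele)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(genotypes.dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for vid, row in genotypes.variants.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in genotypes.dosages[vid])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_bed9(track, path) -> None:
    """BED9 with the state mnemonic in the name column."""
    df = track.intervals
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.state}\t0\t.\t"
                f"{row.start}\t{row.end}\t0,0,0\n"
            )


def write_summary_stats(ss: SummaryStats, path) -> None:
    ss.table.to_csv(path, sep="\t", index=False)
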