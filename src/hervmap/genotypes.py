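"""Genotype container shared by the eQTL, null-matching and SMR stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypeSet:
    """Individuals x variants dosage matrix with per-variant metadata.

    ``dosages``: DataFrame indexed by individual, columns = variant ids,
    values in {0, 1, 2} (NaN allowed for missing calls).
    ``variants``: DataFrame indexed by variant_id with at least chrom, pos
    (1-based), ref, alt, maf.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            # allow different order but identical sets
            if set(self.dosages.columns) != set(self.variants.index):
                raise ValueError("dosage columns and variant table disagree")
            self.variants = self.variants.loc[self.dosages.columns]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> pd.Series:
        freq = self.dosages.mean(axis=0, skipna=True) / 2
        return np.minimum(freq, 1 - freq)

    def ld_r(self, variant_ids: list[str]) -> np.ndarray:
        """In-sample dosage correlation matrix (missing mean-imputed)."""
        mat = self.dosages[variant_ids].to_numpy(dtype=float)
        col_mean = np.nanmean(mat, axis=0)
        nan_mask = np.isnan(mat)
        if nan_mask.any():
            mat = np.where(nan_mask, col_mean[None, :], mat)
        mat = mat - mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd[sd == 0] = np.nan
        r = (mat.T @ mat) / mat.shape[0] / np.outer(sd, sd)
        np.fill_diagonal(r, 1.0)
        return np.nan_to_num(r)

    def subset_individuals(self, individuals: list[str]) -> "GenotypeSet":
        return GenotypeSet(self.dosages.loc[individuals], self.variants.copy())


def read_dosage_tsv(path) -> GenotypeSet:
    """Read variants-as-rows dosage TSV (first column variant_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.T
    freq = dosages.mean(axis=0) / 2
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, dosages.shape[1] + 1),
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(freq, 1 - freq),
        },
        index=dosages.columns,
    )
    variants.index.name = "variant_id"
    return GenotypeSet(dosages=dosages, variants=variants)


def read_vcf(path) -> GenotypeSet:
    """Read a GT-only VCF (as written by the simulator) into dosages."""
    gt_map = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": np.nan,
              "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}
    rows, meta, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            gts = [gt_map.get(g.split(":")[0], np.nan) for g in fields[9:]]
            meta.append({"variant_id": vid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
            rows.append(gts)
    variants = pd.DataFrame(meta).set_index("variant_id")
    dosages = pd.DataFrame(np.array(rows, dtype=float).T, index=samples,
                           columns=variants.index)
    freq = dosages.mean(axis=0, skipna=True) / 2
    variants["maf"] = np.minimum(freq, 1 - freq).to_numpy()
    return GenotypeSet(dosages=dosages, variants=variants)
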