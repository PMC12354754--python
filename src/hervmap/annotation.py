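"""Combined HERV + gene feature space.

Retroviral loci that share even a single base with a protein-coding exon are
removed before quantification: in 3' single-cell RNA-seq a read falling in
such a locus cannot be attributed to autonomous retroviral transcription
rather than host-gene expression.  The surviving loci are classified by
genomic context (intronic sense/antisense, intergenic) and written together
with the genes as one combined GTF reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, GeneModel, HervLocus


class ChromosomeNamespaceError(ValueError):
    """Gene and repeat annotations use disjoint chromosome naming schemes."""


def _check_shared_namespace(hervs: list[HervLocus], genes: list[GeneModel]) -> None:
    herv_chroms = {h.chrom for h in hervs}
    gene_chroms = {g.chrom for g in genes}
    if herv_chroms and gene_chroms and not herv_chroms & gene_chroms:
        raise ChromosomeNamespaceError(
            "no shared chromosome names between HERVs and genes "
            f"(e.g. {sorted(herv_chroms)[0]!r} vs {sorted(gene_chroms)[0]!r}); "
            "check 'chr' prefix conventions"
        )


def _exon_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        for i, exon in enumerate(gene.exons):
            trees.setdefault(exon.chrom, IntervalTree()).addi(
                exon.start, exon.end, f"{gene.gene_id}:exon{i}"
            )
    return trees


def filter_exon_overlaps(
    hervs: list[HervLocus], genes: list[GeneModel]
) -> tuple[list[HervLocus], pd.DataFrame]:
    """Drop every HERV that overlaps any protein-coding exon by >= 1 bp.

    Overlap is strand-agnostic.  Returns the retained loci and a table of
    removals (herv_id, exon_id of the first offending exon).  Idempotent.
    """
    if not hervs or not genes:
        raise ValueError("both HERV and gene lists must be non-empty")
    _check_shared_namespace(hervs, genes)
    trees = _exon_trees(genes)
    retained: list[HervLocus] = []
    removed_rows = []
    for herv in hervs:
        tree = trees.get(herv.chrom)
        hits = sorted(tree.overlap(herv.interval.start, herv.interval.end)) if tree else []
        if hits:
            removed_rows.append(
                {"herv_id": herv.herv_id, "exon_id": hits[0].data}
            )
        else:
            retained.append(herv)
    removed = pd.DataFrame(removed_rows, columns=["herv_id", "exon_id"])
    return retained, removed


def _containing_gene(herv: HervLocus, genes: list[GeneModel]) -> GeneModel | None:
    """Gene whose body fully contains the locus; multi-gene hits resolved by
    nearest TSS, ties by lexicographic gene_id."""
    hits = [g for g in genes if g.interval.contains(herv.interval)]
    if not hits:
        return None
    hits.sort(key=lambda g: (abs(g.tss - herv.tss), g.gene_id))
    return hits[0]


def classify_genomic_region(herv: HervLocus, genes: list[GeneModel]) -> str:
    """Classify a (post-filter) locus as intron_sense / intron_antisense /
    intergenic relative to the gene bodies."""
    gene = _containing_gene(herv, genes)
    if gene is None:
        return "intergenic"
    return "intron_sense" if gene.strand == herv.strand else "intron_antisense"


def nearest_gene_tss(
    herv: HervLocus, genes: list[GeneModel]
) -> tuple[str | None, int | None]:
    """Nearest gene by |TSS - TSS| on the same chromosome.

    Returns (gene_id, signed distance): positive when the gene TSS lies
    downstream of the HERV TSS on the forward axis.  Ties go to the
    lexicographically smaller gene_id.  (None, None) if the chromosome holds
    no gene.
    """
    candidates = [g for g in genes if g.chrom == herv.chrom]
    if not candidates:
        return None, None
    best = min(candidates, key=lambda g: (abs(g.tss - herv.tss), g.gene_id))
    return best.gene_id, best.tss - herv.tss


# ---------------------------------------------------------------------------
# GTF / rmsk I/O (GENCODE dialect; internal 0-based half-open <-> GTF 1-based)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _gtf_line(chrom, source, feature, start0, end, strand, attrs: dict) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    return f"{chrom}\t{source}\t{feature}\t{start0 + 1}\t{end}\t.\t{strand}\t.\t{attr_str}"


def write_combined_reference(
    genes: list[GeneModel], hervs: list[HervLocus], path
) -> None:
    """Write genes and retained HERVs as one GTF.

    Each HERV becomes a single-exon gene/transcript/exon record set spanning
    the locus, so downstream quantifiers treat loci exactly like genes.
    """
    lines = []
    for gene in genes:
        iv = gene.interval
        base = {"gene_id": gene.gene_id, "gene_type": "protein_coding"}
        lines.append(_gtf_line(iv.chrom, "hervmap", "gene", iv.start, iv.end, iv.strand, base))
        tx = {**base, "transcript_id": f"{gene.gene_id}.t1"}
        lines.append(_gtf_line(iv.chrom, "hervmap", "transcript", iv.start, iv.end, iv.strand, tx))
        for exon in gene.exons:
            lines.append(_gtf_line(exon.chrom, "hervmap", "exon", exon.start, exon.end, iv.strand, tx))
    for herv in hervs:
        iv = herv.interval
        base = {"gene_id": herv.herv_id, "gene_type": "herv", "family": herv.family}
        tx = {**base, "transcript_id": f"{herv.herv_id}.t1"}
        lines.append(_gtf_line(iv.chrom, "hervmap", "gene", iv.start, iv.end, iv.strand, base))
        lines.append(_gtf_line(iv.chrom, "hervmap", "transcript", iv.start, iv.end, iv.strand, tx))
        lines.append(_gtf_line(iv.chrom, "hervmap", "exon", iv.start, iv.end, iv.strand, tx))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_combined_reference(path) -> tuple[list[GeneModel], list[HervLocus]]:
    """Read a GENCODE-dialect GTF back into gene and HERV models.

    Only gene_id / gene_type / family attributes are interpreted; features
    with gene_type "herv" become loci, everything else a gene.
    """
    genes: dict[str, GeneModel] = {}
    hervs: dict[str, HervLocus] = {}
    exon_buffer: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, _src, feature, start1, end, _score, strand, _frame, attr_str = fields
            attrs = dict(_ATTR_RE.findall(attr_str))
            iv = GenomicInterval(chrom, int(start1) - 1, int(end), strand)
            gid = attrs["gene_id"]
            kind = attrs.get("gene_type", "protein_coding")
            if feature == "gene":
                if kind == "herv":
                    hervs[gid] = HervLocus(gid, iv, family=attrs.get("family", "ERV1"))
                else:
                    genes[gid] = GeneModel(gid, iv, exons=[])
            elif feature == "exon" and kind != "herv":
                exon_buffer.setdefault(gid, []).append(iv)
    for gid, exons in exon_buffer.items():
        if gid in genes:
            genes[gid].exons = sorted(exons, key=lambda e: e.start)
    return list(genes.values()), list(hervs.values())


RMSK_COLUMNS = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"]


def read_rmsk(path) -> list[HervLocus]:
    """Read a RepeatMasker-style TSV into HERV loci.

    A ``locus_id`` column, when present, is used verbatim; otherwise ids
    follow the repName_dupN-chrom convention, numbering duplicate repeat
    names per chromosome in coordinate order.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(RMSK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rmsk table missing columns: {sorted(missing)}")
    df = df.sort_values(["genoName", "genoStart"]).reset_index(drop=True)
    has_ids = "locus_id" in df.columns
    counters: dict[tuple[str, str], int] = {}
    loci = []
    for row in df.itertuples(index=False):
        if has_ids:
            herv_id = row.locus_id
        else:
            key = (row.repName, row.genoName)
            n = counters.get(key, 0)
            counters[key] = n + 1
            suffix = f"_dup{n}" if n else ""
            herv_id = f"{row.repName}{suffix}-{row.genoName}"
        loci.append(
            HervLocus(
                herv_id,
                GenomicInterval(row.genoName, int(row.genoStart), int(row.genoEnd), row.strand),
                family=row.repFamily,
            )
        )
    return loci


def write_rmsk(hervs: list[HervLocus], path) -> None:
    rows = []
    for h in hervs:
        rep_name = h.herv_id.split("-")[0].split("_dup")[0]
        rows.append(
            {
                "genoName": h.chrom,
                "genoStart": h.interval.start,
                "genoEnd": h.interval.end,
                "strand": h.strand,
                "repName": rep_name,
                "repClass": "LTR",
                "repFamily": h.family,
                "locus_id": h.herv_id,
            }
        )
    pd.DataFrame(rows, columns=RMSK_COLUMNS + ["locus_id"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class AnnotationSet:
    """Convenience bundle of a filtered, classified annotation."""

    genes: list[GeneModel]
    hervs: list[HervLocus]
    removed: pd.DataFrame

    @property
    def herv_ids(self) -> list[str]:
        return [h.herv_id for h in self.hervs]


def build_annotation(hervs: list[HervLocus], genes: list[GeneModel]) -> AnnotationSet:
    """Filter exon overlaps then classify every surviving locus."""
    retained, removed = filter_exon_overlaps(hervs, genes)
    classified = [h.with_region_class(classify_genomic_region(h, genes)) for h in retained]
    return AnnotationSet(genes=genes, hervs=classified, removed=removed)
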