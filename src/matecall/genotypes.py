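"""Distinguishing-SNP discovery between homozygous parental lines.

A *distinguishing site* is an exonic position at which the two parental
inbred lines carry different homozygous alleles, so any read covering the
site can be attributed to one parent. Genes are *detectable* in a cross
when they carry at least ``min_snps`` such sites spanning at least
``min_span`` of the longest annotated transcript.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .transcripts import TranscriptModels, load_mask_bed, position_masked

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "load_genotypes",
    "find_distinguishing_sites",
    "score_detectability",
    "TranscriptModels",
    "load_mask_bed",
]

_GT_CODES = {"hom_ref", "hom_alt", "het", "missing"}

SITE_COLUMNS = [
    "chrom",
    "pos",
    "gene_id",
    "transcript_pos",
    "male_allele",
    "female_allele",
]


@dataclass
class Thresholds:
    """Detection and classification cutoffs.

    min_snps
        Minimum number of distinguishing SNPs per gene (sites).
    min_span
        Minimum fraction of the longest transcript spanned by the most
        proximal and distal qualifying SNPs.
    min_site_cov
        Minimum total read depth for a site to participate at all.
    min_allele_calls
        Minimum reads carrying an allele to call that allele present.
    min_sum_cov
        Minimum depth summed over a sex's informative sites.
    tpm_floor
        Expression floor (TPM) for cross-referencing reference tissues.
    span_inclusive
        If True, span = (max - min + 1)/L instead of (max - min)/L.
    sum_allele_specific
        If True, the summed-coverage rule sums only the sex's own allele
        depth rather than total site depth.
    """

    min_snps: int = 5
    min_span: float = 0.75
    min_site_cov: int = 3
    min_allele_calls: int = 3
    min_sum_cov: int = 15
    tpm_floor: float = 1.0
    span_inclusive: bool = False
    sum_allele_specific: bool = False

    def __post_init__(self) -> None:
        for name in ("min_snps", "min_site_cov", "min_allele_calls", "min_sum_cov"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_span <= 1:
            raise ValueError("min_span must be in (0, 1]")
        if self.tpm_floor <= 0:
            raise ValueError("tpm_floor must be positive")
        if self.min_sum_cov < self.min_snps * self.min_site_cov:
            warnings.warn(
                "min_sum_cov < min_snps * min_site_cov: the summed-coverage "
                "rule is weaker than the per-site rules imply",
                stacklevel=2,
            )

    def span_fraction(self, min_pos: int, max_pos: int, length: int) -> float:
        span = max_pos - min_pos + (1 if self.span_inclusive else 0)
        return span / length


def _parse_gt(value: str) -> str:
    """Map a VCF-style GT string to {hom_ref, hom_alt, het, missing}."""
    v = str(value).strip()
    if v in _GT_CODES:
        return v
    alleles = v.replace("|", "/").split("/")
    if any(a in (".", "") for a in alleles):
        return "missing"
    uniq = set(alleles)
    if uniq == {"0"}:
        return "hom_ref"
    if len(uniq) == 1:
        return "hom_alt"
    return "het"


def load_genotypes(path: str, line_ids: list[str]) -> pd.DataFrame:
    """Load per-line genotype calls at SNP sites.

    Accepts a VCF (extension .vcf/.vcf.gz/.bcf) or a TSV with columns
    chrom, pos, ref, alt plus one GT-style column per line. Returns a
    frame with chrom, pos, ref, alt and one column per requested line
    coded {hom_ref, hom_alt, het, missing}. Multi-allelic and non-SNP
    records are skipped with a logged count.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        df = _load_genotypes_vcf(path, line_ids)
    else:
        df = _load_genotypes_tsv(path, line_ids)
    if df.empty:
        logger.warning("no usable genotype records loaded from %s", path)
    return df


def _load_genotypes_vcf(path: str, line_ids: list[str]) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    missing = [s for s in line_ids if s not in vcf.samples]
    if missing:
        raise ValueError(f"line id(s) not in VCF {path}: {missing}")
    idx = [vcf.samples.index(s) for s in line_ids]
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}
    rows = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = v.gt_types
        row = dict(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0])
        for s, i in zip(line_ids, idx):
            row[s] = code[int(gt[i])]
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNP records in %s", n_skipped, path)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *line_ids])


def _load_genotypes_tsv(path: str, line_ids: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", *line_ids])
    missing = [s for s in line_ids if s not in df.columns]
    if missing:
        raise ValueError(f"line id(s) not in table {path}: {missing}")
    keep = (
        (df["ref"].str.len() == 1)
        & (df["alt"].str.len() == 1)
        & ~df["alt"].str.contains(",")
    )
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNP records in %s", n_skipped, path)
    df = df.loc[keep, ["chrom", "pos", "ref", "alt", *line_ids]].copy()
    for s in line_ids:
        df[s] = df[s].map(_parse_gt)
    return df.reset_index(drop=True)


def find_distinguishing_sites(
    genotypes: pd.DataFrame,
    male_line: str,
    female_line: str,
    transcript_models: TranscriptModels,
    mask_regions=None,
) -> pd.DataFrame:
    """Fixed homozygous differences between the two lines, restricted to
    positions exonic in exactly one gene's longest transcript.

    Sites are dropped when either line is heterozygous or missing, when the
    position falls in ``mask_regions``, overlaps exons of more than one gene
    (e.g. overlapping genes on opposite strands), is not exonic in any gene,
    or is exonic only in an isoform shorter than the longest transcript
    (counts of each are logged).
    """
    for line in (male_line, female_line):
        if line not in genotypes.columns:
            raise ValueError(f"line {line!r} absent from genotype table")

    counts = dict(not_fixed=0, masked=0, multi_gene=0, not_exonic=0, shorter_isoform=0)
    rows = []
    allele_of = {"hom_ref": "ref", "hom_alt": "alt"}
    for rec in genotypes.itertuples(index=False):
        gm = getattr(rec, male_line)
        gf = getattr(rec, female_line)
        if gm not in allele_of or gf not in allele_of or gm == gf:
            counts["not_fixed"] += 1
            continue
        if position_masked(mask_regions, rec.chrom, rec.pos):
            counts["masked"] += 1
            continue
        genes = transcript_models.genes_at(rec.chrom, rec.pos)
        if len(genes) == 0:
            counts["not_exonic"] += 1
            continue
        if len(genes) > 1:
            counts["multi_gene"] += 1
            continue
        (gene_id,) = genes
        tpos = transcript_models.transcript_position(gene_id, rec.pos)
        if tpos is None:
            counts["shorter_isoform"] += 1
            continue
        male_allele = rec.ref if gm == "hom_ref" else rec.alt
        female_allele = rec.ref if gf == "hom_ref" else rec.alt
        rows.append(
            dict(
                chrom=rec.chrom,
                pos=rec.pos,
                gene_id=gene_id,
                transcript_pos=tpos,
                male_allele=male_allele,
                female_allele=female_allele,
                strand=transcript_models.strand(gene_id),
            )
        )
    dropped = {k: v for k, v in counts.items() if v}
    if dropped:
        logger.info("excluded candidate sites: %s", dropped)
    out = pd.DataFrame(rows, columns=SITE_COLUMNS + ["strand"])
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def score_detectability(
    sites: pd.DataFrame,
    transcript_models: TranscriptModels,
    thresholds: Thresholds | None = None,
    cross_id: str = "",
) -> pd.DataFrame:
    """Per-gene SNP count, transcript-span fraction, and detectable flag.

    One row per gene with at least one distinguishing site. A gene with
    sites but no transcript model raises KeyError naming the gene.
    """
    thr = thresholds or Thresholds()
    rows = []
    for gene_id, grp in sites.groupby("gene_id", sort=True):
        if gene_id not in transcript_models:
            raise KeyError(f"gene {gene_id!r} has sites but no transcript model")
        length = transcript_models.longest_length(gene_id)
        tpos = grp["transcript_pos"]
        n = len(grp)
        span = thr.span_fraction(int(tpos.min()), int(tpos.max()), length) if n >= 2 else 0.0
        rows.append(
            dict(
                gene_id=gene_id,
                cross_id=cross_id,
                n_sites=n,
                span_fraction=span,
                detectable=(n >= thr.min_snps) and (span >= thr.min_span),
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "cross_id", "n_sites", "span_fraction", "detectable"]
    )
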