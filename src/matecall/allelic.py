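"""Per-library parent-of-origin classification from allele depths.

Each detectable gene in each library is classified as male-derived,
female-derived, both, or undetermined. The rules are threshold-based and
deterministic: a site participates only with total depth >= min_site_cov;
an allele is present at a site with >= min_allele_calls reads; a sex's
criteria hold when it has >= min_snps present sites, depth summed over
those sites >= min_sum_cov, and the sites span >= min_span of the longest
transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genotypes import Thresholds
from .transcripts import TranscriptModels

logger = logging.getLogger(__name__)

__all__ = [
    "SexCoverageCall",
    "load_allele_depths",
    "site_presence",
    "classify_gene",
    "classify_library",
    "cross_organ_update",
    "summarize_calls",
]

DEPTH_COLUMNS = [
    "library_id",
    "chrom",
    "pos",
    "depth_male_allele",
    "depth_female_allele",
    "depth_other",
]

CALL_COLUMNS = [
    "gene_id",
    "library_id",
    "cross_id",
    "organ",
    "n_sites_male",
    "n_sites_female",
    "sum_cov",
    "sum_cov_male",
    "sum_cov_female",
    "span_male",
    "span_female",
    "call",
    "evidence_source",
]

MALE_CALLS = frozenset({"male", "both"})
FEMALE_CALLS = frozenset({"female", "both"})


@dataclass
class SexCoverageCall:
    gene_id: str
    library_id: str
    cross_id: str
    organ: str
    n_sites_male: int
    n_sites_female: int
    sum_cov: int
    sum_cov_male: int
    sum_cov_female: int
    span_male: float
    span_female: float
    call: str
    evidence_source: str = "snp"


def load_allele_depths(
    path: str, sites: pd.DataFrame, library_id: str | None = None
) -> pd.DataFrame:
    """Load per-site allele depths and orient them to the parental alleles.

    Accepts a VCF with a per-sample AD field (one sample) or a TSV with
    columns library_id, chrom, pos, plus either (depth_male_allele,
    depth_female_allele[, depth_other]) — already oriented — or (ref, alt,
    ref_depth, alt_depth), which is oriented here against ``sites``.
    Records at positions absent from ``sites`` are skipped with a log;
    depth on alleles matching neither parent accumulates in depth_other.
    """
    path = str(path)
    site_idx = sites.set_index(["chrom", "pos"])
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        raw = _read_depth_vcf(path, library_id)
    else:
        raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if library_id is not None and "library_id" not in raw.columns:
            raw["library_id"] = library_id
    if raw.empty:
        return pd.DataFrame(columns=DEPTH_COLUMNS)
    if "depth_male_allele" in raw.columns:
        if "depth_other" not in raw.columns:
            raw["depth_other"] = 0
        known = raw.set_index(["chrom", "pos"]).index.isin(site_idx.index)
        if (~known).any():
            logger.info("skipped %d records at non-distinguishing positions", int((~known).sum()))
        return raw.loc[known, DEPTH_COLUMNS].reset_index(drop=True)
    return _orient_depths(raw, site_idx)


def _read_depth_vcf(path: str, library_id: str | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    if library_id is None:
        if len(vcf.samples) != 1:
            raise ValueError("library_id required for multi-sample depth VCF")
        sample, si = vcf.samples[0], 0
    else:
        sample = library_id if library_id in vcf.samples else vcf.samples[0]
        si = vcf.samples.index(sample)
    rows = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            continue
        depths = [max(int(d), 0) for d in ad[si]]
        alleles = [v.REF] + list(v.ALT)
        rows.append(
            dict(
                library_id=library_id or sample,
                chrom=v.CHROM,
                pos=v.POS,
                alleles=alleles,
                depths=depths,
            )
        )
    return pd.DataFrame(rows)


def _orient_depths(raw: pd.DataFrame, site_idx: pd.DataFrame) -> pd.DataFrame:
    """Map ref/alt (or listed-allele) depths onto male/female parental alleles."""
    rows = []
    n_skipped = 0
    for rec in raw.itertuples(index=False):
        key = (rec.chrom, rec.pos)
        if key not in site_idx.index:
            n_skipped += 1
            continue
        site = site_idx.loc[key]
        if "alleles" in raw.columns:
            alleles, depths = rec.alleles, rec.depths
        else:
            alleles = [rec.ref, rec.alt]
            depths = [int(rec.ref_depth), int(rec.alt_depth)]
        dm = df_ = other = 0
        for a, d in zip(alleles, depths):
            if a == site["male_allele"]:
                dm += d
            elif a == site["female_allele"]:
                df_ += d
            else:
                other += d
        rows.append(
            dict(
                library_id=rec.library_id,
                chrom=rec.chrom,
                pos=rec.pos,
                depth_male_allele=dm,
                depth_female_allele=df_,
                depth_other=other,
            )
        )
    if n_skipped:
        logger.info("skipped %d records at non-distinguishing positions", n_skipped)
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)


def site_presence(
    depth_male: int,
    depth_female: int,
    depth_other: int = 0,
    thresholds: Thresholds | None = None,
) -> tuple[bool, bool]:
    """(male_present, female_present) flags for one site.

    The site participates only if its total depth reaches min_site_cov;
    each allele is then present iff it has min_allele_calls reads. Both
    flags can hold at one site; a covered site where neither allele
    reaches min_allele_calls supports neither sex.
    """
    thr = thresholds or Thresholds()
    total = depth_male + depth_female + depth_other
    if total < thr.min_site_cov:
        return (False, False)
    return (depth_male >= thr.min_allele_calls, depth_female >= thr.min_allele_calls)


def _sex_evidence(
    present: pd.DataFrame, allele_col: str, length: int, thr: Thresholds
) -> tuple[int, int, float, bool]:
    """(n_sites, sum_cov, span, criteria_met) for one sex's present sites."""
    n = len(present)
    if n == 0:
        return 0, 0, 0.0, False
    if thr.sum_allele_specific:
        total = int(present[allele_col].sum())
    else:
        total = int(
            (
                present["depth_male_allele"]
                + present["depth_female_allele"]
                + present["depth_other"]
            ).sum()
        )
    span = 0.0
    if n >= 2:
        span = thr.span_fraction(
            int(present["transcript_pos"].min()),
            int(present["transcript_pos"].max()),
            length,
        )
    met = n >= thr.min_snps and total >= thr.min_sum_cov and span >= thr.min_span
    return n, total, span, met


def classify_gene(
    gene_id: str,
    records: pd.DataFrame,
    sites: pd.DataFrame,
    transcript_length: int,
    thresholds: Thresholds | None = None,
    library_id: str = "",
    cross_id: str = "",
    organ: str = "",
) -> SexCoverageCall:
    """Classify one detectable gene in one library.

    ``records`` holds the library's AlleleDepthRecords at this gene's
    sites; ``sites`` the gene's distinguishing sites (for transcript_pos).
    """
    merged = records.merge(
        sites[["chrom", "pos", "transcript_pos"]], on=["chrom", "pos"], how="inner"
    )
    thr = thresholds or Thresholds()
    if merged.empty:
        covered = merged
    else:
        # vectorized form of site_presence over the gene's sites
        total = (
            merged["depth_male_allele"]
            + merged["depth_female_allele"]
            + merged["depth_other"]
        )
        participates = total >= thr.min_site_cov
        merged["male_present"] = participates & (
            merged["depth_male_allele"] >= thr.min_allele_calls
        )
        merged["female_present"] = participates & (
            merged["depth_female_allele"] >= thr.min_allele_calls
        )
        covered = merged[participates]
    if covered.empty:
        n_m = n_f = sum_m = sum_f = 0
        span_m = span_f = 0.0
        met_m = met_f = False
        sum_total = 0
    else:
        n_m, sum_m, span_m, met_m = _sex_evidence(
            covered[covered["male_present"]], "depth_male_allele", transcript_length, thr
        )
        n_f, sum_f, span_f, met_f = _sex_evidence(
            covered[covered["female_present"]],
            "depth_female_allele",
            transcript_length,
            thr,
        )
        sum_total = int(
            (
                covered["depth_male_allele"]
                + covered["depth_female_allele"]
                + covered["depth_other"]
            ).sum()
        )
    if met_m and met_f:
        call = "both"
    elif met_m:
        call = "male"
    elif met_f:
        call = "female"
    else:
        call = "undetermined"
    return SexCoverageCall(
        gene_id=gene_id,
        library_id=library_id,
        cross_id=cross_id,
        organ=organ,
        n_sites_male=n_m,
        n_sites_female=n_f,
        sum_cov=sum_total,
        sum_cov_male=sum_m,
        sum_cov_female=sum_f,
        span_male=span_m,
        span_female=span_f,
        call=call,
    )


def classify_library(
    depths: pd.DataFrame,
    sites: pd.DataFrame,
    detectability: pd.DataFrame,
    transcript_models: TranscriptModels,
    thresholds: Thresholds | None = None,
    library_id: str = "",
    cross_id: str = "",
    organ: str = "",
) -> pd.DataFrame:
    """Classify every detectable gene for one library.

    Genes detectable in the cross but without qualifying evidence are
    emitted as undetermined (never dropped), so denominators stay
    auditable.
    """
    detectable = detectability.loc[detectability["detectable"], "gene_id"]
    lib_depths = depths
    if "library_id" in depths.columns and library_id:
        lib_depths = depths[depths["library_id"] == library_id]
    site_by_gene = dict(tuple(sites.groupby("gene_id")))
    depth_keyed = lib_depths.merge(
        sites[["chrom", "pos", "gene_id"]], on=["chrom", "pos"], how="inner"
    )
    depth_by_gene = dict(tuple(depth_keyed.groupby("gene_id")))
    empty = pd.DataFrame(columns=DEPTH_COLUMNS)
    calls = []
    for gene_id in detectable:
        call = classify_gene(
            gene_id,
            depth_by_gene.get(gene_id, empty),
            site_by_gene[gene_id],
            transcript_models.longest_length(gene_id),
            thresholds,
            library_id=library_id,
            cross_id=cross_id,
            organ=organ,
        )
        calls.append(vars(call))
    return pd.DataFrame(calls, columns=CALL_COLUMNS)


def cross_organ_update(
    calls: pd.DataFrame,
    parent_cov: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Propagate SNP-derived calls to other organs of the same cross.

    A gene called male (resp. female) from SNP evidence in any organ of a
    cross is added to the other organs of that cross whose parent-specific
    read span for that parent reaches min_span. SNP-derived calls are
    never overwritten or downgraded; propagated evidence only adds an
    origin (undetermined -> male, female -> both, ...), and the row is
    marked evidence_source=parent_specific_update.

    ``parent_cov`` needs columns gene_id, library_id, parent
    ({male, female}), covered_span_fraction.
    """
    thr = thresholds or Thresholds()
    out = calls.copy().reset_index(drop=True)
    known = set(out["library_id"])
    unknown = set(parent_cov["library_id"]) - known
    if unknown:
        raise ValueError(f"parent coverage references unknown libraries: {sorted(unknown)}")
    cov_idx = parent_cov.set_index(["gene_id", "library_id", "parent"])[
        "covered_span_fraction"
    ]
    for sex, has_sex in (("male", MALE_CALLS), ("female", FEMALE_CALLS)):
        snp_rows = out[(out["evidence_source"] == "snp") & out["call"].isin(has_sex)]
        seeded = set(zip(snp_rows["gene_id"], snp_rows["cross_id"]))
        for i in out.index:
            row = out.loc[i]
            if row["call"] in has_sex:
                continue
            if (row["gene_id"], row["cross_id"]) not in seeded:
                continue
            span = cov_idx.get((row["gene_id"], row["library_id"], sex))
            if span is None or span < thr.min_span:
                continue
            out.loc[i, "call"] = "both" if row["call"] in ("male", "female") else sex
            out.loc[i, "evidence_source"] = "parent_specific_update"
    return out


def summarize_calls(calls: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-gene call summary and the mean-libraries-per-male-gene statistic.

    Returns one row per gene: libraries with a male call, libraries with a
    female call, distinct organs and crosses with any determined call; and
    the mean number of libraries per gene with >= 1 male call (NaN when no
    gene has a male call).
    """
    if calls.empty:
        cols = ["gene_id", "libraries_male", "libraries_female", "organs", "crosses"]
        return pd.DataFrame(columns=cols), float("nan")
    rows = []
    for gene_id, grp in calls.groupby("gene_id", sort=True):
        determined = grp[grp["call"] != "undetermined"]
        rows.append(
            dict(
                gene_id=gene_id,
                libraries_male=int(grp["call"].isin(MALE_CALLS).sum()),
                libraries_female=int(grp["call"].isin(FEMALE_CALLS).sum()),
                organs=determined["organ"].nunique(),
                crosses=determined["cross_id"].nunique(),
            )
        )
    summary = pd.DataFrame(rows)
    male = summary[summary["libraries_male"] > 0]
    mean_libs = float(male["libraries_male"].mean()) if len(male) else float("nan")
    return summary, mean_libs
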