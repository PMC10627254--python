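"""Downstream statistics on the parent-of-origin call table.

Gene-list enrichment of the male-derived set uses an exact binomial
upper tail: with k list members among n male-derived genes and K list
members among N detectable background genes, p = P(X > k) for
X ~ Binomial(n, K/N), computed with the exact survival function (no
normal approximation, no multiple-testing correction across lists).
Also here: organ/cross sharing fractions, reads-per-SNP abundance
ranking, expression cross-referencing against male reference tissues,
and the Kolmogorov-Smirnov coverage QC between crosses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allelic import MALE_CALLS, site_presence
from .genotypes import Thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "SharingStats",
    "binomial_enrichment",
    "run_enrichment_suite",
    "sharing_statistics",
    "abundance_per_snp",
    "cross_reference_expression",
    "qc_coverage_comparison",
]


@dataclass
class EnrichmentResult:
    """One gene list versus the male-derived set on the detectable background."""

    list_name: str
    k: int  # male-derived genes in the list
    n: int  # total male-derived genes
    K: int  # detectable genes in the list
    N: int  # total detectable genes
    frac_male: float
    frac_background: float
    p_value: float

    def as_row(self) -> dict:
        row = vars(self).copy()
        # display convention: fractions as percentages, 2 decimals
        row["frac_male_pct"] = round(100 * self.frac_male, 2)
        row["frac_background_pct"] = round(100 * self.frac_background, 2)
        return row


def binomial_enrichment(
    k: int, n: int, K: int, N: int, list_name: str = "", method: str = "binomial"
) -> EnrichmentResult:
    """Exact upper-tail enrichment, p = P(X > k).

    The default models X ~ Binomial(n, K/N) (sampling the male-derived
    set with replacement from the background rate). ``method=
    "hypergeometric"`` uses the without-replacement tail
    X ~ Hypergeom(N, K, n) instead; it is offered for comparison and is
    not the default.
    """
    if N <= 0 or n < 0:
        raise ValueError("need N > 0 and n >= 0")
    if K > N:
        raise ValueError("K cannot exceed N")
    if K == 0 and k > 0:
        raise ValueError("k > 0 with K = 0 is impossible: the list has no detectable genes")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if method == "binomial":
        p_value = float(stats.binom.sf(k, n, K / N))
    elif method == "hypergeometric":
        p_value = float(stats.hypergeom.sf(k, N, K, n))
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(
        list_name=list_name,
        k=k,
        n=n,
        K=K,
        N=N,
        frac_male=k / n if n else 0.0,
        frac_background=K / N,
        p_value=p_value,
    )


def run_enrichment_suite(
    male_genes: set[str] | pd.Series,
    detectable_genes: set[str] | pd.Series,
    gene_lists: dict[str, set[str]],
) -> pd.DataFrame:
    """Enrichment of each gene list in the male-derived set.

    Lists are intersected with the detectable background before counting
    (K counts only detectable list members). Lists may share genes; no
    correction is applied across lists.
    """
    detectable = set(detectable_genes)
    if not detectable:
        raise ValueError("empty detectable background")
    male = set(male_genes) & detectable
    outside = set(male_genes) - detectable
    if outside:
        logger.warning(
            "%d male-called genes outside the detectable background ignored",
            len(outside),
        )
    rows = []
    for name, members in gene_lists.items():
        in_bg = set(members) & detectable
        res = binomial_enrichment(
            k=len(in_bg & male),
            n=len(male),
            K=len(in_bg),
            N=len(detectable),
            list_name=name,
        )
        rows.append(res.as_row())
    return pd.DataFrame(rows)


@dataclass
class SharingStats:
    within_cross: float | None  # fraction male in any organ also male in all organs
    across_cross: float | None  # mean fraction shared between corresponding organs
    per_cross: pd.DataFrame
    per_pair: pd.DataFrame


def _male_sets(calls: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """(cross, organ) -> set of male-called genes."""
    male = calls[calls["call"].isin(MALE_CALLS)]
    return {
        key: set(grp["gene_id"]) for key, grp in male.groupby(["cross_id", "organ"])
    }


def sharing_statistics(calls: pd.DataFrame) -> SharingStats:
    """Within-cross (across organs) and across-cross (within organ) sharing.

    Within-cross: of the genes male-called in at least one organ of a
    cross, the fraction male-called in every organ of that cross; pooled
    over crosses with >= 2 organs. Across-cross: for each ordered pair of
    crosses and each organ present in both, the fraction of genes
    male-called in the first cross's organ that are also male-called in
    the second cross's same organ, averaged over pairs and organs.
    Statistics undefined for the input design are reported as None.
    """
    by = _male_sets(calls)
    organs_of: dict[str, set[str]] = {}
    for cross, organ in calls.groupby(["cross_id", "organ"]).groups:
        organs_of.setdefault(cross, set()).add(organ)

    cross_rows = []
    for cross, organs in sorted(organs_of.items()):
        if len(organs) < 2:
            continue
        any_organ = set().union(*(by.get((cross, o), set()) for o in organs))
        all_organs = (
            set.intersection(*(by.get((cross, o), set()) for o in organs))
            if any_organ
            else set()
        )
        cross_rows.append(
            dict(
                cross_id=cross,
                n_organs=len(organs),
                male_any=len(any_organ),
                male_all=len(all_organs),
            )
        )
    per_cross = pd.DataFrame(
        cross_rows, columns=["cross_id", "n_organs", "male_any", "male_all"]
    )
    denom = int(per_cross["male_any"].sum()) if len(per_cross) else 0
    within = float(per_cross["male_all"].sum()) / denom if denom else None
    if not len(per_cross):
        within = None

    pair_rows = []
    for a, b in itertools.permutations(sorted(organs_of), 2):
        for organ in sorted(organs_of[a] & organs_of[b]):
            src = by.get((a, organ), set())
            if not src:
                continue
            shared = len(src & by.get((b, organ), set()))
            pair_rows.append(
                dict(
                    cross_from=a,
                    cross_to=b,
                    organ=organ,
                    n_male=len(src),
                    n_shared=shared,
                    fraction=shared / len(src),
                )
            )
    per_pair = pd.DataFrame(
        pair_rows,
        columns=["cross_from", "cross_to", "organ", "n_male", "n_shared", "fraction"],
    )
    across = float(per_pair["fraction"].mean()) if len(per_pair) else None
    return SharingStats(
        within_cross=within, across_cross=across, per_cross=per_cross, per_pair=per_pair
    )


def abundance_per_snp(
    calls: pd.DataFrame,
    depths: pd.DataFrame,
    sites: pd.DataFrame,
    thresholds: Thresholds | None = None,
    top_quantile: float = 0.95,
) -> pd.DataFrame:
    """Mean male-allele reads per male-informative SNP, with a top-5% flag.

    For each (gene, library) where the gene is male-called, the
    male-allele depth summed over male-present sites divided by the
    number of those sites; per gene, the mean over such libraries. Genes
    at or above the ``top_quantile`` percentile of the per-gene mean are
    flagged (ties at the boundary included).
    """
    thr = thresholds or Thresholds()
    keyed = depths.merge(
        sites[["chrom", "pos", "gene_id"]], on=["chrom", "pos"], how="inner"
    )
    male_calls = calls[calls["call"].isin(MALE_CALLS)]
    per_lib = []
    call_idx = set(zip(male_calls["gene_id"], male_calls["library_id"]))
    for (gene, lib), grp in keyed.groupby(["gene_id", "library_id"]):
        if (gene, lib) not in call_idx:
            continue
        present = grp[
            grp.apply(
                lambda r: site_presence(
                    r["depth_male_allele"],
                    r["depth_female_allele"],
                    r["depth_other"],
                    thr,
                )[0],
                axis=1,
            )
        ]
        if present.empty:
            continue
        per_lib.append(
            dict(
                gene_id=gene,
                library_id=lib,
                reads_per_snp=float(present["depth_male_allele"].sum()) / len(present),
            )
        )
    if not per_lib:
        return pd.DataFrame(columns=["gene_id", "mean_reads_per_snp", "n_libraries", "top5"])
    lib_df = pd.DataFrame(per_lib)
    gene_df = (
        lib_df.groupby("gene_id")
        .agg(mean_reads_per_snp=("reads_per_snp", "mean"), n_libraries=("reads_per_snp", "size"))
        .reset_index()
    )
    cutoff = float(np.quantile(gene_df["mean_reads_per_snp"], top_quantile))
    gene_df["top5"] = gene_df["mean_reads_per_snp"] >= cutoff
    return gene_df.sort_values("mean_reads_per_snp", ascending=False).reset_index(drop=True)


def cross_reference_expression(
    male_genes: set[str],
    expression: pd.DataFrame,
    gene_lists: dict[str, set[str]] | None = None,
    thresholds: Thresholds | None = None,
    ag_testis_cols: list[str] | None = None,
    sperm_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-reference male-derived genes against male reference tissues.

    ``expression`` is indexed by gene_id with TPM columns. Per gene:
    expressed_ag_testis (TPM >= floor in any AG/testis column),
    sperm_supported (TPM >= floor in all sperm replicate columns),
    ag_candidate (TPM < floor in all sperm replicates — the stronger
    candidates for an accessory-gland-specific origin), plus one boolean
    column per gene list. Genes missing from the table count as TPM 0.
    """
    thr = thresholds or Thresholds()
    cols = list(expression.columns)
    ag_testis_cols = ag_testis_cols or [
        c for c in cols if "sperm" not in c.lower()
    ]
    sperm_cols = sperm_cols or [c for c in cols if "sperm" in c.lower()]
    if not sperm_cols:
        raise ValueError("no sperm replicate columns identified")
    missing = [g for g in male_genes if g not in expression.index]
    if missing:
        logger.info("%d male-derived genes absent from expression table (TPM 0)", len(missing))
    rows = []
    for gene in sorted(male_genes):
        if gene in expression.index:
            tpm = expression.loc[gene]
        else:
            tpm = pd.Series(0.0, index=cols)
        row = dict(
            gene_id=gene,
            expressed_ag_testis=bool((tpm[ag_testis_cols] >= thr.tpm_floor).any()),
            sperm_supported=bool((tpm[sperm_cols] >= thr.tpm_floor).all()),
            ag_candidate=bool((tpm[sperm_cols] < thr.tpm_floor).all()),
        )
        for name, members in (gene_lists or {}).items():
            row[f"in_{name}"] = gene in members
        rows.append(row)
    return pd.DataFrame(rows)


def qc_coverage_comparison(
    depths: pd.DataFrame, group_cols: tuple[str, str] = ("cross_id", "organ")
) -> pd.DataFrame:
    """Two-sample KS comparison of per-SNP male-allele coverage between
    crosses, within each tissue.

    ``depths`` needs cross_id, organ and depth_male_allele columns.
    Returns one row per (tissue, cross pair) with the KS statistic and p;
    pairs with a group of fewer than 2 sites are reported as NaN.
    """
    cross_col, organ_col = group_cols
    rows = []
    for organ, grp in depths.groupby(organ_col):
        crosses = sorted(grp[cross_col].unique())
        for a, b in itertools.combinations(crosses, 2):
            xa = grp.loc[grp[cross_col] == a, "depth_male_allele"].to_numpy(float)
            xb = grp.loc[grp[cross_col] == b, "depth_male_allele"].to_numpy(float)
            if len(xa) < 2 or len(xb) < 2:
                stat = p = float("nan")
            else:
                res = stats.ks_2samp(xa, xb)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                dict(organ=organ, cross_a=a, cross_b=b, ks_statistic=stat, p_value=p)
            )
    return pd.DataFrame(
        rows, columns=["organ", "cross_a", "cross_b", "ks_statistic", "p_value"]
    )
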