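"""Synthetic crosses with known parent-of-origin ground truth.

The generator emulates the data the pipeline assumes: two fully
homozygous parental lines differing at exonic SNPs, per-gene relative
transcript abundance, a per-gene origin mixture (female_only /
male_only / both), Poisson per-site allele depths with an optional
3'-positional bias (transcript degradation under polyA selection), and
a small symmetric cross-allele error rate. Ground truth is recorded per
gene so downstream classification can be scored for recovery.

Positional bias uses w(pos) = (pos / L) ** degradation_bias, renormalized
to mean 1 over the transcript, so abundance_scale is always the mean
per-site depth at relative abundance 1. Each library draws from its own
RNG stream keyed on (seed, library_id), so libraries are independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transcripts import TranscriptModels

__all__ = [
    "SimConfig",
    "SyntheticGenomes",
    "ORIGINS",
    "ORGANS",
    "simulate_genomes",
    "simulate_library",
    "simulate_reads",
    "confusion_matrix",
    "recovery_metrics",
    "run_recovery",
    "write_genotypes_vcf",
    "write_depths_tsv",
    "write_truth_tsv",
    "write_reads_fastq",
    "write_reference_fasta",
]

ORIGINS = ("female_only", "male_only", "both")
ORGANS = ("parovaria", "seminal_receptacle", "spermatheca")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cross.

    n_genes
        Number of simulated genes (single-exon transcripts).
    transcript_length_range
        (min, max) transcript length in bases, inclusive.
    snp_rate
        Per-base probability of a fixed inter-line difference.
    origin_mix
        Probabilities over (female_only, male_only, both).
    abundance_scale
        Mean reads per site at relative abundance 1.
    degradation_bias
        Exponent >= 0 of the 3' positional weight; 0 gives uniform
        coverage.
    error_rate
        Probability that a read reports the other parent's allele.
    n_libraries
        Libraries to simulate (organs cycle through parovaria, seminal
        receptacle, spermatheca across crosses).
    seed
        Base seed for all RNG streams.
    """

    n_genes: int = 300
    transcript_length_range: tuple[int, int] = (500, 3000)
    snp_rate: float = 0.01
    origin_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    abundance_scale: float = 10.0
    degradation_bias: float = 0.0
    error_rate: float = 0.0
    n_libraries: int = 3
    seed: int = 0
    abundance_sigma: float = 0.5  # lognormal spread of relative abundance

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_libraries < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.transcript_length_range
        if lo < 1 or hi < lo:
            raise ValueError("transcript_length_range must satisfy 1 <= min <= max")
        # snp_rate 0 is allowed: the no-variation degenerate case is a
        # useful control (no distinguishing sites anywhere downstream)
        if not 0 <= self.snp_rate < 1:
            raise ValueError("snp_rate must be in [0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if min(self.origin_mix) < 0 or abs(sum(self.origin_mix) - 1) > 1e-9:
            raise ValueError("origin_mix must be nonnegative and sum to 1")
        if self.abundance_scale <= 0 or self.degradation_bias < 0:
            raise ValueError("abundance_scale > 0 and degradation_bias >= 0 required")


@dataclass
class SyntheticGenomes:
    """One simulated cross: genotypes, models, truth, and sequences."""

    genotypes: pd.DataFrame
    models: TranscriptModels
    truth: pd.DataFrame
    reference_seqs: dict[str, str]
    site_truth: pd.DataFrame  # chrom,pos,gene_id,transcript_pos,alleles,strand
    male_line: str = "sire"
    female_line: str = "dam"
    config: SimConfig = field(default_factory=SimConfig)


def _lib_rng(seed: int, library_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(library_id.encode()) & 0x7FFFFFFF])


def _position_weights(length: int, bias: float) -> np.ndarray:
    """3'-bias weights over transcript positions 1..L, mean-1 normalized."""
    if bias == 0:
        return np.ones(length)
    w = (np.arange(1, length + 1) / length) ** bias
    return w / w.mean()


def simulate_genomes(
    config: SimConfig, male_line: str = "sire", female_line: str = "dam"
) -> SyntheticGenomes:
    """Simulate two homozygous parental genotypes and transcript models.

    Genes are laid out on one synthetic chromosome, alternating strand,
    each as a single-exon transcript (the assignment logic operates in
    transcript coordinates either way). Every simulated SNP lies in the
    exon of exactly one gene, and truth records one row per gene.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.transcript_length_range
    chrom = "chrS"
    cursor = 1
    geno_rows, truth_rows, exon_rows, site_rows = [], [], [], []
    ref_seqs: dict[str, str] = {}
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:04d}"
        tx_id = f"{gene_id}.t1"
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        start = cursor
        end = start + length - 1
        cursor = end + 101  # intergenic gap
        tx_seq = "".join(rng.choice(_BASES, size=length))
        ref_seqs[gene_id] = tx_seq
        exon_rows.append(
            dict(
                gene_id=gene_id,
                transcript_id=tx_id,
                chrom=chrom,
                strand=strand,
                exon_start=start,
                exon_end=end,
            )
        )
        snp_tpos = np.flatnonzero(rng.random(length) < config.snp_rate) + 1
        for tp in snp_tpos:
            ref_tx = tx_seq[tp - 1]
            alt_tx = str(rng.choice([b for b in "ACGT" if b != ref_tx]))
            male_has_alt = bool(rng.integers(2))
            male_tx, female_tx = (alt_tx, ref_tx) if male_has_alt else (ref_tx, alt_tx)
            if strand == "+":
                gpos = start + int(tp) - 1
                ref_g, alt_g = ref_tx, alt_tx
                male_g, female_g = male_tx, female_tx
            else:
                gpos = end - int(tp) + 1
                ref_g = ref_tx.translate(_COMPLEMENT)
                alt_g = alt_tx.translate(_COMPLEMENT)
                male_g = male_tx.translate(_COMPLEMENT)
                female_g = female_tx.translate(_COMPLEMENT)
            geno_rows.append(
                {
                    "chrom": chrom,
                    "pos": gpos,
                    "ref": ref_g,
                    "alt": alt_g,
                    male_line: "hom_alt" if male_has_alt else "hom_ref",
                    female_line: "hom_ref" if male_has_alt else "hom_alt",
                }
            )
            site_rows.append(
                dict(
                    chrom=chrom,
                    pos=gpos,
                    gene_id=gene_id,
                    transcript_pos=int(tp),
                    male_allele=male_g,
                    female_allele=female_g,
                    strand=strand,
                    male_allele_tx=male_tx,
                    female_allele_tx=female_tx,
                )
            )
        origin = ORIGINS[int(rng.choice(3, p=config.origin_mix))]
        fa = float(rng.lognormal(0.0, config.abundance_sigma))
        ma = float(rng.lognormal(0.0, config.abundance_sigma))
        truth_rows.append(
            dict(
                gene_id=gene_id,
                origin=origin,
                female_abundance=0.0 if origin == "male_only" else fa,
                male_abundance=0.0 if origin == "female_only" else ma,
                transcript_length=length,
                snp_transcript_positions=[int(t) for t in snp_tpos],
            )
        )
    genotypes = pd.DataFrame(
        geno_rows, columns=["chrom", "pos", "ref", "alt", male_line, female_line]
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    site_truth = pd.DataFrame(
        site_rows,
        columns=[
            "chrom",
            "pos",
            "gene_id",
            "transcript_pos",
            "male_allele",
            "female_allele",
            "strand",
            "male_allele_tx",
            "female_allele_tx",
        ],
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return SyntheticGenomes(
        genotypes=genotypes,
        models=TranscriptModels.from_tables(pd.DataFrame(exon_rows)),
        truth=pd.DataFrame(truth_rows),
        reference_seqs=ref_seqs,
        site_truth=site_truth,
        male_line=male_line,
        female_line=female_line,
        config=config,
    )


def simulate_library(
    genomes: SyntheticGenomes,
    config: SimConfig,
    library_id: str,
    abundance_scale: float | None = None,
) -> pd.DataFrame:
    """Simulate one library's allele depths at every distinguishing site.

    Each parental allele's depth at a site is Poisson with mean
    (parent abundance) x abundance_scale x w(pos); a fraction error_rate
    of each allele's reads is then reassigned to the other allele
    (binomial thinning). Returns an oriented allele-depth table.
    """
    scale = config.abundance_scale if abundance_scale is None else abundance_scale
    rng = _lib_rng(config.seed, library_id)
    truth = genomes.truth.set_index("gene_id")
    rows = []
    for gene_id, sites in genomes.site_truth.groupby("gene_id", sort=True):
        if gene_id not in truth.index:
            raise KeyError(f"unknown gene {gene_id!r} in site table")
        t = truth.loc[gene_id]
        length = int(t["transcript_length"])
        w = _position_weights(length, config.degradation_bias)
        wp = w[sites["transcript_pos"].to_numpy() - 1]
        dm = rng.poisson(float(t["male_abundance"]) * scale * wp)
        df_ = rng.poisson(float(t["female_abundance"]) * scale * wp)
        if config.error_rate > 0:
            m2f = rng.binomial(dm, config.error_rate)
            f2m = rng.binomial(df_, config.error_rate)
            dm = dm - m2f + f2m
            df_ = df_ - f2m + m2f
        for (_, site), a, b in zip(sites.iterrows(), dm, df_):
            rows.append(
                dict(
                    library_id=library_id,
                    chrom=site["chrom"],
                    pos=int(site["pos"]),
                    depth_male_allele=int(a),
                    depth_female_allele=int(b),
                    depth_other=0,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "library_id",
            "chrom",
            "pos",
            "depth_male_allele",
            "depth_female_allele",
            "depth_other",
        ],
    )


def simulate_reads(
    genomes: SyntheticGenomes,
    config: SimConfig,
    library_id: str,
    read_length: int = 100,
) -> pd.DataFrame:
    """Optional synthetic read set: fixed-length fragments carrying the
    parental allele at covered SNP positions.

    Read counts per (gene, parent) are Poisson with mean
    abundance x abundance_scale x L / read_length; start positions follow
    the 3'-bias weight. With error_rate > 0, each covered SNP base flips
    to the other parent's allele independently with that probability.
    Returns read_id, gene_id, start, seq, true_parent.
    """
    rng = _lib_rng(config.seed, library_id + ":reads")
    truth = genomes.truth.set_index("gene_id")
    out = []
    serial = 0
    for gene_id, sites in genomes.site_truth.groupby("gene_id", sort=True):
        t = truth.loc[gene_id]
        length = int(t["transcript_length"])
        if length < read_length:
            continue
        tx_pos = sites["transcript_pos"].to_numpy()
        n_starts = length - read_length + 1
        w = _position_weights(length, config.degradation_bias)[:n_starts]
        w = w / w.sum()
        base_seq = genomes.reference_seqs[gene_id]
        for parent, abundance in (
            ("male", float(t["male_abundance"])),
            ("female", float(t["female_abundance"])),
        ):
            if abundance == 0:
                continue
            hap = list(base_seq)
            own = sites[f"{parent}_allele_tx"].to_numpy()
            other = sites[
                ("female" if parent == "male" else "male") + "_allele_tx"
            ].to_numpy()
            for p, a in zip(tx_pos, own):
                hap[p - 1] = a
            n_reads = rng.poisson(abundance * config.abundance_scale * length / read_length)
            if n_reads == 0:
                continue
            starts = rng.choice(n_starts, size=n_reads, p=w) + 1
            for s in starts:
                frag = hap[s - 1 : s - 1 + read_length]
                if config.error_rate > 0:
                    for j, (p, o) in enumerate(zip(tx_pos, other)):
                        if s <= p < s + read_length and rng.random() < config.error_rate:
                            frag[p - s] = o
                out.append(
                    dict(
                        read_id=f"{gene_id}:{int(s)}:{serial}",
                        gene_id=gene_id,
                        start=int(s),
                        seq="".join(frag),
                        true_parent=parent,
                    )
                )
                serial += 1
    return pd.DataFrame(out, columns=["read_id", "gene_id", "start", "seq", "true_parent"])


# ----------------------------------------------------------------------
# recovery scoring


def _gene_level_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-library calls to one class per gene (union of origins)."""
    rows = []
    for gene_id, grp in calls.groupby("gene_id", sort=True):
        has_m = grp["call"].isin(("male", "both")).any()
        has_f = grp["call"].isin(("female", "both")).any()
        if has_m and has_f:
            cls = "both"
        elif has_m:
            cls = "male"
        elif has_f:
            cls = "female"
        else:
            cls = "undetermined"
        rows.append(dict(gene_id=gene_id, called=cls))
    return pd.DataFrame(rows, columns=["gene_id", "called"])


def confusion_matrix(
    truth: pd.DataFrame, calls: pd.DataFrame, genes: set[str] | None = None
) -> pd.DataFrame:
    """True origin class x called class counts.

    ``genes`` is the evaluated universe (normally the detectable genes);
    it defaults to the distinct genes in ``calls``. Genes in the universe
    without any call count as undetermined, so the table always sums to
    the universe size.
    """
    unknown = set(calls["gene_id"]) - set(truth["gene_id"])
    if unknown:
        raise ValueError(f"calls reference genes absent from truth: {sorted(unknown)[:5]}")
    gene_calls = _gene_level_calls(calls)
    if genes is not None:
        unknown = set(genes) - set(truth["gene_id"])
        if unknown:
            raise ValueError(f"gene universe outside truth: {sorted(unknown)[:5]}")
        gene_calls = gene_calls[gene_calls["gene_id"].isin(genes)]
        missing = sorted(set(genes) - set(gene_calls["gene_id"]))
        if missing:
            gene_calls = pd.concat(
                [gene_calls, pd.DataFrame(dict(gene_id=missing, called="undetermined"))],
                ignore_index=True,
            )
    merged = gene_calls.merge(truth[["gene_id", "origin"]], on="gene_id")
    table = pd.crosstab(merged["origin"], merged["called"])
    return table.reindex(
        index=list(ORIGINS), columns=["female", "male", "both", "undetermined"], fill_value=0
    )


def recovery_metrics(truth: pd.DataFrame, calls: pd.DataFrame) -> dict[str, float]:
    """Sensitivity/specificity of male-origin recovery on detectable genes.

    sensitivity_male: fraction of truth male_only genes (in the call
    table) with a male call in >= 1 library. false_male_rate: fraction of
    truth female_only genes with any male call (specificity_female is its
    complement).
    """
    cm = confusion_matrix(truth, calls)
    male_true = cm.loc["male_only"].sum()
    male_hit = cm.loc["male_only", ["male", "both"]].sum()
    fem_true = cm.loc["female_only"].sum()
    fem_false = cm.loc["female_only", ["male", "both"]].sum()
    return dict(
        sensitivity_male=float(male_hit / male_true) if male_true else float("nan"),
        false_male_rate=float(fem_false / fem_true) if fem_true else float("nan"),
        specificity_female=1 - float(fem_false / fem_true) if fem_true else float("nan"),
    )


def run_recovery(
    config: SimConfig,
    thresholds=None,
    cross_id: str = "c1",
    abundance_scale: float | None = None,
):
    """Simulate a cross and run the full SNP pipeline on it.

    Returns (genomes, sites, detectability, calls): distinguishing sites
    rediscovered from the simulated genotypes, per-gene detectability,
    and per-library classification of every detectable gene.
    """
    from .allelic import classify_library
    from .genotypes import Thresholds, find_distinguishing_sites, score_detectability

    thr = thresholds or Thresholds()
    genomes = simulate_genomes(config)
    sites = find_distinguishing_sites(
        genomes.genotypes, genomes.male_line, genomes.female_line, genomes.models
    )
    det = score_detectability(sites, genomes.models, thr, cross_id=cross_id)
    calls = []
    for i in range(config.n_libraries):
        organ = ORGANS[i % len(ORGANS)]
        lib = f"{cross_id}_lib{i + 1}_{organ}"
        depths = simulate_library(genomes, config, lib, abundance_scale=abundance_scale)
        calls.append(
            classify_library(
                depths,
                sites,
                det,
                genomes.models,
                thr,
                library_id=lib,
                cross_id=cross_id,
                organ=organ,
            )
        )
    calls = pd.concat(calls, ignore_index=True) if calls else pd.DataFrame()
    return genomes, sites, det, calls


# ----------------------------------------------------------------------
# writers


def write_genotypes_vcf(genomes: SyntheticGenomes, path: str) -> None:
    """Two-sample GT-only VCF, every call homozygous."""
    gt = {"hom_ref": "0/0", "hom_alt": "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chrS>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{genomes.male_line}\t{genomes.female_line}\n"
        )
        for rec in genomes.genotypes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t"
                f"{gt[getattr(rec, genomes.male_line)]}\t"
                f"{gt[getattr(rec, genomes.female_line)]}\n"
            )


def write_depths_tsv(depths: pd.DataFrame, path: str) -> None:
    depths.to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: pd.DataFrame, path: str) -> None:
    out = truth.copy()
    out["snp_transcript_positions"] = out["snp_transcript_positions"].map(
        lambda xs: ",".join(map(str, xs))
    )
    out.to_csv(path, sep="\t", index=False)


def write_reads_fastq(reads: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for rec in reads.itertuples(index=False):
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")


def write_reference_fasta(genomes: SyntheticGenomes, path: str) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(genomes.reference_seqs):
            seq = genomes.reference_seqs[gene_id]
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
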