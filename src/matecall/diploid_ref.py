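"""Parent-specific transcript references and allele-based read assignment.

Each parent's personalized transcript set is the reference longest
transcript with that parent's alleles substituted at the distinguishing
sites. Reads placed in transcript coordinates are assigned to a parent
when they overlap at least one distinguishing site and match that
parent's alleles at every overlapped site; reads overlapping no site, or
matching both or neither parent, stay unassigned. The resulting
parent-specific read spans feed the cross-organ update of the
classification step.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "build_parent_fasta",
    "write_parent_fasta",
    "assign_reads",
    "reads_from_fastq",
    "reads_from_sam",
    "parent_spans",
]

READ_COLUMNS = ["read_id", "gene_id", "start", "seq"]
ASSIGN_COLUMNS = ["read_id", "gene_id", "start", "end", "parent"]


def _load_reference(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return {k: str(v) for k, v in reference.items()}
    return {
        rec.id.split("|")[0]: str(rec.seq)
        for rec in SeqIO.parse(str(reference), "fasta")
    }


def build_parent_fasta(
    reference, sites: pd.DataFrame, parent_id: str, parent: str = "male"
) -> dict[str, str]:
    """Substitute one parent's alleles into the reference transcripts.

    ``reference`` is a FASTA path or {gene_id: sequence} mapping of
    longest transcripts (coding strand). ``parent`` selects which allele
    column of ``sites`` to apply ({male, female}). Site alleles are on
    the genomic strand; when ``sites`` carries a strand column, alleles
    of minus-strand genes are complemented onto the coding strand before
    substitution. Genes without sites come through unchanged. A site
    whose transcript position exceeds the transcript raises; a reference
    base matching neither parental allele is warned and substituted
    anyway.
    """
    if parent not in ("male", "female"):
        raise ValueError("parent must be 'male' or 'female'")
    seqs = _load_reference(reference)
    allele_col = f"{parent}_allele"
    other_col = "female_allele" if parent == "male" else "male_allele"
    has_strand = "strand" in sites.columns
    comp = str.maketrans("ACGT", "TGCA")
    out = {g: list(s) for g, s in seqs.items()}
    n_mismatch = 0
    for rec in sites.itertuples(index=False):
        if rec.gene_id not in out:
            raise KeyError(f"transcript for gene {rec.gene_id!r} absent from reference")
        seq = out[rec.gene_id]
        tp = int(rec.transcript_pos)
        if not 1 <= tp <= len(seq):
            raise ValueError(
                f"site transcript_pos {tp} out of range for gene "
                f"{rec.gene_id!r} (length {len(seq)})"
            )
        own = getattr(rec, allele_col)
        other = getattr(rec, other_col)
        if has_strand and rec.strand == "-":
            own = own.translate(comp)
            other = other.translate(comp)
        ref_base = seq[tp - 1]
        if ref_base not in (own, other):
            n_mismatch += 1
        seq[tp - 1] = own
    if n_mismatch:
        logger.warning(
            "%d sites where the reference base matches neither parental allele",
            n_mismatch,
        )
    return {g: "".join(s) for g, s in out.items()}


def write_parent_fasta(seqs: dict[str, str], parent_id: str, path: str) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{g}|{parent_id}", description="")
        for g, s in sorted(seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def reads_from_fastq(path: str) -> pd.DataFrame:
    """Parse reads whose ids encode transcript placement as
    ``gene:start:serial`` (the simulator's convention)."""
    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        gene_id, start, _ = rec.id.rsplit(":", 2)
        rows.append(
            dict(read_id=rec.id, gene_id=gene_id, start=int(start), seq=str(rec.seq))
        )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def reads_from_sam(path: str) -> pd.DataFrame:
    """Adapter for externally aligned reads: SAM records aligned against
    transcript references named by gene id (reference name up to '|')."""
    import pysam

    rows = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name is None:
                n_unmapped += 1
                continue
            rows.append(
                dict(
                    read_id=aln.query_name,
                    gene_id=aln.reference_name.split("|")[0],
                    start=aln.reference_start + 1,
                    seq=aln.query_sequence or "",
                )
            )
    if n_unmapped:
        logger.info("%d reads mapped to no transcript", n_unmapped)
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def assign_reads(
    reads: pd.DataFrame | str | Path,
    male_seqs: dict[str, str],
    female_seqs: dict[str, str],
    sites: pd.DataFrame,
    library_id: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign transcript-placed reads to a parent by exact allele match.

    Returns (assignments, spans). A read is assigned to the parent whose
    alleles it matches at every overlapped distinguishing site, and left
    'unassigned' when it overlaps no site or matches neither parent at
    all overlapped sites (e.g. a conflicting mix of parental alleles, or
    a base that is neither allele). Spans are per (gene, parent):
    (max assigned-read end - min assigned-read start) / transcript
    length, capped at 1.
    """
    if not isinstance(reads, pd.DataFrame):
        reads = reads_from_fastq(reads)
    site_pos = {
        g: sorted(grp["transcript_pos"].astype(int))
        for g, grp in sites.groupby("gene_id")
    }
    rows = []
    for rec in reads.itertuples(index=False):
        gene = rec.gene_id
        start = int(rec.start)
        end = start + len(rec.seq) - 1
        parent = "unassigned"
        positions = [p for p in site_pos.get(gene, ()) if start <= p <= end]
        if positions and gene in male_seqs and gene in female_seqs:
            match_m = all(
                rec.seq[p - start] == male_seqs[gene][p - 1] for p in positions
            )
            match_f = all(
                rec.seq[p - start] == female_seqs[gene][p - 1] for p in positions
            )
            if match_m and not match_f:
                parent = "male"
            elif match_f and not match_m:
                parent = "female"
        rows.append(
            dict(read_id=rec.read_id, gene_id=gene, start=start, end=end, parent=parent)
        )
    assignments = pd.DataFrame(rows, columns=ASSIGN_COLUMNS)
    lengths = {g: len(s) for g, s in male_seqs.items()}
    spans = parent_spans(assignments, lengths, library_id=library_id)
    return assignments, spans


def parent_spans(
    assignments: pd.DataFrame, transcript_lengths: dict[str, int], library_id: str = ""
) -> pd.DataFrame:
    """Per (gene, parent) footprint span fraction of assigned reads."""
    rows = []
    assigned = assignments[assignments["parent"] != "unassigned"]
    for (gene, parent), grp in assigned.groupby(["gene_id", "parent"], sort=True):
        length = transcript_lengths[gene]
        frac = min((int(grp["end"].max()) - int(grp["start"].min())) / length, 1.0)
        rows.append(
            dict(
                gene_id=gene,
                library_id=library_id,
                parent=parent,
                covered_span_fraction=frac,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "library_id", "parent", "covered_span_fraction"]
    )
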