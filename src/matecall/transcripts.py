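"""Transcript models and genomic/transcript coordinate mapping.

All genomic coordinates are 1-based inclusive (VCF/GFF convention).
Transcript coordinates are 1-based positions along the spliced transcript
in its 5'->3' direction, so position 1 is the transcript's 5' end
regardless of genomic strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    # transcript_id -> list of (start, end) 1-based inclusive exons
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _tx_length(exons: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in exons)


class TranscriptModels:
    """Gene -> transcripts -> exons, with interval and coordinate lookups.

    The container answers three questions the pipeline asks repeatedly:
    which gene(s) have an exon at a genomic position, what is a gene's
    longest transcript (ties broken by lexicographically smallest
    transcript id), and where does a genomic position fall on that
    longest transcript.
    """

    def __init__(self, genes: dict[str, _Gene]):
        self._genes = genes
        self._longest: dict[str, tuple[str, int]] = {}
        for gid, g in genes.items():
            if not g.transcripts:
                continue
            best = min(
                g.transcripts, key=lambda t: (-_tx_length(g.transcripts[t]), t)
            )
            self._longest[gid] = (best, _tx_length(g.transcripts[best]))
        # exon intervals over ALL transcripts (gene-overlap tests)
        self._any_exon: dict[str, IntervalTree] = {}
        for g in genes.values():
            tree = self._any_exon.setdefault(g.chrom, IntervalTree())
            for exons in g.transcripts.values():
                for s, e in exons:
                    tree.addi(s, e + 1, g.gene_id)

    # ------------------------------------------------------------------
    # constructors

    @classmethod
    def from_tables(cls, exons: pd.DataFrame) -> "TranscriptModels":
        """Build from a table with columns gene_id, transcript_id, chrom,
        strand, exon_start, exon_end (1-based inclusive)."""
        genes: dict[str, _Gene] = {}
        for row in exons.itertuples(index=False):
            g = genes.setdefault(
                row.gene_id, _Gene(row.gene_id, row.chrom, row.strand)
            )
            g.transcripts.setdefault(row.transcript_id, []).append(
                (int(row.exon_start), int(row.exon_end))
            )
        for g in genes.values():
            for tx in g.transcripts.values():
                tx.sort()
        return cls(genes)

    @classmethod
    def from_gff3(cls, path: str) -> "TranscriptModels":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        rows = []
        for gene in db.features_of_type("gene"):
            gid = gene.id
            for tx in db.children(gene, level=1):
                if tx.featuretype not in ("mRNA", "transcript"):
                    continue
                for exon in db.children(tx, featuretype="exon"):
                    rows.append(
                        dict(
                            gene_id=gid,
                            transcript_id=tx.id,
                            chrom=gene.seqid,
                            strand=gene.strand,
                            exon_start=exon.start,
                            exon_end=exon.end,
                        )
                    )
        if not rows:
            logger.warning("no gene/mRNA/exon features found in %s", path)
            return cls({})
        return cls.from_tables(pd.DataFrame(rows))

    # ------------------------------------------------------------------
    # queries

    def gene_ids(self) -> list[str]:
        return sorted(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def chrom(self, gene_id: str) -> str:
        return self._genes[gene_id].chrom

    def strand(self, gene_id: str) -> str:
        return self._genes[gene_id].strand

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        """Gene ids with an exon (in any transcript) covering ``pos``."""
        tree = self._any_exon.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree[pos]}

    def longest_transcript(self, gene_id: str) -> tuple[str, int]:
        """(transcript_id, spliced length) of the gene's longest transcript."""
        if gene_id not in self._longest:
            raise KeyError(f"gene {gene_id!r} has no transcript model")
        return self._longest[gene_id]

    def longest_length(self, gene_id: str) -> int:
        return self.longest_transcript(gene_id)[1]

    def transcript_position(self, gene_id: str, pos: int) -> int | None:
        """1-based position of genomic ``pos`` on the gene's longest
        transcript, or None if the position is not exonic there."""
        g = self._genes[gene_id]
        tx_id, _ = self.longest_transcript(gene_id)
        exons = g.transcripts[tx_id]
        if g.strand == "-":
            offset = 0
            for s, e in sorted(exons, key=lambda x: -x[0]):
                if s <= pos <= e:
                    return offset + (e - pos + 1)
                offset += e - s + 1
        else:
            offset = 0
            for s, e in exons:
                if s <= pos <= e:
                    return offset + (pos - s + 1)
                offset += e - s + 1
        return None

    # ------------------------------------------------------------------
    # output

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid in self.gene_ids():
                g = self._genes[gid]
                for tx_id, exons in sorted(g.transcripts.items()):
                    gs = min(s for s, _ in exons)
                    ge = max(e for _, e in exons)
                    fh.write(
                        f"{g.chrom}\tmatecall\tgene\t{gs}\t{ge}\t.\t"
                        f"{g.strand}\t.\tID={gid}\n"
                    )
                    fh.write(
                        f"{g.chrom}\tmatecall\tmRNA\t{gs}\t{ge}\t.\t"
                        f"{g.strand}\t.\tID={tx_id};Parent={gid}\n"
                    )
                    for i, (s, e) in enumerate(exons, 1):
                        fh.write(
                            f"{g.chrom}\tmatecall\texon\t{s}\t{e}\t.\t"
                            f"{g.strand}\t.\tID={tx_id}.exon{i};"
                            f"Parent={tx_id}\n"
                        )


def load_mask_bed(path: str) -> dict[str, IntervalTree]:
    """Read a BED mask (half-open [start, end)) into 1-based interval trees.

    Returns chrom -> IntervalTree where a genomic position p (1-based) is
    masked iff tree[p] is nonempty.
    """
    masks: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            start, end = int(start), int(end)
            if end <= start:
                continue
            # BED [start, end) 0-based -> 1-based inclusive [start+1, end]
            masks.setdefault(chrom, IntervalTree()).addi(start + 1, end + 1)
    return masks


def position_masked(
    masks: dict[str, IntervalTree] | None, chrom: str, pos: int
) -> bool:
    if not masks:
        return False
    tree = masks.get(chrom)
    return tree is not None and bool(tree[pos])
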