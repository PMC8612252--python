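"""Contig-level taxonomy assignment by strict best-hit voting.

A contig of at least 5 kb is assigned to a phylum only when at least 60% of
its genes give best hits to that same phylum — a strict concordance rule,
not simple majority voting. Genes without any best hit stay in the
denominator by default, so they dilute support; a config switch restricts
the denominator to genes with hits.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .io_formats import BestHit, ContigRecord, PipelineConfig

UNASSIGNED = "unassigned"


@dataclass
class TaxonomyCall:
    """Voting outcome for one contig."""

    contig_id: str
    phylum: str                  # phylum name or "unassigned"
    support_frac: float
    n_genes: int
    excluded_reason: str | None = None

    report_name = "taxonomy_calls"
    report_columns = ("contig_id", "phylum", "support_frac", "n_genes", "excluded_reason")

    def to_row(self):
        return (
            self.contig_id,
            self.phylum,
            f"{self.support_frac:.4f}",
            self.n_genes,
            self.excluded_reason or "",
        )


def contig_phylum_votes(contig: ContigRecord, besthits: Iterable) -> Counter:
    """Tally best-hit phyla over the contig's genes.

    Genes without a hit contribute to no phylum (but still count toward the
    assignment denominator downstream).
    """
    by_gene = {bh.gene_id: bh.subject_phylum for bh in besthits}
    votes: Counter = Counter()
    for gene in contig.genes:
        phylum = by_gene.get(gene.gene_id)
        if phylum is not None:
            votes[phylum] += 1
    return votes


def assign_taxonomy(
    contig: ContigRecord, besthits: Iterable, config: PipelineConfig
) -> TaxonomyCall:
    """Assign a phylum to a contig under the strict concordance rule.

    Contigs shorter than ``contig_min_len`` are excluded. Otherwise the
    contig is assigned the unique phylum whose vote fraction reaches
    ``taxonomy_min_frac`` (inclusive); at most one phylum can reach 60% of
    all genes, so the assignment is unique by construction.
    """
    votes = contig_phylum_votes(contig, besthits)
    n_genes = contig.n_genes
    denom = sum(votes.values()) if config.hits_only_denominator else n_genes
    top_phylum, top_count = (None, 0)
    if votes:
        # deterministic tie-break by name; a tie can never reach >= 60% anyway
        top_phylum, top_count = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    support = top_count / denom if denom else 0.0

    if contig.length < config.contig_min_len:
        return TaxonomyCall(
            contig_id=contig.contig_id,
            phylum=UNASSIGNED,
            support_frac=support,
            n_genes=n_genes,
            excluded_reason="too_short",
        )
    phylum = top_phylum if (top_phylum is not None and support >= config.taxonomy_min_frac) else UNASSIGNED
    return TaxonomyCall(
        contig_id=contig.contig_id,
        phylum=phylum,
        support_frac=support,
        n_genes=n_genes,
    )


def drop_exact_duplicates(contigs: Iterable) -> list:
    """Drop contigs whose (length, gene layout) exactly duplicates an earlier
    one. Sequence-level dereplication (95/95 clustering) is an upstream,
    external step; this helper only removes byte-identical annotations."""
    seen: set = set()
    kept: list = []
    for contig in contigs:
        key = (
            contig.length,
            tuple((g.start, g.end, g.strand, tuple(sorted(g.domains))) for g in contig.genes),
        )
        if key in seen:
            continue
        seen.add(key)
        kept.append(contig)
    return kept
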