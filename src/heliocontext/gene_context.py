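"""Anchor-centred gene neighborhoods and operon (cotranscription) candidates.

Two neighborhood definitions are used downstream: ``by_genes`` (up to 10
genes on each side of the anchor — the unit of the enrichment test) and
``by_window`` (every gene overlapping the anchor ± 10 kb — the unit of
visual context inspection).

Cotranscription candidates follow two strict criteria: consecutive genes
must lie on the same strand and be separated by an intergenic distance of
fewer than 10 bp. Distances are computed as ``start − end − 1``, so abutting
genes score 0 and overlapping genes score negative; overlaps qualify.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import ContigRecord, GeneRecord, PipelineConfig

MODES = ("by_genes", "by_window")


@dataclass
class NeighborhoodContext:
    """Genes around an anchor, with a multiset of their domain annotations.

    ``domain_multiset`` counts each member gene once per distinct domain, so
    a count is "number of member genes carrying the domain".
    """

    anchor: GeneRecord
    members: list
    mode: str
    domain_multiset: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"bad neighborhood mode {self.mode!r}")


@dataclass
class OperonCandidate:
    """A maximal same-strand chain of closely spaced genes around an anchor."""

    genes: list                 # ordered, includes the anchor
    strand: str
    gaps: list                  # intergenic distances between consecutive genes

    report_name = "operon_candidates"
    report_columns = ("genes", "strand", "gaps", "n_genes")

    def to_row(self):
        return (
            ",".join(g.gene_id for g in self.genes),
            self.strand,
            ",".join(str(d) for d in self.gaps),
            len(self.genes),
        )


def intergenic_distance(upstream: GeneRecord, downstream: GeneRecord) -> int:
    """bp between two genes on the same contig: ``downstream.start −
    upstream.end − 1``. Negative iff the genes overlap; 0 iff abutting."""
    if upstream.contig_id != downstream.contig_id:
        raise ValueError(
            f"genes {upstream.gene_id} and {downstream.gene_id} are on different contigs"
        )
    if downstream.start < upstream.start:
        raise ValueError("downstream gene starts before upstream gene")
    return downstream.start - upstream.end - 1


def _anchor_index(contig: ContigRecord, anchor: GeneRecord | str) -> int:
    anchor_id = anchor if isinstance(anchor, str) else anchor.gene_id
    for i, g in enumerate(contig.genes):
        if g.gene_id == anchor_id:
            return i
    raise ValueError(f"anchor {anchor_id} not found on contig {contig.contig_id}")


def extract_neighborhood(
    contig: ContigRecord,
    anchor: GeneRecord | str,
    mode: str,
    config: PipelineConfig,
) -> NeighborhoodContext:
    """Collect the genes around an anchor.

    ``by_genes``: up to ``flank_min_genes`` (10) genes on each side in
    positional order. ``by_window``: every gene overlapping
    [anchor.start − 10 kb, anchor.end + 10 kb]. The anchor itself is never a
    member.
    """
    if mode not in MODES:
        raise ValueError(f"bad neighborhood mode {mode!r}")
    i = _anchor_index(contig, anchor)
    anchor_gene = contig.genes[i]
    if mode == "by_genes":
        k = config.flank_min_genes
        members = contig.genes[max(0, i - k):i] + contig.genes[i + 1:i + 1 + k]
    else:
        lo = anchor_gene.start - config.context_window
        hi = anchor_gene.end + config.context_window
        members = [
            g for j, g in enumerate(contig.genes)
            if j != i and g.end >= lo and g.start <= hi
        ]
    multiset: Counter = Counter()
    for g in members:
        for acc in g.domains:
            multiset[acc] += 1
    return NeighborhoodContext(
        anchor=anchor_gene, members=members, mode=mode, domain_multiset=multiset
    )


def _qualifies(left: GeneRecord, right: GeneRecord, config: PipelineConfig) -> bool:
    return (
        left.strand == right.strand
        and intergenic_distance(left, right) < config.operon_max_gap
    )


def find_operon_candidates(
    contig: ContigRecord,
    anchor: GeneRecord | str,
    config: PipelineConfig,
) -> list:
    """Emit the maximal cotranscription chain through the anchor, if any.

    Starting at the anchor, the chain extends transitively in both
    directions while each consecutive same-strand pair is separated by fewer
    than ``operon_max_gap`` bp (overlaps, being negative, qualify). With
    ``config.direct_neighbors_only`` the chain is limited to the anchor's
    immediate qualifying neighbors. Returns an empty list when no neighbor
    qualifies.
    """
    i = _anchor_index(contig, anchor)
    genes = contig.genes
    lo = hi = i
    while lo > 0 and _qualifies(genes[lo - 1], genes[lo], config):
        lo -= 1
        if config.direct_neighbors_only:
            break
    while hi + 1 < len(genes) and _qualifies(genes[hi], genes[hi + 1], config):
        hi += 1
        if config.direct_neighbors_only:
            break
    if lo == hi:
        return []
    chain = genes[lo:hi + 1]
    gaps = [intergenic_distance(a, b) for a, b in zip(chain, chain[1:])]
    return [OperonCandidate(genes=chain, strand=genes[i].strand, gaps=gaps)]
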