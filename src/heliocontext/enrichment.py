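"""Domain overrepresentation around heliorhodopsin loci.

For each genome with a heliorhodopsin gene flanked by at least 10 genes on
each side, every domain present in the 20-gene neighborhood is tested with
an upper-tail hypergeometric probability: drawing n = 20 genes without
replacement from the genome's N protein-coding genes, of which K carry the
domain, what is P(X >= k) for the k carriers observed among the neighbors?
P values from all tests in a run are Benjamini–Hochberg adjusted together,
and a domain is *selected* when it is significant (q < 0.05) in at least
10% of the eligible genomes. The whole procedure can be rerun within each
phylum contributing at least five eligible genomes.

The population is gene-level: K and k count genes carrying the domain, so a
gene with two copies of a domain counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .gene_context import extract_neighborhood
from .io_formats import GenomeAnnotation, PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """One hypergeometric test: a domain at a heliorhodopsin locus."""

    genome_id: str
    anchor_id: str
    accession: str
    k: int      # neighborhood genes carrying the domain (anchor excluded)
    K: int      # genes carrying the domain genome-wide
    n: int      # draw size (neighborhood genes)
    N: int      # protein-coding genes in the genome
    p: float
    q: float = float("nan")

    report_name = "enrichment_records"
    report_columns = ("genome_id", "anchor_id", "accession", "k", "K", "n", "N", "p", "q")

    def to_row(self):
        return (
            self.genome_id, self.anchor_id, self.accession,
            self.k, self.K, self.n, self.N,
            f"{self.p:.6g}", f"{self.q:.6g}",
        )


@dataclass
class DomainSummary:
    """Cross-genome selection outcome for one domain."""

    accession: str
    n_genomes_eligible: int
    n_genomes_present: int
    n_genomes_significant: int
    selected: bool

    report_name = "domain_summaries"
    report_columns = (
        "accession", "n_genomes_eligible", "n_genomes_present",
        "n_genomes_significant", "selected",
    )

    def to_row(self):
        return (
            self.accession, self.n_genomes_eligible, self.n_genomes_present,
            self.n_genomes_significant, self.selected,
        )


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exactly 1.0 at k = 0."""
    if N < 1 or K < 0 or n < 0 or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds (k={k}, K={K}, n={n}, N={N})")
    if k < 0 or k > min(n, K):
        raise ValueError(f"k out of range (k={k}, K={K}, n={n}, N={N})")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence) -> list:
    """Benjamini–Hochberg step-up adjustment, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1; every p must lie in (0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


# ---------------------------------------------------------------------------
# Locus eligibility and per-locus testing
# ---------------------------------------------------------------------------

def _auto_anchors(genome: GenomeAnnotation, config: PipelineConfig) -> list:
    return sorted(
        g.gene_id for g in genome.iter_genes() if config.her_accession in g.domains
    )


def eligible_loci(
    genomes: Iterable,
    config: PipelineConfig,
    anchors: Mapping | None = None,
) -> list:
    """(genome_id, anchor_id) pairs whose anchor has at least
    ``flank_min_genes`` genes on each side of the same contig.

    ``anchors`` maps genome_id to an iterable of anchor gene_ids; when
    omitted, anchors are genes annotated with the heliorhodopsin accession.
    """
    loci: list = []
    for genome in genomes:
        wanted = (
            sorted(anchors.get(genome.genome_id, ()))
            if anchors is not None
            else _auto_anchors(genome, config)
        )
        if not wanted:
            continue
        index = genome.gene_index()
        for anchor_id in wanted:
            if anchor_id not in index:
                raise ValueError(f"anchor {anchor_id} not found in genome {genome.genome_id}")
            contig, i = index[anchor_id]
            if i >= config.flank_min_genes and (contig.n_genes - i - 1) >= config.flank_min_genes:
                loci.append((genome.genome_id, anchor_id))
    return sorted(loci)


def test_neighborhood_domains(
    genome: GenomeAnnotation,
    anchor_id: str,
    config: PipelineConfig,
) -> list:
    """Hypergeometric tests for every domain present in the anchor's 20-gene
    neighborhood. The anchor's own domains are excluded from k; q is filled
    later by the run-level BH adjustment."""
    if not eligible_loci([genome], config, anchors={genome.genome_id: [anchor_id]}):
        raise ValueError(f"locus {genome.genome_id}/{anchor_id} is not eligible")
    contig, _ = genome.gene_index()[anchor_id]
    ctx = extract_neighborhood(contig, anchor_id, "by_genes", config)
    n = len(ctx.members)
    N = genome.n_genes

    genome_counts: dict = {}
    for gene in genome.iter_genes():
        for acc in gene.domains:
            genome_counts[acc] = genome_counts.get(acc, 0) + 1

    records = []
    for acc in sorted(ctx.domain_multiset):
        k = ctx.domain_multiset[acc]
        K = genome_counts[acc]
        records.append(
            EnrichmentRecord(
                genome_id=genome.genome_id,
                anchor_id=anchor_id,
                accession=acc,
                k=k, K=K, n=n, N=N,
                p=hypergeometric_upper_tail(k, K, n, N),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Run-level orchestration
# ---------------------------------------------------------------------------

def run_enrichment(
    genomes: Sequence,
    config: PipelineConfig,
    anchors: Mapping | None = None,
) -> list:
    """Test every eligible locus and BH-adjust all tests of the run together
    (or within each genome with ``config.per_genome_bh``)."""
    by_id = {g.genome_id: g for g in genomes}
    records: list = []
    for genome_id, anchor_id in eligible_loci(genomes, config, anchors):
        records.extend(test_neighborhood_domains(by_id[genome_id], anchor_id, config))
    if not records:
        return records
    if config.per_genome_bh:
        for gid in sorted({r.genome_id for r in records}):
            group = [r for r in records if r.genome_id == gid]
            for rec, q in zip(group, bh_adjust([r.p for r in group])):
                rec.q = q
    else:
        for rec, q in zip(records, bh_adjust([r.p for r in records])):
            rec.q = q
    return records


def summarize_selection(
    records: Iterable,
    genomes: Sequence,
    config: PipelineConfig,
    anchors: Mapping | None = None,
) -> list:
    """Cross-genome selection of domains.

    A genome is significant for a domain when any of its loci has
    q < ``fdr_alpha``. Default selection requires significance in at least
    ``prevalence_min`` of the eligible genomes; ``selection_mode =
    "present_frac"`` instead requires presence in that fraction plus
    significance in at least one genome.
    """
    eligible_genomes = sorted({gid for gid, _ in eligible_loci(genomes, config, anchors)})
    n_eligible = len(eligible_genomes)
    if n_eligible == 0:
        raise ValueError("no eligible genomes")

    present: dict = {}
    significant: dict = {}
    for rec in records:
        present.setdefault(rec.accession, set()).add(rec.genome_id)
        if rec.q < config.fdr_alpha:
            significant.setdefault(rec.accession, set()).add(rec.genome_id)

    summaries = []
    for acc in sorted(present):
        n_present = len(present[acc])
        n_sig = len(significant.get(acc, ()))
        if config.selection_mode == "significant_frac":
            selected = n_sig / n_eligible >= config.prevalence_min
        else:
            selected = n_present / n_eligible >= config.prevalence_min and n_sig >= 1
        summaries.append(
            DomainSummary(
                accession=acc,
                n_genomes_eligible=n_eligible,
                n_genomes_present=n_present,
                n_genomes_significant=n_sig,
                selected=selected,
            )
        )
    return summaries


def per_phylum_runs(
    genomes: Sequence,
    config: PipelineConfig,
    anchors: Mapping | None = None,
) -> dict:
    """Rerun the whole selection procedure within each phylum contributing at
    least ``phylum_min_genomes`` eligible genomes; smaller phyla are omitted
    with a logged note."""
    by_phylum: dict = {}
    for genome in genomes:
        if genome.phylum is not None:
            by_phylum.setdefault(genome.phylum, []).append(genome)

    out: dict = {}
    for phylum in sorted(by_phylum):
        members = by_phylum[phylum]
        n_elig = len({gid for gid, _ in eligible_loci(members, config, anchors)})
        if n_elig < config.phylum_min_genomes:
            log.info(
                "phylum %s omitted: %d eligible genomes (< %d)",
                phylum, n_elig, config.phylum_min_genomes,
            )
            continue
        records = run_enrichment(members, config, anchors)
        out[phylum] = summarize_selection(records, members, config, anchors)
    return out
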