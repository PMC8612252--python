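import pytest

import heliocontext as hc


@pytest.fixture(scope="session")
def config():
    return hc.PipelineConfig()


@pytest.fixture(scope="session")
def cohort(config):
    """A moderate planted cohort shared by read-only tests."""
    return hc.generate_cohort(12, config, seed=11)


def make_gene(gene_id, start, end, strand="+", contig_id="c1", domains=()):
    return hc.GeneRecord(
        gene_id=gene_id, contig_id=contig_id, start=start, end=end,
        strand=strand, domains=set(domains),
    )


def make_contig(specs, contig_id="c1", length=None):
    """Build a contig from (gene_id, start, end, strand, domains) tuples."""
    genes = [
        make_gene(gid, start, end, strand, contig_id, domains)
        for gid, start, end, strand, domains in specs
    ]
    if length is None:
        length = max(g.end for g in genes) + 50
    return hc.ContigRecord(contig_id=contig_id, length=length, genes=genes)


def chain_contig(gaps, strands, start=1000, gene_len=600, contig_id="c1", domains_per_gene=None):
    """Build a contig of consecutive genes with the given intergenic gaps.

    ``gaps[i]`` separates gene i from gene i+1; ``strands`` has one entry per
    gene. Gene ids are g1, g2, ...
    """
    specs = []
    pos = start
    for i, strand in enumerate(strands):
        end = pos + gene_len - 1
        domains = domains_per_gene[i] if domains_per_gene else ()
        specs.append((f"g{i + 1}", pos, end, strand, domains))
        if i < len(gaps):
            pos = end + gaps[i] + 1
    return make_contig(specs, contig_id=contig_id)


def single_contig_genome(contig, genome_id="G1", **kwargs):
    return hc.GenomeAnnotation(genome_id=genome_id, contigs=[contig], **kwargs)
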