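"""Seeded generator of annotated genomes with planted ground truth.

Every pipeline stage has a planted counterpart here: contigs carry ordered,
stranded genes with realistic intergenic gaps (operonic junctions 0–9 bp
with occasional overlaps, non-operonic 30–300 bp); domains are assigned
from a background frequency with optional enrichment planted around a
heliorhodopsin anchor; proteins carry planted 7-TM architectures with
helix-7 motifs; envelope marker complements follow the planted
monoderm/diderm label; and best-hit tables have controllable phylum
concordance. The planted truth is returned alongside the annotations and
serialises to JSON next to the dataset.

All randomness flows through a single numpy Generator keyed by the seed;
identical seeds yield byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    BestHit,
    ContigRecord,
    DomainHit,
    GeneRecord,
    GenomeAnnotation,
    PipelineConfig,
    write_annotations,
    write_besthits,
    write_domain_hits,
)
from .rhodopsin_screen import TMSegment, TopologyModel

HELIX_ALPHABET = "LIVF"         # strongly hydrophobic core residues
LOOP_ALPHABET = "TNQGEP"        # hydrophilic, free of S/D/K so planted helix-7
                                # motifs are the only anchor-pattern matches
INSIDE_BASIC = "KR"             # positive-inside enrichment of cytoplasmic loops
INSIDE_BASIC_FRAC = 0.4

STRAND_CHOICES = ("+", "-")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic genome."""

    genome_id: str
    anchor_id: str
    phylum: str
    planted_rhodopsins: list = field(default_factory=list)   # (protein_id, class, motif_pos)
    planted_operons: list = field(default_factory=list)      # chains of gene_ids
    planted_enriched_domains: list = field(default_factory=list)  # (acc, nbhd_freq, bg_freq)
    envelope_label: str = "monoderm"
    phylum_concordance: float = 0.8

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=list)


# ---------------------------------------------------------------------------
# Proteins
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _loop_seq(rng: np.random.Generator, n: int, inside: bool) -> str:
    if not inside:
        return _draw(rng, LOOP_ALPHABET, n)
    chars = []
    for basic in rng.random(n) < INSIDE_BASIC_FRAC:
        chars.append(
            INSIDE_BASIC[rng.integers(0, len(INSIDE_BASIC))]
            if basic
            else LOOP_ALPHABET[rng.integers(0, len(LOOP_ALPHABET))]
        )
    return "".join(chars)


def generate_protein(
    n_helices: int = 7,
    motif: tuple | None = ("SxxxK", 7),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    helix_len: int = 23,
    loop_len: int = 16,
    nterm_len: int = 24,
    cterm_len: int = 12,
    n_terminus_side: str = "in",
):
    """Build a membrane protein with planted topology and optional motif.

    Helices are Leu/Ile/Val/Phe runs, loops hydrophilic; loops on the side
    of the N terminus are Lys/Arg-enriched so the positive-inside rule
    recovers ``n_terminus_side``. ``motif`` is ``(pattern, helix_index)``;
    the pattern is embedded mid-helix at a recorded position.

    Returns ``(sequence, TopologyModel, motif_pos)`` where ``motif_pos`` is
    the 1-based residue of the planted pattern (None when no motif).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if motif is not None and len(motif[0]) > helix_len:
        raise ValueError("motif longer than helix")

    parts: list = []
    segments: list = []
    motif_pos = None
    pos = 0

    parts.append(_loop_seq(rng, nterm_len, inside=(n_terminus_side == "in")))
    pos += nterm_len
    for h in range(1, n_helices + 1):
        if motif is not None and h == motif[1]:
            # the polar motif residues cost hydropathy, so the motif helix is
            # built from the strongest hydrophobics only
            helix = _draw(rng, "LIV", helix_len)
            pattern = motif[0]
            offset = (helix_len - len(pattern)) // 2
            planted = pattern[0] + _draw(rng, "LIV", len(pattern) - 2) + pattern[-1]
            helix = helix[:offset] + planted + helix[offset + len(pattern):]
            motif_pos = pos + offset + 1
        else:
            helix = _draw(rng, HELIX_ALPHABET, helix_len)
        parts.append(helix)
        segments.append(TMSegment(index=h, start=pos + 1, end=pos + helix_len))
        pos += helix_len
        if h < n_helices:
            # loop after TM h: same side as the N terminus iff h is even
            inside = ((h % 2 == 0) == (n_terminus_side == "in"))
            parts.append(_loop_seq(rng, loop_len, inside=inside))
            pos += loop_len
    cterm_inside = ((n_helices % 2 == 0) == (n_terminus_side == "in"))
    parts.append(_loop_seq(rng, cterm_len, inside=cterm_inside))

    topology = TopologyModel(
        protein_id="", segments=segments, n_terminus_side=n_terminus_side
    )
    return "".join(parts), topology, motif_pos


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def _background_accessions(n: int) -> list:
    return [f"BG{i:03d}" for i in range(1, n + 1)]


def generate_cohort(
    n_genomes: int,
    config: PipelineConfig,
    seed: int,
    *,
    genes_range: tuple = (100, 400),
    gene_len_range: tuple = (300, 3000),
    p_operonic: float = 0.25,
    p_decoy: float = 0.10,
    overlap_frac: float = 0.2,
    background_domains: int = 40,
    background_freq: float = 0.02,
    enriched_domains: tuple = (("ENR001", 0.40, 0.02),),
    enrichment_frac: float = 1.0,
    envelope_labels: tuple | None = None,
    phyla: tuple = ("Actinobacteriota", "Chloroflexi", "Firmicutes"),
    concordance: float = 0.8,
    with_proteins: bool = True,
    genome_prefix: str = "G",
):
    """Generate ``n_genomes`` single-contig genomes with planted truth.

    Each genome carries one heliorhodopsin anchor with at least 10 genes on
    each side. Enrichment is planted in the first
    ``ceil(enrichment_frac * n_genomes)`` genomes by giving
    ``round(freq * 20)`` of the 20 neighborhood genes the chosen accession
    (background frequency applies outside the neighborhood). Envelope labels
    alternate monoderm/diderm unless given; diderms receive 10–27 distinct
    markers, monoderms 0–2. Phyla are assigned round-robin.

    Returns ``(genomes, truths)``, deterministic given ``seed``.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    for _, nf, bf in enriched_domains:
        if not (0 <= nf <= 1 and 0 <= bf <= 1):
            raise ValueError("planted frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bg_accs = _background_accessions(background_domains)
    n_enriched = math.ceil(enrichment_frac * n_genomes)

    genomes: list = []
    truths: list = []
    for gi in range(n_genomes):
        genome_id = f"{genome_prefix}{gi + 1:04d}"
        contig_id = f"{genome_id}_c1"
        n_genes = int(rng.integers(genes_range[0], genes_range[1] + 1))
        anchor_idx = int(rng.integers(12, n_genes - 12))

        # strands and junction types
        strands = [STRAND_CHOICES[rng.integers(0, 2)]]
        jtypes = [None]  # junction j joins genes j-1 and j
        gaps = [0]
        for _ in range(1, n_genes):
            u = rng.random()
            if u < p_operonic:
                jtypes.append("operonic")
                strands.append(strands[-1])
                if rng.random() < overlap_frac:
                    gaps.append(int(rng.integers(-20, 0)))
                else:
                    gaps.append(int(rng.integers(0, config.operon_max_gap)))
            elif u < p_operonic + p_decoy:
                jtypes.append("decoy")
                strands.append("-" if strands[-1] == "+" else "+")
                gaps.append(int(rng.integers(0, config.operon_max_gap)))
            else:
                jtypes.append("spacer")
                strands.append(STRAND_CHOICES[rng.integers(0, 2)])
                gaps.append(int(rng.integers(30, 301)))

        lengths = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=n_genes)
        starts = np.empty(n_genes, dtype=np.int64)
        ends = np.empty(n_genes, dtype=np.int64)
        starts[0] = 1 + int(rng.integers(0, 200))
        ends[0] = starts[0] + lengths[0] - 1
        for j in range(1, n_genes):
            starts[j] = ends[j - 1] + gaps[j] + 1
            ends[j] = starts[j] + lengths[j] - 1
        contig_len = int(ends[-1] + rng.integers(20, 200))

        gene_ids = [f"{genome_id}_g{j + 1:04d}" for j in range(n_genes)]
        domains: list = [set() for _ in range(n_genes)]

        # background domain annotations
        mask = rng.random((n_genes, len(bg_accs))) < background_freq
        for j, acc_idx in zip(*np.nonzero(mask)):
            domains[j].add(bg_accs[acc_idx])

        domains[anchor_idx].add(config.her_accession)

        member_idx = list(range(anchor_idx - config.flank_min_genes, anchor_idx)) + list(
            range(anchor_idx + 1, anchor_idx + 1 + config.flank_min_genes)
        )
        planted_enriched = []
        if gi < n_enriched:
            for acc, nbhd_freq, bg_freq in enriched_domains:
                n_plant = round(nbhd_freq * len(member_idx))
                for j in rng.choice(member_idx, size=n_plant, replace=False):
                    domains[int(j)].add(acc)
                outside = rng.random(n_genes) < bg_freq
                for j in np.nonzero(outside)[0]:
                    if int(j) not in member_idx and int(j) != anchor_idx:
                        domains[int(j)].add(acc)
                planted_enriched.append((acc, nbhd_freq, bg_freq))

        # envelope markers
        if envelope_labels is not None:
            envelope_label = envelope_labels[gi % len(envelope_labels)]
        else:
            envelope_label = "diderm" if gi % 2 else "monoderm"
        if envelope_label == "diderm":
            n_markers = int(rng.integers(config.diderm_min_markers, len(config.marker_set) + 1))
        else:
            n_markers = int(rng.integers(0, config.monoderm_max_markers + 1))
        for m in rng.choice(len(config.marker_set), size=n_markers, replace=False):
            domains[int(rng.integers(0, n_genes))].add(config.marker_set[int(m)])

        genes = [
            GeneRecord(
                gene_id=gene_ids[j],
                contig_id=contig_id,
                start=int(starts[j]),
                end=int(ends[j]),
                strand=strands[j],
                domains=domains[j],
            )
            for j in range(n_genes)
        ]
        contig = ContigRecord(contig_id=contig_id, length=contig_len, genes=genes)

        # planted operon chain through the anchor
        lo = anchor_idx
        while lo > 0 and jtypes[lo] == "operonic":
            lo -= 1
        hi = anchor_idx
        while hi + 1 < n_genes and jtypes[hi + 1] == "operonic":
            hi += 1
        planted_operons = [gene_ids[lo:hi + 1]] if hi > lo else []

        # planted rhodopsin proteins: the anchor plus one type-1 and one reject
        proteins: dict = {}
        planted_rhodopsins: list = []
        if with_proteins:
            seq, _, pos = generate_protein(7, (config.her_motif, 7), rng=rng)
            proteins[gene_ids[anchor_idx]] = seq
            planted_rhodopsins.append((gene_ids[anchor_idx], "heliorhodopsin", pos))
            seq, _, pos = generate_protein(7, (config.type1_motif, 7), rng=rng)
            proteins[gene_ids[0]] = seq
            planted_rhodopsins.append((gene_ids[0], "type1", pos))
            seq, _, _ = generate_protein(6, None, rng=rng)
            proteins[gene_ids[1]] = seq
            planted_rhodopsins.append((gene_ids[1], "rejected", None))

        phylum = phyla[gi % len(phyla)]
        genomes.append(
            GenomeAnnotation(
                genome_id=genome_id,
                contigs=[contig],
                completeness=round(float(rng.uniform(0.85, 1.0)), 3),
                phylum=phylum,
                proteins=proteins,
            )
        )
        truths.append(
            SyntheticTruth(
                genome_id=genome_id,
                anchor_id=gene_ids[anchor_idx],
                phylum=phylum,
                planted_rhodopsins=planted_rhodopsins,
                planted_operons=planted_operons,
                planted_enriched_domains=planted_enriched,
                envelope_label=envelope_label,
                phylum_concordance=concordance,
            )
        )
    return genomes, truths


# ---------------------------------------------------------------------------
# Best hits
# ---------------------------------------------------------------------------

def generate_besthits(
    contig: ContigRecord,
    concordance: float,
    phylum: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    decoy_phyla: tuple = ("DecoyPhylumA", "DecoyPhylumB"),
    no_hit_frac: float = 0.5,
):
    """Best-hit table for a contig with a planted concordance level.

    Exactly ``ceil(concordance * n_genes)`` genes hit the target phylum; the
    remainder split between decoy phyla and no-hits. Deterministic given the
    seed (or supplied generator).
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = contig.n_genes
    n_conc = math.ceil(concordance * n)
    order = rng.permutation(n)
    hits: list = []
    for rank, j in enumerate(order):
        gene_id = contig.genes[int(j)].gene_id
        if rank < n_conc:
            hits.append(BestHit(gene_id=gene_id, subject_phylum=phylum))
        elif rng.random() < no_hit_frac:
            hits.append(BestHit(gene_id=gene_id, subject_phylum=None))
        else:
            hits.append(BestHit(gene_id=gene_id, subject_phylum=decoy_phyla[int(rng.integers(0, len(decoy_phyla)))]))
    hits.sort(key=lambda bh: bh.gene_id)
    return hits


# ---------------------------------------------------------------------------
# Dataset serialisation
# ---------------------------------------------------------------------------

def write_dataset(genomes, truths, out_dir, seed: int = 0) -> Path:
    """Write a cohort as GFF3 + protein FASTA + hit/best-hit TSVs + truth
    JSON, one file set per genome. Deterministic given the cohort and seed
    (the seed drives best-hit generation)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    for genome, truth in zip(genomes, truths):
        stem = out_dir / genome.genome_id
        write_annotations(genome, f"{stem}.gff3", f"{stem}.faa" if genome.proteins else None)
        hits = [
            DomainHit(protein_id=g.gene_id, accession=acc, evalue=1e-10,
                      ali_start=1, ali_end=50)
            for g in genome.iter_genes()
            for acc in sorted(g.domains)
        ]
        write_domain_hits(hits, f"{stem}.hits.tsv")
        besthits = generate_besthits(
            genome.contigs[0], truth.phylum_concordance, truth.phylum, rng=rng
        )
        write_besthits(besthits, f"{stem}.besthits.tsv")
        Path(f"{stem}.truth.json").write_text(truth.to_json() + "\n")
    return out_dir


def simulate_dataset(out_dir, n_genomes: int, config: PipelineConfig, seed: int, **kwargs) -> Path:
    """Generate a cohort and write it under ``out_dir`` in one step."""
    genomes, truths = generate_cohort(n_genomes, config, seed, **kwargs)
    return write_dataset(genomes, truths, out_dir, seed=seed)
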