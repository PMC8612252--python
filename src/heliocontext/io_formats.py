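"""Record types, configuration and file formats for the gene-context pipeline.

All downstream modules operate on the containers defined here: ordered,
stranded gene models (:class:`GeneRecord`, :class:`ContigRecord`,
:class:`GenomeAnnotation`), per-protein domain hits (:class:`DomainHit`),
per-gene best hits with subject phylum (:class:`BestHit`), and the single
home for every numeric threshold (:class:`PipelineConfig`).

Coordinates are 1-based inclusive throughout (the GFF3 convention); contigs
are treated as linear, with no wrap-around adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: Placeholder outer-envelope marker accessions (27 slots). The curated marker
#: identities are distributed with the source study's supplementary data and can
#: be supplied via a marker list file; these slots keep the classifier testable.
DEFAULT_MARKER_SET = tuple(f"OMM{i:03d}" for i in range(1, 28))

#: Pfam accession of the heliorhodopsin family model, used to auto-detect
#: anchor genes from domain annotations.
HER_ACCESSION = "PF18761"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All numeric thresholds and behavioural switches, with field defaults
    matching the published screening and context-analysis criteria.

    Units: coordinates and gaps in bp, loop lengths in amino acids, fractions
    in [0, 1].
    """

    evalue_max: float = 1e-3            # domain hits kept iff evalue < this (strict)
    required_tm: int = 7                # transmembrane helices required of a rhodopsin
    her_motif: str = "SxxxK"            # helix-7 motif of heliorhodopsins
    type1_motif: str = "DxxxK"          # helix-7 motif of type-1 (proteo)rhodopsins
    marker_set: tuple = DEFAULT_MARKER_SET
    diderm_min_markers: int = 10        # distinct markers for a diderm verdict
    monoderm_max_markers: int = 2       # at most this many -> monoderm-consistent
    contig_min_len: int = 5000          # bp; shorter contigs excluded from taxonomy
    taxonomy_min_frac: float = 0.60     # inclusive best-hit concordance threshold
    operon_max_gap: int = 10            # bp; cotranscription requires gap < this
    context_window: int = 10_000        # bp each side for by-window neighborhoods
    flank_min_genes: int = 10           # genes required on each side of an anchor
    draw_size: int = 20                 # hypergeometric draw (2 x flank_min_genes)
    fdr_alpha: float = 0.05             # BH-corrected significance cutoff
    prevalence_min: float = 0.10        # fraction of genomes for domain selection
    phylum_min_genomes: int = 5         # eligible genomes needed for a per-phylum run
    loop_min_len: int = 50              # aa; inter-TM loops reported iff longer
    her_accession: str = HER_ACCESSION
    # behavioural switches (defaults follow the primary reading of the method)
    hit_table_format: str = "tsv"       # "tsv" (5-column) or "domtbl" (profile-HMM per-domain)
    hits_only_denominator: bool = False  # taxonomy support over genes-with-hits only
    direct_neighbors_only: bool = False  # operon chains limited to direct anchor neighbors
    per_genome_bh: bool = False          # BH within each genome instead of run-wide
    selection_mode: str = "significant_frac"  # or "present_frac"

    def __post_init__(self) -> None:
        positive = (
            "evalue_max", "required_tm", "diderm_min_markers", "contig_min_len",
            "taxonomy_min_frac", "operon_max_gap", "context_window",
            "flank_min_genes", "draw_size", "fdr_alpha", "prevalence_min",
            "phylum_min_genomes", "loop_min_len",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"PipelineConfig.{name} must be positive")
        if self.draw_size != 2 * self.flank_min_genes:
            raise ValueError("draw_size must equal 2 * flank_min_genes")
        if self.hit_table_format not in ("tsv", "domtbl"):
            raise ValueError(f"unknown hit_table_format: {self.hit_table_format!r}")
        if self.selection_mode not in ("significant_frac", "present_frac"):
            raise ValueError(f"unknown selection_mode: {self.selection_mode!r}")
        self.marker_set = tuple(self.marker_set)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["marker_set"] = list(self.marker_set)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def read_marker_list(path: str | Path) -> tuple:
    """Read a marker list file (one accession per line, '#' comments allowed)."""
    markers = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                markers.append(line)
    return tuple(markers)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """A protein-coding gene on a contig, with its domain annotations."""

    gene_id: str
    contig_id: str
    start: int          # bp, 1-based inclusive
    end: int            # bp, inclusive; end >= start
    strand: str         # "+" or "-"
    domains: set = field(default_factory=set)
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.domains = set(self.domains)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ContigRecord:
    """A linear contig holding genes strictly sorted by (start, end)."""

    contig_id: str
    length: int
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(g.start, g.end) for g in self.genes]
        if keys != sorted(keys) or len(set(keys)) != len(keys):
            raise ValueError(f"contig {self.contig_id}: genes not strictly sorted by (start, end)")
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(f"contig {self.contig_id}: gene {g.gene_id} extends past contig end")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class GenomeAnnotation:
    """A genome (or MAG): contigs plus optional completeness/phylum metadata
    and protein sequences keyed by gene_id."""

    genome_id: str
    contigs: list = field(default_factory=list)
    completeness: float | None = None   # fraction in [0, 1]; None = unknown
    phylum: str | None = None           # None = unknown
    proteins: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.genome_id}: duplicate contig_ids")
        if self.completeness is not None and not 0.0 <= self.completeness <= 1.0:
            raise ValueError(f"genome {self.genome_id}: completeness outside [0, 1]")

    @property
    def n_genes(self) -> int:
        return sum(c.n_genes for c in self.contigs)

    def iter_genes(self):
        for contig in self.contigs:
            yield from contig.genes

    def gene_index(self) -> dict:
        """gene_id -> (ContigRecord, position index) over the whole genome."""
        idx = {}
        for contig in self.contigs:
            for i, g in enumerate(contig.genes):
                if g.gene_id in idx:
                    raise ValueError(f"genome {self.genome_id}: duplicate gene_id {g.gene_id}")
                idx[g.gene_id] = (contig, i)
        return idx


@dataclass
class DomainHit:
    """A single profile-HMM domain hit on a protein."""

    protein_id: str
    accession: str
    evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValueError(f"hit {self.protein_id}/{self.accession}: evalue must be > 0")
        if self.ali_start > self.ali_end:
            raise ValueError(f"hit {self.protein_id}/{self.accession}: ali_start > ali_end")


@dataclass
class BestHit:
    """Best database hit of a gene, reduced to the subject's phylum."""

    gene_id: str
    subject_phylum: str | None  # None = no hit


# ---------------------------------------------------------------------------
# GFF3 + FASTA annotation IO
# ---------------------------------------------------------------------------

_GENE_TYPES = ("CDS", "gene")


def _prescan_gff3(path: str | Path) -> None:
    """Validate coordinates and ID uniqueness before handing the file to
    gffutils, so hard errors name the offending feature."""
    seen: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: line {lineno}: fewer than 9 GFF3 columns")
            if cols[2] not in _GENE_TYPES:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"<line {lineno}>")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"feature {fid}: malformed coordinates") from exc
            if end < start:
                raise ValueError(f"feature {fid}: end < start ({end} < {start})")
            if fid in seen:
                raise ValueError(f"duplicate gene_id {fid}")
            seen.add(fid)


def read_annotations(
    gff3_path: str | Path,
    fasta_path: str | Path | None = None,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read a GFF3 annotation (CDS/gene features) and optional protein FASTA.

    Contig lengths come from ``##sequence-region`` pragmas where present and
    are otherwise inferred as the maximum gene end. Genome metadata is read
    from ``##genome-id``, ``##completeness`` and ``##phylum`` pragmas when the
    file carries them (as files written by :func:`write_annotations` do).
    """
    _prescan_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="error", keep_order=True
    )

    meta: dict = {}
    seq_lengths: dict = {}
    for directive in db.directives:
        parts = directive.split()
        if parts[0] == "sequence-region" and len(parts) >= 4:
            seq_lengths[parts[1]] = int(parts[3])
        elif parts[0] == "genome-id" and len(parts) >= 2:
            meta["genome_id"] = parts[1]
        elif parts[0] == "completeness" and len(parts) >= 2:
            meta["completeness"] = float(parts[1])
        elif parts[0] == "phylum" and len(parts) >= 2:
            meta["phylum"] = parts[1]

    ftypes = set(db.featuretypes())
    use_type = "CDS" if "CDS" in ftypes else "gene"
    by_contig: dict = {}
    for feat in db.features_of_type(use_type, order_by=("seqid", "start", "end")):
        fid = feat.id
        domains = set(feat.attributes.get("domains", []))
        product = feat.attributes.get("product", [None])[0]
        gene = GeneRecord(
            gene_id=fid,
            contig_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in STRANDS else "+",
            domains=domains,
            product=product,
        )
        by_contig.setdefault(feat.seqid, []).append(gene)

    contigs = []
    for contig_id in sorted(by_contig):
        genes = sorted(by_contig[contig_id], key=lambda g: (g.start, g.end))
        length = seq_lengths.get(contig_id, max(g.end for g in genes))
        contigs.append(ContigRecord(contig_id=contig_id, length=length, genes=genes))

    proteins: dict = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            proteins[rec.id] = str(rec.seq)

    gid = genome_id or meta.get("genome_id") or Path(gff3_path).stem
    return GenomeAnnotation(
        genome_id=gid,
        contigs=contigs,
        completeness=meta.get("completeness"),
        phylum=meta.get("phylum"),
        proteins=proteins,
    )


def write_annotations(
    annotation: GenomeAnnotation,
    gff3_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    """Write a :class:`GenomeAnnotation` as GFF3 (plus optional protein FASTA).

    Domain accessions and genome metadata are carried in attributes/pragmas so
    that ``read_annotations(write_annotations(x))`` round-trips exactly.
    """
    lines = ["##gff-version 3", f"##genome-id {annotation.genome_id}"]
    if annotation.completeness is not None:
        lines.append(f"##completeness {annotation.completeness!r}")
    if annotation.phylum is not None:
        lines.append(f"##phylum {annotation.phylum}")
    for contig in annotation.contigs:
        lines.append(f"##sequence-region {contig.contig_id} 1 {contig.length}")
    for contig in annotation.contigs:
        for g in contig.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.product is not None:
                attrs.append(f"product={g.product}")
            if g.domains:
                attrs.append("domains=" + ",".join(sorted(g.domains)))
            lines.append(
                "\t".join(
                    [
                        contig.contig_id,
                        "heliocontext",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
            )
    Path(gff3_path).write_text("\n".join(lines) + "\n")

    if fasta_path is not None:
        records = [
            SeqRecord(Seq(seq), id=pid, description="")
            for pid, seq in sorted(annotation.proteins.items())
        ]
        SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Tabular IO: domain hits, best hits
# ---------------------------------------------------------------------------

def read_domain_hits(path: str | Path, config: PipelineConfig) -> list:
    """Read a domain-hit table, keeping only hits with evalue < evalue_max.

    Two dialects are accepted (``config.hit_table_format``): a minimal
    5-column TSV (protein_id, accession, evalue, ali_start, ali_end) and the
    whitespace-delimited per-domain tabular output of profile-HMM searches.
    Rows with unparseable E-values are skipped with a counted warning.
    """
    hits: list = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            if config.hit_table_format == "tsv":
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 5:
                    cols = line.split()
                if cols[0] == "protein_id":  # header
                    continue
                protein_id, accession, ev, a, b = cols[0], cols[1], cols[2], cols[3], cols[4]
            else:  # per-domain tabular dialect of profile-HMM searches
                cols = line.split()
                if len(cols) < 19:
                    skipped += 1
                    continue
                protein_id = cols[0]
                accession = cols[4] if cols[4] != "-" else cols[3]
                ev, a, b = cols[12], cols[17], cols[18]
            try:
                evalue = float(ev)
                ali_start, ali_end = int(a), int(b)
            except ValueError:
                skipped += 1
                continue
            if evalue < config.evalue_max:
                hits.append(
                    DomainHit(
                        protein_id=protein_id,
                        accession=accession,
                        evalue=evalue,
                        ali_start=ali_start,
                        ali_end=ali_end,
                    )
                )
    if skipped:
        log.warning("%s: skipped %d unparseable hit rows", path, skipped)
    return hits


def write_domain_hits(hits: Iterable, path: str | Path) -> None:
    """Write domain hits in the minimal 5-column TSV dialect."""
    rows = sorted(
        (h.protein_id, h.accession, h.evalue, h.ali_start, h.ali_end) for h in hits
    )
    with open(path, "w") as fh:
        fh.write("protein_id\taccession\tevalue\tali_start\tali_end\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def attach_domain_hits(annotation: GenomeAnnotation, hits: Iterable) -> GenomeAnnotation:
    """Attach hit accessions to ``GeneRecord.domains`` by protein_id (in place)."""
    genes = {g.gene_id: g for g in annotation.iter_genes()}
    unmatched = 0
    for hit in hits:
        gene = genes.get(hit.protein_id)
        if gene is None:
            unmatched += 1
            continue
        gene.domains.add(hit.accession)
    if unmatched:
        log.debug("%d hits had no matching gene", unmatched)
    return annotation


def read_besthits(path: str | Path) -> list:
    """Read a best-hit TSV (gene_id, subject_phylum); empty/NA/- means no hit."""
    out: list = []
    seen: set = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[0] == "gene_id":  # header
                continue
            gene_id = cols[0]
            if gene_id in seen:
                raise ValueError(f"multiple best hits for gene {gene_id}")
            seen.add(gene_id)
            phylum = cols[1].strip() if len(cols) > 1 else ""
            subject = None if phylum in ("", "NA", "-") else phylum
            out.append(BestHit(gene_id=gene_id, subject_phylum=subject))
    return out


def write_besthits(besthits: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsubject_phylum\n")
        for bh in sorted(besthits, key=lambda b: b.gene_id):
            fh.write(f"{bh.gene_id}\t{bh.subject_phylum or 'NA'}\n")


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_reports(results: Iterable, out_dir: str | Path, kinds: Sequence | None = None) -> dict:
    """Write result records as one TSV per result kind.

    Every record class participating in reporting defines ``report_name``
    (file stem), ``report_columns`` and ``to_row()``. Rows are sorted by their
    full value tuple, so identical inputs yield byte-identical files. Pass
    ``kinds`` (record classes) to emit header-only files for kinds with no
    records.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and not out_dir.is_dir():
        raise NotADirectoryError(str(out_dir))
    out_dir.mkdir(parents=True, exist_ok=True)

    grouped: dict = {}
    for kind in kinds or ():
        grouped[kind] = []
    for rec in results:
        if not hasattr(rec, "report_name"):
            raise TypeError(f"{type(rec).__name__} is not a reportable record")
        grouped.setdefault(type(rec), []).append(rec)

    written: dict = {}
    for kind, records in grouped.items():
        path = out_dir / f"{kind.report_name}.tsv"
        rows = sorted(tuple(str(v) for v in r.to_row()) for r in records)
        with open(path, "w") as fh:
            fh.write("\t".join(kind.report_columns) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        written[kind.report_name] = path
    return written
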