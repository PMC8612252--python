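"""Rhodopsin screening: transmembrane topology, helix-7 motif, classification.

A candidate protein is called a heliorhodopsin when it has seven
transmembrane (TM) helices and an SxxxK motif in (or within three residues
of) helix 7; a DxxxK motif in the same window instead marks a type-1
(proteo)rhodopsin. Everything else is rejected with explicit reasons.

Heliorhodopsins have an inverted membrane orientation relative to type-1/2
rhodopsins: the N terminus is cytoplasmic ("in") and the C terminus
extracellular. An "out" N terminus therefore conflicts with the expected
heliorhodopsin topology, but the screen records it as a warning rather than
a rejection — TM count and motif are the retention criteria.

Topology normally comes from an external predictor's table
(:func:`read_topology_table`); :func:`predict_topology_fallback` provides a
deterministic Kyte–Doolittle hydropathy fallback when no table is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .io_formats import PipelineConfig

log = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Fallback-predictor parameters: 19-residue window (the classical span of a
# membrane-crossing helix), runs above threshold merged across gaps of <= 3
# residues, and a 15-residue floor on the merged run.
HYDROPATHY_WINDOW = 19
HYDROPATHY_THRESHOLD = 1.0
MERGE_GAP = 3
MIN_HELIX_LEN = 15

VERDICTS = ("heliorhodopsin", "type1", "rejected")


@dataclass
class TMSegment:
    """One transmembrane helix, residue coordinates 1-based inclusive."""

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"TM segment {self.index}: bad coordinates")


@dataclass
class TopologyModel:
    """TM segmentation of a protein plus the side of its N terminus.

    ``n_terminus_side`` determines loop sidedness by alternation: with an
    "in" N terminus, the loop after TM1 is extracellular, after TM2
    cytoplasmic, and so on.
    """

    protein_id: str
    segments: list = field(default_factory=list)
    n_terminus_side: str = "unknown"    # "in" | "out" | "unknown"

    def __post_init__(self) -> None:
        if self.n_terminus_side not in ("in", "out", "unknown"):
            raise ValueError(f"{self.protein_id}: bad n_terminus_side")
        prev_end = 0
        for i, seg in enumerate(self.segments, 1):
            if seg.index != i:
                raise ValueError(f"{self.protein_id}: segment indices out of order")
            if seg.start <= prev_end:
                raise ValueError(f"{self.protein_id}: overlapping or unsorted TM segments")
            prev_end = seg.end

    @property
    def n_tm(self) -> int:
        return len(self.segments)


@dataclass
class RhodopsinCall:
    """Classification verdict for one candidate protein."""

    protein_id: str
    verdict: str
    motif_pos: int | None = None
    reasons: list = field(default_factory=list)

    report_name = "rhodopsin_calls"
    report_columns = ("protein_id", "verdict", "motif_pos", "reasons")

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"{self.protein_id}: bad verdict {self.verdict!r}")
        if self.verdict == "rejected" and not self.reasons:
            raise ValueError(f"{self.protein_id}: rejection without a reason")

    def to_row(self):
        return (
            self.protein_id,
            self.verdict,
            "" if self.motif_pos is None else self.motif_pos,
            ",".join(self.reasons),
        )


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def predict_topology_fallback(sequence: str, protein_id: str = "") -> TopologyModel:
    """Segment a sequence into TM helices by sliding-window hydropathy.

    Residues whose centred 19-window Kyte–Doolittle mean exceeds the
    threshold are marked; marked runs separated by gaps of at most 3 residues
    are merged and runs of at least 15 residues become helices. The side of
    the N terminus follows the positive-inside rule: loops on the cytoplasmic
    face are enriched in Lys/Arg, so whichever loop parity carries more K+R
    is called "in". Fully deterministic.
    """
    if len(sequence) < 100:
        raise ValueError("sequence too short for topology prediction (< 100 aa)")
    values = np.empty(len(sequence))
    nonstandard = 0
    for i, aa in enumerate(sequence):
        v = KYTE_DOOLITTLE.get(aa)
        if v is None:
            nonstandard += 1
            v = 0.0
        values[i] = v
    if nonstandard:
        log.warning("%s: %d non-standard residues treated as hydropathy 0",
                    protein_id or "<sequence>", nonstandard)

    kernel = np.ones(HYDROPATHY_WINDOW)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    means = num / den           # true mean over the window residues in range
    marked = means >= HYDROPATHY_THRESHOLD

    # runs of marked residues
    runs: list = []
    start = None
    for i, m in enumerate(marked):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(sequence) - 1])

    merged: list = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= MERGE_GAP:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    segments = [
        TMSegment(index=i + 1, start=a + 1, end=b + 1)
        for i, (a, b) in enumerate(r for r in merged if r[1] - r[0] + 1 >= MIN_HELIX_LEN)
    ]

    side = _positive_inside_side(sequence, segments)
    return TopologyModel(protein_id=protein_id, segments=segments, n_terminus_side=side)


def _positive_inside_side(sequence: str, segments: list) -> str:
    """Assign the N-terminus side by comparing K+R counts between the two
    loop parities (region 0 = before TM1 shares the N terminus' side)."""
    if not segments:
        return "unknown"
    bounds = [0] + [s.end for s in segments]          # region i starts after TM i
    starts = [s.start - 1 for s in segments] + [len(sequence)]
    even_kr = odd_kr = 0
    for region, (lo, hi) in enumerate(zip(bounds, starts)):
        kr = sum(1 for aa in sequence[lo:hi] if aa in "KR")
        if region % 2 == 0:
            even_kr += kr
        else:
            odd_kr += kr
    if even_kr > odd_kr:
        return "in"
    if odd_kr > even_kr:
        return "out"
    return "unknown"


def read_topology_table(path: str | Path) -> dict:
    """Read a topology TSV (protein_id, index, start, end, n_terminus_side)
    into a dict of :class:`TopologyModel` keyed by protein_id."""
    rows: dict = {}
    sides: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[0] == "protein_id":
                continue
            pid, index, start, end = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
            side = cols[4] if len(cols) > 4 else "unknown"
            rows.setdefault(pid, []).append(TMSegment(index=index, start=start, end=end))
            sides[pid] = side
    return {
        pid: TopologyModel(
            protein_id=pid,
            segments=sorted(segs, key=lambda s: s.index),
            n_terminus_side=sides[pid],
        )
        for pid, segs in rows.items()
    }


def write_topology_table(topologies: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tindex\tstart\tend\tn_terminus_side\n")
        for pid in sorted(topologies):
            topo = topologies[pid]
            for seg in topo.segments:
                fh.write(f"{pid}\t{seg.index}\t{seg.start}\t{seg.end}\t{topo.n_terminus_side}\n")


# ---------------------------------------------------------------------------
# Motif location and classification
# ---------------------------------------------------------------------------

MOTIF_WINDOW_PAD = 3  # residues of slack around predicted helix-7 boundaries


def _parse_anchor_pattern(pattern: str) -> tuple:
    """An anchor pattern is a fixed residue, three wildcards, a fixed residue
    (e.g. ``SxxxK``)."""
    if len(pattern) != 5 or pattern[1:4] != "xxx":
        raise ValueError(f"bad anchor pattern {pattern!r} (expected e.g. 'SxxxK')")
    first, last = pattern[0], pattern[4]
    if not (first.isalpha() and first.isupper() and last.isalpha() and last.isupper()):
        raise ValueError(f"bad anchor pattern {pattern!r}")
    return first, last


def locate_helix7_motif(sequence: str, topology: TopologyModel, pattern: str) -> int | None:
    """Return the first 1-based position in the helix-7 window where the
    anchor pattern matches, or None.

    The window is TM7 extended by three residues on each side, because
    predicted helix boundaries are imprecise; the match must lie entirely
    within the window.
    """
    if topology.n_tm < 7:
        raise ValueError(f"{topology.protein_id or '<protein>'}: topology has fewer than 7 TM segments")
    first, last = _parse_anchor_pattern(pattern)
    tm7 = topology.segments[6]
    lo = max(1, tm7.start - MOTIF_WINDOW_PAD)
    hi = min(len(sequence), tm7.end + MOTIF_WINDOW_PAD)
    for pos in range(lo, hi - 3):           # pos 1-based; motif spans pos..pos+4 <= hi
        if sequence[pos - 1] == first and sequence[pos + 3] == last:
            return pos
    return None


def classify_rhodopsin(
    protein_id: str,
    sequence: str,
    topology: TopologyModel | None,
    config: PipelineConfig,
) -> RhodopsinCall:
    """Classify one protein as heliorhodopsin, type-1 rhodopsin, or reject.

    Retention requires exactly ``config.required_tm`` helices and the
    family-diagnostic motif in the helix-7 window: SxxxK for heliorhodopsins,
    DxxxK for type-1 rhodopsins. When both motifs match (at different
    offsets), heliorhodopsin takes precedence with an ``ambiguous_motif``
    note. An "out" N terminus on a heliorhodopsin call is recorded as
    ``orientation_conflict`` without changing the verdict.
    """
    if not sequence:
        raise ValueError(f"{protein_id}: empty sequence")
    if topology is None:
        topology = predict_topology_fallback(sequence, protein_id=protein_id)

    if topology.n_tm != config.required_tm:
        return RhodopsinCall(protein_id=protein_id, verdict="rejected", reasons=["tm_count"])

    her_pos = locate_helix7_motif(sequence, topology, config.her_motif)
    t1_pos = locate_helix7_motif(sequence, topology, config.type1_motif)

    if her_pos is not None:
        reasons = []
        if t1_pos is not None:
            reasons.append("ambiguous_motif")
        if topology.n_terminus_side == "out":
            reasons.append("orientation_conflict")
        return RhodopsinCall(
            protein_id=protein_id, verdict="heliorhodopsin", motif_pos=her_pos, reasons=reasons
        )
    if t1_pos is not None:
        return RhodopsinCall(protein_id=protein_id, verdict="type1", motif_pos=t1_pos)
    return RhodopsinCall(protein_id=protein_id, verdict="rejected", reasons=["no_motif"])


def screen_proteins(
    proteins: Mapping,
    config: PipelineConfig,
    topologies: Mapping | None = None,
) -> list:
    """Classify every protein in ``proteins`` (id -> sequence); results are
    sorted by protein_id, so output is invariant to input order."""
    calls = []
    for pid in sorted(proteins):
        topo = topologies.get(pid) if topologies else None
        calls.append(classify_rhodopsin(pid, proteins[pid], topo, config))
    return calls
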