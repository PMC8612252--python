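"""Fusion-diagnostic motifs and terminal/loop extensions of heliorhodopsins.

Two motif families diagnose the known heliorhodopsin domain fusions:

* the MORN repeat (membrane occupation and recognition nexus), a 14-residue
  repeat with consensus ``YEGEWxNGKxHGYG`` that occurs in tandem (typically
  three copies) at the cytoplasmic N terminus of some heliorhodopsins;
* the zinc ribbon, two CxxC half-sites separated by exactly 17 residues
  (``CxxC-17x-CxxC``, 25 residues in all), found at the N terminus of
  Thermoplasmatales heliorhodopsins and likely coordinating a metal.

Beyond fixed motifs, the module extracts the regions a profile-profile
search would examine: N-/C-terminal extensions (always reported) and
inter-TM loops longer than 50 aa, labelled ECL1–3/ICL1–3 by topological
alternation from the side of the N terminus (ntv/ctv for the termini).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import PipelineConfig
from .rhodopsin_screen import TopologyModel

MORN_CONSENSUS = "YEGEWxNGKxHGYG"
ZINC_HALF_SITE = "CxxC"
ZINC_SPACER = 17

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MotifMatch:
    """One fixed-span motif occurrence."""

    protein_id: str
    motif_name: str
    start: int          # residue coords, 1-based inclusive
    end: int
    matched_seq: str
    mismatches: int = 0

    report_name = "motif_matches"
    report_columns = ("protein_id", "motif_name", "start", "end", "matched_seq", "mismatches")

    def to_row(self):
        return (self.protein_id, self.motif_name, self.start, self.end,
                self.matched_seq, self.mismatches)


@dataclass
class ExtensionRegion:
    """A terminal extension or long loop of a 7-TM protein."""

    protein_id: str
    label: str          # ntv | ctv | ECL1..ECL3 | ICL1..ICL3
    start: int
    end: int
    length: int

    report_name = "extension_regions"
    report_columns = ("protein_id", "label", "start", "end", "length")

    def to_row(self):
        return (self.protein_id, self.label, self.start, self.end, self.length)


# ---------------------------------------------------------------------------
# Consensus matching
# ---------------------------------------------------------------------------

class ConsensusMatcher:
    """Fixed-span matcher for a consensus of upper-case residues and
    lower-case ``x`` wildcards; mismatches are counted on the fixed
    positions only."""

    def __init__(self, pattern: str):
        if not pattern:
            raise ValueError("empty consensus pattern")
        fixed = []
        for i, ch in enumerate(pattern):
            if ch == "x":
                continue
            if ch not in _AA:
                raise ValueError(f"illegal character {ch!r} in consensus pattern")
            fixed.append((i, ch))
        self.pattern = pattern
        self.span = len(pattern)
        self._fixed = tuple(fixed)

    def mismatches_at(self, sequence: str, pos: int) -> int | None:
        """Mismatch count of the window starting at 0-based ``pos``, or None
        if the window does not fit."""
        if pos < 0 or pos + self.span > len(sequence):
            return None
        return sum(1 for i, ch in self._fixed if sequence[pos + i] != ch)

    def find_all(self, sequence: str, max_mismatch: int = 0, overlapping: bool = True) -> list:
        """0-based (position, mismatches) pairs; non-overlapping scanning is
        greedy left-to-right."""
        out = []
        pos = 0
        limit = len(sequence) - self.span
        while pos <= limit:
            mm = self.mismatches_at(sequence, pos)
            if mm is not None and mm <= max_mismatch:
                out.append((pos, mm))
                pos += 1 if overlapping else self.span
            else:
                pos += 1
        return out


def compile_consensus(pattern: str) -> ConsensusMatcher:
    """Compile a consensus string (e.g. ``YEGEWxNGKxHGYG``) into a matcher."""
    return ConsensusMatcher(pattern)


def find_morn_repeats(sequence: str, max_mismatch: int = 0, protein_id: str = "") -> list:
    """All MORN-repeat matches, greedy left-to-right and non-overlapping —
    tandem repeats abut, so overlaps would double-count copies."""
    matcher = compile_consensus(MORN_CONSENSUS)
    return [
        MotifMatch(
            protein_id=protein_id,
            motif_name="MORN",
            start=pos + 1,
            end=pos + matcher.span,
            matched_seq=sequence[pos:pos + matcher.span],
            mismatches=mm,
        )
        for pos, mm in matcher.find_all(sequence, max_mismatch=max_mismatch, overlapping=False)
    ]


def find_zinc_ribbon(sequence: str, protein_id: str = "", spacer: int = ZINC_SPACER) -> list:
    """All zinc-ribbon matches (CxxC, exactly ``spacer`` arbitrary residues,
    CxxC). Overlapping matches are all reported, since cysteine spacing
    patterns can nest."""
    span = 8 + spacer
    out = []
    for pos in range(len(sequence) - span + 1):
        if (
            sequence[pos] == "C"
            and sequence[pos + 3] == "C"
            and sequence[pos + 4 + spacer] == "C"
            and sequence[pos + 7 + spacer] == "C"
        ):
            out.append(
                MotifMatch(
                    protein_id=protein_id,
                    motif_name="zinc_ribbon",
                    start=pos + 1,
                    end=pos + span,
                    matched_seq=sequence[pos:pos + span],
                    mismatches=0,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Extensions and loops
# ---------------------------------------------------------------------------

def _loop_label(loop_index: int, n_terminus_side: str) -> str:
    """Label the loop after TM ``loop_index`` (1..6) by alternation.

    With an "in" N terminus the loop after TM1 is extracellular (ECL1),
    after TM2 cytoplasmic (ICL1), ... after TM6 ICL3; an "out" N terminus
    swaps every ECL with the corresponding ICL.
    """
    extracellular = (loop_index % 2 == 1) == (n_terminus_side == "in")
    number = (loop_index + 1) // 2
    return f"{'ECL' if extracellular else 'ICL'}{number}"


def extract_extensions(
    sequence: str, topology: TopologyModel, config: PipelineConfig
) -> list:
    """Terminal extensions and long loops of a 7-TM protein.

    The N-terminal region before TM1 (``ntv``) and the C-terminal region
    after TM7 (``ctv``) are reported whenever non-empty, regardless of
    length; inter-TM loops are reported only when strictly longer than
    ``config.loop_min_len`` (50 aa).
    """
    if topology.n_tm != 7:
        raise ValueError(f"{topology.protein_id or '<protein>'}: topology must have 7 TM segments")
    if topology.n_terminus_side == "unknown":
        raise ValueError(f"{topology.protein_id or '<protein>'}: n_terminus_side must be known")
    segs = topology.segments
    pid = topology.protein_id
    regions: list = []

    def add(label: str, start: int, end: int) -> None:
        if end >= start:
            regions.append(
                ExtensionRegion(
                    protein_id=pid, label=label, start=start, end=end,
                    length=end - start + 1,
                )
            )

    add("ntv", 1, segs[0].start - 1)
    for i in range(6):
        start, end = segs[i].end + 1, segs[i + 1].start - 1
        if end - start + 1 > config.loop_min_len:
            add(_loop_label(i + 1, topology.n_terminus_side), start, end)
    add("ctv", segs[6].end + 1, len(sequence))
    return regions


def write_extensions_fasta(regions: Iterable, sequences: dict, path) -> None:
    """Write extension regions as FASTA, headers ``protein_id|label|start-end``,
    for downstream external clustering."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.protein_id, r.start)):
            seq = sequences[r.protein_id][r.start - 1:r.end]
            fh.write(f">{r.protein_id}|{r.label}|{r.start}-{r.end}\n{seq}\n")
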