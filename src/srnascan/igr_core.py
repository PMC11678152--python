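"""Intergenic region (IGR) extraction, orientation classification and
per-IGR composition / coding-potential features.

An IGR is the gap between two consecutive gene-like features (CDS, tRNA or
rRNA) on the same replicon. The orientation of the two flanking genes puts
each IGR in one of four classes:

* ``DP``  (double promoter)  — divergent flanks (-, +)
* ``DT``  (double terminator) — convergent flanks (+, -)
* ``CO_F`` — co-oriented forward (+, +)
* ``CO_R`` — co-oriented reverse (-, -)

IGR sequences are reported on the forward strand and are not trimmed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotation_io import AnnotationSet, FeatureRecord, GENE_KINDS

ORIENTATION_CLASSES = ("DP", "DT", "CO_F", "CO_R")

_COMP = str.maketrans("ACGTN", "TGCAN")
START_CODONS = ("ATG", "GTG")  # GTG starts are common in actinobacteria
STOP_CODONS = ("TAA", "TAG", "TGA")


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation class from the strands of the flanking genes."""
    table = {
        ("+", "-"): "DT",
        ("-", "+"): "DP",
        ("+", "+"): "CO_F",
        ("-", "-"): "CO_R",
    }
    try:
        return table[(left_strand, right_strand)]
    except KeyError:
        raise ValueError(f"invalid strand pair ({left_strand!r}, {right_strand!r})")


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases; NaN for all-N/empty input."""
    seq = seq.upper()
    atcg = sum(seq.count(b) for b in "ACGT")
    if atcg == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / atcg


@dataclass(frozen=True)
class IntergenicRegion:
    """A gap between two gene-like features; coords 0-based half-open."""

    id: str
    replicon: str
    start: int
    end: int
    left_gene: str
    right_gene: str
    orientation_class: str
    sequence: str
    gc: float

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_igrs(
    ann: AnnotationSet,
    genome: dict[str, str],
    include_terminal: bool = False,
    id_prefix: str = "IGR",
) -> list[IntergenicRegion]:
    """Extract IGRs between consecutive CDS/tRNA/rRNA features.

    Overlapping or abutting genes yield no IGR. Terminal gaps (before the
    first or after the last gene of a replicon) are excluded by default
    since they lack a second flanking gene; ``include_terminal=True``
    reports them with the missing flank empty and orientation class of the
    single neighbour pair left undefined (``CO_F``-style classification is
    impossible, so they get class ``"terminal"``).
    """
    igrs: list[IntergenicRegion] = []
    counter = 0
    for replicon in ann.replicons:
        seq = genome[replicon]
        genes = [f for f in ann.by_replicon(replicon) if f.kind in GENE_KINDS]
        genes.sort(key=lambda f: (f.start, f.end))
        if include_terminal and genes:
            first = genes[0]
            if first.start >= 1:
                counter += 1
                s = seq[0 : first.start]
                igrs.append(
                    IntergenicRegion(
                        f"{id_prefix}_{counter}", replicon, 0, first.start,
                        "", first.id, "terminal", s, gc_content(s),
                    )
                )
        # track the rightmost end seen so far so overlapping genes are handled
        prev: FeatureRecord | None = None
        for g in genes:
            if prev is not None and g.start > prev.end:
                counter += 1
                s = seq[prev.end : g.start]
                igrs.append(
                    IntergenicRegion(
                        id=f"{id_prefix}_{counter}",
                        replicon=replicon,
                        start=prev.end,
                        end=g.start,
                        left_gene=prev.id,
                        right_gene=g.id,
                        orientation_class=classify_orientation(prev.strand, g.strand),
                        sequence=s,
                        gc=gc_content(s),
                    )
                )
            if prev is None or g.end > prev.end:
                prev = g
        if include_terminal and genes:
            last = prev
            if last.end < len(seq):
                counter += 1
                s = seq[last.end :]
                igrs.append(
                    IntergenicRegion(
                        f"{id_prefix}_{counter}", replicon, last.end, len(seq),
                        last.id, "", "terminal", s, gc_content(s),
                    )
                )
    return igrs


@dataclass(frozen=True)
class CodingCall:
    igr_id: str
    longest_orf_aa: int
    is_coding: bool


def _longest_orf_codons(seq: str) -> int:
    """Longest ORF in a single forward sequence, all three frames.

    Returns the number of codons strictly between the start codon (ATG/GTG)
    and the stop codon; 0 when no complete ORF exists.
    """
    best = 0
    n = len(seq)
    for frame in range(3):
        start_at = None
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if codon in STOP_CODONS:
                if start_at is not None:
                    best = max(best, (p - start_at) // 3 - 1)
                    start_at = None
            elif start_at is None and codon in START_CODONS:
                start_at = p
    return best


def longest_orf_aa(seq: str) -> int:
    """Longest complete ORF over both strands (six frames), in residues.

    Residues are counted between start and stop codons exclusive: an ORF of
    ``ATG + k codons + stop`` scores ``k``.
    """
    seq = seq.upper()
    rc = seq.translate(_COMP)[::-1]
    return max(_longest_orf_codons(seq), _longest_orf_codons(rc))


def coding_call(igr: IntergenicRegion, min_aa: int = 100) -> CodingCall:
    """Coding-potential call for an IGR from its longest six-frame ORF."""
    aa = longest_orf_aa(igr.sequence) if igr.length >= 3 else 0
    return CodingCall(igr_id=igr.id, longest_orf_aa=aa, is_coding=aa >= min_aa)
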