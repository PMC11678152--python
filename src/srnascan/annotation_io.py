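"""Genome/annotation loading, validation, and merging of annotation sets.

Coordinates are handled 0-based half-open internally; GFF3 input/output
converts from/to the 1-based inclusive convention of the format.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

FEATURE_KINDS = {"CDS", "tRNA", "rRNA", "putative_sRNA", "antisense", "other"}
#: feature kinds that delimit intergenic regions
GENE_KINDS = {"CDS", "tRNA", "rRNA"}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class FeatureRecord:
    """A stranded genomic feature; ``start``/``end`` are 0-based half-open."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    kind: str = "other"
    source: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.id}: invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.kind not in FEATURE_KINDS:
            object.__setattr__(self, "kind", "other")

    @classmethod
    def from_one_based(cls, id, replicon, start, end, strand, kind="other", source=""):
        """Build from 1-based inclusive coordinates (GFF3 convention)."""
        return cls(id, replicon, start - 1, end, strand, kind, source)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "FeatureRecord") -> bool:
        return (
            self.replicon == other.replicon
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AnnotationSet:
    """A validated, position-sorted collection of features over named replicons."""

    replicons: dict[str, int]
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.replicon, f.start, f.end))
        self.validate()

    def validate(self) -> None:
        seen = set()
        for f in self.features:
            if f.id in seen:
                raise AnnotationError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)
            if f.replicon not in self.replicons:
                raise AnnotationError(
                    f"feature {f.id}: unknown replicon {f.replicon!r}"
                )
            if f.end > self.replicons[f.replicon]:
                raise AnnotationError(
                    f"feature {f.id}: end {f.end} exceeds length of {f.replicon} "
                    f"({self.replicons[f.replicon]})"
                )

    def by_replicon(self, replicon: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.replicon == replicon]

    def __len__(self) -> int:
        return len(self.features)


def load_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into a dict of replicon -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _gff_kind(featuretype: str) -> str:
    return featuretype if featuretype in FEATURE_KINDS else "other"


def load_annotation_set(genome, features_file) -> AnnotationSet:
    """Load and validate a GFF3 feature file against genome sequences.

    ``genome`` is a FASTA path or a dict of replicon -> sequence.
    Features on unknown replicons or extending past the replicon end are
    rejected with an :class:`AnnotationError` naming the offending record.
    """
    seqs = genome if isinstance(genome, dict) else load_fasta(genome)
    replicons = {name: len(seq) for name, seq in seqs.items()}
    try:
        db = gffutils.create_db(
            str(features_file),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return AnnotationSet(replicons=replicons, features=[])
    feats = []
    for f in db.all_features():
        if f.start is None or f.end is None or f.start > f.end or f.start < 1:
            raise AnnotationError(
                f"feature {f.id!r} on {f.seqid}: malformed coordinates "
                f"({f.start}..{f.end})"
            )
        feats.append(
            FeatureRecord.from_one_based(
                id=f.id,
                replicon=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                kind=_gff_kind(f.featuretype),
                source=f.source if f.source not in (None, ".") else "",
            )
        )
    return AnnotationSet(replicons=replicons, features=feats)


def load_annotation_text(genome, gff_text: str) -> AnnotationSet:
    """Like :func:`load_annotation_set` but from GFF3 text in memory."""
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(gff_text)
        name = fh.name
    try:
        return load_annotation_set(genome, name)
    finally:
        Path(name).unlink(missing_ok=True)


def write_gff3(ann: AnnotationSet, path, program: str = "srnascan") -> None:
    """Write an AnnotationSet as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in ann.replicons.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for f in ann.features:
            src = f.source or program
            fh.write(
                f"{f.replicon}\t{src}\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.id}\n"
            )


@dataclass
class MergeReport:
    """Bookkeeping from merging two annotation sets."""

    n_a: int
    n_b: int
    n_b_overlapping_a: int
    n_merged_records: int
    n_out: int


def merge_annotations(
    set_a: AnnotationSet, set_b: AnnotationSet, min_overlap: int = 1
) -> tuple[AnnotationSet, MergeReport]:
    """Merge two annotation sets over the same replicons.

    Same-strand features overlapping by at least ``min_overlap`` nt are
    collapsed into a single record spanning their union, with the sources of
    all contributors recorded. Opposite-strand features are never merged.
    The report counts features of ``set_b`` overlapping ``set_a`` (same
    strand), the annotation-agreement number of the two detectors.
    """
    if set(set_a.replicons) != set(set_b.replicons):
        raise AnnotationError("annotation sets cover different replicon universes")
    all_feats = list(set_a.features) + list(set_b.features)
    # union-find over same-strand overlap components
    parent = list(range(len(all_feats)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, f in enumerate(all_feats):
        key = (f.replicon, f.strand)
        tree = trees.setdefault(key, IntervalTree())
        for iv in tree.overlap(f.start, f.end):
            if min(f.end, iv.end) - max(f.start, iv.begin) >= min_overlap:
                union(iv.data, idx)
        tree.addi(f.start, f.end, idx)

    n_a = len(set_a.features)
    a_trees: dict[tuple[str, str], IntervalTree] = {}
    for f in set_a.features:
        a_trees.setdefault((f.replicon, f.strand), IntervalTree()).addi(f.start, f.end)
    n_b_overlap = sum(
        1
        for f in set_b.features
        if any(
            min(f.end, iv.end) - max(f.start, iv.begin) >= min_overlap
            for iv in a_trees.get((f.replicon, f.strand), IntervalTree()).overlap(
                f.start, f.end
            )
        )
    )

    groups: dict[int, list[FeatureRecord]] = {}
    for idx, f in enumerate(all_feats):
        groups.setdefault(find(idx), []).append(f)

    merged: list[FeatureRecord] = []
    n_merged_records = 0
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        start = min(f.start for f in members)
        end = max(f.end for f in members)
        span_matches = [f for f in members if f.start == start and f.end == end]
        sources = sorted({f.source for f in members if f.source})
        kind = members[0].kind
        if span_matches:
            # union equals an existing record: keep its identity
            keep = min(span_matches, key=lambda f: f.id)
            merged.append(replace(keep, source="+".join(sources) or keep.source))
        else:
            n_merged_records += 1
            ids = sorted({f.id for f in members})
            merged.append(
                FeatureRecord(
                    id="m_" + "_".join(ids),
                    replicon=members[0].replicon,
                    start=start,
                    end=end,
                    strand=members[0].strand,
                    kind=kind,
                    source="+".join(sources),
                )
            )
    # resolve id collisions: identical records collapse (merging a set with
    # itself), distinct records with the same id are renamed
    seen: dict[str, FeatureRecord] = {}
    for f in merged:
        if f.id not in seen:
            seen[f.id] = f
        elif seen[f.id] != f:
            k = 2
            while f"{f.id}_{k}" in seen:
                k += 1
            seen[f"{f.id}_{k}"] = replace(f, id=f"{f.id}_{k}")
    out = AnnotationSet(replicons=dict(set_a.replicons), features=list(seen.values()))
    report = MergeReport(
        n_a=n_a,
        n_b=len(set_b.features),
        n_b_overlapping_a=n_b_overlap,
        n_merged_records=n_merged_records,
        n_out=len(out),
    )
    return out, report
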