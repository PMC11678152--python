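"""Cross-strain conservation of intergenic regions.

Reference IGRs are searched against the IGR complement of each comparator
genome with a seeded local aligner (exact k-mer prefilter, optimal local
affine alignment via Biopython). A pair is a reciprocal best hit (RBBH)
when each sequence is the other's highest-scoring hit in its genome and
the hit passes the e-value (< 1e-5) and query-coverage (> 70%) gates. An
IGR is called conserved when it has an RBBH partner in at least
``min_strains`` genomes (default 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align

_COMP = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    subject_genome: str
    score: float
    evalue: float
    query_coverage: float
    identity: float
    subject_strand: str = "+"


@dataclass
class ConservationRecord:
    igr_id: str
    genomes_with_homolog: int
    hits: list[AlignmentHit] = field(default_factory=list)
    conserved: bool = False


class LocalAligner:
    """Seeded local aligner with Karlin–Altschul-style e-values.

    Scoring defaults: match +1, mismatch -2, gap open 5, gap extend 2
    (first gap position costs open+extend, BLAST-style). The e-value is
    ``K * m * n * exp(-lambda * score)`` with configurable (K, lambda);
    only the crossing of the e-value threshold matters downstream, not
    exact BLAST statistics.
    """

    def __init__(
        self,
        match: float = 1.0,
        mismatch: float = -2.0,
        gap_open: float = 5.0,
        gap_extend: float = 2.0,
        K: float = 0.71,
        lam: float = 1.28,
        seed_k: int = 13,
    ):
        self.K = K
        self.lam = lam
        self.seed_k = seed_k
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.match_score = match
        self._aligner.mismatch_score = mismatch
        self._aligner.open_gap_score = -(gap_open + gap_extend)
        self._aligner.extend_gap_score = -gap_extend

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)

    def score(self, q: str, s: str) -> float:
        return float(self._aligner.score(q, s))

    def align(self, q: str, s: str, check_reverse: bool = True):
        """Best local alignment of q against s (both strands).

        Returns (score, evalue, query_coverage, identity, strand).
        """
        if not q or not s:
            raise ValueError("sequences must be non-empty")
        q = q.upper()
        candidates = [(s.upper(), "+")]
        if check_reverse:
            candidates.append((revcomp(s), "-"))
        best = None
        for subj, strand in candidates:
            sc = self.score(q, subj)
            if best is None or sc > best[0]:
                best = (sc, subj, strand)
        sc, subj, strand = best
        if sc <= 0:
            return 0.0, self.evalue(0.0, len(q), len(s)), 0.0, 0.0, strand
        aln = next(iter(self._aligner.align(q, subj)))
        qspan = aln.aligned[0]
        qcov = sum(e - b for b, e in qspan) / len(q)
        matches = 0
        cols = 0
        for (qb, qe), (sb, se) in zip(aln.aligned[0], aln.aligned[1]):
            for i in range(qe - qb):
                cols += 1
                if q[qb + i] == subj[sb + i]:
                    matches += 1
        identity = matches / cols if cols else 0.0
        return sc, self.evalue(sc, len(q), len(subj)), qcov, identity, strand

    # -- seeding ---------------------------------------------------------

    def _kmers(self, seq: str) -> set[str]:
        k = self.seed_k
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _best_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    genome: str,
    aligner: LocalAligner,
    evalue_max: float,
    min_coverage: float,
) -> dict[str, AlignmentHit]:
    """Best hit per query against a subject collection (BLAST-style).

    Candidates sharing an exact seed k-mer with the query (either strand)
    are ranked by score-only alignment; only the top candidate (ties
    broken toward the lowest subject id) is fully aligned and gated on
    e-value and query coverage.
    """
    fwd_kmers = {sid: aligner._kmers(s.upper()) for sid, s in subjects.items()}
    rev_kmers = {sid: aligner._kmers(revcomp(s)) for sid, s in subjects.items()}
    hits: dict[str, AlignmentHit] = {}
    for qid, q in queries.items():
        q = q.upper()
        qk = aligner._kmers(q)
        best = None  # (score, sid, strand)
        for sid in sorted(subjects):
            strands = []
            if qk & fwd_kmers[sid]:
                strands.append("+")
            if qk & rev_kmers[sid]:
                strands.append("-")
            for strand in strands:
                s = subjects[sid] if strand == "+" else revcomp(subjects[sid])
                sc = aligner.score(q, s)
                if best is None or sc > best[0]:
                    best = (sc, sid, strand)
        if best is None:
            continue
        sc, sid, strand = best
        sc, ev, cov, ident, strand = aligner.align(q, subjects[sid])
        if ev < evalue_max and cov > min_coverage:
            hits[qid] = AlignmentHit(qid, sid, genome, sc, ev, cov, ident, strand)
    return hits


def find_rbbh_pairs(
    ref_igrs: dict[str, str],
    other_igrs: dict[str, dict[str, str]],
    aligner: LocalAligner | None = None,
    evalue_max: float = 1e-5,
    min_coverage: float = 0.70,
) -> dict[str, dict[str, AlignmentHit]]:
    """Reciprocal best hits of reference IGRs per comparator genome.

    Returns ``{genome: {ref_igr_id: AlignmentHit}}`` with only reciprocal
    pairs passing the e-value and query-coverage gates in the forward
    direction (coverage is query-relative in each direction).
    """
    if not ref_igrs:
        raise ValueError("reference IGR collection is empty")
    aligner = aligner or LocalAligner()
    out: dict[str, dict[str, AlignmentHit]] = {}
    for genome, subjects in other_igrs.items():
        if not subjects:
            out[genome] = {}
            continue
        fwd = _best_hits(ref_igrs, subjects, genome, aligner, evalue_max, min_coverage)
        rev = _best_hits(subjects, ref_igrs, "ref", aligner, evalue_max, min_coverage)
        pairs = {}
        for qid, hit in fwd.items():
            back = rev.get(hit.subject_id)
            if back is not None and back.subject_id == qid:
                pairs[qid] = hit
        out[genome] = pairs
    return out


def call_conserved(
    ref_igr_ids,
    rbbh: dict[str, dict[str, AlignmentHit]],
    min_strains: int = 4,
) -> tuple[dict[str, ConservationRecord], dict[int, int]]:
    """Conservation records plus the IGR conservation profile.

    The profile is a histogram over conserved IGRs of the number of
    genomes in which each appears.
    """
    if min_strains > len(rbbh):
        raise ValueError(
            f"min_strains={min_strains} exceeds number of genomes ({len(rbbh)})"
        )
    records = {}
    for igr_id in ref_igr_ids:
        hits = [g[igr_id] for g in rbbh.values() if igr_id in g]
        rec = ConservationRecord(
            igr_id=igr_id,
            genomes_with_homolog=len(hits),
            hits=hits,
            conserved=len(hits) >= min_strains,
        )
        records[igr_id] = rec
    profile: dict[int, int] = {}
    for rec in records.values():
        if rec.conserved:
            profile[rec.genomes_with_homolog] = profile.get(rec.genomes_with_homolog, 0) + 1
    return records, profile


def igr_families(rbbh: dict[str, dict[str, AlignmentHit]]) -> list[set[str]]:
    """IGR families as connected components of the RBBH graph.

    Nodes are ``"genome:igr_id"`` (reference genome named ``"ref"``).
    """
    g = nx.Graph()
    for genome, pairs in rbbh.items():
        for qid, hit in pairs.items():
            g.add_edge(f"ref:{qid}", f"{genome}:{hit.subject_id}")
    return [set(c) for c in nx.connected_components(g)]
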