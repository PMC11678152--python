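"""Expression profiling of assembled transcripts.

Covers TPM normalisation, expression breadth (cumulative detection
curves), the reliability filter for putative sRNAs (detected with at
least ``min_reads`` reads in at least ``min_samples`` samples), operon
statistics, and mapping sRNAs into transcription-unit spans and
biosynthetic gene cluster intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, FeatureRecord

CATEGORIES = ("CDS", "tRNA", "rRNA", "antisense", "novel")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million matrix from raw counts and transcript lengths.

    ``rate = count / length``; each sample column is scaled so TPM sums to
    1e6. All-zero samples stay all-zero (with a warning).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths < 1).any() or lengths.isna().any():
        raise ValueError("all transcript lengths must be >= 1")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with no counts: {list(totals.index[zero_cols])}; TPM set to 0"
        )
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def expression_breadth(
    counts: pd.DataFrame, categories: pd.Series | None = None
) -> pd.DataFrame:
    """Cumulative detection curves: fraction expressed in >= k samples.

    A transcript is "expressed in a sample" when its count is > 0. Returns
    a DataFrame indexed by k (1..n_samples) with one column per category
    plus ``all``; empty categories yield NaN columns.
    """
    n_samples = counts.shape[1]
    n_expressed = (counts > 0).sum(axis=1)
    ks = np.arange(1, n_samples + 1)
    out = {}
    groups = {"all": counts.index}
    if categories is not None:
        categories = categories.reindex(counts.index)
        for cat in CATEGORIES:
            groups[cat] = counts.index[categories == cat]
    for name, idx in groups.items():
        if len(idx) == 0:
            out[name] = np.full(n_samples, np.nan)
            continue
        vals = n_expressed.loc[idx].to_numpy()
        out[name] = [(vals >= k).mean() for k in ks]
    return pd.DataFrame(out, index=pd.Index(ks, name="k"))


def filter_putative_srnas(
    counts: pd.DataFrame, min_samples: int = 10, min_reads: int = 20
) -> pd.Series:
    """Reliability flags for putative sRNA transcripts.

    A transcript is retained iff it has at least ``min_reads`` reads in at
    least ``min_samples`` samples (the joint rule; both thresholds
    adjustable).
    """
    return (counts >= min_reads).sum(axis=1) >= min_samples


def summarize_expression(
    counts: pd.DataFrame,
    lengths: pd.Series,
    categories: pd.Series,
    min_samples: int = 10,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Per-transcript expression summary table.

    Columns: category, length, n_samples_expressed, max_tpm,
    reliable_srna (the sRNA filter applied to ``novel`` transcripts).
    """
    tpm = compute_tpm(counts, lengths)
    reliable = filter_putative_srnas(counts, min_samples, min_reads)
    cats = categories.reindex(counts.index)
    return pd.DataFrame(
        {
            "category": cats,
            "length": lengths.reindex(counts.index),
            "n_samples_expressed": (counts > 0).sum(axis=1),
            "max_tpm": tpm.max(axis=1),
            "reliable_srna": reliable & (cats == "novel"),
        }
    )


# ---------------------------------------------------------------------------
# operons / transcription units


@dataclass(frozen=True)
class TranscriptionUnit:
    tu_id: str
    gene_ids: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def kind(self) -> str:
        if self.n_genes == 1:
            return "single"
        return "pair" if self.n_genes == 2 else "multi"


def classify_operons(tus: list[TranscriptionUnit]) -> dict:
    """Operon statistics: class counts, size histogram, mean genes/operon.

    The mean is computed over multi-gene TUs (n_genes >= 2); it is NaN when
    every TU is a singleton.
    """
    if any(tu.n_genes == 0 for tu in tus):
        raise ValueError("transcription units must contain at least one gene")
    sizes = [tu.n_genes for tu in tus]
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    multi = [s for s in sizes if s >= 2]
    return {
        "n_single": sum(1 for tu in tus if tu.kind == "single"),
        "n_pair": sum(1 for tu in tus if tu.kind == "pair"),
        "n_multi": sum(1 for tu in tus if tu.kind == "multi"),
        "size_histogram": dict(sorted(hist.items())),
        "max_genes": max(sizes) if sizes else 0,
        "mean_genes_per_operon": float(np.mean(multi)) if multi else float("nan"),
    }


def tu_spans(
    tus: list[TranscriptionUnit], ann: AnnotationSet
) -> dict[str, tuple[str, int, int, str]]:
    """Genomic span of each TU: (replicon, start, end, strand) from members."""
    by_id = {f.id: f for f in ann.features}
    spans = {}
    for tu in tus:
        feats = [by_id[g] for g in tu.gene_ids if g in by_id]
        if not feats:
            continue
        spans[tu.tu_id] = (
            feats[0].replicon,
            min(f.start for f in feats),
            max(f.end for f in feats),
            feats[0].strand,
        )
    return spans


def map_srnas_to_tus_bgc(
    srnas: list[FeatureRecord],
    tu_span_map: dict[str, tuple[str, int, int, str]],
    bgc_intervals: list[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Membership of sRNAs in TU spans and BGC intervals.

    An sRNA belongs to a TU when its interval lies entirely within the
    TU's genomic span on the same replicon (any strand; antisense
    membership is flagged). It belongs to a BGC when overlapping the BGC
    interval by >= 1 nt. BGC intervals are (replicon, start, end, name),
    0-based half-open.
    """
    rows = []
    known_replicons = {rep for rep, *_ in tu_span_map.values()} | {
        b[0] for b in bgc_intervals
    }
    for s in srnas:
        if known_replicons and s.replicon not in known_replicons:
            warnings.warn(f"sRNA {s.id}: unknown replicon {s.replicon!r}; skipped")
            continue
        tu_hit = ""
        tu_relation = ""
        for tu_id, (rep, b, e, strand) in tu_span_map.items():
            if rep == s.replicon and b <= s.start and s.end <= e:
                tu_hit = tu_id
                tu_relation = "sense" if s.strand == strand else "antisense-to-TU"
                break
        bgc_hit = ""
        rel_pos = np.nan
        for rep, b, e, name in bgc_intervals:
            if rep == s.replicon and s.start < e and b < s.end:
                bgc_hit = name
                rel_pos = (s.start - b) / max(e - b, 1)
                break
        rows.append(
            {
                "srna_id": s.id,
                "replicon": s.replicon,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "tu_id": tu_hit,
                "tu_relation": tu_relation,
                "bgc": bgc_hit,
                "bgc_relative_position": rel_pos,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "srna_id", "replicon", "start", "end", "strand",
            "tu_id", "tu_relation", "bgc", "bgc_relative_position",
        ],
    )
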