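"""Tabular readers/writers for the pipeline's file interfaces.

Counts tables are TSV with columns ``transcript_id, category, length``
followed by one column per sample. Transcription units are TSV with
``tu_id`` and a comma-joined ``gene_ids`` column. BGC intervals are
BED-like (replicon, start, end, name; 0-based half-open).
"""

from __future__ import annotations

import pandas as pd

from .igr_core import IntergenicRegion
from .expression import TranscriptionUnit


def write_igr_table(igrs: list[IntergenicRegion], path, coding_calls=None) -> None:
    coding = {c.igr_id: c for c in coding_calls or []}
    rows = []
    for g in igrs:
        row = {
            "igr_id": g.id,
            "replicon": g.replicon,
            "start": g.start + 1,  # 1-based inclusive for reporting
            "end": g.end,
            "length": g.length,
            "orientation_class": g.orientation_class,
            "left_gene": g.left_gene,
            "right_gene": g.right_gene,
            "gc": round(g.gc, 4),
        }
        if g.id in coding:
            row["longest_orf_aa"] = coding[g.id].longest_orf_aa
            row["is_coding"] = coding[g.id].is_coding
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_igr_fasta(igrs: list[IntergenicRegion], path) -> None:
    with open(path, "w") as fh:
        for g in igrs:
            fh.write(f">{g.id} {g.replicon}:{g.start + 1}-{g.end}\n{g.sequence}\n")


def read_fasta_dict(path) -> dict[str, str]:
    from .annotation_io import load_fasta

    return load_fasta(path)


def read_counts_table(path) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Counts TSV -> (counts, categories, lengths)."""
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    if "category" not in df.columns or "length" not in df.columns:
        raise ValueError("counts table needs 'category' and 'length' columns")
    categories = df["category"]
    lengths = df["length"]
    counts = df.drop(columns=["category", "length"])
    return counts, categories, lengths


def write_counts_table(path, counts, categories, lengths) -> None:
    out = pd.concat(
        [categories.rename("category"), lengths.rename("length"), counts], axis=1
    )
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_design_table(path) -> pd.DataFrame:
    """Design TSV with columns sample, time_point, replicate."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample")


def read_tu_table(path) -> list[TranscriptionUnit]:
    df = pd.read_csv(path, sep="\t")
    return [
        TranscriptionUnit(r.tu_id, tuple(str(r.gene_ids).split(",")))
        for r in df.itertuples()
    ]


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for i, r in enumerate(df.itertuples(index=False)):
        name = str(r[3]) if len(r) > 3 else f"interval_{i}"
        out.append((str(r[0]), int(r[1]), int(r[2]), name))
    return out
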