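"""End-to-end orchestration of the sRNA discovery pipeline on a strain family.

The stages mirror the discovery workflow: IGR extraction for the reference
and each comparator, RBBH conservation calling, comparative structure
screening of conserved IGR families, expression-based sRNA filtering,
growth-curve differential expression, and consensus sRNA-mRNA target
calling with opposite-expression corroboration. The same driver powers
the synthetic end-to-end evaluation and the command-line interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import conservation as cons
from . import diffexp, expression, structure, targets
from .igr_core import IntergenicRegion, extract_igrs
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    StrainFamily,
    evaluate_recovery,
    simulate_counts,
    simulate_strain_family,
)


@dataclass
class PipelineResult:
    igrs: list[IntergenicRegion]
    conservation_records: dict
    conservation_profile: dict[int, int]
    structure_calls: dict[str, list[structure.StructureCall]]
    retained_srnas: set[str] = field(default_factory=set)
    de_results: dict[str, pd.DataFrame] = field(default_factory=dict)
    oe_pairs: pd.DataFrame | None = None
    target_calls: list[targets.TargetCall] = field(default_factory=list)
    recovery: pd.DataFrame | None = None
    truth: GroundTruth | None = None


def conserved_family_alignments(
    ref_igrs: list[IntergenicRegion],
    comparator_igrs: dict[str, list[IntergenicRegion]],
    rbbh: dict[str, dict[str, cons.AlignmentHit]],
    records: dict[str, cons.ConservationRecord],
) -> list[structure.FamilyAlignment]:
    """One reference-anchored alignment per conserved IGR family.

    Each family holds the reference IGR plus its RBBH partner from every
    genome where one exists; partners hit on the reverse strand enter the
    alignment reverse-complemented.
    """
    by_id = {g.id: g for g in ref_igrs}
    comp_by_id = {
        genome: {g.id: g for g in igrs} for genome, igrs in comparator_igrs.items()
    }
    fams = []
    for igr_id, rec in records.items():
        if not rec.conserved:
            continue
        seqs = {igr_id: by_id[igr_id].sequence}
        for hit in rec.hits:
            s = comp_by_id[hit.subject_genome][hit.subject_id].sequence
            if hit.subject_strand == "-":
                s = cons.revcomp(s)
            seqs[f"{hit.subject_genome}:{hit.subject_id}"] = s
        fams.append(structure.align_family(igr_id, seqs, ref_id=igr_id))
    return fams


def run_discovery(
    fam: StrainFamily,
    min_strains: int = 4,
    scan_kwargs: dict | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Conservation + structure screen over a strain family."""
    scan_kwargs = scan_kwargs or {}
    ref_igrs = extract_igrs(fam.ref_annotation, fam.ref_genome)
    ref_seqs = {g.id: g.sequence for g in ref_igrs}
    comp_igrs = {}
    comp_seqs = {}
    for name, (genome, ann) in fam.comparators.items():
        igrs = extract_igrs(ann, genome, id_prefix=f"{name}_IGR")
        comp_igrs[name] = igrs
        comp_seqs[name] = {g.id: g.sequence for g in igrs}
    rbbh = cons.find_rbbh_pairs(ref_seqs, comp_seqs)
    records, profile = cons.call_conserved(list(ref_seqs), rbbh, min_strains=min_strains)
    alignments = conserved_family_alignments(ref_igrs, comp_igrs, rbbh, records)
    rng = np.random.default_rng(seed)
    calls = {
        aln.family_id: structure.scan_igr_windows(aln, rng=rng, **scan_kwargs)
        for aln in alignments
    }
    return PipelineResult(
        igrs=ref_igrs,
        conservation_records=records,
        conservation_profile=profile,
        structure_calls=calls,
    )


def structure_calls_genome_coords(
    result: PipelineResult,
) -> list[dict]:
    """Positive structure calls lifted from IGR to genome coordinates."""
    by_id = {g.id: g for g in result.igrs}
    out = []
    for igr_id, calls in result.structure_calls.items():
        igr = by_id[igr_id]
        for c in calls:
            if c.positive:
                out.append(
                    {
                        "igr_id": igr_id,
                        "replicon": igr.replicon,
                        "start": igr.start + c.window_start,
                        "end": igr.start + c.window_end,
                        "strand": c.strand,
                        "p_structured": c.p_structured,
                    }
                )
    return out


def run_end_to_end(
    cfg: SimulationConfig,
    min_strains: int = 4,
    scan_kwargs: dict | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """simulate -> igrs -> conserve -> scan -> filter -> de -> targets."""
    seed = cfg.seed if seed is None else seed
    fam = simulate_strain_family(cfg)
    result = run_discovery(fam, min_strains=min_strains, scan_kwargs=scan_kwargs, seed=seed)
    result.truth = fam.truth

    counts, design, categories, lengths, mrna_seqs = simulate_counts(
        cfg, fam.srna_seqs, fam.truth
    )
    novel = categories.index[categories == "novel"]
    retained = expression.filter_putative_srnas(
        counts.loc[novel], min_samples=10, min_reads=20
    )
    result.retained_srnas = set(retained.index[retained])

    de = diffexp.de_test(counts, design["time_point"], reference=cfg.time_points[0])
    result.de_results = de
    srna_ids = [i for i in counts.index if categories[i] == "novel"]
    mrna_ids = [i for i in counts.index if categories[i] == "CDS"]
    de_srna = {k: v.loc[srna_ids] for k, v in de.items()}
    de_mrna = {k: v.loc[mrna_ids] for k, v in de.items()}
    oe = diffexp.opposite_expression(de_srna, de_mrna, min_contrasts=2)
    result.oe_pairs = oe

    # target prediction: DE sRNAs that passed the reliability filter
    de_srna_ids = sorted(
        {
            fid
            for tbl in de_srna.values()
            for fid in tbl.index[tbl["call"] != "ns"]
        }
        & result.retained_srnas
        & set(fam.srna_seqs)
    )
    srna_seqs = {i: fam.srna_seqs[i] for i in de_srna_ids}
    preds, _excluded = targets.predict_targets(srna_seqs, mrna_seqs)
    rng = np.random.default_rng(seed + 13)
    calls = targets.call_targets(preds, srna_seqs, mrna_seqs, oe_pairs=oe, rng=rng)
    result.target_calls = calls

    outputs = {
        "conserved_igrs": {
            i for i, r in result.conservation_records.items() if r.conserved
        },
        "structure_calls": structure_calls_genome_coords(result),
        "retained_srnas": result.retained_srnas,
        "de_calls": {
            fid for tbl in de.values() for fid in tbl.index[tbl["call"] != "ns"]
        },
        "target_calls": [
            (c.srna_id, c.mrna_id)
            for c in calls
            if c.consensus and c.oe_contrast_count >= 2
        ],
    }
    result.recovery = evaluate_recovery(outputs, fam.truth)
    return result
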