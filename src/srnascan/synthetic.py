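"""Synthetic study-condition generator with ground truth.

Two generators emulate the study design end to end:

* :func:`simulate_strain_family` — a GC-rich (72%, Streptomyces-like)
  reference genome with non-overlapping genes of random strand, plus
  comparator strains derived by per-site substitution (default 5%) with
  single-nucleotide indels at 10% of the substitution rate. Selected
  IGRs receive planted structured sRNAs (stacked GC-rich hairpins, stems
  at least ``hairpin_stem`` bp); inside planted loci the divergence is
  reduced by ``conserved_locus_divergence_factor`` and stem pairs undergo
  compensatory (pair-preserving) swaps so that covariation-aware
  detection is exercised.

* :func:`simulate_counts` — negative-binomial count matrices over four
  time points x replicates. A subset of planted sRNAs is differentially
  expressed at the late time points; each has a planted target mRNA
  carrying an exact reverse-complement site and the opposite expression
  shift. Decoy mRNAs have neither.

Both are fully deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, FeatureRecord
from .igr_core import extract_igrs

_DNA = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_strains: int = 8
    genome_len: int = 200_000
    n_genes: int = 150
    gene_len_range: tuple[int, int] = (350, 750)
    igr_len_range: tuple[int, int] = (100, 450)
    gc: float = 0.72
    divergence: float = 0.05
    conserved_locus_divergence_factor: float = 0.2
    indel_fraction: float = 0.10  # of the substitution rate, split ins/del
    n_planted_srnas: int = 20
    hairpin_stem: int = 10
    n_hairpins: int = 2
    stem_extra_range: tuple[int, int] = (4, 8)  # stems: hairpin_stem + U[lo, hi]
    hairpin_loop: int = 4
    hairpin_spacer: int = 5
    #: per-pair, per-strain probability of a pair-preserving stem swap;
    #: kept below the background substitution rate so planted loci remain
    #: less diverged than the background in raw identity
    compensatory_swap_prob: float = 0.04
    # expression design
    time_points: tuple[str, ...] = ("24h", "48h", "72h", "96h")
    #: distinct 2-contrast expression programs; planted pairs rotate over
    #: (pattern x sign) so co-regulated pairs rarely share a full program
    de_patterns: tuple[tuple[str, str], ...] = (
        ("72h", "96h"),
        ("48h", "72h"),
        ("48h", "96h"),
    )
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    planted_log2fc: float = 3.0
    site_len: int = 20
    n_target_pairs: int = 10
    n_decoy_mrnas: int = 500
    mrna_len: int = 200
    #: decoy/target transcripts use a neutral (uniform) composition so
    #: that chance complementarity against the GC-rich sRNAs leaves an
    #: informative negative control for the interaction engine
    mrna_gc: float = 0.50
    n_noise_srnas: int = 20

    def validate(self) -> None:
        if self.n_strains < 1 or self.n_genes < 2 or self.n_planted_srnas < 0:
            raise ValueError("counts must be positive")
        for p in (self.divergence, self.conserved_locus_divergence_factor, self.gc):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_target_pairs > self.n_planted_srnas:
            raise ValueError("cannot plant more target pairs than sRNAs")


@dataclass
class GroundTruth:
    planted_srna_loci: list[dict] = field(default_factory=list)
    planted_conserved_igrs: list[str] = field(default_factory=list)
    planted_de_features: dict[str, float] = field(default_factory=dict)
    planted_target_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        data = asdict(self)
        data["planted_target_pairs"] = [list(p) for p in self.planted_target_pairs]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["planted_target_pairs"] = [tuple(p) for p in data["planted_target_pairs"]]
        return cls(**data)


@dataclass
class StrainFamily:
    config: SimulationConfig
    ref_genome: dict[str, str]
    ref_annotation: AnnotationSet
    comparators: dict[str, tuple[dict[str, str], AnnotationSet]]
    truth: GroundTruth
    srna_seqs: dict[str, str] = field(default_factory=dict)
    #: per strain: planted-locus coordinates (indel-adjusted)
    srna_locus_coords: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=dict
    )
    #: per sRNA: stem pair positions (ref coords) for compensatory swaps
    _stem_pairs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    return rng.choice(_DNA, size=n, p=[at, gc / 2, gc / 2, at])


def _build_srna(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, list[tuple[int, int]]]:
    """A structured sRNA: stacked GC-rich hairpins; returns seq + pair coords."""
    parts: list[str] = []
    pairs: list[tuple[int, int]] = []
    pos = 0
    lo, hi = cfg.stem_extra_range
    for h in range(cfg.n_hairpins):
        stem_len = cfg.hairpin_stem + int(rng.integers(lo, hi + 1))
        stem = "".join(rng.choice(_DNA, stem_len, p=[0.05, 0.45, 0.45, 0.05]))
        loop = "".join(_random_seq(rng, cfg.hairpin_loop, cfg.gc))
        rc = stem.translate(_COMP)[::-1]
        parts.append(stem + loop + rc)
        total = 2 * stem_len + cfg.hairpin_loop
        for k in range(stem_len):
            pairs.append((pos + k, pos + total - 1 - k))
        pos += total
        if h < cfg.n_hairpins - 1:
            spacer = "".join(_random_seq(rng, cfg.hairpin_spacer, cfg.gc))
            parts.append(spacer)
            pos += cfg.hairpin_spacer
    return "".join(parts), pairs


def simulate_strain_family(cfg: SimulationConfig) -> StrainFamily:
    """Reference genome + diverged comparator strains with planted sRNAs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    seq = _random_seq(rng, cfg.genome_len, cfg.gc)

    # place genes sequentially: igr-gap, gene, igr-gap, gene, ...
    features: list[FeatureRecord] = []
    pos = 0
    for i in range(cfg.n_genes):
        gap = int(rng.integers(*cfg.igr_len_range))
        glen = int(rng.integers(*cfg.gene_len_range))
        start = pos + gap
        end = start + glen
        if end > cfg.genome_len:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            FeatureRecord(f"gene_{i:04d}", "chr", start, end, strand, "CDS", "sim")
        )
        pos = end
    if len(features) < cfg.n_genes:
        raise ValueError(
            f"genome_len {cfg.genome_len} too small for {cfg.n_genes} genes"
        )
    ann = AnnotationSet(replicons={"chr": cfg.genome_len}, features=features)

    # plant structured sRNAs in the larger inter-gene gaps
    gaps = []
    for a, b in zip(features, features[1:]):
        gaps.append((a.end, b.start))
    srna_seqs: dict[str, str] = {}
    stem_pairs: dict[str, list[tuple[int, int]]] = {}
    loci: list[dict] = []
    min_len_needed = (
        cfg.n_hairpins * (2 * (cfg.hairpin_stem + cfg.stem_extra_range[1]) + cfg.hairpin_loop)
        + (cfg.n_hairpins - 1) * cfg.hairpin_spacer
        + 20
    )
    eligible = [g for g in gaps if g[1] - g[0] >= min_len_needed]
    if len(eligible) < cfg.n_planted_srnas:
        raise ValueError("not enough IGRs long enough to host planted sRNAs")
    chosen = [
        eligible[i]
        for i in rng.choice(len(eligible), cfg.n_planted_srnas, replace=False)
    ]
    for k, (gs, ge) in enumerate(sorted(chosen)):
        srna, pairs = _build_srna(rng, cfg)
        offset = int(rng.integers(gs + 10, ge - len(srna) - 9))
        seq[offset : offset + len(srna)] = list(srna)
        sid = f"srna_{k:03d}"
        srna_seqs[sid] = srna
        stem_pairs[sid] = [(offset + a, offset + b) for a, b in pairs]
        loci.append(
            {"srna_id": sid, "replicon": "chr", "start": offset, "end": offset + len(srna)}
        )
    genome = {"chr": "".join(seq)}

    # identify host IGRs for the planted loci
    igrs = extract_igrs(ann, genome)
    for locus in loci:
        locus["igr_id"] = next(
            (
                g.id
                for g in igrs
                if g.start <= locus["start"] and locus["end"] <= g.end
            ),
            "",
        )
    truth = GroundTruth(
        planted_srna_loci=loci,
        planted_conserved_igrs=sorted({l["igr_id"] for l in loci if l["igr_id"]}),
    )

    planted_mask = np.zeros(cfg.genome_len, dtype=bool)
    for locus in loci:
        planted_mask[locus["start"] : locus["end"]] = True
    comparators: dict[str, tuple[dict[str, str], AnnotationSet]] = {}
    sub_p = cfg.divergence
    sub_p_cons = cfg.divergence * cfg.conserved_locus_divergence_factor
    indel_p = cfg.divergence * cfg.indel_fraction / 2.0  # each of ins / del
    bases = "ACGT"
    boundaries: dict[int, list[tuple[str, str]]] = {}
    for f in features:
        boundaries.setdefault(f.start, []).append((f.id, "start"))
        boundaries.setdefault(f.end, []).append((f.id, "end"))
    for locus in loci:
        boundaries.setdefault(locus["start"], []).append((locus["srna_id"], "start"))
        boundaries.setdefault(locus["end"], []).append((locus["srna_id"], "end"))
    srna_locus_coords: dict[str, dict[str, tuple[int, int]]] = {}
    for s in range(cfg.n_strains):
        srng = np.random.default_rng(cfg.seed + 1000 + s)
        out: list[str] = []
        new_coords: dict[str, dict[str, int]] = {}
        swapped: set[int] = set()
        # decide compensatory swaps for this strain up front (a swap is a
        # mutation, so a zero-divergence strain gets none)
        if cfg.divergence > 0:
            for sid, plist in stem_pairs.items():
                for a, b in plist:
                    if srng.random() < cfg.compensatory_swap_prob:
                        swapped.add(a)
                        swapped.add(b)
        i = 0
        n = cfg.genome_len
        while i < n:
            if i in boundaries:
                for fid, which in boundaries[i]:
                    new_coords.setdefault(fid, {})[which] = len(out)
            c = seq[i]
            if planted_mask[i]:
                if i in swapped:
                    # pair-preserving swap: complement both partners
                    # (e.g. a G:C pair becomes C:G), keeping the helix intact
                    out.append(str(c).translate(_COMP))
                    i += 1
                    continue
                if srng.random() < sub_p_cons:
                    out.append(srng.choice([x for x in bases if x != c]))
                else:
                    out.append(str(c))
                i += 1
                continue
            r = srng.random()
            if r < indel_p:  # deletion of this nucleotide
                i += 1
                continue
            if r < 2 * indel_p:  # insertion before this nucleotide
                out.append(str(srng.choice(_DNA)))
            if srng.random() < sub_p:
                out.append(srng.choice([x for x in bases if x != c]))
            else:
                out.append(str(c))
            i += 1
        if n in boundaries:
            for fid, which in boundaries[n]:
                new_coords.setdefault(fid, {})[which] = len(out)
        strain_seq = "".join(out)
        strain_feats = []
        for f in features:
            coords = new_coords.get(f.id, {})
            ns, ne = coords.get("start"), coords.get("end")
            if ns is None or ne is None or ne <= ns:
                continue
            strain_feats.append(
                FeatureRecord(f.id, "chr", ns, ne, f.strand, f.kind, "sim")
            )
        strain_ann = AnnotationSet(
            replicons={"chr": len(strain_seq)}, features=strain_feats
        )
        strain_name = f"strain_{s:02d}"
        comparators[strain_name] = ({"chr": strain_seq}, strain_ann)
        srna_locus_coords[strain_name] = {
            locus["srna_id"]: (
                new_coords[locus["srna_id"]]["start"],
                new_coords[locus["srna_id"]]["end"],
            )
            for locus in loci
        }

    return StrainFamily(
        config=cfg,
        ref_genome=genome,
        ref_annotation=ann,
        comparators=comparators,
        truth=truth,
        srna_seqs=srna_seqs,
        srna_locus_coords=srna_locus_coords,
        _stem_pairs=stem_pairs,
    )


def simulate_counts(
    cfg: SimulationConfig,
    srna_seqs: dict[str, str],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, dict[str, str]]:
    """NB count matrix with planted DE sRNAs and anti-correlated targets.

    Returns (counts, design, categories, lengths, mrna_seqs) and updates
    ``truth`` with the planted DE features and target pairs. Counts use a
    feature-specific log-normal base mean and NB dispersion
    ``cfg.nb_dispersion``; each planted-DE sRNA is shifted by
    ``2**planted_log2fc`` at the late time points and its target mRNA by
    the inverse. Target mRNAs carry an exact reverse-complement site of
    length ``site_len`` from their sRNA. Additional sparse "noise" sRNAs
    exercise the reliability filter.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 777)
    srna_ids = sorted(srna_seqs)
    de_ids = [
        srna_ids[i]
        for i in rng.choice(len(srna_ids), cfg.n_target_pairs, replace=False)
    ]

    mrna_seqs: dict[str, str] = {}
    target_pairs: list[tuple[str, str]] = []
    for k, sid in enumerate(de_ids):
        mid = f"mrna_target_{k:03d}"
        body = "".join(_random_seq(rng, cfg.mrna_len, cfg.mrna_gc))
        sseq = srna_seqs[sid]
        site_at = int(rng.integers(0, len(sseq) - cfg.site_len + 1))
        site = sseq[site_at : site_at + cfg.site_len].translate(_COMP)[::-1]
        mid_pos = cfg.mrna_len // 2
        mrna_seqs[mid] = body[:mid_pos] + site + body[mid_pos + cfg.site_len :]
        target_pairs.append((sid, mid))
    for k in range(cfg.n_decoy_mrnas):
        mrna_seqs[f"mrna_decoy_{k:04d}"] = "".join(
            _random_seq(rng, cfg.mrna_len, cfg.mrna_gc)
        )

    noise_ids = [f"noise_srna_{k:03d}" for k in range(cfg.n_noise_srnas)]
    feature_ids = srna_ids + noise_ids + sorted(mrna_seqs)
    categories = pd.Series(
        ["novel"] * (len(srna_ids) + len(noise_ids)) + ["CDS"] * len(mrna_seqs),
        index=feature_ids,
        name="category",
    )
    lengths = pd.Series(
        [len(srna_seqs[i]) for i in srna_ids]
        + [80] * len(noise_ids)
        + [cfg.mrna_len] * len(mrna_seqs),
        index=feature_ids,
        name="length",
    )

    base = pd.Series(
        np.exp(rng.normal(np.log(150.0), 1.0, len(feature_ids))), index=feature_ids
    )
    # planted sRNAs are well expressed so that a DE-downshifted sRNA
    # (mean / 2**lfc at late time points) still clears the read filter
    base[srna_ids] = np.exp(rng.normal(np.log(300.0), 0.4, len(srna_ids)))
    base[noise_ids] = np.exp(rng.normal(np.log(2.0), 0.5, len(noise_ids)))

    fold = 2.0**cfg.planted_log2fc
    de_features: dict[str, float] = {}
    de_program: dict[str, tuple[str, ...]] = {}
    for k, (sid, mid) in enumerate(target_pairs):
        pattern = cfg.de_patterns[(k // 2) % len(cfg.de_patterns)]
        sign = 1.0 if k % 2 == 0 else -1.0
        de_features[sid] = sign * cfg.planted_log2fc
        de_features[mid] = -sign * cfg.planted_log2fc
        de_program[sid] = pattern
        de_program[mid] = pattern

    samples = []
    design_rows = []
    for tp in cfg.time_points:
        for r in range(1, cfg.n_replicates + 1):
            samples.append(f"{tp}_r{r}")
            design_rows.append({"sample": f"{tp}_r{r}", "time_point": tp, "replicate": r})
    design = pd.DataFrame(design_rows).set_index("sample")

    r_disp = 1.0 / cfg.nb_dispersion
    counts = np.zeros((len(feature_ids), len(samples)), dtype=int)
    for si, sample in enumerate(samples):
        tp = design.loc[sample, "time_point"]
        mu = base.copy()
        for fid, lfc in de_features.items():
            if tp in de_program[fid]:
                mu[fid] = base[fid] * (fold if lfc > 0 else 1.0 / fold)
        p = r_disp / (r_disp + mu.to_numpy())
        counts[:, si] = rng.negative_binomial(r_disp, p)
    counts_df = pd.DataFrame(counts, index=feature_ids, columns=samples)

    truth.planted_de_features = de_features
    truth.planted_target_pairs = target_pairs
    return counts_df, design, categories, lengths, mrna_seqs


# ---------------------------------------------------------------------------
# recovery evaluation


def _interval_recovered(locus: dict, calls: list[dict]) -> bool:
    need = 0.5 * (locus["end"] - locus["start"])
    for c in calls:
        if c.get("replicon", locus.get("replicon")) != locus.get("replicon"):
            continue
        ov = min(locus["end"], c["end"]) - max(locus["start"], c["start"])
        if ov >= need:
            return True
    return False


def evaluate_recovery(outputs: dict, truth: GroundTruth) -> pd.DataFrame:
    """Precision/recall/F1 per pipeline stage against the ground truth.

    ``outputs`` may contain any of:

    * ``conserved_igrs``: set of IGR ids called conserved
    * ``structure_calls``: list of dicts with replicon/start/end (genome coords)
    * ``retained_srnas``: set of sRNA feature ids passing the filter
    * ``de_calls``: set of feature ids called DE in any contrast
    * ``target_calls``: list of (srna_id, mrna_id) consensus+OE pairs

    Interval stages count a planted locus as recovered when a call covers
    at least 50% of its length; a call is a true positive when it
    recovers some planted locus.
    """
    if not truth.planted_srna_loci and not truth.planted_de_features:
        raise ValueError("empty ground truth")
    rows = []

    def pr(n_tp_called, n_called, n_tp_truth, n_truth, stage):
        precision = n_tp_called / n_called if n_called else float("nan")
        recall = n_tp_truth / n_truth if n_truth else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall)
            if n_called and n_truth and (precision + recall) > 0
            else float("nan")
        )
        rows.append(
            {
                "stage": stage,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "n_called": n_called,
                "n_truth": n_truth,
            }
        )

    if "conserved_igrs" in outputs:
        called = set(outputs["conserved_igrs"])
        t = set(truth.planted_conserved_igrs)
        tp = len(called & t)
        pr(tp, len(called), tp, len(t), "conservation")
    if "structure_calls" in outputs:
        calls = outputs["structure_calls"]
        loci = truth.planted_srna_loci
        rec = [l for l in loci if _interval_recovered(l, calls)]
        tp_calls = sum(
            1
            for c in calls
            if any(_interval_recovered(l, [c]) for l in loci)
        )
        pr(tp_calls, len(calls), len(rec), len(loci), "structure")
    if "retained_srnas" in outputs:
        called = set(outputs["retained_srnas"])
        t = {l["srna_id"] for l in truth.planted_srna_loci}
        pr(len(called & t), len(called), len(called & t), len(t), "srna_filter")
    if "de_calls" in outputs:
        called = set(outputs["de_calls"])
        t = set(truth.planted_de_features)
        pr(len(called & t), len(called), len(called & t), len(t), "de")
    if "target_calls" in outputs:
        called = {tuple(p) for p in outputs["target_calls"]}
        t = set(truth.planted_target_pairs)
        pr(len(called & t), len(called), len(called & t), len(t), "targets")
    return pd.DataFrame(rows)
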