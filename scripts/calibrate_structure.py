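"""One-time calibration of the structure screen's logistic classifier.

Generates a synthetic strain family under the screen's default study
conditions, runs conservation + family alignment, extracts per-window
(z, sci) features on both strands, labels windows by overlap with the
planted structured loci, and fits a logistic regression on (-z, sci).
The rounded coefficients are frozen as ``srnascan.structure.DEFAULT_LOGISTIC``.

Usage: python scripts/calibrate_structure.py [--seed 20240]
"""

import argparse

import numpy as np
from sklearn.linear_model import LogisticRegression

from srnascan import conservation as cons
from srnascan import structure
from srnascan.igr_core import extract_igrs
from srnascan.pipeline import conserved_family_alignments
from srnascan.synthetic import SimulationConfig, simulate_strain_family


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, n_genes=225)
    fam = simulate_strain_family(cfg)
    ref_igrs = extract_igrs(fam.ref_annotation, fam.ref_genome)
    ref_seqs = {g.id: g.sequence for g in ref_igrs}
    comp_igrs = {}
    comp_seqs = {}
    for name, (genome, ann) in fam.comparators.items():
        igrs = extract_igrs(ann, genome, id_prefix=f"{name}_IGR")
        comp_igrs[name] = igrs
        comp_seqs[name] = {g.id: g.sequence for g in igrs}
    rbbh = cons.find_rbbh_pairs(ref_seqs, comp_seqs)
    records, _ = cons.call_conserved(list(ref_seqs), rbbh, min_strains=4)
    alignments = conserved_family_alignments(ref_igrs, comp_igrs, rbbh, records)

    igr_by_id = {g.id: g for g in ref_igrs}
    loci_by_igr = {}
    for locus in fam.truth.planted_srna_loci:
        loci_by_igr.setdefault(locus["igr_id"], []).append(locus)

    rng = np.random.default_rng(args.seed)
    X, y = [], []
    for aln in alignments:
        igr = igr_by_id[aln.family_id]
        loci = loci_by_igr.get(aln.family_id, [])
        for f in structure.window_features(aln, rng=rng):
            w0 = igr.start + f["start"]
            w1 = igr.start + f["end"]
            label = 0
            for locus in loci:
                ov = min(w1, locus["end"]) - max(w0, locus["start"])
                if ov >= 0.5 * (locus["end"] - locus["start"]):
                    label = 1
            X.append([-f["z"], f["sci"]])
            y.append(label)
    X = np.asarray(X)
    y = np.asarray(y)
    print(f"windows: {len(y)}  positives: {y.sum()}")
    lr = LogisticRegression(C=1.0).fit(X, y)
    a, b = lr.coef_[0]
    c = lr.intercept_[0]
    print(f"fitted  a={a:.3f}  b={b:.3f}  c={c:.3f}")
    print(f"freeze as DEFAULT_LOGISTIC = ({a:.2f}, {b:.2f}, {c:.2f})")
    # resubstitution check at p > 0.5
    p = lr.predict_proba(X)[:, 1]
    pos = p > 0.5
    print(
        f"window-level: sens {pos[y == 1].mean():.3f}  "
        f"spec {1 - pos[y == 0].mean():.3f}"
    )


if __name__ == "__main__":
    main()
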