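"""Conserved noncoding elements and binding-site turnover.

Detects avian (>= 10 species) and tetrapod (>= 3 species) CNEs from the
simulated multi-species alignment at the >70% identity / >= 100 bp
criterion with exons masked, annotates which planted SNP positions fall
inside them, and scores a reference-vs-alternate allele of one CNE for
gained and lost transcription-factor binding motifs.
"""

import argparse
import pathlib

import pandas as pd

from piedmap import cneseek

# small built-in JASPAR-style motif set (synthetic demonstration motifs)
DEMO_MOTIFS = """\
>M001 boxA
A [ 12  1  0 14  1  0 ]
C [  1  1  0  0  1  2 ]
G [  1 12 14  0  1  0 ]
T [  0  0  0  0 11 12 ]
>M002 boxB
A [  0 13  0  1 13 ]
C [ 13  0  0  0  1 ]
G [  1  1 13  0  0 ]
T [  0  0  1 13  0 ]
"""


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=pathlib.Path, default=pathlib.Path("results/data"))
    ap.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    block = cneseek.read_alignment(args.datadir / "alignment.fa",
                                   args.datadir / "alignment_species.tsv")
    exons = []
    with open(args.datadir / "exons.bed") as fh:
        for line in fh:
            f = line.split("\t")
            exons.append((int(f[1]), int(f[2])))
    cnes = cneseek.detect_cnes(block, exons)
    cneseek.write_cne_bed(cnes, block.ref_name, args.outdir / "cnes.bed")
    for c in cnes:
        print(f"{c.clade} CNE {c.start}-{c.end} ({c.end - c.start} bp, "
              f">= {c.supporting_species} species, "
              f"mean identity {c.mean_identity:.2f})")

    # SNPs at the centre of each detected element stand in for candidates
    snp_positions = [(c.start + c.end) // 2 for c in cnes]
    annotated = cneseek.snps_in_cnes(snp_positions, cnes)
    annotated.to_csv(args.outdir / "snps_in_cnes.tsv", sep="\t", index=False)
    print(f"{len(annotated)} SNP-in-CNE annotations")

    motif_path = args.outdir / "demo_motifs.jaspar"
    motif_path.write_text(DEMO_MOTIFS)
    pwms = cneseek.read_jaspar_pwms(motif_path)
    if cnes:
        c = cnes[0]
        lo, hi = c.start - block.ref_start, c.end - block.ref_start
        ref_seq = block.ref_seq[lo:hi]
        # mutate the best occurrence of the first motif at the position
        # where the substitution costs the score most
        pwm = pwms[0]
        best = max(range(len(ref_seq) - pwm.length + 1),
                   key=lambda o: pwm.score(ref_seq[o : o + pwm.length])[1])
        info = pwm.information
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        drops = [
            info[j] * (pwm.matrix[j, base_idx[ref_seq[best + j]]] - pwm.matrix[j].min())
            for j in range(pwm.length)
        ]
        j = int(max(range(pwm.length), key=drops.__getitem__))
        mid = best + j
        alt_seq = (ref_seq[:mid] + "ACGT"[int(pwm.matrix[j].argmin())]
                   + ref_seq[mid + 1 :])
        gained, lost = cneseek.tfbs_gain_loss(ref_seq, alt_seq, pwms,
                                              core_cutoff=0.70, matrix_cutoff=0.70)
        pd.concat([gained.assign(change="gained"), lost.assign(change="lost")],
                  ignore_index=True).to_csv(args.outdir / "tfbs_gain_loss.tsv",
                                            sep="\t", index=False)
        print(f"Allele swap at CNE position {c.start + mid}: "
              f"{len(gained)} motifs gained, {len(lost)} lost")


if __name__ == "__main__":
    main()
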