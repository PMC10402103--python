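"""Allele-frequency differentiation between piebald-like cases and
background genomes.

Genotype-likelihood LRT per site with a Bonferroni genome-wide
threshold, the fixation-based candidate-SNP filter (alt allele fixed in
cases, never homozygous in background), and haplotype-group delineation
from shared homozygous-alt site sets.
"""

import argparse
import pathlib

from piedmap import popdiff


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--datadir", type=pathlib.Path, default=pathlib.Path("results/data"))
    ap.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sites = popdiff.read_vcf(args.datadir / "panel.vcf",
                             args.datadir / "panel_samples.tsv")
    results = popdiff.pfst_scan(sites, alpha=args.alpha)
    results.to_csv(args.outdir / "pfst_sites.tsv", sep="\t", index=False)
    thr = popdiff.genomewide_threshold(len(sites), args.alpha)
    n_sig = int(results["significant"].sum())
    print(f"{len(sites)} sites tested; Bonferroni threshold {thr:.3g}; "
          f"{n_sig} genome-wide significant")

    candidates = popdiff.candidate_snp_filter(sites)
    candidates.to_csv(args.outdir / "candidate_snps.tsv", sep="\t", index=False)
    with open(args.outdir / "candidate_snps.bed", "w") as fh:
        for row in candidates.itertuples(index=False):
            fh.write(f"{row.scaffold}\t{row.pos - 1}\t{row.pos}\tcandidate\n")
    span = (f"{candidates['pos'].min()}-{candidates['pos'].max()}"
            if len(candidates) else "none")
    print(f"{len(candidates)} candidate SNPs (fixed in cases, never hom-alt "
          f"in background), spanning {span}")

    sig_sites = [s for s, ok in zip(sites, results["significant"]) if ok]
    popdiff.genotype_matrix(sig_sites).to_csv(
        args.outdir / "genotype_matrix.tsv", sep="\t")
    groups = popdiff.delineate_groups(sig_sites, min_defining_snps=3)
    with open(args.outdir / "haplotype_groups.tsv", "w") as fh:
        fh.write("group_id\tsample\tn_defining_snps\tspan\n")
        for g in groups:
            for m in g.members:
                fh.write(f"{g.group_id}\t{m}\t{len(g.defining_snps)}\t"
                         f"{g.span[0]}:{g.span[1]}-{g.span[2]}\n")
    for g in groups:
        print(f"Haplotype group {g.group_id}: {len(g.members)} samples, "
              f"{len(g.defining_snps)} defining SNPs at "
              f"{g.span[0]}:{g.span[1]}-{g.span[2]}")


if __name__ == "__main__":
    main()
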