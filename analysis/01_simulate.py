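"""Generate every synthetic input dataset, with planted truth sidecars.

Emulates the study's five input classes at desk scale: an F2 intercross
genotyped at mapped markers with a planted major-effect QTL, a piebald
case vs background variant panel with a planted fixed haplotype, a
multi-species alignment with planted conserved noncoding elements, a
read-depth track with a planted 37-kb heterozygous tandem duplication,
and RNA-seq allele counts with planted copy-specific SNPs. Writes the
files downstream scripts consume under results/data/ plus a JSON truth
sidecar per simulation.
"""

import argparse
import pathlib

from piedmap import cneseek, cross, simdata
from piedmap.simdata import CNEPlant, CrossSpec, DupPlantSpec, PanelSpec, QTLSpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    # F2 cross: 150 birds, 5 chromosomes x 50 markers, QTL on chromosome 3
    spec = CrossSpec(
        n_individuals=150,
        chromosomes=[(50, 100.0)] * 5,
        genotyping_error_rate=0.005,
        missing_rate=0.05,
        seed=args.seed,
    )
    truth, observed, true_map = simdata.sim_f2_cross(spec)
    qtl = QTLSpec(chromosome=3, position_cM=50.0, additive_effect=0.25,
                  dominance_effect=0.0, residual_sd=0.16)
    pheno, info = simdata.sim_phenotypes(truth, true_map, [qtl], seed=args.seed)
    cross.write_genotypes_tsv(observed, out / "f2_genotypes.tsv")
    cross.write_genotypes_tsv(truth, out / "f2_genotypes_truth.tsv")
    cross.write_map_tsv(true_map, out / "f2_true_map.tsv")
    pheno.to_csv(out / "f2_phenotypes.tsv", sep="\t")
    simdata.write_truth_json(
        {"qtl": vars(qtl), **info, "spec": {"n": spec.n_individuals}},
        out / "f2_truth.json",
    )
    print(f"F2 cross: {observed.n_markers} markers x {observed.n_individuals} birds; "
          f"planted QTL chr3@50cM, realized PVE {info['realized_pve']:.3f}")

    # variant panel: 20 piebald cases vs 30 background, 5 planted fixed SNPs
    panel = PanelSpec(n_case=20, n_background=30, n_sites=2000,
                      planted_sites=tuple(range(1000, 1005)),
                      gl_error_rate=0.02, seed=args.seed)
    sites = simdata.sim_population_sites(panel)
    simdata.write_vcf(sites, out / "panel.vcf")
    simdata.write_sample_sheet(sites, out / "panel_samples.tsv")
    simdata.write_truth_json(
        {"planted_positions": [sites[i].pos for i in panel.planted_sites]},
        out / "panel_truth.json",
    )
    print(f"Panel: {panel.n_sites} sites, planted fixed haplotype at "
          f"{[sites[i].pos for i in panel.planted_sites]}")

    # alignment: 15 avian + 6 tetrapod species, two planted CNEs, one exon
    plants = [CNEPlant(12_000, 12_180, 0.95, n_avian=12, n_tetrapod=4),
              CNEPlant(30_000, 30_150, 0.92, n_avian=11, n_tetrapod=0)]
    exons = [(20_000, 21_000)]
    block, exon_bed = simdata.sim_alignment(
        15, 6, plants, background_identity=0.40, exons=exons,
        seed=args.seed, length=50_000,
    )
    cneseek.write_alignment(block, out / "alignment.fa", out / "alignment_species.tsv")
    with open(out / "exons.bed", "w") as fh:
        for s, e in exon_bed:
            fh.write(f"{block.ref_name}\t{s}\t{e}\texon\n")
    simdata.write_truth_json({"planted_cnes": [vars(p) for p in plants]},
                             out / "alignment_truth.json")
    print(f"Alignment: 50 kb x 21 species, planted CNEs at "
          f"{[(p.start, p.end) for p in plants]}")

    # coverage: 1 Mb scaffold, planted 37-kb het tandem duplication at 30x
    dup = DupPlantSpec(genome_length=1_000_000, window=5_000,
                       dup_interval=(500_000, 537_000),
                       copy_state="heterozygous", mean_depth=30.0,
                       noise_model="poisson", seed=args.seed)
    track, evidence = simdata.sim_coverage(dup)
    simdata.write_coverage_tsv(track, out / "coverage.tsv")
    evidence["discordant"].to_csv(out / "evidence_discordant.tsv", sep="\t", index=False)
    evidence["softclip"].to_csv(out / "evidence_softclip.tsv", sep="\t", index=False)
    simdata.write_truth_json({"dup_interval": dup.dup_interval,
                              "copy_state": dup.copy_state}, out / "coverage_truth.json")
    print(f"Coverage: 1 Mb at 30x, planted {dup.copy_state} dup "
          f"{dup.dup_interval[0]}-{dup.dup_interval[1]}")

    # RNA-seq allele counts: 40 SNPs, 6 planted copy-specific
    planted_cs = set(range(0, 6))
    counts, ase_truth = simdata.sim_allele_counts(
        40, white_depth=60, pigmented_depth=60, copy_specific=planted_cs,
        seed=args.seed,
    )
    counts.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
    simdata.write_truth_json({"white_allele": ase_truth}, out / "ase_truth.json")
    print(f"Allele counts: 40 SNPs, {len(planted_cs)} planted copy-specific")


if __name__ == "__main__":
    main()
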