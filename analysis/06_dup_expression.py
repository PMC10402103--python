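"""Tandem-duplication calling and copy-specific expression.

Normalizes the windowed coverage track to copy number 2, calls the
duplication from elevated-window runs, refines breakpoints from
soft-clip junction evidence, and classifies RNA-seq SNPs as
copy-specific (mono-allelic in white tissue, bi-allelic in pigmented)
or shared.
"""

import argparse
import pathlib

import pandas as pd

from piedmap import simdata, svdup


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=pathlib.Path, default=pathlib.Path("results/data"))
    ap.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    track = simdata.read_coverage_tsv(args.datadir / "coverage.tsv")
    norm = svdup.normalize_coverage(track)
    evidence = {
        "discordant": pd.read_csv(args.datadir / "evidence_discordant.tsv", sep="\t"),
        "softclip": pd.read_csv(args.datadir / "evidence_softclip.tsv", sep="\t"),
    }
    calls = [svdup.refine_breakpoints(c, evidence)
             for c in svdup.call_duplication(norm)]
    with open(args.outdir / "dup_calls.tsv", "w") as fh:
        fh.write("scaffold\tstart\tend\tgenotype\tmean_normalized\t"
                 "bp_uncertainty\tdepth_only\tn_softclip\tn_discordant\n")
        for c in calls:
            fh.write(f"{c.scaffold}\t{c.start}\t{c.end}\t{c.genotype}\t"
                     f"{c.mean_normalized:.3f}\t{c.bp_uncertainty}\t"
                     f"{c.depth_only}\t{c.n_softclip}\t{c.n_discordant}\n")
    for c in calls:
        span_kb = (c.end - c.start) / 1000
        print(f"Duplication {c.scaffold}:{c.start}-{c.end} ({span_kb:.0f} kb), "
              f"{c.genotype}, mean CN {c.mean_normalized:.2f}, breakpoints "
              f"+/-{c.bp_uncertainty} bp"
              + (" (depth only)" if c.depth_only else
                 f" ({c.n_softclip} soft-clips, {c.n_discordant} discordant pairs)"))

    counts = pd.read_csv(args.datadir / "allele_counts.tsv", sep="\t")
    classes = svdup.classify_copy_specific(counts)
    classes.to_csv(args.outdir / "ase_classes.tsv", sep="\t", index=False)
    n_cs = int((classes["class"] == "copy_specific").sum())
    print(f"{n_cs} of {len(classes)} SNPs classified copy-specific")

    # normalized expression for a gene-sized count in each tissue pool
    for tissue in ("white", "pigmented"):
        sub = counts[counts["tissue"] == tissue]
        gene_reads = int((sub["ref_count"] + sub["alt_count"]).sum())
        value = svdup.normalized_expression(gene_reads, 2_000_000)
        print(f"Normalized gene expression ({tissue}): {value:.1f} per million reads")


if __name__ == "__main__":
    main()
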