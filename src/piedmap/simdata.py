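"""Synthetic data with planted ground truth for every pipeline stage.

Each generator emulates one class of study input at desk scale: an F2
intercross genotyped at mapped markers (with genotyping error and
missingness), region-proportion phenotypes driven by planted QTLs, a
case/background variant panel with planted fixed haplotypes and
phred-scaled genotype likelihoods, reference-anchored multi-species
alignments with planted conserved elements, windowed read-depth tracks
with a planted tandem duplication plus junction evidence, and RNA-seq
allele-count tables with planted copy-specific expression.

All generators are deterministic given their integer seed; a single
global seed is expanded into independent per-stage streams so each
stage's output is reproducible on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from piedmap.cneseek import AlignmentBlock
from piedmap.cross import GeneticMap, MarkerGenotypes, MISSING, haldane_r
from piedmap.popdiff import SiteRecord

_STAGES = {
    "cross": 0,
    "phenotype": 1,
    "panel": 2,
    "alignment": 3,
    "coverage": 4,
    "ase": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for one pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


def _check_prob(x: float, name: str) -> None:
    if not np.isfinite(x) or not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {x}")


# ---------------------------------------------------------------------------
# F2 intercross


@dataclass(frozen=True)
class CrossSpec:
    """An F2 intercross design: marker grid, noise rates, seed."""

    n_individuals: int
    chromosomes: list[tuple[int, float]]  # (n_markers, length_cM)
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        _check_prob(self.genotyping_error_rate, "genotyping_error_rate")
        _check_prob(self.missing_rate, "missing_rate")
        for n_mark, length in self.chromosomes:
            if n_mark < 2:
                raise ValueError("each chromosome needs >= 2 markers")
            if not np.isfinite(length) or length <= 0:
                raise ValueError("length_cM must be positive and finite")


@dataclass(frozen=True)
class QTLSpec:
    """One planted QTL: map location plus additive/dominance effects."""

    chromosome: int
    position_cM: float
    additive_effect: float
    dominance_effect: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def sim_f2_cross(spec: CrossSpec):
    """Simulate an F2 cross under Haldane (no-interference) recombination.

    Returns ``(truth, observed, true_map)``: error-free genotypes, the same
    genotypes with independent symmetric miscalls and missingness, and the
    generating genetic map (markers evenly spaced per chromosome).
    """
    rng = stage_rng(spec.seed, "cross")
    n = spec.n_individuals
    marker_rows, call_blocks, map_rows = [], [], []
    for ci, (n_mark, length) in enumerate(spec.chromosomes, start=1):
        cm = np.linspace(0.0, length, n_mark)
        r = haldane_r(np.diff(cm))
        # two independent gametes per individual; allele flips with prob r
        gametes = np.empty((2, n_mark, n), dtype=np.int8)
        for k in range(2):
            g = (rng.random(n) < 0.5).astype(np.int8)
            gametes[k, 0] = g
            for j in range(1, n_mark):
                flip = rng.random(n) < r[j - 1]
                g = np.where(flip, 1 - g, g).astype(np.int8)
                gametes[k, j] = g
        call_blocks.append(gametes.sum(axis=0, dtype=np.int8))
        scf = f"scf{ci}"
        for j in range(n_mark):
            pos = 1 + int(round(cm[j] * 1e4)) + j  # ~100 kb per cM, ids unique
            mid = f"{scf}:{pos}"
            marker_rows.append((mid, scf, pos, "autosomal"))
            map_rows.append((f"LG{ci}", mid, scf, pos, cm[j]))

    markers = pd.DataFrame(
        marker_rows, columns=["marker_id", "scaffold", "pos", "chrom_class"]
    ).set_index("marker_id")
    individuals = [f"F2_{i + 1:04d}" for i in range(n)]
    truth_calls = np.vstack(call_blocks)
    truth = MarkerGenotypes(markers, individuals, truth_calls)

    obs = truth_calls.copy()
    if spec.genotyping_error_rate > 0:
        err = rng.random(obs.shape) < spec.genotyping_error_rate
        # symmetric miscall: replace with one of the two other classes
        shift = rng.integers(1, 3, size=obs.shape)
        obs = np.where(err, (obs + shift) % 3, obs).astype(np.int8)
    if spec.missing_rate > 0:
        obs = np.where(rng.random(obs.shape) < spec.missing_rate, MISSING, obs)
    observed = MarkerGenotypes(markers.copy(), individuals, obs.astype(np.int8))

    true_map = GeneticMap(
        pd.DataFrame(map_rows, columns=["group", "marker_id", "scaffold", "pos", "cM"])
    )
    return truth, observed, true_map


def sim_phenotypes(
    truth: MarkerGenotypes,
    gmap: GeneticMap,
    qtls: list[QTLSpec],
    seed: int,
    residual_sd: float | None = None,
    baseline: float = 0.5,
    name: str = "dorsal body",
):
    """Phenotypes from planted QTLs: additive + dominance + Gaussian noise.

    Each QTL contributes a·(n_B − 1) + d·1[het] using the truth genotype at
    the map marker nearest its position. The latent value (around
    ``baseline``) is clamped to [0, 1] since the phenotype plays the role of
    a white-plumage proportion; clamp events are counted in the returned
    info dict, alongside the realized PVE of the planted QTLs.
    """
    rng = stage_rng(seed, "phenotype")
    if residual_sd is None:
        residual_sd = qtls[0].residual_sd if qtls else 0.0
    groups = gmap.group_names()
    design_cols = []
    for q in qtls:
        if not 1 <= q.chromosome <= len(groups):
            raise ValueError(f"QTL chromosome {q.chromosome} not on the map")
        sub = gmap.group(groups[q.chromosome - 1])
        cm = sub["cM"].to_numpy(float)
        if not cm[0] - 1e-9 <= q.position_cM <= cm[-1] + 1e-9:
            raise ValueError(f"QTL at {q.position_cM} cM is off group {groups[q.chromosome - 1]}")
        marker = sub["marker_id"].iloc[int(np.argmin(np.abs(cm - q.position_cM)))]
        g = truth.calls[truth.markers.index.get_loc(marker)].astype(float)
        design_cols.append((g - 1.0, (g == 1).astype(float), q))
    latent = np.full(truth.n_individuals, baseline, dtype=float)
    for add, dom, q in design_cols:
        latent += q.additive_effect * add + q.dominance_effect * dom
    latent += rng.normal(0.0, residual_sd, size=truth.n_individuals)
    pheno = np.clip(latent, 0.0, 1.0)
    n_clamped = int(np.sum((latent < 0.0) | (latent > 1.0)))

    realized_pve = float("nan")
    if qtls:
        X = np.column_stack(
            [np.ones_like(pheno)] + [c for add, dom, _ in design_cols for c in (add, dom)]
        )
        beta, *_ = np.linalg.lstsq(X, pheno, rcond=None)
        resid = pheno - X @ beta
        tss = np.sum((pheno - pheno.mean()) ** 2)
        realized_pve = float(1.0 - resid @ resid / tss) if tss > 0 else 0.0

    table = pd.DataFrame({name: pheno}, index=pd.Index(truth.individuals, name="individual_id"))
    return table, {"realized_pve": realized_pve, "n_clamped": n_clamped}


# ---------------------------------------------------------------------------
# Case/background variant panel


@dataclass(frozen=True)
class PanelSpec:
    """Case/background genotype panel with a planted fixed haplotype."""

    n_case: int
    n_background: int
    n_sites: int
    planted_sites: tuple[int, ...] = ()
    gl_error_rate: float = 0.0
    background_alt_max: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_background, self.n_sites) < 1:
            raise ValueError("counts must be >= 1")
        _check_prob(self.gl_error_rate, "gl_error_rate")
        if any(not 0 <= i < self.n_sites for i in self.planted_sites):
            raise ValueError("planted site index outside panel")


_PHRED_CAP = 255


def _pl_from_call(call: np.ndarray, e: float) -> np.ndarray:
    """Phred-scaled likelihoods for a symmetric miscall channel.

    P(call | true=g) is 1-e when g equals the call, e/2 otherwise; the
    vector is normalized so its minimum entry is 0.
    """
    n = call.shape[0]
    if e <= 0:
        pl = np.full((n, 3), _PHRED_CAP, dtype=np.int32)
    else:
        wrong = min(_PHRED_CAP, int(round(-10 * np.log10((e / 2) / (1 - e)))))
        pl = np.full((n, 3), wrong, dtype=np.int32)
    pl[np.arange(n), call] = 0
    return pl


def sim_population_sites(spec: PanelSpec) -> list[SiteRecord]:
    """Variant panel with group-shared null sites and planted fixed sites.

    Null sites draw one allele frequency shared by both groups, genotypes
    under Hardy-Weinberg. Planted sites are homozygous-alt in every case
    sample and segregate at low frequency with no hom-alt genotypes in the
    background. Calls pass through a symmetric miscall channel at
    ``gl_error_rate`` (never applied where it would break the plant) and
    PL fields are generated consistent with the channel.
    """
    rng = stage_rng(spec.seed, "panel")
    n_case, n_bg = spec.n_case, spec.n_background
    samples = [f"case{i + 1:03d}" for i in range(n_case)] + [
        f"bg{i + 1:03d}" for i in range(n_bg)
    ]
    groups = np.array(["case"] * n_case + ["background"] * n_bg)
    planted = set(spec.planted_sites)
    e = spec.gl_error_rate
    bases = np.array(list("ACGT"))
    sites = []
    for s in range(spec.n_sites):
        if s in planted:
            gt_case = np.full(n_case, 2, dtype=np.int8)
            p_bg = rng.uniform(0.0, spec.background_alt_max)
            gt_bg = (rng.random(n_bg) < p_bg).astype(np.int8)  # 0 or het only
            gt = np.concatenate([gt_case, gt_bg])
            call = gt.copy()
        else:
            p = rng.uniform(0.05, 0.95)
            gt = (rng.random((2, n_case + n_bg)) < p).sum(axis=0).astype(np.int8)
            call = gt.copy()
            if e > 0:
                err = rng.random(call.shape) < e
                shift = rng.integers(1, 3, size=call.shape)
                call = np.where(err, (call + shift) % 3, call).astype(np.int8)
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            SiteRecord(
                scaffold="scf507",
                pos=1000 + 100 * s,
                ref=str(bases[ref]),
                alt=str(bases[alt]),
                gt=call,
                pl=_pl_from_call(call, e),
                samples=samples,
                groups=groups,
            )
        )
    return sites


def write_vcf(sites: list[SiteRecord], path) -> None:
    """Write a panel as a minimal VCF with GT and PL per sample."""
    if not sites:
        raise ValueError("no sites to write")
    samples = sites[0].samples
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
            '"Phred-scaled genotype likelihoods">\n'
        )
        for scf in dict.fromkeys(s.scaffold for s in sites):
            fh.write(f"##contig=<ID={scf}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for s in sites:
            cells = [
                f"{gt_text[int(g)]}:{pl[0]},{pl[1]},{pl[2]}"
                for g, pl in zip(s.gt, s.pl)
            ]
            fh.write(
                f"{s.scaffold}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\tGT:PL\t"
                + "\t".join(cells)
                + "\n"
            )


def write_sample_sheet(sites: list[SiteRecord], path) -> None:
    pd.DataFrame({"sample": sites[0].samples, "group": sites[0].groups}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Multi-species alignment with planted conserved elements


@dataclass(frozen=True)
class CNEPlant:
    """A planted conserved element: interval, identity, per-clade support."""

    start: int
    end: int  # half-open bp on the reference
    identity: float
    n_avian: int = 0
    n_tetrapod: int = 0


def sim_alignment(
    n_avian: int,
    n_tetrapod: int,
    planted_cnes: list[CNEPlant],
    background_identity: float,
    exons: list[tuple[int, int]],
    seed: int,
    length: int = 50_000,
    gap_fraction: float = 0.2,
    ref_name: str = "reference",
):
    """Reference-anchored alignment with planted high-identity islands.

    Species sequences are column-aligned to an ungapped reference. At each
    base a species matches the reference with the interval's identity
    (planted, for its supporting species) or ``background_identity``
    elsewhere; non-matching bases become a gap with probability
    ``gap_fraction`` and a different nucleotide otherwise, so per-base
    identity is exactly the requested level. Returns the alignment block
    and the exon intervals (0-based half-open) unchanged.
    """
    spans = sorted((c.start, c.end) for c in planted_cnes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("planted CNE intervals overlap")
    for c in planted_cnes:
        if not (0 <= c.start < c.end <= length):
            raise ValueError("planted CNE outside the reference")
        if c.n_avian > n_avian or c.n_tetrapod > n_tetrapod:
            raise ValueError("more supporting species than exist in clade")
    rng = stage_rng(seed, "alignment")
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=length)
    species_names = [f"avian{i + 1:02d}" for i in range(n_avian)] + [
        f"tetrapod{i + 1:02d}" for i in range(n_tetrapod)
    ]
    clades = {n: ("avian" if n.startswith("avian") else "tetrapod") for n in species_names}
    seqs = {}
    for si, name in enumerate(species_names):
        ident = np.full(length, background_identity)
        for c in planted_cnes:
            n_sup = c.n_avian if clades[name] == "avian" else c.n_tetrapod
            rank = si if clades[name] == "avian" else si - n_avian
            if rank < n_sup:
                ident[c.start : c.end] = c.identity
        match = rng.random(length) < ident
        gap = ~match & (rng.random(length) < gap_fraction)
        shift = rng.integers(1, 4, size=length)
        idx = np.where(match, ref_idx, (ref_idx + shift) % 4)
        seq = bases[idx]
        seq[gap] = "-"
        seqs[name] = "".join(seq)
    block = AlignmentBlock(
        ref_name=ref_name,
        ref_start=0,
        ref_seq="".join(bases[ref_idx]),
        species_seqs=seqs,
        clades=clades,
    )
    return block, list(exons)


# ---------------------------------------------------------------------------
# Coverage with a planted tandem duplication


@dataclass(frozen=True)
class DupPlantSpec:
    """A planted tandem duplication in a windowed coverage track."""

    genome_length: int
    window: int
    dup_interval: tuple[int, int]  # half-open bp
    copy_state: str = "heterozygous"  # or "homozygous"
    mean_depth: float = 30.0
    noise_model: str = "poisson"  # "poisson" | "negative_binomial" | "fixed"
    nb_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        s, e = self.dup_interval
        if not (0 <= s < e <= self.genome_length):
            raise ValueError("dup_interval outside the genome")
        if self.window <= 0 or self.window > self.genome_length:
            raise ValueError("window must be in (0, genome_length]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.copy_state not in ("heterozygous", "homozygous"):
            raise ValueError("copy_state must be heterozygous or homozygous")
        if self.noise_model not in ("poisson", "negative_binomial", "fixed"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def sim_coverage(spec: DupPlantSpec):
    """Windowed depth track plus junction evidence for a planted dup.

    Per-window mean depth scales with local copy number (2 outside the
    duplication; 3 het / 4 hom inside, pro-rated for partial overlap).
    Evidence: discordant-pair clusters at both duplication edges and
    soft-clip records whose clipped sequence remaps to the partner
    breakpoint of the tandem junction, at rates proportional to depth.
    """
    rng = stage_rng(spec.seed, "coverage")
    n_win = spec.genome_length // spec.window
    starts = np.arange(n_win) * spec.window
    ends = starts + spec.window
    ds, de = spec.dup_interval
    overlap = np.clip(np.minimum(ends, de) - np.maximum(starts, ds), 0, None)
    gain = 1.0 if spec.copy_state == "heterozygous" else 2.0
    cn = 2.0 + gain * overlap / spec.window
    mu = spec.mean_depth * cn / 2.0
    if spec.noise_model == "fixed":
        raw = mu
    elif spec.noise_model == "poisson":
        raw = rng.poisson(mu * spec.window) / spec.window
    else:
        k = spec.nb_dispersion
        lam = rng.gamma(shape=k, scale=mu * spec.window / k)
        raw = rng.poisson(lam) / spec.window
    track = pd.DataFrame(
        {"scaffold": "scf507", "start": starts, "end": ends, "depth": raw}
    )

    frac = gain / 2.0  # fraction of chromosomes carrying the junction
    n_junction = max(1, int(round(spec.mean_depth * frac)))
    discordant = pd.DataFrame(
        {
            "scaffold": ["scf507", "scf507"],
            "position": [ds, de],
            "count": [n_junction, n_junction],
            "insert_mean": [de - ds + 400.0] * 2,
            "insert_sd": [60.0, 60.0],
        }
    )
    clip_rows = []
    for _ in range(n_junction):
        clip_rows.append(("scf507", de, "right", ds))  # read runs off the junction
        clip_rows.append(("scf507", ds, "left", de))
    softclips = pd.DataFrame(
        clip_rows, columns=["scaffold", "position", "clip_side", "remap_pos"]
    )
    evidence = {"discordant": discordant, "softclip": softclips}
    return track, evidence


def write_coverage_tsv(track: pd.DataFrame, path) -> None:
    track[["scaffold", "start", "end", "depth"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_coverage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["scaffold", "start", "end", "depth"],
        dtype={"scaffold": str},
    )


# ---------------------------------------------------------------------------
# RNA-seq allele counts with planted copy-specific expression


def sim_allele_counts(
    n_snps: int,
    white_depth: int,
    pigmented_depth: int,
    copy_specific: set[int],
    seed: int,
    n_white: int = 2,
    n_pigmented: int = 2,
):
    """Allele-count table with planted copy-specific SNPs.

    Copy-specific SNPs are mono-allelic in white-tissue samples (the
    white-expressed gene copy carries one allele, chosen at random) and
    balanced in pigmented tissue, where both copies are expressed; all
    other SNPs are balanced in both tissues. Counts are binomial at the
    given depths. Returns (table, truth) where truth maps each planted SNP
    to its white-expressed allele.
    """
    if white_depth <= 0 or pigmented_depth <= 0:
        raise ValueError("depths must be positive")
    if any(not 0 <= i < n_snps for i in copy_specific):
        raise ValueError("copy-specific index outside the SNP set")
    rng = stage_rng(seed, "ase")
    rows, truth = [], {}
    for s in range(n_snps):
        snp = f"snp{s + 1:04d}"
        if s in copy_specific:
            white_allele = "ref" if rng.random() < 0.5 else "alt"
            truth[snp] = white_allele
            f_white = 0.0 if white_allele == "ref" else 1.0
        else:
            f_white = 0.5
        for w in range(n_white):
            alt = rng.binomial(white_depth, f_white)
            rows.append((snp, f"white{w + 1}", "white", white_depth - alt, alt))
        for p in range(n_pigmented):
            alt = rng.binomial(pigmented_depth, 0.5)
            rows.append((snp, f"pig{p + 1}", "pigmented", pigmented_depth - alt, alt))
    table = pd.DataFrame(
        rows, columns=["snp_id", "sample", "tissue", "ref_count", "alt_count"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# Truth sidecars


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)
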