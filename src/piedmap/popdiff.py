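"""Population allele-frequency differentiation between phenotype groups.

Implements a probabilistic FST-style site test: per-sample genotype
likelihoods are weighted by Hardy-Weinberg genotype frequencies at a
candidate allele frequency, the frequency is fitted separately per group
and pooled, and twice the log-likelihood-ratio is referred to a
chi-square with one degree of freedom. Genome-wide significance uses
Bonferroni correction (alpha divided by the number of sites tested).

The exact formula behind the statistic published with the study's
toolchain is not printed anywhere; the construction here is this
package's documented interpretation of a genotype-likelihood
likelihood-ratio test and is validated against a brute-force frequency
grid rather than against that tool.

Also implements the study-style candidate-SNP rule — the alternate
allele homozygous in every (non-missing) case sample and never
homozygous in any background sample — and delineation of haplotype
groups by clustering samples on their shared homozygous-alt site sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from scipy.stats import chi2

MISSING = -1

CASE, BACKGROUND, EXCLUDED = "case", "background", "excluded"


@dataclass
class SiteRecord:
    """One biallelic variant site with calls, PLs and group labels."""

    scaffold: str
    pos: int  # 1-based bp
    ref: str
    alt: str
    gt: np.ndarray  # per-sample call in {0,1,2,MISSING}
    pl: np.ndarray  # per-sample phred likelihoods, shape (n, 3), min 0
    samples: list[str]
    groups: np.ndarray  # per-sample label in {case, background, excluded}

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.pl = np.asarray(self.pl)
        self.groups = np.asarray(self.groups)
        n = len(self.samples)
        if not (self.gt.shape == (n,) and self.pl.shape == (n, 3) == (n, 3)):
            raise ValueError("gt/pl shapes do not match the sample list")


@dataclass
class PfstResult:
    scaffold: str
    pos: int
    lrt_stat: float
    p_value: float
    significant: bool = False


@dataclass
class HaplotypeGroup:
    group_id: int
    members: list[str]
    defining_snps: list[tuple[str, int]]
    span: tuple[str, int, int]  # scaffold, start, end (1-based inclusive bp)


def _likelihoods(pl: np.ndarray) -> np.ndarray:
    """Phred PLs to relative genotype likelihoods (max entry 1)."""
    return np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)


def _group_loglik(lik: np.ndarray, p: float) -> float:
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    marg = lik @ hwe
    if np.any(marg <= 0):
        return -np.inf
    return float(np.log(marg).sum())


def _fit_freq(lik: np.ndarray) -> float:
    """Maximized log-likelihood over allele frequency p in [0, 1]."""
    res = minimize_scalar(
        lambda p: -_group_loglik(lik, p),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # the bounded optimizer never evaluates the exact endpoints; check them
    best = -res.fun
    for p in (0.0, 1.0):
        best = max(best, _group_loglik(lik, p))
    return best


def pfst_site(site: SiteRecord) -> PfstResult:
    """Genotype-likelihood LRT for an allele-frequency difference.

    Alternative: separate frequencies per group; null: one pooled
    frequency. Statistic 2*(lnL_case + lnL_background - lnL_pooled),
    p-value from chi-square df=1. Samples with missing calls are dropped.
    """
    keep = site.gt != MISSING
    case = keep & (site.groups == CASE)
    bg = keep & (site.groups == BACKGROUND)
    if case.sum() < 2 or bg.sum() < 2:
        raise ValueError("need >= 2 non-missing samples in each group")
    lik = _likelihoods(site.pl)
    l_case = _fit_freq(lik[case])
    l_bg = _fit_freq(lik[bg])
    l_pool = _fit_freq(lik[case | bg])
    stat = max(0.0, 2.0 * (l_case + l_bg - l_pool))
    return PfstResult(site.scaffold, site.pos, stat, float(chi2.sf(stat, df=1)))


def pfst_scan(sites: list[SiteRecord], alpha: float = 0.05) -> pd.DataFrame:
    """Per-site LRT results with a Bonferroni significance flag."""
    results = [pfst_site(s) for s in sites]
    thr = genomewide_threshold(len(sites), alpha)
    return pd.DataFrame(
        {
            "scaffold": [r.scaffold for r in results],
            "pos": [r.pos for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.p_value < thr for r in results],
        }
    )


def genomewide_threshold(n_sites: int, alpha: float = 0.05) -> float:
    """Bonferroni p-value threshold: alpha / number of sites tested."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return alpha / n_sites


def candidate_snp_filter(
    sites: list[SiteRecord], min_case_callrate: float = 0.8
) -> pd.DataFrame:
    """Sites where the alt allele is fixed in cases, never hom in background.

    A site qualifies iff every non-missing case sample is homozygous-alt
    with case call rate >= ``min_case_callrate``, and no background sample
    is homozygous-alt (at any background call rate).
    """
    rows = []
    for s in sites:
        case = s.groups == CASE
        bg = s.groups == BACKGROUND
        if not case.any() or not bg.any():
            raise ValueError("both groups must be non-empty")
        gc = s.gt[case]
        gb = s.gt[bg]
        case_called = gc != MISSING
        case_rate = case_called.mean()
        bg_rate = (gb != MISSING).mean()
        ok = (
            case_called.any()
            and case_rate >= min_case_callrate
            and np.all(gc[case_called] == 2)
            and not np.any(gb == 2)
        )
        if ok:
            rows.append((s.scaffold, s.pos, s.ref, s.alt, case_rate, bg_rate))
    return pd.DataFrame(
        rows, columns=["scaffold", "pos", "ref", "alt", "case_callrate", "bg_callrate"]
    )


def delineate_groups(
    sites: list[SiteRecord],
    min_defining_snps: int = 5,
    min_similarity: float = 0.5,
) -> list[HaplotypeGroup]:
    """Cluster samples by shared homozygous-alt sites within a region.

    Average-linkage hierarchical clustering on Jaccard distance between
    samples' hom-alt site sets, cut at 1 - ``min_similarity``; a cluster's
    defining set is the sites homozygous-alt in all of its members, and
    clusters with fewer than ``min_defining_snps`` defining sites are
    discarded. Deterministic given input order and parameters.
    """
    if not sites:
        return []
    samples = sites[0].samples
    hom = np.stack([s.gt == 2 for s in sites], axis=1)  # samples x sites
    carrier = hom.any(axis=1)
    if not carrier.any():
        return []
    idx = np.flatnonzero(carrier)
    X = hom[idx]
    if len(idx) == 1:
        labels = np.array([1])
    else:
        dist = pdist(X, metric="jaccard")
        labels = fcluster(linkage(dist, method="average"), t=1.0 - min_similarity,
                          criterion="distance")
    out = []
    for gid in sorted(set(labels)):
        members = idx[labels == gid]
        shared = X[labels == gid].all(axis=0)
        defining = [
            (sites[j].scaffold, sites[j].pos) for j in np.flatnonzero(shared)
        ]
        if len(defining) < min_defining_snps:
            continue
        positions = [p for _, p in defining]
        out.append(
            HaplotypeGroup(
                group_id=len(out) + 1,
                members=[samples[i] for i in members],
                defining_snps=defining,
                span=(defining[0][0], min(positions), max(positions)),
            )
        )
    return out


def genotype_matrix(sites: list[SiteRecord]) -> pd.DataFrame:
    """Samples x sites genotype matrix ordered for heatmap plotting.

    Rows are samples ordered case-first (then by hom-alt count, so
    samples sharing a fixed haplotype cluster visually); columns are
    ``scaffold:pos``; values are alt-allele counts with -1 for missing.
    """
    if not sites:
        return pd.DataFrame()
    samples = sites[0].samples
    mat = np.stack([s.gt for s in sites], axis=1)
    cols = [f"{s.scaffold}:{s.pos}" for s in sites]
    df = pd.DataFrame(mat, index=pd.Index(samples, name="sample"), columns=cols)
    df.insert(0, "group", sites[0].groups)
    order = sorted(
        range(len(samples)),
        key=lambda i: (sites[0].groups[i] != CASE, -(mat[i] == 2).sum()),
    )
    return df.iloc[order]


# ---------------------------------------------------------------------------
# VCF + sample-sheet input


def read_vcf(vcf_path, sample_sheet_path) -> list[SiteRecord]:
    """Read biallelic sites (GT + PL) with group labels from a sample sheet.

    Samples absent from the sheet are labelled ``excluded``; multi-allelic
    records are skipped.
    """
    from cyvcf2 import VCF

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    label = dict(zip(sheet["sample"], sheet["group"]))
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    groups = np.array([label.get(s, EXCLUDED) for s in samples])
    sites = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = var.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 encodes unknown
        pl = var.format("PL")
        sites.append(
            SiteRecord(
                scaffold=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                gt=gt,
                pl=np.asarray(pl, dtype=np.int32),
                samples=samples,
                groups=groups,
            )
        )
    return sites
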