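"""Single-QTL genome scan by Haley-Knott regression.

Genotype probabilities at markers and a pseudo-marker grid come from a
three-state hidden Markov model (AA, AB, BB) with stationary prior
(1/4, 1/2, 1/4), transitions from two independent meioses each
recombining with the Haldane fraction r = (1 - e^(-d/50))/2, and a
symmetric genotyping-error emission. The scan regresses the phenotype on
the expected additive dosage P(BB) - P(AA) and dominance P(AB) at every
position; LOD = (n/2) log10(RSS0 / RSS1). Genome-wide significance is
the empirical (1 - alpha) quantile of the maximum LOD over phenotype
permutations; support intervals use the 2-LOD drop rule and percent
variance explained is 1 - 10^(-2 LOD / n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from piedmap.cross import GeneticMap, MarkerGenotypes, MISSING, haldane_r

MAX_LOD = 999.0  # cap for degenerate perfect fits
_PRIOR = np.array([0.25, 0.5, 0.25])


def transition_matrix(r: float) -> np.ndarray:
    """F2 genotype transition for one interval with recombination r."""
    return np.array(
        [
            [(1 - r) ** 2, 2 * r * (1 - r), r**2],
            [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
            [r**2, 2 * r * (1 - r), (1 - r) ** 2],
        ]
    )


def emission_matrix(calls: np.ndarray, error_prob: float) -> np.ndarray:
    """Per-individual emission over true genotypes for one marker.

    Observed call matches truth with probability 1 - error_prob, each
    wrong call error_prob/2; missing calls emit uniformly.
    """
    n = calls.shape[0]
    em = np.full((n, 3), error_prob / 2.0)
    typed = calls != MISSING
    em[typed, calls[typed]] = 1.0 - error_prob
    em[~typed] = 1.0 / 3.0
    return em


def forward_backward(emissions: np.ndarray, d_cM: np.ndarray):
    """Vectorized HMM pass over positions x individuals x 3 states.

    Returns (posterior, loo_posterior, loglik): the smoothed state
    probabilities, the leave-one-out posteriors (own emission replaced by
    a flat one — the flanking-marker predictive used for error LOD), and
    the per-individual natural-log likelihood.
    """
    P, n, _ = emissions.shape
    T = [transition_matrix(float(r)) for r in haldane_r(d_cM)] if P > 1 else []
    pred = np.empty((P, n, 3))
    alpha = np.empty((P, n, 3))
    logc = np.zeros(n)
    pred[0] = _PRIOR
    for m in range(P):
        if m > 0:
            pred[m] = alpha[m - 1] @ T[m - 1]
        a = pred[m] * emissions[m]
        c = a.sum(axis=1, keepdims=True)
        logc += np.log(c[:, 0])
        alpha[m] = a / c
    beta = np.empty((P, n, 3))
    beta[P - 1] = 1.0
    for m in range(P - 2, -1, -1):
        b = (emissions[m + 1] * beta[m + 1]) @ T[m].T
        beta[m] = b / b.sum(axis=1, keepdims=True)
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    loo = pred * beta
    loo /= loo.sum(axis=2, keepdims=True)
    return post, loo, logc


@dataclass
class GenotypeProbabilities:
    """HMM genotype probabilities on markers plus a pseudo-marker grid."""

    positions: pd.DataFrame  # group, cM, marker_id ("" for pseudo-markers)
    probs: np.ndarray  # (n_positions, n_individuals, 3)
    individuals: list[str]

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("genotype probability vectors must sum to 1")


def calc_genoprob(
    g: MarkerGenotypes,
    gmap: GeneticMap,
    step_cM: float = 1.0,
    error_prob: float = 1e-4,
) -> GenotypeProbabilities:
    """Genotype probabilities at every marker and grid position."""
    if not 0.0 <= error_prob < 0.5:
        raise ValueError("error_prob must be in [0, 0.5)")
    frames, blocks = [], []
    for name, sub in gmap.groups():
        if sub.empty:
            raise ValueError(f"empty linkage group {name}")
        cm = sub["cM"].to_numpy(float)
        ids = sub["marker_id"].tolist()
        grid = np.arange(cm[0], cm[-1] + 1e-9, step_cM) if step_cM > 0 else np.array([])
        all_cm = np.concatenate([cm, grid])
        all_ids = ids + [""] * grid.size
        order = np.argsort(all_cm, kind="stable")
        # drop grid points that duplicate a marker position
        keep, seen = [], set()
        for i in order:
            key = round(all_cm[i], 9)
            if all_ids[i] == "" and key in seen:
                continue
            seen.add(key)
            keep.append(i)
        pos_cm = all_cm[keep]
        pos_ids = [all_ids[i] for i in keep]
        em = np.empty((len(keep), g.n_individuals, 3))
        for j, i in enumerate(keep):
            if pos_ids[j] == "":
                em[j] = 1.0 / 3.0
            else:
                calls = g.calls[g.markers.index.get_loc(pos_ids[j])]
                em[j] = emission_matrix(calls, error_prob)
        post, _, _ = forward_backward(em, np.diff(pos_cm))
        frames.append(
            pd.DataFrame({"group": name, "cM": pos_cm, "marker_id": pos_ids})
        )
        blocks.append(post)
    return GenotypeProbabilities(
        pd.concat(frames, ignore_index=True), np.concatenate(blocks), list(g.individuals)
    )


@dataclass
class ScanResult:
    """Per-position LOD scores with an optional permutation threshold."""

    table: pd.DataFrame  # group, cM, marker_id, lod
    phenotype: str
    threshold_5pct: float | None = None
    n_perm: int = 0


def _design_bases(probs: np.ndarray) -> np.ndarray:
    """Orthonormal column bases of [1, additive, dominance] per position."""
    P, n, _ = probs.shape
    X = np.empty((P, n, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = probs[:, :, 2] - probs[:, :, 0]
    X[:, :, 2] = probs[:, :, 1]
    bases = np.zeros_like(X)
    for p in range(P):
        u, s, _ = np.linalg.svd(X[p], full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum())
        bases[p, :, :rank] = u[:, :rank]
    return bases


def hk_lod_matrix(probs: np.ndarray, Y: np.ndarray, bases: np.ndarray | None = None) -> np.ndarray:
    """LOD for each position (rows) against each phenotype column of Y."""
    if bases is None:
        bases = _design_bases(probs)
    n = Y.shape[0]
    yty = (Y**2).sum(axis=0)
    rss0 = yty - n * Y.mean(axis=0) ** 2
    proj = np.einsum("pnk,nb->pkb", bases, Y)
    rss1 = yty[None, :] - (proj**2).sum(axis=1)
    rss1 = np.maximum(rss1, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(rss0[None, :] / rss1)
    lod = np.where(rss1 <= 1e-12 * np.maximum(rss0, 1.0), MAX_LOD, lod)
    lod = np.where(rss0 <= 0, 0.0, lod)  # zero phenotypic variance
    return np.minimum(np.nan_to_num(lod, nan=0.0), MAX_LOD)


def hk_scan(probs: GenotypeProbabilities, phenotype: pd.Series) -> ScanResult:
    """Haley-Knott regression scan of one phenotype over all positions.

    Individuals with a missing phenotype are dropped listwise; requires
    at least 10 phenotyped individuals.
    """
    y = phenotype.reindex(probs.individuals)
    keep = y.notna().to_numpy()
    if keep.sum() < 10:
        raise ValueError("need >= 10 individuals with phenotypes")
    if np.var(y.to_numpy(float)[keep]) == 0:
        import warnings

        warnings.warn("zero phenotypic variance: all LOD scores are 0")
    lod = hk_lod_matrix(probs.probs[:, keep, :], y.to_numpy(float)[keep, None])[:, 0]
    table = probs.positions.copy()
    table["lod"] = lod
    return ScanResult(table, phenotype=str(phenotype.name))


def perm_threshold(
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is shuffled against the intact genotype
    structure ``n_perm`` times; the threshold is the empirical
    (1 - alpha) quantile (linear interpolation) of the per-permutation
    genome-wide maximum LOD.
    """
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} < 100: quantile estimate is unstable")
    y = phenotype.reindex(probs.individuals)
    keep = y.notna().to_numpy()
    yv = y.to_numpy(float)[keep]
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(yv) for _ in range(n_perm)])
    bases = _design_bases(probs.probs[:, keep, :])
    maxlod = hk_lod_matrix(probs.probs[:, keep, :], Y, bases=bases).max(axis=0)
    return float(np.quantile(maxlod, 1.0 - alpha))


@dataclass
class QTLInterval:
    group: str
    peak_cM: float
    peak_marker: str
    low_cM: float
    high_cM: float
    peak_lod: float
    pve: float
    peak_tied: bool = False


def lod_interval(scan: ScanResult, group, n: int, drop: float = 2.0) -> QTLInterval:
    """Support interval by the ``drop``-LOD rule around the group peak.

    The interval is the contiguous span around the peak where LOD stays
    within ``drop`` of the peak, expanded by one evaluated position past
    the drop boundary on each side. Peak ties break to the left-most
    position (and are reported).
    """
    sub = scan.table[scan.table["group"] == group].reset_index(drop=True)
    if sub.empty:
        raise KeyError(f"no positions in group {group!r}")
    lod = sub["lod"].to_numpy(float)
    if np.all(lod <= 0):
        raise ValueError(f"group {group!r} has no LOD signal; interval undefined")
    peak = int(np.argmax(lod))
    tied = bool(np.sum(lod == lod[peak]) > 1)
    cut = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lod) - 1)
    return QTLInterval(
        group=group,
        peak_cM=float(sub["cM"].iloc[peak]),
        peak_marker=str(sub["marker_id"].iloc[peak]),
        low_cM=float(sub["cM"].iloc[lo]),
        high_cM=float(sub["cM"].iloc[hi]),
        peak_lod=float(lod[peak]),
        pve=pve(float(lod[peak]), n),
        peak_tied=tied,
    )


def pve(lod: float, n: int) -> float:
    """Percent variance explained: 1 - 10^(-2 LOD / n), as a fraction."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def qtl_summary(
    scan: ScanResult, threshold: float, n: int, drop: float = 2.0
) -> pd.DataFrame:
    """Per-group peak summary for groups clearing the threshold."""
    rows = []
    for group in dict.fromkeys(scan.table["group"]):
        sub = scan.table[scan.table["group"] == group]
        if sub["lod"].max() < threshold:
            continue
        qi = lod_interval(scan, group, n=n, drop=drop)
        rows.append(
            (
                scan.phenotype,
                group,
                qi.peak_marker,
                qi.peak_cM,
                qi.peak_lod,
                qi.pve,
                qi.low_cM,
                qi.high_cM,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype",
            "group",
            "peak_marker",
            "peak_cM",
            "peak_lod",
            "pve",
            "interval_low_cM",
            "interval_high_cM",
        ],
    )
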