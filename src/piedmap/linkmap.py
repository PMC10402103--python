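"""F2 genetic-map construction by staged filtering and linkage analysis.

The pipeline mirrors a standard intercross map build: drop autosomal
markers with significant segregation distortion from 1:2:1 (Bonferroni-
corrected chi-square), collapse markers with byte-identical genotype
vectors, filter by genotyping rate (50% everywhere, then 66% on large
scaffolds), estimate pairwise recombination fractions by maximum
likelihood under the phase-known F2 two-locus model, form linkage groups
as connected components of the (r <= 0.15, LOD >= 6) linkage graph,
order markers within scaffolds by physical position and chain scaffolds
greedily by terminal recombination fractions, convert adjacent fractions
to centimorgans with the Haldane transform, erase individual genotypes
whose error LOD (posterior odds of a miscall from the flanking-marker
HMM) exceeds 5, and iteratively drop markers whose removal raises the
map likelihood or collapses the map without physical support.

Z-linked markers segregate differently in an intercross and are mapped
in a separate run: they skip the 1:2:1 distortion test and form their
own linkage groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2

from piedmap.cross import (
    AUTOSOMAL,
    GeneticMap,
    MarkerGenotypes,
    MISSING,
    Z_LINKED,
    haldane_cM,
)
from piedmap.qtlscan import emission_matrix, forward_backward

_PRIOR = np.array([0.25, 0.5, 0.25])
_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Marker filters


def segregation_filter(g: MarkerGenotypes, alpha: float = 0.01):
    """Drop autosomal markers distorted from 1:2:1 at p < alpha / M.

    M is the number of markers tested; Z-linked markers and markers with
    fewer than 2 non-missing calls are never tested (the latter are
    flagged in the report). Returns (retained, report).
    """
    testable, rows = [], []
    for i, mid in enumerate(g.markers.index):
        if g.markers["chrom_class"].iloc[i] != AUTOSOMAL:
            continue
        calls = g.calls[i]
        if (calls != MISSING).sum() < 2:
            rows.append((mid, np.nan, "too_few_calls"))
            continue
        testable.append((i, mid))
    M = len(testable)
    cutoff = alpha / M if M else 0.0
    dropped = set()
    for i, mid in testable:
        calls = g.calls[i]
        counts = np.bincount(calls[calls != MISSING], minlength=3)[:3]
        n = counts.sum()
        expected = n * _PRIOR
        x2 = float(((counts - expected) ** 2 / expected).sum())
        p = float(chi2.sf(x2, df=2))
        if p < cutoff:
            dropped.add(mid)
            rows.append((mid, p, "distorted"))
    report = pd.DataFrame(rows, columns=["marker_id", "p_value", "reason"])
    keep = [m for m in g.markers.index if m not in dropped]
    return g.subset(keep), report


def collapse_duplicates(g: MarkerGenotypes):
    """Keep one representative per set of identical genotype vectors.

    Identity is strict, including the missingness pattern. The
    representative is the marker with the lowest scaffold then lowest bp;
    returns (retained, mapping of collapsed marker -> representative).
    """
    _, inverse = np.unique(g.calls, axis=0, return_inverse=True)
    mapping: dict[str, str] = {}
    keep = []
    order = sorted(
        range(g.n_markers),
        key=lambda i: (str(g.markers["scaffold"].iloc[i]), int(g.markers["pos"].iloc[i]),
                       str(g.markers.index[i])),
    )
    rep_for: dict[int, str] = {}
    for i in order:
        grp = inverse[i]
        mid = str(g.markers.index[i])
        if grp not in rep_for:
            rep_for[grp] = mid
            keep.append(mid)
        else:
            mapping[mid] = rep_for[grp]
    keep_in_order = [m for m in g.markers.index if m in set(keep)]
    return g.subset(keep_in_order), mapping


def genotyping_rate_filter(
    g: MarkerGenotypes,
    first_pass: float = 0.50,
    second_pass: float = 0.66,
    large_scaffold: int = 40,
) -> MarkerGenotypes:
    """Two-pass genotyping-rate filter.

    Pass 1 removes markers typed in < ``first_pass`` of individuals.
    Pass 2 applies only within scaffolds that still hold more than
    ``large_scaffold`` markers, removing markers typed in <
    ``second_pass`` of individuals.
    """
    rate = g.call_rate()
    keep1 = rate >= first_pass
    g1 = g.subset(g.markers.index[keep1])
    rate1 = g1.call_rate()
    counts = g1.markers["scaffold"].value_counts()
    big = g1.markers["scaffold"].map(counts) > large_scaffold
    keep2 = ~(big.to_numpy() & (rate1 < second_pass))
    return g1.subset(g1.markers.index[keep2])


# ---------------------------------------------------------------------------
# Pairwise recombination


@dataclass(frozen=True)
class PairLinkage:
    marker_a: str
    marker_b: str
    r_hat: float
    lod_linkage: float
    n_joint: int
    flag: str = ""


_HAPS = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])


def _joint_table(r: float) -> np.ndarray:
    """P(genotype pair) in a phase-known F2 at recombination r (3x3)."""
    hp = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
    P = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            P[_HAPS[i, 0] + _HAPS[j, 0], _HAPS[i, 1] + _HAPS[j, 1]] += hp[i] * hp[j]
    return P


def _pair_loglik(counts: np.ndarray, r: float) -> float:
    P = _joint_table(r)
    mask = counts > 0
    if np.any(P[mask] <= 0):
        return -np.inf
    return float((counts[mask] * np.log(P[mask])).sum())


def estimate_rf(calls_a: np.ndarray, calls_b: np.ndarray,
                name_a: str = "A", name_b: str = "B") -> PairLinkage:
    """ML recombination fraction for one marker pair.

    Maximizes the F2 two-locus likelihood over r in [0, 0.5] on the
    jointly non-missing individuals; LOD compares against r = 0.5. Pairs
    with < 10 joint individuals are flagged low-information; monomorphic
    markers give an undefined estimate (flagged, r_hat = NaN).
    """
    both = (calls_a != MISSING) & (calls_b != MISSING)
    a, b = calls_a[both].astype(int), calls_b[both].astype(int)
    n = int(both.sum())
    if n == 0 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return PairLinkage(name_a, name_b, np.nan, np.nan, n, "monomorphic")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1.0)
    res = minimize_scalar(
        lambda r: -_pair_loglik(counts, r),
        bounds=(1e-9, 0.5 - 1e-9),
        method="bounded",
        options={"xatol": 1e-10},
    )
    cands = [(float(res.x), -float(res.fun))]
    for r0 in (0.0, 0.5):
        cands.append((r0, _pair_loglik(counts, r0)))
    r_hat, ll = max(cands, key=lambda t: t[1])
    lod = (ll - _pair_loglik(counts, 0.5)) / _LN10
    flag = "low_information" if n < 10 else ""
    return PairLinkage(name_a, name_b, r_hat, max(lod, 0.0), n, flag)


def pairwise_linkage(g: MarkerGenotypes) -> pd.DataFrame:
    """estimate_rf over all marker pairs (upper triangle)."""
    rows = []
    ids = list(g.markers.index)
    for i, j in combinations(range(len(ids)), 2):
        pl = estimate_rf(g.calls[i], g.calls[j], ids[i], ids[j])
        rows.append((pl.marker_a, pl.marker_b, pl.r_hat, pl.lod_linkage, pl.n_joint, pl.flag))
    return pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "r_hat", "lod_linkage", "n_joint", "flag"]
    )


def form_groups(
    pairs: pd.DataFrame,
    markers: list[str],
    max_rf: float = 0.15,
    min_lod: float = 6.0,
):
    """Linkage groups as connected components of the linkage graph.

    Two markers are linked iff r_hat <= max_rf AND lod >= min_lod.
    Returns (groups, singletons): groups is a list of marker-id lists
    (size >= 2), deterministic in input order.
    """
    index = {m: i for i, m in enumerate(markers)}
    linked = pairs[(pairs["r_hat"] <= max_rf) & (pairs["lod_linkage"] >= min_lod)]
    ii = linked["marker_a"].map(index).to_numpy()
    jj = linked["marker_b"].map(index).to_numpy()
    n = len(markers)
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for m in markers:
        groups.setdefault(labels[index[m]], []).append(m)
    multi = [v for v in groups.values() if len(v) > 1]
    singles = [v[0] for v in groups.values() if len(v) == 1]
    return multi, singles


# ---------------------------------------------------------------------------
# Ordering and spacing


def order_and_space(
    g: MarkerGenotypes,
    group_markers: list[str],
    max_spacing_cM: float = 50.0,
):
    """Order one linkage group and assign cumulative cM positions.

    Markers are ordered by bp within each scaffold; scaffolds are chained
    greedily, at each step attaching (and orienting) the scaffold whose
    terminal marker has the smallest recombination fraction to either end
    of the growing chain — an automated stand-in for ordering scaffolds
    by hand from the pairwise fractions. Adjacent spacing is the Haldane
    transform -50 ln(1 - 2r), capped at ``max_spacing_cM`` (capped
    intervals are flagged in the returned report).
    """
    sub = g.subset(group_markers)
    by_scaffold: dict[str, list[str]] = {}
    for mid in sub.markers.index:
        by_scaffold.setdefault(str(sub.markers.loc[mid, "scaffold"]), []).append(mid)
    for scf in by_scaffold:
        by_scaffold[scf].sort(key=lambda m: int(sub.markers.loc[m, "pos"]))

    def rf(ma: str, mb: str) -> float:
        ia, ib = g.markers.index.get_loc(ma), g.markers.index.get_loc(mb)
        r = estimate_rf(g.calls[ia], g.calls[ib], ma, mb).r_hat
        return 0.5 if np.isnan(r) else r

    scaffolds = sorted(by_scaffold, key=lambda s: (-len(by_scaffold[s]), s))
    chain = list(by_scaffold[scaffolds[0]])
    for _ in scaffolds[1:]:
        best = None
        for scf in scaffolds[1:]:
            markers_s = by_scaffold[scf]
            if markers_s[0] in chain:
                continue
            for oriented in (markers_s, markers_s[::-1]):
                for end, joined in (("right", chain + oriented), ("left", oriented + chain)):
                    cost = rf(chain[-1], oriented[0]) if end == "right" else rf(
                        oriented[-1], chain[0]
                    )
                    if best is None or cost < best[0]:
                        best = (cost, joined)
        if best is None:
            break
        chain = best[1]

    spacings, capped = [0.0], []
    for ma, mb in zip(chain, chain[1:]):
        r = rf(ma, mb)
        d = haldane_cM(r, max_cM=max_spacing_cM)
        if r >= 0.5:
            capped.append((ma, mb))
        spacings.append(float(d))
    cm = np.cumsum(spacings)
    frag = pd.DataFrame(
        {
            "marker_id": chain,
            "scaffold": [str(g.markers.loc[m, "scaffold"]) for m in chain],
            "pos": [int(g.markers.loc[m, "pos"]) for m in chain],
            "cM": cm,
        }
    )
    return frag, capped


# ---------------------------------------------------------------------------
# Genotype cleaning


def error_lod_scores(
    g: MarkerGenotypes, gmap: GeneticMap, genotype_error_prob: float = 0.01
) -> pd.DataFrame:
    """Error LOD for every typed genotype at a mapped marker.

    The posterior over the true genotype is taken from the HMM with the
    tested marker's own observation left out (flat emission), so it
    reflects only the flanking markers and the 1:2:1 prior; the error LOD
    is the log10 posterior odds that the truth differs from the observed
    call once the call's miscall emission is folded in.
    """
    e = genotype_error_prob
    rows = []
    mapped = set(gmap.table["marker_id"])
    missing_from_map = [m for m in g.markers.index if m not in mapped]
    if missing_from_map:
        warnings.warn(f"{len(missing_from_map)} markers not on the map were skipped")
    for name, sub in gmap.groups():
        ids = [m for m in sub["marker_id"] if m in g.markers.index]
        if not ids:
            continue
        cm = sub.set_index("marker_id").loc[ids, "cM"].to_numpy(float)
        idx = [g.markers.index.get_loc(m) for m in ids]
        em = np.stack([emission_matrix(g.calls[i], e) for i in idx])
        _, loo, _ = forward_backward(em, np.diff(cm))
        for j, (mid, gi) in enumerate(zip(ids, idx)):
            calls = g.calls[gi]
            for k in np.flatnonzero(calls != MISSING):
                c = int(calls[k])
                q = loo[j, k]
                num = (1.0 - q[c]) * (e / 2.0)
                den = q[c] * (1.0 - e)
                errlod = np.log10(num / den) if den > 0 else np.inf
                rows.append((name, mid, g.individuals[k], c, float(errlod)))
    return pd.DataFrame(
        rows, columns=["group", "marker_id", "individual", "call", "error_lod"]
    )


def error_lod_clean(
    g: MarkerGenotypes,
    gmap: GeneticMap,
    genotype_error_prob: float = 0.01,
    threshold: float = 5.0,
):
    """Set genotypes with error LOD > threshold to missing.

    Returns (cleaned, removed) where removed lists the erased calls.
    """
    scores = error_lod_scores(g, gmap, genotype_error_prob)
    removed = scores[scores["error_lod"] > threshold]
    cleaned = g.copy()
    ind_index = {s: i for i, s in enumerate(g.individuals)}
    for row in removed.itertuples(index=False):
        cleaned.calls[g.markers.index.get_loc(row.marker_id), ind_index[row.individual]] = MISSING
    return cleaned, removed.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Drop-one-marker evaluation


def _group_loglik(g: MarkerGenotypes, ids: list[str], cm: np.ndarray,
                  error_prob: float) -> float:
    idx = [g.markers.index.get_loc(m) for m in ids]
    em = np.stack([emission_matrix(g.calls[i], error_prob) for i in idx])
    _, _, logc = forward_backward(em, np.diff(cm))
    return float(logc.sum())


def _unlinked_loglik(g: MarkerGenotypes, mid: str, error_prob: float) -> float:
    em = emission_matrix(g.calls[g.markers.index.get_loc(mid)], error_prob)
    return float(np.log(em @ _PRIOR).sum())


def drop_one_marker_eval(
    gmap: GeneticMap,
    g: MarkerGenotypes,
    shrink_cM: float = 10.0,
    max_gap_bp: int = 1_000_000,
    error_prob: float = 0.01,
    max_spacing_cM: float = 50.0,
    max_iter: int = 10,
):
    """Iteratively drop markers that the map is better off without.

    A marker is dropped when (a) the multipoint likelihood improves —
    all markers' data under the map versus the remaining markers under
    the re-fitted map with the candidate's data modelled as unlinked
    (1:2:1) — or (b) it is non-terminal and its removal shortens the
    group by more than ``shrink_cM`` without physical-distance support
    (its flanking markers are on the same scaffold less than
    ``max_gap_bp`` apart, or on different scaffolds). One marker is
    removed per iteration, to a fixpoint or ``max_iter``. Returns
    (revised_map, dropped_ids).
    """
    tab = gmap.table.copy()
    dropped: list[str] = []
    for _ in range(max_iter):
        worst = None
        for name in dict.fromkeys(tab["group"]):
            sub = tab[tab["group"] == name].reset_index(drop=True)
            if len(sub) < 3:
                continue
            ids = sub["marker_id"].tolist()
            cm = sub["cM"].to_numpy(float)
            length = cm[-1] - cm[0]
            ll_with = _group_loglik(g, ids, cm, error_prob)
            for k in range(len(ids)):
                rest = ids[:k] + ids[k + 1 :]
                spac = np.diff(cm).tolist()
                if 0 < k < len(ids) - 1:
                    ia = g.markers.index.get_loc(ids[k - 1])
                    ib = g.markers.index.get_loc(ids[k + 1])
                    r = estimate_rf(g.calls[ia], g.calls[ib]).r_hat
                    newd = float(haldane_cM(0.5 if np.isnan(r) else r, max_spacing_cM))
                    spac = spac[: k - 1] + [newd] + spac[k + 1 :]
                else:
                    spac = spac[1:] if k == 0 else spac[:-1]
                new_cm = np.concatenate([[0.0], np.cumsum(spac)])
                ll_without = _group_loglik(g, rest, new_cm, error_prob) + _unlinked_loglik(
                    g, ids[k], error_prob
                )
                gain = ll_without - ll_with
                drop_a = gain > 0
                drop_b = False
                if 0 < k < len(ids) - 1:
                    shrink = length - (new_cm[-1] - new_cm[0])
                    scf_a = str(g.markers.loc[ids[k - 1], "scaffold"])
                    scf_b = str(g.markers.loc[ids[k + 1], "scaffold"])
                    gap = abs(
                        int(g.markers.loc[ids[k + 1], "pos"])
                        - int(g.markers.loc[ids[k - 1], "pos"])
                    )
                    supported = scf_a == scf_b and gap >= max_gap_bp
                    drop_b = shrink > shrink_cM and not supported
                if drop_a or drop_b:
                    score = gain if drop_a else 0.0
                    if worst is None or score > worst[0]:
                        worst = (score, name, ids[k], rest, new_cm)
        if worst is None:
            break
        _, name, mid, rest, new_cm = worst
        dropped.append(mid)
        keep = tab["marker_id"] != mid
        tab = tab[keep].reset_index(drop=True)
        sel = tab["group"] == name
        tab.loc[sel, "cM"] = new_cm
    return GeneticMap(tab.reset_index(drop=True)), dropped


# ---------------------------------------------------------------------------
# Pipeline


def build_map(
    g: MarkerGenotypes,
    alpha: float = 0.01,
    max_rf: float = 0.15,
    min_lod: float = 6.0,
    error_prob: float = 0.01,
    error_lod_threshold: float = 5.0,
    shrink_cM: float = 10.0,
    max_spacing_cM: float = 50.0,
):
    """Run the full staged map build; autosomes and Z mapped separately.

    Returns (map, cleaned_genotypes, report). Stage order is fixed:
    distortion filter, duplicate collapse, genotyping-rate filter,
    pairwise linkage, grouping, ordering/spacing, error-LOD cleaning,
    drop-one-marker evaluation.
    """
    report: dict = {"n_input": g.n_markers}
    g1, distortion_report = segregation_filter(g, alpha=alpha)
    report["n_after_distortion"] = g1.n_markers
    g2, dup_map = collapse_duplicates(g1)
    report["n_after_duplicates"] = g2.n_markers
    g3 = genotyping_rate_filter(g2)
    report["n_after_rate_filter"] = g3.n_markers

    fragments = []
    singletons: list[str] = []
    group_counter = 0
    for cls, prefix in ((AUTOSOMAL, "LG"), (Z_LINKED, "ZLG")):
        ids = [m for m in g3.markers.index if g3.markers.loc[m, "chrom_class"] == cls]
        if not ids:
            continue
        sub = g3.subset(ids)
        pairs = pairwise_linkage(sub)
        groups, singles = form_groups(pairs, ids, max_rf=max_rf, min_lod=min_lod)
        singletons.extend(singles)
        groups.sort(key=len, reverse=True)
        for members in groups:
            group_counter += 1
            frag, _ = order_and_space(g3, members, max_spacing_cM=max_spacing_cM)
            frag.insert(0, "group", f"{prefix}{group_counter}")
            fragments.append(frag)
    gmap = GeneticMap(pd.concat(fragments, ignore_index=True)) if fragments else GeneticMap()
    report["n_groups"] = group_counter
    report["n_singletons"] = len(singletons)

    cleaned, removed = error_lod_clean(
        g3.subset(gmap.table["marker_id"]), gmap,
        genotype_error_prob=error_prob, threshold=error_lod_threshold,
    )
    report["n_genotypes_removed"] = len(removed)
    gmap, dropped = drop_one_marker_eval(
        gmap, cleaned, shrink_cM=shrink_cM, error_prob=error_prob,
        max_spacing_cM=max_spacing_cM,
    )
    report["n_markers_dropped_eval"] = len(dropped)
    report["distortion"] = distortion_report
    report["duplicates"] = dup_map
    report["singletons"] = singletons
    cleaned = cleaned.subset(gmap.table["marker_id"])
    return gmap, cleaned, report
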