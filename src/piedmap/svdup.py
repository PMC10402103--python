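"""Tandem-duplication detection from windowed read depth, plus
copy-specific expression classification.

Depth in non-overlapping windows is normalized so the genome-wide
reference statistic (median by default, robust to the duplication
itself) maps to copy number 2. A duplication call is a run of
consecutive windows at or above a copy-number gain threshold;
half-open cutpoints of 2.5 and 3.5 — midpoints between the expected
integer copy-number bands — separate absent / heterozygous / homozygous
states. Soft-clip records whose clipped sequence remaps to the partner
edge of a tandem junction refine breakpoints to base-pair precision;
depth remains the primary caller and junction evidence corroborates.

For a duplicated gene, copy-specific polymorphisms are SNPs mono-allelic
in the RNA of white tissue (where only one copy is expressed) but
bi-allelic in pigmented tissue (both copies expressed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HET_MIN, HOM_MIN = 2.5, 3.5  # normalized copy-number cutpoints (half-open)


def normalize_coverage(
    track: pd.DataFrame,
    reference_stat=np.median,
    exclude_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scale windowed depth so the reference statistic equals copy number 2.

    ``normalized = 2 * depth / reference_stat(depth outside the exclusion
    mask)``. Requires at least 10 windows and a positive reference value.
    """
    if len(track) < 10:
        raise ValueError("need at least 10 windows to normalize")
    depth = track["depth"].to_numpy(float)
    ref_depth = depth if exclude_mask is None else depth[~np.asarray(exclude_mask, bool)]
    ref = float(reference_stat(ref_depth))
    if ref <= 0:
        raise ValueError("reference statistic is zero; cannot normalize")
    out = track.copy()
    out["normalized"] = 2.0 * depth / ref
    return out


@dataclass
class DupCall:
    scaffold: str
    start: int  # half-open bp
    end: int
    genotype: str  # "het" | "hom"
    mean_normalized: float
    bp_uncertainty: int  # +/- bp on each breakpoint
    depth_only: bool = True
    n_softclip: int = 0
    n_discordant: int = 0


def call_duplication(
    track: pd.DataFrame,
    gain_threshold: float = HET_MIN,
    min_windows: int = 3,
) -> list[DupCall]:
    """Duplication candidates from runs of elevated normalized windows.

    A candidate is a maximal run of >= ``min_windows`` consecutive
    windows with normalized copy number >= ``gain_threshold``; the
    segment mean assigns the genotype (< 3.5 het, >= 3.5 hom). Intervals
    are window-resolution pending breakpoint refinement.
    """
    norm = track["normalized"].to_numpy(float)
    above = np.concatenate([[False], norm >= gain_threshold, [False]])
    diff = np.diff(above.astype(np.int8))
    starts, ends = np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)
    window = int(track["end"].iloc[0] - track["start"].iloc[0])
    calls = []
    for s, e in zip(starts, ends):
        if e - s < min_windows:
            continue
        seg = norm[s:e]
        calls.append(
            DupCall(
                scaffold=str(track["scaffold"].iloc[0]),
                start=int(track["start"].iloc[s]),
                end=int(track["end"].iloc[e - 1]),
                genotype="hom" if seg.mean() >= HOM_MIN else "het",
                mean_normalized=float(seg.mean()),
                bp_uncertainty=window,
            )
        )
    return calls


def refine_breakpoints(call: DupCall, evidence: dict[str, pd.DataFrame],
                       search_bp: int | None = None) -> DupCall:
    """Replace window-level breakpoints with modal soft-clip positions.

    Needs clip clusters near both call edges whose clipped sequences
    remap to the partner edge in tandem orientation (left-clipped at the
    start remapping near the end, right-clipped at the end remapping
    near the start). Modal positions get +/-1 bp uncertainty; ties
    between modes leave the call unrefined with a warning. Without
    usable evidence the call keeps its window-level uncertainty and the
    depth-only flag.
    """
    clips = evidence.get("softclip", pd.DataFrame())
    disc = evidence.get("discordant", pd.DataFrame())
    search = search_bp if search_bp is not None else 2 * call.bp_uncertainty
    if len(clips):
        wrong = clips["scaffold"] != call.scaffold
        if wrong.any():
            warnings.warn("soft-clip evidence on another scaffold ignored")
            clips = clips[~wrong]
    if not len(clips):
        return call

    def modal(side: str, near: int, partner: int):
        sel = clips[
            (clips["clip_side"] == side)
            & (clips["position"].sub(near).abs() <= search)
            & (clips["remap_pos"].sub(partner).abs() <= search)
        ]
        if not len(sel):
            return None, 0
        counts = sel["position"].value_counts()
        top = counts[counts == counts.max()]
        if len(top) > 1:
            warnings.warn("tied soft-clip modes; breakpoint left unrefined")
            return None, 0
        return int(top.index[0]), int(counts.max())

    left, n_left = modal("left", call.start, call.end)
    right, n_right = modal("right", call.end, call.start)
    if left is None or right is None:
        return call
    n_disc = 0
    if len(disc):
        near = disc[
            (disc["scaffold"] == call.scaffold)
            & (
                (disc["position"].sub(left).abs() <= search)
                | (disc["position"].sub(right).abs() <= search)
            )
        ]
        n_disc = int(near["count"].sum())
    return DupCall(
        scaffold=call.scaffold,
        start=left,
        end=right,
        genotype=call.genotype,
        mean_normalized=call.mean_normalized,
        bp_uncertainty=1,
        depth_only=False,
        n_softclip=n_left + n_right,
        n_discordant=n_disc,
    )


def screen_samples(
    tracks: dict[str, pd.DataFrame], region: tuple[str, int, int]
) -> pd.DataFrame:
    """Genotype a region's copy state across many samples from depth.

    Mean normalized copy number over the region is binned half-open:
    < 2.5 absent, [2.5, 3.5) het, >= 3.5 hom.
    """
    scaffold, start, end = region
    rows = []
    for sample, track in tracks.items():
        sel = track[
            (track["scaffold"] == scaffold)
            & (track["end"] > start)
            & (track["start"] < end)
        ]
        if sel.empty:
            raise ValueError(f"region outside coverage track for {sample}")
        mean_cn = float(sel["normalized"].mean())
        state = "absent" if mean_cn < HET_MIN else ("het" if mean_cn < HOM_MIN else "hom")
        rows.append((sample, mean_cn, state))
    return pd.DataFrame(rows, columns=["sample", "mean_normalized", "genotype"])


def normalized_expression(
    gene_read_count: float, total_sample_reads: float, scale: float = 1e6
) -> float:
    """Reads in the gene model per ``scale`` total reads in the sample."""
    if total_sample_reads <= 0:
        raise ValueError("total_sample_reads must be positive")
    return gene_read_count / total_sample_reads * scale


def classify_copy_specific(
    table: pd.DataFrame,
    mono_max_fraction: float = 0.05,
    bi_min_fraction: float = 0.20,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Classify SNPs as copy-specific, shared, or uninformative.

    Counts are pooled within tissue. A SNP is copy-specific when the
    white-tissue minor-allele fraction is <= ``mono_max_fraction`` and
    the pigmented-tissue minor-allele fraction is >= ``bi_min_fraction``;
    the allele expressed in white tissue tags the gene copy active in
    both tissues. SNPs lacking a sample at ``min_depth`` in either
    tissue are uninformative.
    """
    rows = []
    for snp, sub in table.groupby("snp_id", sort=False):
        ok = {}
        for tissue in ("white", "pigmented"):
            t = sub[sub["tissue"] == tissue]
            deep = t[(t["ref_count"] + t["alt_count"]) >= min_depth]
            ok[tissue] = deep
        if any(len(ok[t]) == 0 for t in ok):
            rows.append((snp, "uninformative", np.nan, np.nan, ""))
            continue
        fracs = {}
        for tissue, t in ok.items():
            ref, alt = t["ref_count"].sum(), t["alt_count"].sum()
            fracs[tissue] = (min(ref, alt) / (ref + alt), ref, alt)
        w_minor, w_ref, w_alt = fracs["white"]
        p_minor, _, _ = fracs["pigmented"]
        if w_minor <= mono_max_fraction and p_minor >= bi_min_fraction:
            allele = "ref" if w_ref >= w_alt else "alt"
            rows.append((snp, "copy_specific", w_minor, p_minor, allele))
        else:
            rows.append((snp, "shared", w_minor, p_minor, ""))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "class", "white_minor_fraction",
                 "pigmented_minor_fraction", "white_allele"],
    )
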