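"""Shared containers for F2 intercross data and genetic maps.

Genotypes at codominant markers are coded as the number of copies of the
B founder allele: 0 (AA), 1 (AB), 2 (BB), with -1 for missing. Map
distances use the Haldane function (no crossover interference), so a
distance of d centimorgans corresponds to a recombination fraction
r = (1 - e^(-d/50)) / 2 per meiosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: genotype code -> text used in TSV files
CALL_TO_TEXT = {0: "AA", 1: "AB", 2: "BB", MISSING: "-"}
TEXT_TO_CALL = {v: k for k, v in CALL_TO_TEXT.items()}

AUTOSOMAL = "autosomal"
Z_LINKED = "Z-linked"


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction between loci d centimorgans apart."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cM, dtype=float) / 50.0))


def haldane_cM(r: np.ndarray | float, max_cM: float = np.inf) -> np.ndarray | float:
    """Map distance d = -50 ln(1 - 2r); capped at ``max_cM`` for r -> 0.5."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -50.0 * np.log1p(-2.0 * r)
    d = np.where(np.isfinite(d), d, np.inf)
    return np.minimum(d, max_cM) if np.ndim(d) else float(min(d, max_cM))


@dataclass
class MarkerGenotypes:
    """Markers x individuals genotype matrix with marker metadata.

    ``markers`` is indexed by marker id with columns ``scaffold``, ``pos``
    (1-based bp) and ``chrom_class`` (autosomal or Z-linked). ``calls`` is
    int8 of shape (n_markers, n_individuals).
    """

    markers: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError("calls shape does not match markers x individuals")
        if "chrom_class" not in self.markers.columns:
            self.markers = self.markers.assign(chrom_class=AUTOSOMAL)
        if (self.markers["pos"] < 1).any():
            raise ValueError("bp positions must be >= 1")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def subset(self, marker_ids) -> "MarkerGenotypes":
        idx = self.markers.index.get_indexer(marker_ids)
        if (idx < 0).any():
            raise KeyError("unknown marker id in subset")
        return MarkerGenotypes(
            self.markers.iloc[idx].copy(), list(self.individuals), self.calls[idx]
        )

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return (self.calls != MISSING).mean(axis=1)

    def copy(self) -> "MarkerGenotypes":
        return MarkerGenotypes(
            self.markers.copy(), list(self.individuals), self.calls.copy()
        )


@dataclass
class GeneticMap:
    """Ordered linkage groups with cumulative cM positions.

    ``table`` columns: group, marker_id, scaffold, pos, cM — ordered by
    group then map position; cM is non-decreasing within each group.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["group", "marker_id", "scaffold", "pos", "cM"]
        )
    )

    def __post_init__(self) -> None:
        for name, sub in self.table.groupby("group", sort=False):
            if (np.diff(sub["cM"].to_numpy(float)) < -1e-9).any():
                raise ValueError(f"cM positions decrease within group {name}")
        if self.table["marker_id"].duplicated().any():
            raise ValueError("marker appears in more than one map position")

    def groups(self):
        yield from self.table.groupby("group", sort=False)

    def group_names(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def group(self, name) -> pd.DataFrame:
        sub = self.table[self.table["group"] == name]
        if sub.empty:
            raise KeyError(f"no linkage group {name!r}")
        return sub

    def length_cM(self, name) -> float:
        cm = self.group(name)["cM"].to_numpy(float)
        return float(cm[-1] - cm[0]) if len(cm) else 0.0


# ---------------------------------------------------------------------------
# TSV round-trip I/O


def write_genotypes_tsv(g: MarkerGenotypes, path) -> None:
    df = pd.DataFrame(
        np.vectorize(CALL_TO_TEXT.get)(g.calls),
        index=g.markers.index,
        columns=g.individuals,
    )
    out = pd.concat([g.markers[["scaffold", "pos", "chrom_class"]], df], axis=1)
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t")


def read_genotypes_tsv(path) -> MarkerGenotypes:
    df = pd.read_csv(path, sep="\t", index_col="marker_id")
    meta = df[["scaffold", "pos", "chrom_class"]].copy()
    meta["scaffold"] = meta["scaffold"].astype(str)
    ind = [c for c in df.columns if c not in ("scaffold", "pos", "chrom_class")]
    calls = df[ind].apply(lambda col: col.map(TEXT_TO_CALL)).to_numpy(dtype=np.int8)
    return MarkerGenotypes(meta, ind, calls)


def write_map_tsv(gmap: GeneticMap, path) -> None:
    tab = gmap.table.copy()
    tab.insert(1, "order", tab.groupby("group", sort=False).cumcount())
    tab.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    tab = pd.read_csv(path, sep="\t", dtype={"group": str, "scaffold": str})
    tab = tab.drop(columns=["order"], errors="ignore")
    return GeneticMap(tab.reset_index(drop=True))
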