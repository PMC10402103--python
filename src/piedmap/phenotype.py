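"""Quantification of white (depigmented) plumage per body region.

Phenotyping starts from pixel counts produced by upstream image
segmentation: for each bird and body region, the total number of pixels
in the region mask and the number of pixels that remain after white
feathers are removed. The proportion of white plumage is

    white = (whole_pixels - pigmented_pixels) / whole_pixels

scored over a fixed vocabulary of 15 body regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the 15 canonical body regions scored for depigmentation
REGIONS = (
    "dorsal head",
    "right lateral head",
    "left lateral head",
    "dorsal neck",
    "ventral neck",
    "right lateral neck",
    "left lateral neck",
    "dorsal body",
    "ventral body",
    "dorsal tail",
    "ventral tail",
    "dorsal right wing",
    "dorsal left wing",
    "ventral right wing",
    "ventral left wing",
)


class UndefinedRegionError(ValueError):
    """Region with zero whole-image pixels: proportion undefined."""


class InconsistentMaskError(ValueError):
    """Pigmented-pixel count exceeds the whole-region count."""


@dataclass(frozen=True)
class RegionMaskCounts:
    individual_id: str
    region: str
    whole_pixels: int
    pigmented_pixels: int


def white_proportion(whole_pixels: int, pigmented_pixels: int) -> float:
    """Fraction of a region's pixels that are white (non-pigmented)."""
    if whole_pixels <= 0:
        raise UndefinedRegionError("whole_pixels must be positive")
    if pigmented_pixels < 0 or pigmented_pixels > whole_pixels:
        raise InconsistentMaskError(
            f"pigmented_pixels {pigmented_pixels} outside [0, {whole_pixels}]"
        )
    return (whole_pixels - pigmented_pixels) / whole_pixels


def score_table(records: list[RegionMaskCounts]) -> pd.DataFrame:
    """Individuals x 15-region table of white-plumage proportions.

    Unknown region names and duplicate (individual, region) pairs are
    rejected; regions never scored for an individual are NaN.
    """
    seen: set[tuple[str, str]] = set()
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        if rec.region not in REGIONS:
            raise KeyError(f"unknown body region {rec.region!r}")
        key = (rec.individual_id, rec.region)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
        rows.setdefault(rec.individual_id, {})[rec.region] = white_proportion(
            rec.whole_pixels, rec.pigmented_pixels
        )
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(REGIONS), index=sorted(rows)
    )
    table.index.name = "individual_id"
    return table


def read_mask_counts_tsv(path) -> list[RegionMaskCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    return [
        RegionMaskCounts(
            r.individual_id, r.region, int(r.whole_pixels), int(r.pigmented_pixels)
        )
        for r in df.itertuples(index=False)
    ]


def write_mask_counts_tsv(records: list[RegionMaskCounts], path) -> None:
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    df.index = df.index.astype(str)
    bad = ~(df.isna() | ((df >= 0) & (df <= 1)))
    if bad.to_numpy().any():
        raise ValueError("phenotype values outside [0, 1]")
    return df
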