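"""Final-map assembly and summary statistics.

Cross-map linkage groups and LD anchors are combined into a final map whose
LGs are renamed by Roman numerals in descending order of physical size
(megabases of assigned scaffold sequence, split scaffolds contributing
half-weight to each of their two LGs).  The module also computes the
summary statistics a linkage-map study reports: a per-LG table with
totals, the map N50 against a reference genome size, mapped and core
genome fractions, and the genome-wide recombination rate
(mean of the two parental map totals divided by genome size).

The reference genome size defaults to 916 Mb, the cytometric genome size
of *Biomphalaria glabrata*; the published per-LG summary table for that
map ships as package data for end-to-end checks.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .crossmap import LinkageGroupDraft
from .ldanchor import AnchorAssignment

__all__ = [
    "FinalMap",
    "N50Result",
    "GenomeStats",
    "build_final_map",
    "summarize",
    "map_n50",
    "genome_stats",
    "to_roman",
    "load_published_lg_table",
]

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def to_roman(n: int) -> str:
    if n < 1:
        raise ValueError("Roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def roman_rank(s: str) -> int:
    vals = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}
    total = 0
    prev = 0
    for ch in reversed(s):
        v = vals[ch]
        total = total - v if v < prev else total + v
        prev = max(prev, v)
    return total


@dataclasses.dataclass
class FinalMap:
    """Named linkage groups with weighted scaffold membership."""

    lgs: pd.DataFrame  # lg, parent_a_cm, parent_b_cm, cross_markers, scaffolds, mb, core
    scaffold_weights: pd.DataFrame  # scaffold_id, lg, weight, source
    genome_size_mb: float = 916.0


class N50Result(NamedTuple):
    n50_mb: float
    rank: int
    reached: bool


@dataclasses.dataclass
class GenomeStats:
    mapped_fraction: float
    core_fraction: float
    core_mb: float
    recomb_rate_cm_per_mb: float
    noncore_core_ratio: float  # largest non-core LG over smallest core LG


def detect_core_count(sizes_mb: Sequence[float]) -> int:
    """Largest relative size gap in the descending size list."""
    sizes = np.sort(np.asarray(sizes_mb, dtype=float))[::-1]
    if len(sizes) < 2:
        return len(sizes)
    ratios = sizes[1:] / np.maximum(sizes[:-1], 1e-300)
    return int(np.argmin(ratios)) + 1


def build_final_map(
    drafts: Sequence[LinkageGroupDraft],
    anchors: Sequence[AnchorAssignment],
    scaffold_lengths: Mapping[str, int],
    genome_size_mb: float = 916.0,
    core_count: int | None = None,
) -> FinalMap:
    """Combine cross-map drafts and LD anchors into the named final map.

    Scaffolds carrying cross markers take weight 1 on the draft holding the
    majority of their markers; LD-anchored scaffolds take weight 1 (or 0.5
    each on two LGs when split).  A scaffold assigned full weight twice is
    an integrity error.
    """
    weight_rows: list[tuple[str, str, float, str]] = []
    cross_assigned: dict[str, str] = {}
    claim: dict[str, float] = {}
    for d in drafts:
        for scaf in d.scaffolds:
            cross_assigned.setdefault(scaf, d.lg_id)
    # a scaffold whose markers landed in two drafts goes with the larger
    # draft (drafts are ordered largest-first and setdefault keeps the first)
    for scaf, lg in cross_assigned.items():
        weight_rows.append((scaf, lg, 1.0, "cross"))
        claim[scaf] = claim.get(scaf, 0.0) + 1.0
    for a in anchors:
        for lg, w in a.lgs:
            weight_rows.append((a.scaffold_id, lg, w, "ld"))
            claim[a.scaffold_id] = claim.get(a.scaffold_id, 0.0) + w
    bad = {s: w for s, w in claim.items() if w > 1.0 + 1e-9}
    if bad:
        raise ValueError(f"scaffolds assigned more than full weight: {sorted(bad)[:5]}")
    weights = pd.DataFrame(
        weight_rows, columns=["scaffold_id", "lg", "weight", "source"]
    )
    weights["length_bp"] = weights["scaffold_id"].map(scaffold_lengths).fillna(0).astype(int)
    weights["mb"] = weights["weight"] * weights["length_bp"] / 1e6

    by_lg = weights.groupby("lg").agg(
        scaffolds=("weight", "sum"), mb=("mb", "sum")
    )
    draft_info = {
        d.lg_id: (
            d.spans.get("A", 0.0),
            d.spans.get("B", 0.0),
            d.n_markers,
        )
        for d in drafts
    }
    by_lg["parent_a_cm"] = [draft_info.get(lg, (0.0, 0.0, 0))[0] for lg in by_lg.index]
    by_lg["parent_b_cm"] = [draft_info.get(lg, (0.0, 0.0, 0))[1] for lg in by_lg.index]
    by_lg["cross_markers"] = [draft_info.get(lg, (0.0, 0.0, 0))[2] for lg in by_lg.index]
    by_lg = by_lg.sort_index().sort_values("mb", ascending=False, kind="stable")
    rename = {old: to_roman(i + 1) for i, old in enumerate(by_lg.index)}
    by_lg.index = [rename[old] for old in by_lg.index]
    weights["lg"] = weights["lg"].map(rename)

    lgs = by_lg.reset_index(names="lg")[
        ["lg", "parent_a_cm", "parent_b_cm", "cross_markers", "scaffolds", "mb"]
    ]
    k = core_count if core_count is not None else min(detect_core_count(lgs["mb"]), len(lgs))
    lgs["core"] = np.arange(len(lgs)) < k
    return FinalMap(
        lgs=lgs,
        scaffold_weights=weights[["scaffold_id", "lg", "weight", "source"]],
        genome_size_mb=genome_size_mb,
    )


def summarize(final_map: FinalMap) -> tuple[pd.DataFrame, pd.Series]:
    """Per-LG rows plus a totals row (cM per parent, markers, scaffolds, Mb)."""
    rows = final_map.lgs[
        ["lg", "parent_a_cm", "parent_b_cm", "cross_markers", "scaffolds", "mb"]
    ].copy()
    totals = pd.Series(
        {
            "parent_a_cm": float(rows["parent_a_cm"].sum()),
            "parent_b_cm": float(rows["parent_b_cm"].sum()),
            "cross_markers": int(rows["cross_markers"].sum()),
            "scaffolds": float(rows["scaffolds"].sum()),
            "mb": float(rows["mb"].sum()),
        }
    )
    return rows, totals


def map_n50(lg_sizes_mb: Sequence[float], genome_size_mb: float) -> N50Result:
    """Size and rank of the LG at which cumulative size reaches half the genome."""
    sizes = np.sort(np.asarray(lg_sizes_mb, dtype=float))[::-1]
    if len(sizes) == 0:
        raise ValueError("no linkage group sizes supplied")
    if (sizes <= 0).any():
        raise ValueError("sizes must be positive")
    half = genome_size_mb / 2.0
    cum = np.cumsum(sizes)
    hit = np.flatnonzero(cum >= half)
    if len(hit) == 0:
        return N50Result(float("nan"), len(sizes), False)
    k = int(hit[0])
    return N50Result(float(sizes[k]), k + 1, True)


def genome_stats(final_map: FinalMap) -> GenomeStats:
    """Mapped/core genome fractions and the genome-wide recombination rate."""
    if final_map.genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    _, totals = summarize(final_map)
    lgs = final_map.lgs
    core = lgs[lgs["core"]] if "core" in lgs.columns else lgs
    core_mb = float(core["mb"].sum())
    rate = (totals["parent_a_cm"] + totals["parent_b_cm"]) / 2.0 / final_map.genome_size_mb
    noncore = lgs[~lgs["core"]] if "core" in lgs.columns else lgs.iloc[0:0]
    if len(noncore) and len(core):
        ratio = float(noncore["mb"].max() / core["mb"].min())
    else:
        ratio = float("nan")
    return GenomeStats(
        mapped_fraction=float(totals["mb"] / final_map.genome_size_mb),
        core_fraction=core_mb / final_map.genome_size_mb,
        core_mb=core_mb,
        recomb_rate_cm_per_mb=float(rate),
        noncore_core_ratio=ratio,
    )


def load_published_lg_table() -> pd.DataFrame:
    """The published *B. glabrata* per-LG summary table (package data)."""
    with resources.files("scafmap.data").joinpath("bglabrata_lg_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def published_final_map(genome_size_mb: float = 916.0, core_count: int = 18) -> FinalMap:
    """Wrap the published table as a :class:`FinalMap` for summary statistics."""
    df = load_published_lg_table().copy()
    df["core"] = np.arange(len(df)) < core_count
    weights = pd.DataFrame(columns=["scaffold_id", "lg", "weight", "source"])
    return FinalMap(lgs=df, scaffold_weights=weights, genome_size_mb=genome_size_mb)
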