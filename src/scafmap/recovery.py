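"""Truth-table scoring of synthetic-data runs.

These helpers compare pipeline output against the generator's truth: which
chromosome each marker and scaffold really came from.  They are only
meaningful for simulated data and are what the recovery checks in the test
suite and the acceptance script are built on.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .crossmap import LinkageGroupDraft
from .ldanchor import AnchorAssignment
from .matrix import GenotypeMatrix
from .simdata import TruthTable

__all__ = [
    "GroupingScore",
    "AnchoringScore",
    "grouping_recovery",
    "draft_chromosomes",
    "anchorable_scaffolds",
    "anchoring_recovery",
]


@dataclasses.dataclass
class GroupingScore:
    n_major_groups: int
    n_markers_major: int
    marker_accuracy: float  # fraction of major-group markers on the majority chromosome
    group_sizes: list[int]


@dataclasses.dataclass
class AnchoringScore:
    n_anchorable: int
    n_assigned: int
    assignment_rate: float
    n_correct: float
    accuracy: float


def grouping_recovery(
    drafts: Sequence[LinkageGroupDraft],
    truth: TruthTable,
    min_major_markers: int = 10,
) -> GroupingScore:
    """Major-group count and marker placement accuracy against the truth."""
    chrom_of = truth.marker_chromosome()
    majors = [d for d in drafts if d.n_markers >= min_major_markers]
    total = 0
    correct = 0
    for d in majors:
        chroms = chrom_of.reindex(d.marker_ids).dropna()
        if len(chroms) == 0:
            continue
        majority = chroms.mode().iloc[0]
        total += len(chroms)
        correct += int((chroms == majority).sum())
    return GroupingScore(
        n_major_groups=len(majors),
        n_markers_major=total,
        marker_accuracy=correct / total if total else float("nan"),
        group_sizes=sorted((d.n_markers for d in drafts), reverse=True),
    )


def draft_chromosomes(
    drafts: Sequence[LinkageGroupDraft], truth: TruthTable
) -> dict[str, str]:
    """Majority truth chromosome per draft linkage group."""
    chrom_of = truth.marker_chromosome()
    out = {}
    for d in drafts:
        chroms = chrom_of.reindex(d.marker_ids).dropna()
        if len(chroms):
            out[d.lg_id] = chroms.mode().iloc[0]
    return out


def anchorable_scaffolds(
    truth: TruthTable,
    mapped: Mapping[str, str],
    panel_matrix: GenotypeMatrix,
    reach_bp: int = 50_000,
) -> list[str]:
    """Unmapped unique scaffolds the panel design can in principle anchor.

    A scaffold counts as anchorable when it carries at least one retained
    panel marker and at least two distinct cross-mapped scaffolds (each with
    retained panel markers) have a marker within ``reach_bp`` of one of its
    markers on the true chromosome.  ``reach_bp`` is the design's meaningful
    LD range; see the methods note.
    """
    tm = truth.markers.set_index("marker_id")
    retained = panel_matrix.markers["marker_id"]
    info = tm.loc[tm.index.intersection(retained)]
    scaf_meta = truth.scaffolds.set_index("scaffold_id")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for row in info.itertuples():
        by_chrom.setdefault(row.chromosome_id, []).append((int(row.chrom_bp), row.scaffold_id))
    out = []
    for scaf, sub in info.groupby("scaffold_id"):
        if scaf in mapped or not bool(scaf_meta.loc[scaf, "is_unique"]):
            continue
        chrom = sub["chromosome_id"].iloc[0]
        own = sub["chrom_bp"].to_numpy()
        partners = set()
        for bp, other in by_chrom.get(chrom, []):
            if other == scaf or other not in mapped:
                continue
            if np.min(np.abs(own - bp)) <= reach_bp:
                partners.add(other)
        if len(partners) >= 2:
            out.append(scaf)
    return sorted(out)


def anchoring_recovery(
    assignments: Iterable[AnchorAssignment],
    anchorable: Sequence[str],
    truth: TruthTable,
    lg_chromosome: Mapping[str, str],
) -> AnchoringScore:
    """Assignment rate over anchorable scaffolds and truth accuracy of assignments."""
    scaf_chrom = truth.scaffold_chromosome()
    anchorable_set = set(anchorable)
    assigned = [a for a in assignments if a.status in ("anchored", "split")]
    n_assigned_anchorable = sum(1 for a in assigned if a.scaffold_id in anchorable_set)
    n_correct = 0.0
    for a in assigned:
        true_chrom = scaf_chrom.get(a.scaffold_id)
        if any(lg_chromosome.get(lg) == true_chrom for lg, _ in a.lgs):
            n_correct += 1
    return AnchoringScore(
        n_anchorable=len(anchorable),
        n_assigned=n_assigned_anchorable,
        assignment_rate=n_assigned_anchorable / len(anchorable) if anchorable else float("nan"),
        n_correct=n_correct,
        accuracy=n_correct / len(assigned) if assigned else float("nan"),
    )
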