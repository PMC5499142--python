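#!/usr/bin/env python
"""Combine cross-map groups and LD anchors into the named final map.

Renames linkage groups by Roman numerals in descending megabase order,
writes the scaffold membership and per-LG summary tables, and prints the
map-level statistics (N50, mapped fraction, recombination rate).
"""

from pathlib import Path

import pandas as pd

from scafmap.crossmap import LinkageGroupDraft
from scafmap.ldanchor import AnchorAssignment
from scafmap.mapsummary import build_final_map, genome_stats, map_n50, summarize

OUT = Path(__file__).resolve().parent.parent / "results"


def load_drafts() -> list[LinkageGroupDraft]:
    groups = pd.read_csv(OUT / "cross_map_groups.tsv", sep="\t")
    markers = pd.read_csv(OUT / "cross_map_markers.tsv", sep="\t")
    drafts = []
    for row in groups.itertuples(index=False):
        sub = markers[markers["lg"] == row.lg]
        d = LinkageGroupDraft(
            row.lg,
            sorted(set(sub["marker_id"])),
            set(sub["scaffold_id"]),
        )
        d.spans = {"A": float(row.span_a_cm), "B": float(row.span_b_cm)}
        drafts.append(d)
    return drafts


def load_anchors() -> list[AnchorAssignment]:
    df = pd.read_csv(OUT / "ld_anchors.tsv", sep="\t")
    out = []
    for scaf, sub in df.groupby("scaffold_id"):
        status = sub["status"].iloc[0]
        lgs = [
            (r.lg, float(r.weight))
            for r in sub.itertuples(index=False)
            if isinstance(r.lg, str) and r.lg and r.weight > 0
        ]
        out.append(AnchorAssignment(scaf, status, lgs))
    return out


def main() -> None:
    lengths = pd.read_csv(OUT / "scaffolds.tsv", sep="\t")
    scaffold_lengths = dict(zip(lengths["scaffold_id"], lengths["length_bp"]))
    genome_mb = lengths["length_bp"].sum() / 1e6

    fm = build_final_map(
        load_drafts(), load_anchors(), scaffold_lengths,
        genome_size_mb=genome_mb, core_count=18,
    )
    fm.scaffold_weights.to_csv(OUT / "final_map_scaffolds.tsv", sep="\t", index=False)
    rows, totals = summarize(fm)
    rows.to_csv(OUT / "final_map_summary.tsv", sep="\t", index=False)

    n50 = map_n50(fm.lgs["mb"], genome_mb)
    stats = genome_stats(fm)
    print(rows.head(20).to_string(index=False))
    print(
        f"totals: {totals['parent_a_cm']:.1f} / {totals['parent_b_cm']:.1f} cM, "
        f"{int(totals['cross_markers'])} markers, {totals['scaffolds']:.1f} scaffolds, "
        f"{totals['mb']:.2f} Mb"
    )
    print(f"map N50 {n50.n50_mb:.3f} Mb at rank {n50.rank}")
    print(
        f"mapped fraction {100 * stats.mapped_fraction:.1f}%, core "
        f"{100 * stats.core_fraction:.1f}%, rate {stats.recomb_rate_cm_per_mb:.2f} cM/Mb"
    )
    print("-> final_map_scaffolds.tsv, final_map_summary.tsv")


if __name__ == "__main__":
    main()
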