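#!/usr/bin/env python
"""Generate the study's synthetic inputs: genome, cross family, LD panel.

Writes the scaffold table, truth tables, and VCFs for the cross and panel
under results/, and prints what was generated.
"""

from pathlib import Path

import pandas as pd

from scafmap.matrix import write_scaffold_table, write_vcf
from scafmap.pipelines import (
    CROSS_BAD_SAMPLES,
    CROSS_CM_PER_MB,
    CROSS_MARKER_DENSITY,
    CROSS_N_OFFSPRING,
    CROSS_NOISE,
    DEFAULT_GENOME,
    PANEL_FOUNDERS,
    PANEL_GENERATIONS,
    PANEL_MARKER_DENSITY,
    PANEL_N_SAMPLES,
    PANEL_NOISE,
    PANEL_POP_SIZE,
)
from scafmap.simdata import (
    NoiseModel,
    apply_noise,
    simulate_cross,
    simulate_genome,
    simulate_population,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    genome, truth = simulate_genome(DEFAULT_GENOME, SEED)
    scaffolds = genome.scaffolds.copy()
    scaffolds["length_bp"] = scaffolds["end_bp"] - scaffolds["start_bp"]
    write_scaffold_table(scaffolds, OUT / "scaffolds.tsv")
    print(
        f"genome: {len(genome.chromosome_lengths)} chromosomes, "
        f"{len(scaffolds)} scaffolds "
        f"({(~scaffolds['is_unique']).sum()} repetitive)"
    )

    family, cross_raw, truth = simulate_cross(
        genome, truth,
        n_offspring=CROSS_N_OFFSPRING,
        marker_density=CROSS_MARKER_DENSITY,
        cm_per_mb=CROSS_CM_PER_MB,
        seed=SEED + 1,
    )
    cross_noisy = apply_noise(
        cross_raw,
        NoiseModel(**CROSS_NOISE, sample_missing_rates=CROSS_BAD_SAMPLES),
        SEED + 2,
    )
    write_vcf(cross_noisy, OUT / "cross.vcf")
    pd.DataFrame(
        {
            "marker_id": cross_raw.markers["marker_id"],
            "parent_a": family.parentA_genotypes,
            "parent_b": family.parentB_genotypes,
        }
    ).to_csv(OUT / "cross_parents.tsv", sep="\t", index=False)
    print(f"cross: {cross_noisy.n_markers} markers x {cross_noisy.n_samples} offspring -> cross.vcf")

    _, panel_raw, truth = simulate_population(
        genome, truth,
        n_samples=PANEL_N_SAMPLES,
        founders=PANEL_FOUNDERS,
        generations=PANEL_GENERATIONS,
        pop_size=PANEL_POP_SIZE,
        marker_density=PANEL_MARKER_DENSITY,
        cm_per_mb=CROSS_CM_PER_MB,
        seed=SEED + 10,
    )
    panel_noisy = apply_noise(panel_raw, NoiseModel(**PANEL_NOISE), SEED + 11)
    write_vcf(panel_noisy, OUT / "panel.vcf")
    print(f"panel: {panel_noisy.n_markers} markers x {panel_noisy.n_samples} snails -> panel.vcf")

    truth.to_tsv(OUT / "truth_scaffolds.tsv", OUT / "truth_markers.tsv")
    print("truth tables -> truth_scaffolds.tsv, truth_markers.tsv")


if __name__ == "__main__":
    main()
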