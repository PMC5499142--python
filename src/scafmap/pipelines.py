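"""End-to-end pipeline drivers at the package's default study conditions.

The defaults here ARE the desk-scale study conditions: an 18-chromosome,
1 Mb-per-chromosome genome in ~500 log-normal scaffolds with a 10%
repetitive fraction; a 96-offspring cross (two planted high-missingness
samples emulate the two excluded libraries, leaving 94) at 60 markers/Mb
and 40 cM per chromosome; and a 96-sample LD panel descended from two
founder haplotypes through four generations of random mating in a
population of 192, at 120 markers/Mb.  The numbered scripts under
``analysis/``, the acceptance checks and the test suite all run these same
functions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .crossmap import LinkageGroupDraft, map_cross, two_point
from .ldanchor import AnchorAssignment, anchor_scaffolds, find_meaningful_pairs, perfect_ld_blocks
from .markerqc import (
    SegregationType,
    classify_matrix,
    exclude_high_missing_samples,
    filter_cross_markers,
    filter_ld_markers,
    prune_redundant,
)
from .matrix import GenotypeMatrix
from .mapsummary import FinalMap, build_final_map
from .recovery import (
    AnchoringScore,
    GroupingScore,
    anchorable_scaffolds,
    anchoring_recovery,
    draft_chromosomes,
    grouping_recovery,
)
from .simdata import (
    CrossFamily,
    GenomeConfig,
    NoiseModel,
    SimGenome,
    TruthTable,
    apply_noise,
    simulate_cross,
    simulate_genome,
    simulate_population,
)

__all__ = [
    "CrossResult",
    "AnchorResult",
    "run_cross_pipeline",
    "run_anchor_pipeline",
    "run_block_pipeline",
    "rf_bias_experiment",
    "synthetic_orthologs",
]

# study conditions -----------------------------------------------------------

DEFAULT_GENOME = GenomeConfig()
CROSS_N_OFFSPRING = 96
CROSS_MARKER_DENSITY = 60.0
CROSS_CM_PER_MB = 40.0
CROSS_NOISE = dict(genotype_error_rate=0.01, missing_rate=0.05, low_conf_rate=0.03)
# two failed libraries, excluded later by the >50%-missing rule
CROSS_BAD_SAMPLES = {0: 0.60, 1: 0.56}
PANEL_N_SAMPLES = 96
PANEL_FOUNDERS = 2
PANEL_GENERATIONS = 4
PANEL_POP_SIZE = 192
PANEL_MARKER_DENSITY = 120.0
PANEL_NOISE = dict(genotype_error_rate=0.001, missing_rate=0.02, low_conf_rate=0.02)
ANCHOR_REACH_BP = 20_000

BLOCK_GENOME = GenomeConfig(
    n_chromosomes=1,
    chromosome_length_bp=12_000_000,
    scaffolds_per_chromosome=48,
    repeat_fraction=0.0,
    scaffold_length_sigma=0.0,
)
BLOCK_WINDOW = ("chr01", 4_000_000, 8_000_000)
BLOCK_GENERATIONS = 12
BLOCK_MARKER_DENSITY = 30.0


@dataclasses.dataclass
class CrossResult:
    genome: SimGenome
    truth: TruthTable
    family: CrossFamily
    matrix: GenotypeMatrix  # filtered, 94 retained offspring
    excluded_samples: list[str]
    parentA: np.ndarray
    parentB: np.ndarray
    types: pd.Series
    drafts: list[LinkageGroupDraft]
    grouping: GroupingScore
    mapped: dict[str, str]  # scaffold -> draft lg id


@dataclasses.dataclass
class AnchorResult:
    matrix: GenotypeMatrix  # filtered + pruned panel
    truth: TruthTable
    pairs: pd.DataFrame
    assignments: list[AnchorAssignment]
    anchorable: list[str]
    score: AnchoringScore
    final_map: FinalMap


def _parent_arrays(family: CrossFamily, raw: GenotypeMatrix, kept: GenotypeMatrix):
    pa = pd.Series(family.parentA_genotypes, index=raw.markers["marker_id"])
    pb = pd.Series(family.parentB_genotypes, index=raw.markers["marker_id"])
    ids = kept.markers["marker_id"]
    return pa.reindex(ids).to_numpy(), pb.reindex(ids).to_numpy()


def run_cross_pipeline(seed: int, genome_config: GenomeConfig | None = None) -> CrossResult:
    """Simulate, filter, type and map the default linkage cross."""
    cfg = genome_config or DEFAULT_GENOME
    genome, truth = simulate_genome(cfg, seed)
    family, raw, truth = simulate_cross(
        genome,
        truth,
        n_offspring=CROSS_N_OFFSPRING,
        marker_density=CROSS_MARKER_DENSITY,
        cm_per_mb=CROSS_CM_PER_MB,
        seed=seed + 1,
    )
    noisy = apply_noise(
        raw, NoiseModel(**CROSS_NOISE, sample_missing_rates=CROSS_BAD_SAMPLES), seed + 2
    )
    filt = filter_cross_markers(noisy)
    filt, excluded = exclude_high_missing_samples(filt)
    parentA, parentB = _parent_arrays(family, raw, filt)
    types = classify_matrix(filt, parentA, parentB)
    types, drafts = map_cross(filt, parentA, parentB, types=types)
    score = grouping_recovery(drafts, truth)
    mapped: dict[str, str] = {}
    for d in drafts:
        for scaf in d.scaffolds:
            mapped.setdefault(scaf, d.lg_id)
    return CrossResult(
        genome, truth, family, filt, excluded, parentA, parentB, types, drafts, score, mapped
    )


def run_anchor_pipeline(seed: int, cross: CrossResult) -> AnchorResult:
    """Simulate the LD panel, find meaningful LD, anchor, and build the map."""
    _, praw, truth = simulate_population(
        cross.genome,
        cross.truth,
        n_samples=PANEL_N_SAMPLES,
        founders=PANEL_FOUNDERS,
        generations=PANEL_GENERATIONS,
        pop_size=PANEL_POP_SIZE,
        marker_density=PANEL_MARKER_DENSITY,
        cm_per_mb=CROSS_CM_PER_MB,
        seed=seed + 10,
    )
    noisy = apply_noise(praw, NoiseModel(**PANEL_NOISE), seed + 11)
    filt = filter_ld_markers(noisy, mode="capture")
    pruned = prune_redundant(filt)
    pairs = find_meaningful_pairs(pruned)
    assignments = anchor_scaffolds(pairs, cross.mapped)
    anchorable = anchorable_scaffolds(truth, cross.mapped, pruned, reach_bp=ANCHOR_REACH_BP)
    score = anchoring_recovery(
        assignments, anchorable, truth, draft_chromosomes(cross.drafts, truth)
    )
    genome_mb = sum(cross.genome.chromosome_lengths) / 1e6
    final_map = build_final_map(
        cross.drafts,
        assignments,
        cross.genome.scaffold_lengths,
        genome_size_mb=genome_mb,
        core_count=min(len(cross.genome.chromosome_lengths), len(cross.drafts)),
    )
    return AnchorResult(pruned, truth, pairs, assignments, anchorable, score, final_map)


def run_block_pipeline(seed: int):
    """Plant a 4 Mb zero-recombination window and recover it as an LD block."""
    genome, truth = simulate_genome(BLOCK_GENOME, seed)
    _, praw, truth = simulate_population(
        genome,
        truth,
        n_samples=PANEL_N_SAMPLES,
        founders=2,
        generations=BLOCK_GENERATIONS,
        pop_size=PANEL_POP_SIZE,
        marker_density=BLOCK_MARKER_DENSITY,
        cm_per_mb=CROSS_CM_PER_MB,
        zero_recomb_window=BLOCK_WINDOW,
        indel_fraction=0.0,
        seed=seed + 1,
    )
    noisy = apply_noise(praw, NoiseModel(**PANEL_NOISE), seed + 2)
    filt = filter_ld_markers(noisy, mode="capture")
    pruned = prune_redundant(filt)
    pairs = find_meaningful_pairs(pruned)
    blocks = perfect_ld_blocks(pairs, genome.scaffold_lengths)
    return genome, truth, pruned, blocks


def rf_bias_experiment(
    seed: int, true_rf: float = 0.1, n_offspring: int = 94, n_replicates: int = 500
) -> float:
    """Mean error of rf-hat for fully informative pairs at the given truth."""
    rng = np.random.default_rng(seed)
    errors = np.empty(n_replicates)
    for i in range(n_replicates):
        t1 = rng.integers(0, 2, size=n_offspring).astype(np.int8)
        rec = rng.random(n_offspring) < true_rf
        t2 = np.where(rec, 1 - t1, t1).astype(np.int8)
        res = two_point(
            "m1", "m2", t1, t2, SegregationType.D1_10, SegregationType.D1_10,
            parents_x=(1, 0), parents_y=(1, 0),
        )
        errors[i] = res.rf - true_rf
    return float(errors.mean())


def synthetic_orthologs(
    scaffold_chromosome: pd.Series,
    scaffold_weights: pd.DataFrame,
    n_external: int = 60,
    genes_per_scaffold: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy cross-species ortholog table with true synteny.

    Each external scaffold draws its focal orthologs from mapped scaffolds
    of a single true chromosome, so concordance should be strongly enriched
    over chance.  ``scaffold_chromosome`` maps focal scaffolds to their true
    chromosome; ``scaffold_weights`` is the final map's membership table.
    """
    rng = np.random.default_rng(seed)
    scaf_chrom = scaffold_chromosome
    mapped_scafs = scaffold_weights["scaffold_id"].unique()
    by_chrom: dict[str, list[str]] = {}
    for s in mapped_scafs:
        by_chrom.setdefault(scaf_chrom.get(s, "?"), []).append(s)
    chroms = sorted(c for c, lst in by_chrom.items() if len(lst) >= genes_per_scaffold)
    rows = []
    g = 0
    for i in range(n_external):
        chrom = chroms[int(rng.integers(len(chroms)))]
        picks = rng.choice(by_chrom[chrom], size=genes_per_scaffold, replace=False)
        for s in picks:
            g += 1
            rows.append(
                (f"ext_g{g:04d}", f"foc_g{g:04d}", 1e-150, 300, 300, f"EXT_{i + 1:03d}", s)
            )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "e_value", "length_a", "length_b", "scaffold_a", "scaffold_b"],
    )
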