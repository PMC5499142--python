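"""Synthetic genomes, F1 crosses and LD panels with known truth.

This module emulates the statistical setting of scaffold anchoring in a
fragmented assembly: a genome of 18 chromosomes broken into many scaffolds
of skewed size (with a repetitive, unmappable fraction), a linkage cross of
two outbred heterozygous parents and ~96 F1 offspring, and a panel of ~96
diploids from a bottlenecked laboratory strain whose linkage disequilibrium
decays with physical distance and can contain large zero-recombination
blocks.  Everything is generated at desk scale (megabase chromosomes) so
the full pipeline runs in minutes, and every simulated scaffold and marker
is recorded in a :class:`TruthTable` for recovery scoring.

Crossovers follow a Haldane model: counts are Poisson with mean equal to
the genetic length in Morgans, positions uniform on the genetic map, with
no interference.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, read_vcf, write_vcf

__all__ = [
    "GenomeConfig",
    "SimGenome",
    "TruthTable",
    "CrossFamily",
    "PopulationPanel",
    "NoiseModel",
    "simulate_genome",
    "simulate_cross",
    "simulate_population",
    "apply_noise",
    "vcf_roundtrip",
    "genome_sequences",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenomeConfig:
    """Scale model of the assembly context.

    Defaults give 18 chromosomes of 1 Mb fragmented into ~500 scaffolds with
    log-normal sizes and a 10% repetitive (non-unique) fraction.
    """

    n_chromosomes: int = 18
    chromosome_length_bp: int = 1_000_000
    scaffolds_per_chromosome: int = 28
    repeat_fraction: float = 0.10
    scaffold_length_sigma: float = 0.9  # log-normal shape; 0 -> equal sizes

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if self.chromosome_length_bp <= 0 or self.scaffolds_per_chromosome <= 0:
            raise ConfigError("lengths and scaffold counts must be positive")
        if not 0 <= self.repeat_fraction < 1:
            raise ConfigError("repeat_fraction must be in [0, 1)")
        if self.scaffold_length_sigma < 0:
            raise ConfigError("scaffold_length_sigma must be non-negative")


@dataclasses.dataclass
class SimGenome:
    chromosome_lengths: list[int]
    scaffolds: pd.DataFrame  # scaffold_id, chromosome_id, start_bp, end_bp, is_unique
    repeat_fraction: float

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return dict(
            zip(
                self.scaffolds["scaffold_id"],
                (self.scaffolds["end_bp"] - self.scaffolds["start_bp"]).astype(int),
            )
        )


@dataclasses.dataclass
class TruthTable:
    """Map from every simulated scaffold and marker back to the truth."""

    scaffolds: pd.DataFrame  # scaffold_id, chromosome_id, start_bp, orientation, is_unique
    markers: pd.DataFrame  # marker_id, scaffold_id, position, chromosome_id, chrom_bp

    def with_markers(self, markers: pd.DataFrame) -> "TruthTable":
        combined = (
            pd.concat([self.markers, markers], ignore_index=True)
            if len(self.markers)
            else markers.reset_index(drop=True)
        )
        return TruthTable(self.scaffolds, combined)

    def marker_chromosome(self) -> pd.Series:
        return self.markers.set_index("marker_id")["chromosome_id"]

    def scaffold_chromosome(self) -> pd.Series:
        return self.scaffolds.set_index("scaffold_id")["chromosome_id"]

    def to_tsv(self, scaffold_path, marker_path) -> None:
        self.scaffolds.to_csv(scaffold_path, sep="\t", index=False)
        self.markers.to_csv(marker_path, sep="\t", index=False)


@dataclasses.dataclass
class CrossFamily:
    parentA_genotypes: np.ndarray  # per marker: 0/1/2
    parentB_genotypes: np.ndarray
    offspring_gametes: np.ndarray  # (n_offspring, 2 parents, n_markers) haplotype index
    n_offspring: int


@dataclasses.dataclass
class PopulationPanel:
    n_samples: int
    haplotype_pool_size: int
    generations: int
    sample_origins: np.ndarray  # (n_samples, 2, n_markers) founder-haplotype index


@dataclasses.dataclass
class NoiseModel:
    """Genotyping noise: call errors, low-confidence calls, and dropout.

    Called genotypes carry Phred qualities in [30, 60]; erroneous calls get
    [0, 20] and low-confidence (but correct) calls [3, 15), which is what the
    downstream Phred-3/Phred-15 quality filters act on.  ``sample_missing_rates``
    overrides the base missing rate for individual samples (by index), used to
    plant the occasional failed library.
    """

    genotype_error_rate: float = 0.01
    missing_rate: float = 0.05
    low_conf_rate: float = 0.03
    called_quality: tuple[int, int] = (30, 61)
    error_quality: tuple[int, int] = (0, 21)
    lowconf_quality: tuple[int, int] = (3, 15)
    missing_quality: tuple[int, int] = (0, 3)
    sample_missing_rates: Mapping[int, float] | None = None

    def validate(self) -> None:
        for r in (self.genotype_error_rate, self.missing_rate, self.low_conf_rate):
            if not 0 <= r <= 1:
                raise ConfigError("noise rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: GenomeConfig, seed: int) -> tuple[SimGenome, TruthTable]:
    """Fragment ``n_chromosomes`` into scaffolds with log-normal sizes.

    Scaffolds tile each chromosome without gaps or overlaps; a random subset
    of size ``repeat_fraction`` (in expectation) is flagged non-unique.
    Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    lengths = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        L = int(config.chromosome_length_bp)
        lengths.append(L)
        k = config.scaffolds_per_chromosome
        if config.scaffold_length_sigma == 0:
            sizes = np.full(k, L / k)
        else:
            sizes = rng.lognormal(mean=0.0, sigma=config.scaffold_length_sigma, size=k)
        sizes = np.maximum((sizes / sizes.sum() * L).astype(int), 1)
        sizes[-1] += L - sizes.sum()
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        for j, (s, w) in enumerate(zip(starts, sizes)):
            rows.append(
                {
                    "scaffold_id": f"S{c + 1:02d}_{j + 1:03d}",
                    "chromosome_id": chrom,
                    "start_bp": int(s),
                    "end_bp": int(s + w),
                    "orientation": int(rng.choice([1, -1])),
                    "is_unique": bool(rng.random() >= config.repeat_fraction),
                }
            )
    scaffolds = pd.DataFrame(rows)
    genome = SimGenome(
        chromosome_lengths=lengths,
        scaffolds=scaffolds[
            ["scaffold_id", "chromosome_id", "start_bp", "end_bp", "is_unique"]
        ].copy(),
        repeat_fraction=config.repeat_fraction,
    )
    truth = TruthTable(
        scaffolds=scaffolds[
            ["scaffold_id", "chromosome_id", "start_bp", "orientation", "is_unique"]
        ].copy(),
        markers=pd.DataFrame(
            columns=["marker_id", "scaffold_id", "position", "chromosome_id", "chrom_bp"]
        ),
    )
    return genome, truth


# ---------------------------------------------------------------------------
# genetic map and meiosis
# ---------------------------------------------------------------------------

def _genetic_map(
    length_bp: int,
    cm_per_mb: float,
    window: tuple[int, int] | None,
) -> tuple[float, callable]:
    """Return (total cM, physical->cM function) with an optional 0-cM window."""
    rate = cm_per_mb / 1e6  # cM per bp
    if window is None:
        total = length_bp * rate

        def phys2cm(bp: np.ndarray) -> np.ndarray:
            return bp * rate

        return total, phys2cm
    a, b = window
    a, b = max(0, a), min(length_bp, b)
    total = (length_bp - (b - a)) * rate

    def phys2cm(bp: np.ndarray) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        return np.where(
            bp < a, bp * rate, np.where(bp < b, a * rate, (bp - (b - a)) * rate)
        )

    return total, phys2cm


def _meiosis(
    hap0: np.ndarray,
    hap1: np.ndarray,
    marker_cm: np.ndarray,
    total_cm: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: Poisson crossovers on the genetic map, random start phase.

    Returns (gamete values, haplotype-of-origin indicator per marker).
    """
    n_xo = rng.poisson(total_cm / 100.0)
    phase = int(rng.integers(2))
    if n_xo == 0:
        origin = np.full(marker_cm.shape, phase, dtype=np.int8)
    else:
        breaks = np.sort(rng.uniform(0.0, total_cm, size=n_xo))
        origin = ((np.searchsorted(breaks, marker_cm, side="right") + phase) % 2).astype(
            np.int8
        )
    values = np.where(origin == 0, hap0, hap1)
    return values, origin


def _place_markers(
    genome: SimGenome,
    density_per_mb: float,
    rng: np.random.Generator,
    prefix: str,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Scatter markers over (unique) scaffolds at the given density.

    Repetitive scaffolds carry no reliable markers (their sequence is
    duplicated elsewhere), mirroring why only unique scaffolds are mappable.
    """
    if density_per_mb <= 0:
        raise ConfigError("marker density must be positive (no markers requested)")
    scaf = genome.scaffolds
    truth_scaf = scaf.set_index("scaffold_id")
    rows = []
    k = 0
    for row in scaf.itertuples(index=False):
        if unique_only and not row.is_unique:
            continue
        length = row.end_bp - row.start_bp
        n = rng.poisson(density_per_mb * length / 1e6)
        if n == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n, length), replace=False))
        for p in pos:
            k += 1
            rows.append(
                {
                    "marker_id": f"{prefix}{k:06d}",
                    "scaffold_id": row.scaffold_id,
                    "position": int(p),
                    "chromosome_id": row.chromosome_id,
                    "chrom_bp": int(row.start_bp + p - 1),
                }
            )
    if not rows:
        raise ConfigError("no markers were placed; increase density")
    df = pd.DataFrame(rows)
    df = df.sort_values(["chromosome_id", "chrom_bp"], kind="stable").reset_index(drop=True)
    del truth_scaf
    return df


def _marker_frame(truth_markers: pd.DataFrame, rng: np.random.Generator, indel_fraction: float = 0.0) -> pd.DataFrame:
    bases = np.array(list("ACGT"))
    n = len(truth_markers)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    is_indel = rng.random(n) < indel_fraction
    ref = bases[ref_idx]
    alt = bases[alt_idx].astype(object)
    for i in np.flatnonzero(is_indel):
        alt[i] = ref[i] + bases[alt_idx[i]]
    return pd.DataFrame(
        {
            "marker_id": truth_markers["marker_id"].to_numpy(),
            "scaffold_id": truth_markers["scaffold_id"].to_numpy(),
            "position": truth_markers["position"].to_numpy(),
            "ref": ref,
            "alt": alt,
            "is_indel": is_indel,
        }
    )


# ---------------------------------------------------------------------------
# F1 cross
# ---------------------------------------------------------------------------

def simulate_cross(
    genome: SimGenome,
    truth: TruthTable,
    n_offspring: int = 96,
    marker_density: float = 60.0,
    cm_per_mb: float = 40.0,
    maf_beta: tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
) -> tuple[CrossFamily, GenotypeMatrix, TruthTable]:
    """Two outbred heterozygous parents and ``n_offspring`` F1 genotypes.

    Parental haplotypes draw marker alleles from per-marker frequencies
    (Beta-distributed), so markers heterozygous in one parent, the other, or
    both all arise.  Each offspring receives one recombinant gamete from each
    parent (Haldane crossovers at ``cm_per_mb``).
    """
    if n_offspring < 2:
        raise ConfigError("need at least 2 offspring")
    rng = np.random.default_rng(seed)
    tmarkers = _place_markers(genome, marker_density, rng, prefix="X")
    n_mark = len(tmarkers)

    p = rng.beta(*maf_beta, size=n_mark)
    haps = rng.random((4, n_mark)) < p  # A1, A2, B1, B2
    hapA = haps[:2].astype(np.int8)
    hapB = haps[2:].astype(np.int8)

    chrom_ids = tmarkers["chromosome_id"].to_numpy()
    chrom_bp = tmarkers["chrom_bp"].to_numpy()
    chroms = list(dict.fromkeys(chrom_ids))
    gametes = np.zeros((n_offspring, 2, n_mark), dtype=np.int8)
    genotypes = np.zeros((n_mark, n_offspring), dtype=np.int8)
    for chrom in chroms:
        idx = np.flatnonzero(chrom_ids == chrom)
        L = int(genome.scaffolds.loc[genome.scaffolds["chromosome_id"] == chrom, "end_bp"].max())
        total_cm, phys2cm = _genetic_map(L, cm_per_mb, None)
        mcm = phys2cm(chrom_bp[idx])
        for o in range(n_offspring):
            gA, oA = _meiosis(hapA[0, idx], hapA[1, idx], mcm, total_cm, rng)
            gB, oB = _meiosis(hapB[0, idx], hapB[1, idx], mcm, total_cm, rng)
            gametes[o, 0, idx] = oA
            gametes[o, 1, idx] = oB
            genotypes[idx, o] = gA + gB

    family = CrossFamily(
        parentA_genotypes=hapA.sum(axis=0),
        parentB_genotypes=hapB.sum(axis=0),
        offspring_gametes=gametes,
        n_offspring=n_offspring,
    )
    qual = rng.integers(30, 61, size=genotypes.shape).astype(np.int16)
    matrix = GenotypeMatrix(
        _marker_frame(tmarkers, rng),
        [f"F1_{i + 1:03d}" for i in range(n_offspring)],
        genotypes,
        qual,
        scaffold_lengths=genome.scaffold_lengths,
    )
    return family, matrix, truth.with_markers(tmarkers)


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

def simulate_population(
    genome: SimGenome,
    truth: TruthTable,
    n_samples: int = 96,
    founders: int = 2,
    generations: int = 4,
    pop_size: int | None = None,
    marker_density: float = 120.0,
    cm_per_mb: float = 40.0,
    zero_recomb_window: tuple[str, int, int] | None = None,
    indel_fraction: float = 0.02,
    maf_beta: tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
) -> tuple[PopulationPanel, GenotypeMatrix, TruthTable]:
    """A panel of unrelated diploids descended from a small founder pool.

    ``generations`` rounds of random mating (with Haldane recombination)
    applied to ``founders`` whole-genome haplotypes give LD that decays with
    physical distance; at ``generations=0`` samples are plain founder
    haplotype pairs (maximal within-chromosome LD).  An optional
    ``zero_recomb_window`` (chromosome, start, end) suppresses all crossovers
    inside it, planting a perfect-LD block of known physical size.  Markers
    monomorphic among the sampled individuals are dropped.
    """
    if n_samples < 2:
        raise ConfigError("need at least 2 samples")
    if founders < 2:
        raise ConfigError("need at least 2 founder haplotypes")
    if generations < 0:
        raise ConfigError("generations must be non-negative")
    rng = np.random.default_rng(seed)
    if pop_size is None:
        pop_size = max(2 * n_samples, founders)
    tmarkers = _place_markers(genome, marker_density, rng, prefix="P")
    n_mark = len(tmarkers)

    # founder alleles: Beta-distributed frequency, conditioned polymorphic
    p = rng.beta(*maf_beta, size=n_mark)
    founder_alleles = np.zeros((founders, n_mark), dtype=np.int8)
    for i in range(n_mark):
        col = (rng.random(founders) < p[i]).astype(np.int8)
        while col.min() == col.max():
            col = (rng.random(founders) < p[i]).astype(np.int8)
        founder_alleles[:, i] = col

    chrom_ids = tmarkers["chromosome_id"].to_numpy()
    chrom_bp = tmarkers["chrom_bp"].to_numpy()
    chroms = list(dict.fromkeys(chrom_ids))
    chrom_idx = {c: np.flatnonzero(chrom_ids == c) for c in chroms}
    maps = {}
    for c in chroms:
        L = int(genome.scaffolds.loc[genome.scaffolds["chromosome_id"] == c, "end_bp"].max())
        win = None
        if zero_recomb_window is not None and zero_recomb_window[0] == c:
            win = (zero_recomb_window[1], zero_recomb_window[2])
        total_cm, phys2cm = _genetic_map(L, cm_per_mb, win)
        maps[c] = (total_cm, phys2cm(chrom_bp[chrom_idx[c]]))

    # origins track the founder haplotype of descent per marker
    origins = rng.integers(0, founders, size=(pop_size, 2)).astype(np.int8)
    origins = np.repeat(origins[:, :, None], n_mark, axis=2)
    for _ in range(generations):
        nxt = np.empty_like(origins)
        for child in range(pop_size):
            pa, pb = rng.choice(pop_size, size=2, replace=False)
            for slot, parent in ((0, pa), (1, pb)):
                for c in chroms:
                    idx = chrom_idx[c]
                    total_cm, mcm = maps[c]
                    _, orig = _meiosis(
                        np.zeros(len(idx), np.int8), np.ones(len(idx), np.int8), mcm, total_cm, rng
                    )
                    h = np.where(
                        orig == 0, origins[parent, 0, idx], origins[parent, 1, idx]
                    )
                    nxt[child, slot, idx] = h
        origins = nxt

    take = rng.choice(pop_size, size=n_samples, replace=False)
    sample_origins = origins[take]
    alleles = founder_alleles[sample_origins, np.arange(n_mark)[None, None, :]]
    genotypes = alleles.sum(axis=1).T.astype(np.int8)  # markers x samples

    poly = (genotypes.min(axis=1) < genotypes.max(axis=1))
    tmarkers = tmarkers.loc[poly].reset_index(drop=True)
    genotypes = genotypes[poly]
    sample_origins = sample_origins[:, :, poly]

    panel = PopulationPanel(
        n_samples=n_samples,
        haplotype_pool_size=founders,
        generations=generations,
        sample_origins=sample_origins,
    )
    qual = rng.integers(30, 61, size=genotypes.shape).astype(np.int16)
    matrix = GenotypeMatrix(
        _marker_frame(tmarkers, rng, indel_fraction=indel_fraction),
        [f"LD_{i + 1:03d}" for i in range(n_samples)],
        genotypes,
        qual,
        scaffold_lengths=genome.scaffold_lengths,
    )
    return panel, matrix, truth.with_markers(tmarkers)


# ---------------------------------------------------------------------------
# noise and round trips
# ---------------------------------------------------------------------------

def apply_noise(matrix: GenotypeMatrix, model: NoiseModel, seed: int) -> GenotypeMatrix:
    """Overlay genotyping errors, low-confidence calls and dropout.

    The input matrix is not modified.  Dropout is applied first (per-sample
    rates honoured), then errors at ``genotype_error_rate`` among the
    remaining called genotypes, then low-confidence quality downgrades.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    g = out.genotypes
    q = out.qualities
    n_mark, n_samp = g.shape
    if n_mark == 0:
        return out

    miss_rates = np.full(n_samp, model.missing_rate)
    if model.sample_missing_rates:
        for key, rate in model.sample_missing_rates.items():
            miss_rates[int(key)] = rate
    miss = rng.random(g.shape) < miss_rates[None, :]
    err = (~miss) & (rng.random(g.shape) < model.genotype_error_rate) & (g != MISSING)
    low = (~miss) & (~err) & (rng.random(g.shape) < model.low_conf_rate) & (g != MISSING)

    shift = rng.integers(1, 3, size=int(err.sum()))
    g[err] = ((g[err] + shift) % 3).astype(np.int8)
    q[err] = rng.integers(*model.error_quality, size=int(err.sum()))
    q[low] = rng.integers(*model.lowconf_quality, size=int(low.sum()))
    g[miss] = MISSING
    q[miss] = rng.integers(*model.missing_quality, size=int(miss.sum()))
    return out


def vcf_roundtrip(matrix: GenotypeMatrix, path) -> GenotypeMatrix:
    """Write ``matrix`` to VCF and read it back (identity up to dtypes)."""
    write_vcf(matrix, path)
    return read_vcf(path)


# ---------------------------------------------------------------------------
# sequence realisation (for probe design on synthetic genomes)
# ---------------------------------------------------------------------------

def genome_sequences(genome: SimGenome, seed: int) -> dict[str, str]:
    """Random nucleotide sequences per scaffold.

    Non-unique scaffolds copy (tile) the sequence of a randomly chosen unique
    scaffold, so an exact-duplication screen sees them as repetitive.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    uniques = genome.scaffolds.loc[genome.scaffolds["is_unique"], "scaffold_id"].tolist()
    for row in genome.scaffolds.itertuples(index=False):
        length = int(row.end_bp - row.start_bp)
        if row.is_unique or not uniques:
            seqs[row.scaffold_id] = "".join(rng.choice(bases, size=length))
    for row in genome.scaffolds.itertuples(index=False):
        if row.is_unique:
            continue
        length = int(row.end_bp - row.start_bp)
        donor = seqs[uniques[int(rng.integers(len(uniques)))]]
        tiled = (donor * (length // max(len(donor), 1) + 1))[:length]
        seqs[row.scaffold_id] = tiled
    return seqs
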