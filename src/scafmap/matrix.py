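"""Genotype matrix container and VCF / TSV input-output.

The central in-memory object of the pipeline is :class:`GenotypeMatrix`, a
markers-by-samples table of unphased diploid genotype codes with a parallel
table of Phred-scaled genotype qualities.  Genotypes are coded as the count
of the alternate allele (0, 1, 2) with -1 for missing.  Marker metadata
(scaffold, 1-based position, alleles, indel flag) lives in a pandas
DataFrame aligned row-for-row with the genotype array.

Serialisation is plain VCFv4.2 with per-sample ``GT`` and ``GQ`` fields;
reading goes through :mod:`pysam`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING = -1

MARKER_COLUMNS = ["marker_id", "scaffold_id", "position", "ref", "alt", "is_indel"]


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed; names the offending line."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Markers x samples diploid genotype codes plus per-genotype qualities.

    Attributes
    ----------
    markers
        DataFrame with columns ``marker_id, scaffold_id, position, ref, alt,
        is_indel``; ``position`` is 1-based as in VCF.
    samples
        Ordered sample identifiers.
    genotypes
        int8 array of shape (n_markers, n_samples); -1 encodes missing.
    qualities
        int16 array of Phred-scaled genotype qualities, same shape.
    scaffold_lengths
        Optional scaffold_id -> length (bp) map, used for VCF contig headers
        and downstream size bookkeeping.
    """

    markers: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    qualities: np.ndarray
    scaffold_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        if self.genotypes.shape != self.qualities.shape:
            raise ValueError("genotype and quality arrays differ in shape")
        if self.genotypes.shape != (len(self.markers), len(self.samples)):
            raise ValueError("marker/sample dimensions inconsistent with arrays")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")
        if len(self.markers) and (self.markers["position"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers.copy(),
            list(self.samples),
            self.genotypes.copy(),
            self.qualities.copy(),
            dict(self.scaffold_lengths) if self.scaffold_lengths else None,
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            self.markers.iloc[idx],
            list(self.samples),
            self.genotypes[idx],
            self.qualities[idx],
            self.scaffold_lengths,
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            self.markers,
            list(keep),
            self.genotypes[:, pos],
            self.qualities[:, pos],
            self.scaffold_lengths,
        )

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return (self.genotypes == MISSING).mean(axis=0)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            list(self.samples) == list(other.samples)
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.qualities, other.qualities)
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
        )


# -- VCF ------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as uncompressed VCFv4.2 with GT and GQ per sample."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=scafmap"]
    lengths = matrix.scaffold_lengths or {}
    for scaf in pd.unique(matrix.markers["scaffold_id"]):
        sub = matrix.markers.loc[matrix.markers["scaffold_id"] == scaf]
        length = int(lengths.get(scaf, int(sub["position"].max()) + 1000))
        lines.append(f"##contig=<ID={scaf},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred)">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    gt = matrix.genotypes
    gq = matrix.qualities
    for i, row in enumerate(matrix.markers.itertuples(index=False)):
        fields = [
            str(row.scaffold_id),
            str(int(row.position)),
            str(row.marker_id),
            str(row.ref),
            str(row.alt),
            ".",
            "PASS",
            ".",
            "GT:GQ",
        ]
        fields.extend(
            f"{_GT_STR[int(gt[i, j])]}:{int(gq[i, j])}" for j in range(gt.shape[1])
        )
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def _diagnose_vcf(path: Path) -> str:
    """Best-effort scan for the first malformed line, for error reporting."""
    n_fixed = 9
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < n_fixed:
                return f"line {lineno}: expected at least {n_fixed} columns"
            if not parts[1].isdigit():
                return f"line {lineno}: POS field '{parts[1]}' is not an integer"
    return "unknown location"


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF with GT/GQ back into a :class:`GenotypeMatrix`."""
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - exercised via malformed input
        raise VcfParseError(f"cannot parse {path} ({_diagnose_vcf(path)})") from exc
    samples = list(vf.header.samples)
    lengths = {c: vf.header.contigs[c].length for c in vf.header.contigs}
    rows = []
    gts: list[list[int]] = []
    gqs: list[list[int]] = []
    try:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            rows.append(
                {
                    "marker_id": rec.id,
                    "scaffold_id": rec.chrom,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "is_indel": len(rec.ref) != len(alt),
                }
            )
            grow, qrow = [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    grow.append(MISSING)
                else:
                    grow.append(int(sum(alleles)))
                gq = call.get("GQ")
                qrow.append(int(gq) if gq is not None else 0)
            gts.append(grow)
            gqs.append(qrow)
    except Exception as exc:
        raise VcfParseError(f"cannot parse {path} ({_diagnose_vcf(path)})") from exc
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    gt_arr = np.array(gts, dtype=np.int8).reshape(len(rows), len(samples))
    gq_arr = np.array(gqs, dtype=np.int16).reshape(len(rows), len(samples))
    return GenotypeMatrix(markers, samples, gt_arr, gq_arr, scaffold_lengths=lengths)


# -- plain-text side tables ------------------------------------------------

def write_scaffold_table(
    scaffolds: pd.DataFrame, path: str | Path, columns: Iterable[str] = ("scaffold_id", "length_bp", "is_unique")
) -> None:
    scaffolds.loc[:, list(columns)].to_csv(path, sep="\t", index=False)


def read_scaffold_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based, half-open) into columns scaffold_id/start/end."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["scaffold_id", "start", "end"]
    )
    return df


def scaffold_lengths_from_table(table: pd.DataFrame | Mapping[str, int]) -> dict[str, int]:
    if isinstance(table, pd.DataFrame):
        return dict(zip(table["scaffold_id"], table["length_bp"].astype(int)))
    return dict(table)
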