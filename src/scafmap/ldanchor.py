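"""Composite linkage disequilibrium on unphased genotypes and LD anchoring.

The Burrows composite disequilibrium for two biallelic loci with genotype
codes x, y in {0, 1, 2} (alternate-allele counts) over the pairwise-complete
samples is

    Delta_AB = (1/n) [2 n_AABB + n_AABb + n_AaBB + 1/2 n_AaBb] - 2 pA pB
             = 1/2 cov(x, y),

and the association statistic is chi2 = n Delta^2 / [(pA qA + DA)(pB qB + DB)]
with DA = P_AA - pA^2 the within-locus Hardy-Weinberg disequilibrium; we
report r^2 = chi2 / n.  The Hardy-Weinberg-corrected denominator keeps
r^2 in [0, 1] even under homozygote excess (the uncorrected form, available
via ``hw_corrected=False``, does not).

Scaffolds absent from the cross map are anchored to linkage groups through
"meaningful" LD pairs (|Delta| >= 0.15 and r^2 >= 0.85, both inclusive):
an unmapped scaffold joins an LG when it shows meaningful LD with markers
on at least two distinct mapped scaffolds of that LG; qualifying for two
LGs splits it half-and-half, for more than two discards it.  Sets of
scaffolds whose every pair has a perfect-LD witness (|Delta| >= 0.15,
r^2 = 1) are reported as haplotype blocks (maximal cliques), the signature
of suppressed recombination such as an inversion.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "composite_ld",
    "find_meaningful_pairs",
    "anchor_scaffolds",
    "perfect_ld_blocks",
    "AnchorAssignment",
    "PerfectLDBlock",
]


@dataclasses.dataclass
class AnchorAssignment:
    scaffold_id: str
    status: str  # anchored | split | discarded | unanchored
    lgs: list[tuple[str, float]]  # (lg_id, weight)


@dataclasses.dataclass
class PerfectLDBlock:
    scaffolds: list[str]
    total_length_bp: int
    n_witness_pairs: int


def composite_ld(
    gx: np.ndarray,
    gy: np.ndarray,
    min_overlap: int = 20,
    hw_corrected: bool = True,
) -> tuple[float, float, int]:
    """Burrows composite Delta_AB and r^2 for one marker pair.

    Returns ``(delta, r2, n_obs)``; ``delta`` and ``r2`` are NaN when the
    pairwise-complete overlap is below ``min_overlap`` or either locus is
    monomorphic within it.
    """
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    obs = (gx != MISSING) & (gy != MISSING)
    n = int(obs.sum())
    if n < max(min_overlap, 1):
        return float("nan"), float("nan"), n
    x = gx[obs].astype(float)
    y = gy[obs].astype(float)
    if x.min() == x.max() or y.min() == y.max():
        return float("nan"), float("nan"), n
    p_a = x.mean() / 2.0
    p_b = y.mean() / 2.0
    delta = (x * y).mean() / 2.0 - 2.0 * p_a * p_b
    if hw_corrected:
        d_a = (x == 2).mean() - p_a**2
        d_b = (y == 2).mean() - p_b**2
    else:
        d_a = d_b = 0.0
    den = (p_a * (1 - p_a) + d_a) * (p_b * (1 - p_b) + d_b)
    if den <= 0:
        return float(delta), float("nan"), n
    return float(delta), float(delta * delta / den), n


# ---------------------------------------------------------------------------
# vectorised all-pairs scan
# ---------------------------------------------------------------------------

def _pair_scan(
    matrix: GenotypeMatrix,
    delta_min: float,
    r2_min: float,
    min_overlap: int,
    inter_scaffold_only: bool,
    block: int = 512,
) -> pd.DataFrame:
    """All marker pairs with |Delta| and r^2 above thresholds, via matmuls."""
    g = matrix.genotypes.astype(np.float64)
    obs = (matrix.genotypes != MISSING).astype(np.float64)
    gz = np.where(matrix.genotypes == MISSING, 0.0, g)
    hom = ((matrix.genotypes == 2)).astype(np.float64)
    m = matrix.n_markers
    scafs = matrix.markers["scaffold_id"].to_numpy()
    mids = matrix.markers["marker_id"].to_numpy()
    out_rows = []
    gz2 = gz * gz
    for s0 in range(0, m, block):
        s1 = min(m, s0 + block)
        N = obs[s0:s1] @ obs.T  # pairwise-complete n
        Sxy = gz[s0:s1] @ gz.T
        Sx = gz[s0:s1] @ obs.T
        Sy = obs[s0:s1] @ gz.T
        Sxx = gz2[s0:s1] @ obs.T
        Syy = obs[s0:s1] @ gz2.T
        Hx = hom[s0:s1] @ obs.T
        Hy = obs[s0:s1] @ hom.T
        with np.errstate(divide="ignore", invalid="ignore"):
            n = np.maximum(N, 1.0)
            pa = Sx / (2 * n)
            pb = Sy / (2 * n)
            delta = Sxy / (2 * n) - 2 * pa * pb
            da = Hx / n - pa**2
            db = Hy / n - pb**2
            den = (pa * (1 - pa) + da) * (pb * (1 - pb) + db)
            r2 = np.where(den > 0, delta * delta / den, np.nan)
        poly_x = (Sxx / n - (Sx / n) ** 2) > 1e-12
        poly_y = (Syy / n - (Sy / n) ** 2) > 1e-12
        ok = (
            (N >= min_overlap)
            & poly_x
            & poly_y
            & (np.abs(delta) >= delta_min - 1e-12)
            & (r2 >= r2_min - 1e-12)
        )
        ii, jj = np.nonzero(ok)
        gi = ii + s0
        keep = gi < jj  # upper triangle only
        if inter_scaffold_only:
            keep &= scafs[gi] != scafs[jj]
        gi, jj = gi[keep], jj[keep]
        for a, b in zip(gi, jj):
            out_rows.append(
                (
                    scafs[a],
                    mids[a],
                    scafs[b],
                    mids[b],
                    float(delta[a - s0, b]),
                    float(r2[a - s0, b]),
                    int(N[a - s0, b]),
                )
            )
    df = pd.DataFrame(
        out_rows,
        columns=["scaffold_i", "marker_i", "scaffold_j", "marker_j", "delta", "r2", "n"],
    )
    return df.sort_values(
        ["scaffold_i", "marker_i", "scaffold_j", "marker_j"], kind="stable"
    ).reset_index(drop=True)


def find_meaningful_pairs(
    matrix: GenotypeMatrix,
    delta_min: float = 0.15,
    r2_min: float = 0.85,
    min_overlap: int = 20,
    inter_scaffold_only: bool = True,
) -> pd.DataFrame:
    """Inter-scaffold marker pairs with |Delta_AB| >= delta_min and r^2 >= r2_min.

    Both thresholds are inclusive; |Delta| is used because allele labelling
    is arbitrary.  Output is deterministically ordered.
    """
    return _pair_scan(matrix, delta_min, r2_min, min_overlap, inter_scaffold_only)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def anchor_scaffolds(
    pairs: pd.DataFrame, mapped: Mapping[str, str]
) -> list[AnchorAssignment]:
    """Single-pass LD anchoring of unmapped scaffolds onto linkage groups.

    ``mapped`` maps cross-mapped scaffold -> LG id.  A scaffold qualifies
    for an LG when it has meaningful LD with at least one variant on each of
    at least two distinct mapped scaffolds of that LG.  Newly anchored
    scaffolds never anchor others (no chaining), so the result is
    independent of iteration order.
    """
    partners: dict[str, dict[str, set[str]]] = {}
    has_ld: set[str] = set()
    for row in pairs.itertuples(index=False):
        for scaf, other in ((row.scaffold_i, row.scaffold_j), (row.scaffold_j, row.scaffold_i)):
            if scaf in mapped:
                continue
            has_ld.add(scaf)
            if other in mapped:
                partners.setdefault(scaf, {}).setdefault(mapped[other], set()).add(other)
    out = []
    for scaf in sorted(has_ld):
        by_lg = partners.get(scaf, {})
        qualifying = sorted(lg for lg, scs in by_lg.items() if len(scs) >= 2)
        if len(qualifying) == 0:
            out.append(AnchorAssignment(scaf, "unanchored", []))
        elif len(qualifying) == 1:
            out.append(AnchorAssignment(scaf, "anchored", [(qualifying[0], 1.0)]))
        elif len(qualifying) == 2:
            out.append(
                AnchorAssignment(scaf, "split", [(lg, 0.5) for lg in qualifying])
            )
        else:
            out.append(AnchorAssignment(scaf, "discarded", []))
    return out


def assignments_frame(assignments: list[AnchorAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        if a.lgs:
            for lg, w in a.lgs:
                rows.append((a.scaffold_id, a.status, lg, w))
        else:
            rows.append((a.scaffold_id, a.status, "", 0.0))
    return pd.DataFrame(rows, columns=["scaffold_id", "status", "lg", "weight"])


# ---------------------------------------------------------------------------
# perfect-LD blocks
# ---------------------------------------------------------------------------

def perfect_ld_blocks(
    pairs: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    delta_min: float = 0.15,
    tol: float = 1e-9,
) -> list[PerfectLDBlock]:
    """Maximal cliques of scaffolds pairwise witnessed by perfect LD.

    A scaffold pair is witnessed when at least one of its marker pairs has
    |Delta| >= delta_min and r^2 >= 1 - tol.  All maximal cliques of size
    >= 2 are reported (overlapping cliques included), largest summed length
    first.
    """
    perfect = pairs[(pairs["r2"] >= 1.0 - tol) & (pairs["delta"].abs() >= delta_min - 1e-12)]
    graph = nx.Graph()
    witness_count: dict[tuple[str, str], int] = {}
    for row in perfect.itertuples(index=False):
        a, b = sorted((row.scaffold_i, row.scaffold_j))
        graph.add_edge(a, b)
        witness_count[(a, b)] = witness_count.get((a, b), 0) + 1
    blocks = []
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        scafs = sorted(clique)
        n_wit = sum(
            witness_count.get((a, b), 0)
            for i, a in enumerate(scafs)
            for b in scafs[i + 1:]
        )
        blocks.append(
            PerfectLDBlock(
                scaffolds=scafs,
                total_length_bp=int(sum(scaffold_lengths[s] for s in scafs)),
                n_witness_pairs=n_wit,
            )
        )
    blocks.sort(key=lambda b: (-b.total_length_bp, b.scaffolds))
    return blocks


def blocks_frame(blocks: list[PerfectLDBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (";".join(b.scaffolds), len(b.scaffolds), b.total_length_bp, b.n_witness_pairs)
            for b in blocks
        ],
        columns=["scaffolds", "n_scaffolds", "total_length_bp", "n_witness_pairs"],
    )
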