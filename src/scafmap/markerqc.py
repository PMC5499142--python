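"""Marker filtering regimes and outcross segregation typing.

Three filter sets are implemented, mirroring how a targeted-capture linkage
study treats its genotype calls:

* cross mode (:func:`filter_cross_markers`): at least 10 individuals in each
  of two genotype classes; at most 30% of samples below Phred 15, and
  genotypes below Phred 15 recoded to missing.
* LD mode (:func:`filter_ld_markers`): at least 20 individuals per class,
  Hardy-Weinberg exact p >= 1e-3, at least 70% of genotypes at Phred >= 15;
  genotypes with Phred in [3, 15) are kept as calls, below 3 set missing.
* whole-genome extras (``mode="wholegenome"``): probe-covered sites dropped,
  non-unique scaffolds dropped, and indels kept only on SNP-free scaffolds.

Segregation typing follows outcross conventions: D1.10 (parent A
heterozygous only), D2.15 (parent B heterozygous only), B3.7 (both
heterozygous), with the null-allele classes C.8 / B1.5 / B2.6 assigned only
when offspring ratios contradict the called parental genotypes and fit the
corresponding null-allele expectation by a chi-square goodness-of-fit test.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chisquare

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "SegregationType",
    "classify_segregation",
    "classify_matrix",
    "filter_cross_markers",
    "exclude_high_missing_samples",
    "hwe_exact_test",
    "filter_ld_markers",
    "prune_redundant",
]


class ClassificationError(ValueError):
    pass


class SegregationType(str, enum.Enum):
    D1_10 = "D1.10"
    D2_15 = "D2.15"
    B3_7 = "B3.7"
    C_8 = "C.8"
    B1_5 = "B1.5"
    B2_6 = "B2.6"
    UNINFORMATIVE = "uninformative"


def _gof_p(observed: np.ndarray, expected_ratio: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float)
    expected = expected_ratio / expected_ratio.sum() * observed.sum()
    keep = expected > 0
    if observed[~keep].sum() > 0:
        return 0.0
    return float(chisquare(observed[keep], expected[keep]).pvalue)


def classify_segregation(
    parentA_gt: int | None,
    parentB_gt: int | None,
    offspring_counts: Mapping[int, int],
    alpha: float = 0.05,
) -> SegregationType:
    """Type a cross marker from parental genotypes and offspring counts.

    ``offspring_counts`` maps genotype codes (0/1/2, with -1 for missing
    allowed) to counts.  Null-allele classes are only assigned when an
    offspring class that is impossible under the called parental genotypes
    is observed and the null-allele segregation ratio fits at ``alpha``:

    * parent A het, parent B hom, yet both homozygote classes present and
      counts fit 2:1:1 -> B1.5 (B carries a null);
    * the mirror case -> B2.6;
    * both parents hom for the same allele, yet ~1/4 of offspring drop out
      (called:missing fits 3:1) -> C.8 (both parents null-het).
    """
    if parentA_gt in (None, MISSING) and parentB_gt in (None, MISSING):
        raise ClassificationError("both parental genotypes missing")
    if sum(v for k, v in offspring_counts.items() if k != MISSING) < 1:
        raise ClassificationError("no called offspring genotypes")
    a_het = parentA_gt == 1
    b_het = parentB_gt == 1
    n = np.array([offspring_counts.get(g, 0) for g in (0, 1, 2)], dtype=float)
    n_miss = float(offspring_counts.get(MISSING, 0))

    if a_het and b_het:
        return SegregationType.B3_7
    if a_het or b_het:
        hom_parent = parentB_gt if a_het else parentA_gt
        impossible = n[2] if hom_parent == 0 else n[0]
        if impossible > 0:
            null_ratio = (
                np.array([2.0, 1.0, 1.0]) if hom_parent == 0 else np.array([1.0, 1.0, 2.0])
            )
            if _gof_p(n, null_ratio) >= alpha:
                return SegregationType.B1_5 if a_het else SegregationType.B2_6
        return SegregationType.D1_10 if a_het else SegregationType.D2_15
    # both parents called homozygous
    if parentA_gt == parentB_gt and n.sum() + n_miss > 0 and n_miss > 0:
        if _gof_p(np.array([n.sum(), n_miss]), np.array([3.0, 1.0])) >= alpha:
            # dropout fraction fits 3:1 called:missing -> double null-het
            return SegregationType.C_8
    return SegregationType.UNINFORMATIVE


def classify_matrix(
    matrix: GenotypeMatrix,
    parentA: np.ndarray,
    parentB: np.ndarray,
    alpha: float = 0.05,
) -> pd.Series:
    """Vector of :class:`SegregationType` for every marker in the matrix."""
    out = []
    g = matrix.genotypes
    for i in range(matrix.n_markers):
        vals, cnts = np.unique(g[i], return_counts=True)
        counts = dict(zip(vals.tolist(), cnts.tolist()))
        try:
            st = classify_segregation(int(parentA[i]), int(parentB[i]), counts, alpha)
        except ClassificationError:
            st = SegregationType.UNINFORMATIVE
        out.append(st)
    return pd.Series(out, index=matrix.markers["marker_id"].to_numpy(), name="segregation")


# ---------------------------------------------------------------------------
# cross filters
# ---------------------------------------------------------------------------

def filter_cross_markers(
    matrix: GenotypeMatrix,
    min_per_class: int = 10,
    max_lowq_fraction: float = 0.30,
    phred_min: int = 15,
) -> GenotypeMatrix:
    """Linkage-cross marker filter.

    Retains markers for which at most ``max_lowq_fraction`` of all samples
    fall below ``phred_min`` and, after recoding those genotypes to missing,
    at least two genotype classes have ``min_per_class`` individuals each.
    """
    g = matrix.genotypes.copy()
    q = matrix.qualities
    lowq = q < phred_min
    lowq_frac = lowq.mean(axis=1)
    g[lowq] = MISSING
    keep = lowq_frac <= max_lowq_fraction + 1e-12
    counts = np.stack([(g == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
    keep &= (counts >= min_per_class).sum(axis=1) >= 2
    out = matrix.subset_markers(keep)
    gg = out.genotypes
    gg[out.qualities < phred_min] = MISSING
    return out


def exclude_high_missing_samples(
    matrix: GenotypeMatrix, max_missing: float = 0.50
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples missing at strictly more than ``max_missing`` of sites."""
    frac = matrix.missing_fraction_per_sample()
    excluded = [s for s, f in zip(matrix.samples, frac) if f > max_missing]
    kept = [s for s in matrix.samples if s not in excluded]
    if not kept:
        raise ValueError("all samples exceed the missingness threshold")
    return matrix.subset_samples(kept), excluded


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the observed
    configuration.  Monomorphic input carries no evidence and returns 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_hom_ref + n_het  # reference allele count
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (n_a - hets) // 2
    hom_a = n - hets - hom_r
    # log P(n_het | n, n_a) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_a + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# LD-panel filters
# ---------------------------------------------------------------------------

def filter_ld_markers(
    matrix: GenotypeMatrix,
    mode: str = "capture",
    probe_intervals: pd.DataFrame | None = None,
    unique_scaffolds: Iterable[str] | None = None,
    min_per_class: int = 20,
    hwe_alpha: float = 1e-3,
    min_goodq_fraction: float = 0.70,
) -> GenotypeMatrix:
    """LD-panel marker filter (capture or whole-genome mode).

    Quality handling differs from the cross filter: calls with Phred in
    [3, 15) are retained as genotypes, only Phred < 3 becomes missing, but at
    least ``min_goodq_fraction`` of samples must sit at Phred >= 15.
    """
    if mode not in ("capture", "wholegenome"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "wholegenome" and (probe_intervals is None or unique_scaffolds is None):
        raise ValueError("wholegenome mode needs probe_intervals and unique_scaffolds")

    g = matrix.genotypes.copy()
    q = matrix.qualities
    g[q < 3] = MISSING
    goodq_frac = (q >= 15).mean(axis=1)
    keep = goodq_frac >= min_goodq_fraction - 1e-12

    counts = np.stack([(g == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
    keep &= (counts >= min_per_class).sum(axis=1) >= 2

    hwe_ok = np.ones(matrix.n_markers, dtype=bool)
    for i in np.flatnonzero(keep):
        hwe_ok[i] = hwe_exact_test(*counts[i]) >= hwe_alpha
    keep &= hwe_ok

    if mode == "wholegenome":
        m = matrix.markers
        unique_set = set(unique_scaffolds)
        keep &= m["scaffold_id"].isin(unique_set).to_numpy()
        if len(probe_intervals):
            covered = np.zeros(matrix.n_markers, dtype=bool)
            by_scaf = {s: d for s, d in probe_intervals.groupby("scaffold_id")}
            for i, (scaf, pos) in enumerate(zip(m["scaffold_id"], m["position"])):
                iv = by_scaf.get(scaf)
                if iv is not None:
                    # BED is 0-based half-open; positions are 1-based
                    covered[i] = bool(((iv["start"] < pos) & (pos <= iv["end"])).any())
            keep &= ~covered
        snp_scaffolds = set(m.loc[~m["is_indel"], "scaffold_id"])
        keep &= ~(m["is_indel"] & m["scaffold_id"].isin(snp_scaffolds)).to_numpy()

    out = matrix.subset_markers(keep)
    gg = out.genotypes
    gg[out.qualities < 3] = MISSING
    return out


def prune_redundant(matrix: GenotypeMatrix, min_diff: int = 8) -> GenotypeMatrix:
    """Greedy per-scaffold pruning of near-duplicate genotype profiles.

    Scanning each scaffold's markers in position order (ties by marker id),
    a marker is kept only if it differs from every already-kept marker on
    the scaffold at ``min_diff`` or more sample genotypes; a missing call
    versus a called genotype counts as a difference.
    """
    m = matrix.markers
    order = np.lexsort((m["marker_id"].to_numpy(), m["position"].to_numpy()))
    keep_mask = np.zeros(matrix.n_markers, dtype=bool)
    g = matrix.genotypes
    kept_by_scaf: dict[str, list[int]] = {}
    for i in order:
        scaf = m["scaffold_id"].iat[i]
        kept = kept_by_scaf.setdefault(scaf, [])
        ok = True
        for j in kept:
            if int((g[i] != g[j]).sum()) < min_diff:
                ok = False
                break
        if ok:
            kept.append(i)
            keep_mask[i] = True
    return matrix.subset_markers(keep_mask)
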