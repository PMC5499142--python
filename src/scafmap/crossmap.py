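"""Two-point linkage analysis of an outbred F1 family.

Recombination fractions and LOD scores are estimated with unknown parental
phase.  For pairs informative in one shared parent (D1.10 x D1.10,
D2.15 x D2.15, and the D-by-B3.7 combinations restricted to homozygous
offspring) the transmitted-allele patterns make the meioses fully
observable, so rf-hat is the recombinant count over informative meioses
under the best of the two phases and the LOD has the closed binomial form

    LOD = n log10 2 + k log10 rf + (n - k) log10 (1 - rf).

For B3.7 x B3.7 pairs the double-heterozygote offspring class is a mixture
of parental and recombinant gamete pairs, so the likelihood is maximised by
expectation-maximisation over the four-class gamete table, separately for
the four phase configurations.  D1.10 x D2.15 pairs share no informative
meioses and are reported as non-estimable.

Markers are grouped by single-linkage transitive closure over pairs with
LOD >= 3.4 plus a recombination-fraction ceiling, because a LOD threshold
alone admits spurious inter-group edges at a rate of ~1e-4 per pair.  The
ceiling is class-specific -- 0.15 for same-parent D-by-D pairs, 0.10 for
B3.7 x B3.7 (whose EM null, measured on simulated independent tables,
concentrates above rf ~0.14), and 0.08 for mixed D-by-B3.7 pairs, whose
informative meioses are roughly halved and whose binomial tails are
correspondingly fatter (see the methods note).  Within groups,
markers collapse into cosegregation bins, bins are ordered by a greedy
nearest-neighbour chain with 2-opt refinement, and map distances are
conservative: putative crossovers supported by a single site are treated
as genotyping errors and removed before events are counted.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .markerqc import SegregationType
from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "TwoPointResult",
    "LinkageGroupDraft",
    "two_point",
    "group_markers",
    "merge_groups",
    "count_recombinations",
    "order_and_position",
    "map_cross",
]

LOG10_2 = float(np.log10(2.0))

# gamete table machinery for B3.7 x B3.7 ------------------------------------

_GAMETES = [(0, 0), (0, 1), (1, 0), (1, 1)]
# coupling: parental gametes are (0,0)/(1,1); repulsion: (0,1)/(1,0)
_REC = {"C": np.array([0, 1, 1, 0]), "R": np.array([1, 0, 0, 1])}
_PHASES = ["CC", "CR", "RC", "RR"]
_COMBOS = [
    (i, j, 3 * (u[0] + v[0]) + (u[1] + v[1]))
    for i, u in enumerate(_GAMETES)
    for j, v in enumerate(_GAMETES)
]


@dataclasses.dataclass
class TwoPointResult:
    marker_x: str
    marker_y: str
    rf: float
    lod: float
    phase: str
    n_informative: int
    estimable: bool = True


@dataclasses.dataclass
class LinkageGroupDraft:
    lg_id: str
    marker_ids: list[str]
    scaffolds: set[str]
    maps: dict = dataclasses.field(default_factory=dict)  # parent -> DataFrame
    spans: dict = dataclasses.field(default_factory=dict)  # parent -> cM

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


# ---------------------------------------------------------------------------
# transmitted-allele patterns
# ---------------------------------------------------------------------------


def _tvals(types: pd.Series | np.ndarray) -> np.ndarray:
    """Segregation types as plain strings (numpy-safe comparisons)."""
    arr = types.to_numpy() if hasattr(types, "to_numpy") else np.asarray(types, dtype=object)
    return np.array([getattr(t, "value", t) for t in arr], dtype=object)

def transmission_pattern(
    genotypes: np.ndarray, seg_type: SegregationType, parent: str, other_parent_gt: int
) -> np.ndarray | None:
    """Alleles transmitted by ``parent`` ('A' or 'B'), -1 where unresolvable.

    For a marker heterozygous only in ``parent`` the other parent is
    homozygous, so every called offspring resolves.  For a B3.7 marker only
    homozygous offspring resolve; heterozygotes are ambiguous.
    """
    g = genotypes
    t = np.full(g.shape, MISSING, dtype=np.int8)
    if seg_type == SegregationType.B3_7:
        t[g == 0] = 0
        t[g == 2] = 1
        return t
    if (seg_type == SegregationType.D1_10 and parent == "A") or (
        seg_type == SegregationType.D2_15 and parent == "B"
    ):
        if other_parent_gt == 0:
            t[g == 0] = 0
            t[g == 1] = 1
        elif other_parent_gt == 2:
            t[g == 1] = 0
            t[g == 2] = 1
        return t
    return None


def _binomial_lod(k: int, n: int) -> tuple[float, float, str]:
    """(rf, lod, phase) for n informative meioses with k mismatches."""
    if n == 0:
        return 0.5, 0.0, "coupling"
    phase = "coupling" if k <= n - k else "repulsion"
    k = min(k, n - k)
    rf = k / n
    lod = n * LOG10_2
    if k > 0:
        lod += k * np.log10(rf) + (n - k) * np.log10(1 - rf)
    return rf, float(lod), phase


def _phase_probs(code: str, r: np.ndarray) -> np.ndarray:
    """(P, 4) gamete probabilities for one parent under phase 'C' or 'R'."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    half_r = r / 2.0
    half_p = (1.0 - r) / 2.0
    if code == "C":
        return np.stack([half_p, half_r, half_r, half_p], axis=1)
    return np.stack([half_r, half_p, half_p, half_r], axis=1)


def _b3_loglik(counts9: np.ndarray, phase: str, r: np.ndarray) -> np.ndarray:
    pA = _phase_probs(phase[0], r)
    pB = _phase_probs(phase[1], r)
    den = np.zeros((pA.shape[0], 9))
    for i, j, c in _COMBOS:
        den[:, c] += pA[:, i] * pB[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts9 > 0, counts9 * np.log10(np.maximum(den, 1e-300)), 0.0)
    return ll.sum(axis=1)


def _b3_em_one_phase(
    counts9: np.ndarray, phase: str, max_iter: int = 300, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """EM for rf under one phase configuration; vectorised over pair rows."""
    counts9 = np.atleast_2d(counts9).astype(float)
    ntot = counts9.sum(axis=1)
    recA = _REC[phase[0]]
    recB = _REC[phase[1]]
    r = np.full(counts9.shape[0], 0.25)
    for _ in range(max_iter):
        pA = _phase_probs(phase[0], r)
        pB = _phase_probs(phase[1], r)
        den = np.zeros_like(counts9)
        num = np.zeros_like(counts9)
        for i, j, c in _COMBOS:
            w = pA[:, i] * pB[:, j]
            den[:, c] += w
            num[:, c] += w * (recA[i] + recB[j])
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        expected_rec = (counts9 * frac).sum(axis=1)
        r_new = np.clip(expected_rec / (2.0 * np.maximum(ntot, 1)), 1e-9, 0.5)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    return r, _b3_loglik(counts9, phase, r)


def b3_two_point(counts9: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximise over the four phase configurations; returns (rf, lod, phase_idx)."""
    counts9 = np.atleast_2d(counts9).astype(float)
    best_r = np.full(counts9.shape[0], 0.5)
    best_ll = np.full(counts9.shape[0], -np.inf)
    best_ph = np.zeros(counts9.shape[0], dtype=int)
    for k, phase in enumerate(_PHASES):
        r, ll = _b3_em_one_phase(counts9, phase)
        better = ll > best_ll + 1e-12
        best_r = np.where(better, r, best_r)
        best_ll = np.where(better, ll, best_ll)
        best_ph = np.where(better, k, best_ph)
    ll_null = _b3_loglik(counts9, "CC", np.full(counts9.shape[0], 0.5))
    lod = np.maximum(best_ll - ll_null, 0.0)
    return best_r, lod, best_ph


def _counts9(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    obs = (gx != MISSING) & (gy != MISSING)
    c = np.zeros(9)
    if obs.any():
        idx = 3 * gx[obs].astype(int) + gy[obs].astype(int)
        np.add.at(c, idx, 1)
    return c


_SUPPORTED = {
    (SegregationType.D1_10, SegregationType.D1_10): "A",
    (SegregationType.D2_15, SegregationType.D2_15): "B",
    (SegregationType.D1_10, SegregationType.B3_7): "A",
    (SegregationType.B3_7, SegregationType.D1_10): "A",
    (SegregationType.D2_15, SegregationType.B3_7): "B",
    (SegregationType.B3_7, SegregationType.D2_15): "B",
    (SegregationType.B3_7, SegregationType.B3_7): "EM",
}


def two_point(
    marker_x: str,
    marker_y: str,
    gx: np.ndarray,
    gy: np.ndarray,
    type_x: SegregationType,
    type_y: SegregationType,
    parents_x: tuple[int, int] = (1, 1),
    parents_y: tuple[int, int] = (1, 1),
) -> TwoPointResult:
    """Two-point rf/LOD for one marker pair (symmetric in its arguments).

    ``parents_x``/``parents_y`` are the (parent A, parent B) genotype codes
    of each marker, needed to resolve which allele a D-type parent sent.
    """
    mode = _SUPPORTED.get((type_x, type_y))
    if mode is None:
        return TwoPointResult(marker_x, marker_y, 0.5, 0.0, "none", 0, estimable=False)
    if mode == "EM":
        counts = _counts9(gx, gy)
        rf, lod, ph = b3_two_point(counts[None, :])
        return TwoPointResult(
            marker_x, marker_y, float(rf[0]), float(lod[0]), _PHASES[int(ph[0])], int(counts.sum())
        )
    parent = mode
    other_x = parents_x[1] if parent == "A" else parents_x[0]
    other_y = parents_y[1] if parent == "A" else parents_y[0]
    tx = transmission_pattern(gx, type_x, parent, other_x)
    ty = transmission_pattern(gy, type_y, parent, other_y)
    obs = (tx != MISSING) & (ty != MISSING)
    n = int(obs.sum())
    k = int((tx[obs] != ty[obs]).sum())
    rf, lod, phase = _binomial_lod(k, n)
    return TwoPointResult(marker_x, marker_y, rf, lod, phase, n)


# ---------------------------------------------------------------------------
# vectorised pairwise screening and grouping
# ---------------------------------------------------------------------------

def _pattern_matrix(
    matrix: GenotypeMatrix,
    types: pd.Series,
    parentA: np.ndarray,
    parentB: np.ndarray,
    parent: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack transmitted-allele patterns for all markers informative in ``parent``."""
    want_d = "D1.10" if parent == "A" else "D2.15"
    tarr = types.to_numpy()
    tv = _tvals(types)
    idx = np.flatnonzero((tv == want_d) | (tv == "B3.7"))
    rows = np.full((len(idx), matrix.n_samples), MISSING, dtype=np.int8)
    for r, i in enumerate(idx):
        other = int(parentB[i]) if parent == "A" else int(parentA[i])
        pat = transmission_pattern(matrix.genotypes[i], tarr[i], parent, other)
        if pat is not None:
            rows[r] = pat
    return rows, idx


def _mismatch_counts(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (k, n): informative overlap n and mismatches k, via matmuls."""
    obs = (patterns != MISSING).astype(np.float32)
    val = ((patterns == 1) & (patterns != MISSING)).astype(np.float32)
    n = obs @ obs.T
    vo = val @ obs.T
    vv = val @ val.T
    k = vo + vo.T - 2.0 * vv
    return np.rint(k).astype(np.int64), np.rint(n).astype(np.int64)


def _pattern_pair_stats(k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised closed-form rf/LOD from mismatch tables (best phase)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        kk = np.minimum(k, n - k)
        nn = np.maximum(n, 1)
        rf = kk / nn
        lod = n * LOG10_2 + np.where(
            kk > 0,
            kk * np.log10(np.maximum(rf, 1e-300))
            + (n - kk) * np.log10(np.maximum(1 - rf, 1e-300)),
            0.0,
        )
    lod = np.where(n > 0, lod, 0.0)
    rf = np.where(n > 0, rf, 0.5)
    return rf, lod


def pairwise_linked(
    matrix: GenotypeMatrix,
    types: pd.Series,
    parentA: np.ndarray,
    parentB: np.ndarray,
    lod_threshold: float = 3.4,
    max_rf: float | None = 0.15,
    max_rf_mixed: float | None = 0.08,
    max_rf_b3: float | None = 0.10,
) -> sp.coo_matrix:
    """Sparse symmetric adjacency over markers with LOD/rf-qualified linkage.

    All supported pair classes are evaluated exactly: same-parent and
    D-by-B3.7 pairs in closed form from transmitted-allele mismatch tables,
    B3.7 x B3.7 pairs by vectorised EM on their 3 x 3 offspring tables.
    ``max_rf`` caps same-class pairs, ``max_rf_mixed`` the D-by-B3.7 pairs
    (whose informative meioses are roughly halved); pass None to disable
    either ceiling.
    """
    n_mark = matrix.n_markers
    if max_rf is None:
        max_rf = 0.5
    if max_rf_mixed is None:
        max_rf_mixed = max_rf
    if max_rf_b3 is None:
        max_rf_b3 = max_rf
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    tv = _tvals(types)

    for parent in ("A", "B"):
        pats, idx = _pattern_matrix(matrix, types, parentA, parentB, parent)
        if len(idx) < 2:
            continue
        k, n = _mismatch_counts(pats)
        rf, lod = _pattern_pair_stats(k, n)
        is_b3 = tv[idx] == "B3.7"
        mixed = is_b3[:, None] ^ is_b3[None, :]
        ceiling = np.where(mixed, max_rf_mixed, max_rf)
        hit = (lod >= lod_threshold) & (rf <= ceiling + 1e-12)
        np.fill_diagonal(hit, False)
        # B3 x B3 handled by EM below (keep the closed form off those cells)
        hit &= ~(is_b3[:, None] & is_b3[None, :])
        ii, jj = np.nonzero(hit)
        rows.append(idx[ii])
        cols.append(idx[jj])

    b3_idx = np.flatnonzero(tv == "B3.7")
    if len(b3_idx) >= 2:
        g3 = matrix.genotypes[b3_idx]
        obs = (g3 != MISSING)
        ind = [((g3 == c) & obs).astype(np.float32) for c in (0, 1, 2)]
        iu, ju = np.triu_indices(len(b3_idx), k=1)
        counts9 = np.empty((len(iu), 9), dtype=np.float64)
        for a in range(3):
            for b in range(3):
                counts9[:, 3 * a + b] = (ind[a] @ ind[b].T)[iu, ju]
        rf, lod, _ = b3_two_point(counts9)
        hit = (lod >= lod_threshold) & (rf <= max_rf_b3 + 1e-12)
        rows.append(b3_idx[iu[hit]])
        cols.append(b3_idx[ju[hit]])

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = np.array([], dtype=int)
        c = np.array([], dtype=int)
    data = np.ones(len(r), dtype=np.int8)
    adj = sp.coo_matrix((data, (r, c)), shape=(n_mark, n_mark))
    return (adj + adj.T).tocoo()


def group_markers(
    matrix: GenotypeMatrix,
    types: pd.Series,
    parentA: np.ndarray,
    parentB: np.ndarray,
    lod_threshold: float = 3.4,
    max_rf: float | None = 0.15,
    max_rf_mixed: float | None = 0.08,
    max_rf_b3: float | None = 0.10,
) -> list[LinkageGroupDraft]:
    """Single-linkage transitive closure into linkage-group drafts.

    Only markers of the three dominant informative types participate; null
    and uninformative markers are left out of rf estimation.  Groups come
    back sorted by size (largest first); singletons are allowed.
    """
    tv = _tvals(types)
    informative = np.isin(tv, ["D1.10", "D2.15", "B3.7"])
    adj = pairwise_linked(
        matrix, types, parentA, parentB, lod_threshold, max_rf, max_rf_mixed, max_rf_b3
    )
    n_comp, labels = connected_components(adj.tocsr(), directed=False)
    marker_ids = matrix.markers["marker_id"].to_numpy()
    scaffold_ids = matrix.markers["scaffold_id"].to_numpy()
    drafts = []
    for comp in range(n_comp):
        members = np.flatnonzero((labels == comp) & informative)
        if len(members) == 0:
            continue
        drafts.append(
            LinkageGroupDraft(
                lg_id="",
                marker_ids=marker_ids[members].tolist(),
                scaffolds=set(scaffold_ids[members].tolist()),
            )
        )
    drafts.sort(key=lambda d: (-d.n_markers, d.marker_ids[0]))
    for i, d in enumerate(drafts):
        d.lg_id = f"G{i + 1:02d}"
    return drafts


# ---------------------------------------------------------------------------
# conservative recombination counting
# ---------------------------------------------------------------------------

def _runs(seq: Sequence[int]) -> list[tuple[int, int]]:
    out = []
    for val, grp in itertools.groupby(seq):
        out.append((val, len(list(grp))))
    return out


def corrected_states(seq: Sequence[int]) -> list[int]:
    """Observed states with single-site (putative error) runs removed.

    Missing entries are skipped; maximal runs of length one, including
    terminal ones, are discarded as genotyping errors and the flanking runs
    merged.  The result is the run-level state sequence.
    """
    observed = [int(x) for x in seq if x is not None and x != MISSING]
    runs = [r for r in _runs(observed) if r[1] > 1]
    merged: list[int] = []
    for val, _ in runs:
        if not merged or merged[-1] != val:
            merged.append(val)
    if not merged and observed:
        merged = [observed[0]]
    return merged


def count_recombinations(seq: Sequence[int]) -> int:
    """Conservative crossover count for one gamete sequence."""
    return max(0, len(corrected_states(seq)) - 1)


# ---------------------------------------------------------------------------
# ordering and map positions
# ---------------------------------------------------------------------------

def _greedy_order(rf: np.ndarray) -> list[int]:
    b = rf.shape[0]
    if b <= 2:
        return list(range(b))
    start = int(np.argmax(rf.sum(axis=1)))
    order = [start]
    left = set(range(b)) - {start}
    while left:
        last = order[-1]
        nxt = min(left, key=lambda j: (rf[last, j], j))
        order.append(nxt)
        left.remove(nxt)
    return order


def _two_opt(order: list[int], rf: np.ndarray, max_passes: int = 40) -> list[int]:
    def cost(o: list[int]) -> float:
        return float(sum(rf[o[i], o[i + 1]] for i in range(len(o) - 1)))

    best = list(order)
    best_cost = cost(best)
    for _ in range(max_passes):
        improved = False
        for i in range(0, len(best) - 1):
            for j in range(i + 1, len(best)):
                cand = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                c = cost(cand)
                if c < best_cost - 1e-12:
                    best, best_cost = cand, c
                    improved = True
        if not improved:
            break
    return best


def order_and_position(
    draft: LinkageGroupDraft,
    matrix: GenotypeMatrix,
    types: pd.Series,
    parentA: np.ndarray,
    parentB: np.ndarray,
    parent: str,
) -> pd.DataFrame:
    """Per-parent ordered map with conservative centimorgan positions.

    Markers with identical transmitted-allele patterns collapse into
    cosegregation bins; bins are chained by greedy nearest-neighbour on
    pairwise rf and refined by 2-opt; adjacent-bin distance is 100 x
    corrected crossover events / informative meioses.  Returns an empty
    frame when the group carries no markers informative in ``parent``.
    """
    mid_to_row = {m: i for i, m in enumerate(matrix.markers["marker_id"])}
    rows = [mid_to_row[m] for m in draft.marker_ids if m in mid_to_row]
    tarr = types.to_numpy()
    tv = _tvals(types)
    want = {"B3.7", "D1.10" if parent == "A" else "D2.15"}
    rows = [r for r in rows if tv[r] in want]
    cols = ["marker_id", "scaffold_id", "position", "bin", "cm"]
    if not rows:
        return pd.DataFrame(columns=cols)

    pats = np.full((len(rows), matrix.n_samples), MISSING, dtype=np.int8)
    for r, i in enumerate(rows):
        other = int(parentB[i]) if parent == "A" else int(parentA[i])
        pats[r] = transmission_pattern(matrix.genotypes[i], tarr[i], parent, other)

    meta = matrix.markers.iloc[rows][["marker_id", "scaffold_id", "position"]].reset_index(
        drop=True
    )
    # deterministic bin assignment: first occurrence in (scaffold, position) order
    sort_key = np.lexsort(
        (meta["marker_id"].to_numpy(), meta["position"].to_numpy(), meta["scaffold_id"].to_numpy())
    )
    bin_of = np.empty(len(rows), dtype=int)
    bin_pats: list[np.ndarray] = []
    seen: dict[bytes, int] = {}
    for r in sort_key:
        key = pats[r].tobytes()
        if key not in seen:
            seen[key] = len(bin_pats)
            bin_pats.append(pats[r])
        bin_of[r] = seen[key]
    B = np.stack(bin_pats)

    if len(B) == 1:
        order = [0]
        positions = np.array([0.0])
    else:
        k, n = _mismatch_counts(B)
        rf, _ = _pattern_pair_stats(k, n)
        order = _two_opt(_greedy_order(rf), rf)
        # orient bins consistently along the chain before counting events;
        # a windowed majority vote guards against single low-overlap links
        oriented = B.copy()
        for pos in range(1, len(order)):
            cur = order[pos]
            vote = 0
            for prev in order[max(0, pos - 8):pos]:
                obs = (oriented[prev] != MISSING) & (oriented[cur] != MISSING)
                if obs.any():
                    agree = int((oriented[prev][obs] == oriented[cur][obs]).sum())
                    vote += 2 * agree - int(obs.sum())
            if vote < 0:
                flip = oriented[cur] != MISSING
                oriented[cur, flip] = 1 - oriented[cur, flip]
        nb = len(order)
        events = np.zeros(nb - 1)
        informative = np.zeros(nb - 1)
        seq = oriented[order]  # bins in map order x samples
        for s in range(matrix.n_samples):
            col = seq[:, s]
            obs_bins = np.flatnonzero(col != MISSING)
            if len(obs_bins) < 2:
                continue
            # informative meioses: intervals spanned by the observed range
            informative[obs_bins[0]:obs_bins[-1]] += 1
            for pos in _switch_positions(col[obs_bins], obs_bins):
                events[pos] += 1
        with np.errstate(invalid="ignore"):
            dists = np.where(informative > 0, 100.0 * events / np.maximum(informative, 1), 0.0)
        positions = np.concatenate([[0.0], np.cumsum(dists)])

    pos_of_bin = {b: positions[i] for i, b in enumerate(order)}
    out = meta.copy()
    out["bin"] = [order.index(b) for b in bin_of]
    out["cm"] = [pos_of_bin[b] for b in bin_of]
    out = out.sort_values(["cm", "scaffold_id", "position"], kind="stable").reset_index(drop=True)
    return out[cols]


def _switch_positions(values: np.ndarray, bin_indices: np.ndarray) -> list[int]:
    """Interval indices receiving a corrected switch, for one gamete.

    ``values`` are the observed states in map order, ``bin_indices`` the bin
    index of each.  Singleton runs are removed; each remaining state switch
    is assigned to the first inter-bin interval of the gap between the two
    observations flanking it.
    """
    runs = []
    start = 0
    for val, grp in itertools.groupby(values):
        ln = len(list(grp))
        runs.append((int(val), start, start + ln - 1))
        start += ln
    kept = [r for r in runs if r[2] > r[1]]
    if not kept:
        return []
    out = []
    for (v1, _, e1), (v2, s2, _) in zip(kept[:-1], kept[1:]):
        if v1 != v2:
            out.append(int(bin_indices[e1]))
    return out


def group_span(map_df: pd.DataFrame) -> float:
    if len(map_df) == 0:
        return 0.0
    return float(map_df["cm"].max())


def position_group(
    draft: LinkageGroupDraft,
    matrix: GenotypeMatrix,
    types: pd.Series,
    parentA: np.ndarray,
    parentB: np.ndarray,
) -> None:
    for parent in ("A", "B"):
        df = order_and_position(draft, matrix, types, parentA, parentB, parent)
        draft.maps[parent] = df
        draft.spans[parent] = group_span(df)


# ---------------------------------------------------------------------------
# group merging
# ---------------------------------------------------------------------------

def _scaffold_positions(draft: LinkageGroupDraft, parent: str) -> pd.Series:
    df = draft.maps.get(parent)
    if df is None or len(df) == 0:
        return pd.Series(dtype=float)
    return df.groupby("scaffold_id")["cm"].median()


def _consistent_order(p1: pd.Series, p2: pd.Series, shared: list[str]) -> bool:
    """True when the shared scaffolds sort identically or fully reversed."""
    order = sorted(shared, key=lambda s: (p1[s], s))
    vals = np.array([p2[s] for s in order])
    return bool(np.all(np.diff(vals) >= 0) or np.all(np.diff(vals) <= 0))


def merge_groups(
    drafts: list[LinkageGroupDraft],
    matrix: GenotypeMatrix,
    types: pd.Series,
    parentA: np.ndarray,
    parentB: np.ndarray,
    min_shared: int = 4,
) -> list[LinkageGroupDraft]:
    """Merge single-parent groups into both-parent groups they overlap.

    A group informative in only one parent is merged into a group with both
    parental maps when they share at least ``min_shared`` scaffolds and the
    shared scaffolds keep a consistent relative order (identical or
    reversed).  Applied iteratively to a fixed point; order conflicts leave
    the groups unmerged.
    """
    drafts = list(drafts)
    changed = True
    while changed:
        changed = False
        for ds in drafts:
            parents_ds = [p for p in ("A", "B") if len(ds.maps.get(p, ())) > 0]
            if len(parents_ds) != 1:
                continue
            ps = parents_ds[0]
            p1 = _scaffold_positions(ds, ps)
            for db in drafts:
                if db is ds:
                    continue
                if any(len(db.maps.get(p, ())) == 0 for p in ("A", "B")):
                    continue
                other = "B" if ps == "A" else "A"
                p2 = _scaffold_positions(db, other)
                shared = sorted(set(p1.index) & set(p2.index))
                if len(shared) < min_shared:
                    continue
                if not _consistent_order(p1, p2, shared):
                    continue
                db.marker_ids = sorted(set(db.marker_ids) | set(ds.marker_ids))
                db.scaffolds |= ds.scaffolds
                position_group(db, matrix, types, parentA, parentB)
                drafts.remove(ds)
                changed = True
                break
            if changed:
                break
    drafts.sort(key=lambda d: (-d.n_markers, d.marker_ids[0]))
    for i, d in enumerate(drafts):
        d.lg_id = f"G{i + 1:02d}"
    return drafts


# ---------------------------------------------------------------------------
# end-to-end cross map
# ---------------------------------------------------------------------------

def map_cross(
    matrix: GenotypeMatrix,
    parentA: np.ndarray,
    parentB: np.ndarray,
    types: pd.Series | None = None,
    lod_threshold: float = 3.4,
    max_rf: float | None = 0.15,
    max_rf_mixed: float | None = 0.08,
    min_shared: int = 4,
) -> tuple[pd.Series, list[LinkageGroupDraft]]:
    """Classify, group, order and merge: the full cross-mapping stage."""
    from .markerqc import classify_matrix

    if types is None:
        types = classify_matrix(matrix, parentA, parentB)
    drafts = group_markers(
        matrix, types, parentA, parentB, lod_threshold, max_rf, max_rf_mixed
    )
    for d in drafts:
        position_group(d, matrix, types, parentA, parentB)
    drafts = merge_groups(drafts, matrix, types, parentA, parentB, min_shared)
    return types, drafts
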