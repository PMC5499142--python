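"""Reciprocal-best-hit orthology and linkage-group concordance.

Orthologs between the focal genome and an external genome are called as
reciprocal best hits (RBH) in two protein BLAST hit tables: a pair is kept
when each gene is the other's single best hit (lowest E-value, ties broken
by bit score, unresolved ties dropped), the qualifying hits have
E <= 1e-100, and both proteins are at least 100 amino acids.

Concordance then asks whether genes that share an external scaffold land
on the same focal linkage group more often than chance.  Scaffolds split
between two LGs contribute weight 1/2 to each; the chance expectation for
pair sharing is sum_i n_i (n_i - 1) / [N (N - 1)] over weighted LG scaffold
counts, with a label-permutation estimate as an independent alternative.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .mapsummary import roman_rank as _roman_rank


def roman_rank(lg: str) -> tuple[int, str]:
    """Sort key: Roman-numeral rank when parseable, else lexicographic."""
    try:
        return (_roman_rank(lg), lg)
    except KeyError:
        return (10**9, lg)

__all__ = [
    "reciprocal_best_hits",
    "lg_concordance",
    "shared_lg_pairs",
    "ConcordanceResult",
]


@dataclasses.dataclass
class ConcordanceResult:
    n_external_scaffolds_multi: int
    majority_fraction: float
    pair_share_fraction: float
    chance_expectation: float
    fold_enrichment: float
    permutation_expectation: float
    permutation_fold: float
    permutation_se: float
    lg_pair_counts: pd.DataFrame


def _best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """query -> unique best subject; queries with unresolved ties dropped."""
    best: dict[str, str] = {}
    has_bits = "bit_score" in hits.columns and hits["bit_score"].notna().all()
    for qid, sub in hits.groupby("query_id"):
        key = (
            sub.sort_values(["e_value", "bit_score"], ascending=[True, False])
            if has_bits
            else sub.sort_values("e_value")
        )
        top = key.iloc[0]
        ties = key[
            (key["e_value"] == top["e_value"])
            & ((key["bit_score"] == top["bit_score"]) if has_bits else True)
        ]
        if ties["subject_id"].nunique() > 1:
            continue
        best[qid] = top["subject_id"]
    return best


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    lengths_a: Mapping[str, int],
    lengths_b: Mapping[str, int],
    gene_scaffold_a: Mapping[str, str] | None = None,
    gene_scaffold_b: Mapping[str, str] | None = None,
    evalue_max: float = 1e-100,
    min_length_aa: int = 100,
) -> pd.DataFrame:
    """Ortholog pairs as reciprocal best hits between two hit tables.

    ``hits_ab`` holds genome-A queries against genome-B subjects and vice
    versa.  Optional gene -> scaffold maps annotate the output.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    emin_ab = hits_ab.groupby(["query_id", "subject_id"])["e_value"].min()
    emin_ba = hits_ba.groupby(["query_id", "subject_id"])["e_value"].min()
    rows = []
    for ga, gb in sorted(best_ab.items()):
        if best_ba.get(gb) != ga:
            continue
        e_ab = float(emin_ab.loc[(ga, gb)])
        e_ba = float(emin_ba.loc[(gb, ga)])
        if e_ab > evalue_max or e_ba > evalue_max:
            continue
        la = int(lengths_a.get(ga, 0))
        lb = int(lengths_b.get(gb, 0))
        if la < min_length_aa or lb < min_length_aa:
            continue
        rows.append(
            (
                ga,
                gb,
                max(e_ab, e_ba),
                la,
                lb,
                (gene_scaffold_a or {}).get(ga, ""),
                (gene_scaffold_b or {}).get(gb, ""),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "e_value", "length_a", "length_b",
            "scaffold_a", "scaffold_b",
        ],
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def _lg_weights(scaffold_weights: pd.DataFrame) -> dict[str, list[tuple[str, float]]]:
    out: dict[str, list[tuple[str, float]]] = {}
    for row in scaffold_weights.itertuples(index=False):
        out.setdefault(row.scaffold_id, []).append((row.lg, row.weight))
    return out


def _share_prob(w1: list[tuple[str, float]], w2: list[tuple[str, float]]) -> float:
    d2 = dict(w2)
    return float(sum(w * d2.get(lg, 0.0) for lg, w in w1))


def lg_concordance(
    orthologs: pd.DataFrame,
    scaffold_weights: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ConcordanceResult:
    """Concordance of shared-external-scaffold gene pairs with focal LGs.

    Only orthologs whose focal scaffold is on the map participate.  The
    analytic chance expectation conditions on the weighted LG size
    spectrum; the permutation alternative shuffles the scaffold -> LG
    assignment vectors across mapped scaffolds.
    """
    if len(orthologs) == 0:
        raise ValueError("empty ortholog list")
    weights = _lg_weights(scaffold_weights)
    df = orthologs[orthologs["scaffold_b"].isin(weights)].copy()
    if len(df) == 0:
        raise ValueError("no orthologs on mapped scaffolds")

    by_ext = {
        ext: sorted(set(sub["scaffold_b"]))
        for ext, sub in df.groupby("scaffold_a")
        if sub["scaffold_b"].nunique() >= 2
    }
    n_multi = len(by_ext)

    def majority_frac(wmap: dict) -> float:
        hits = 0
        for scafs in by_ext.values():
            lg_tot: dict[str, float] = {}
            for s in scafs:
                for lg, w in wmap.get(s, []):
                    lg_tot[lg] = lg_tot.get(lg, 0.0) + w
            if lg_tot and max(lg_tot.values()) >= 0.5 * len(scafs):
                hits += 1
        return hits / n_multi if n_multi else float("nan")

    def share_frac(wmap: dict) -> float:
        tot = 0.0
        num = 0.0
        for scafs in by_ext.values():
            for i, a in enumerate(scafs):
                for b in scafs[i + 1:]:
                    tot += 1.0
                    num += _share_prob(wmap.get(a, []), wmap.get(b, []))
        return num / tot if tot else float("nan")

    # analytic chance: weighted LG sizes over the mapped scaffold universe
    lg_sizes: dict[str, float] = {}
    for wl in weights.values():
        for lg, w in wl:
            lg_sizes[lg] = lg_sizes.get(lg, 0.0) + w
    n_total = sum(lg_sizes.values())
    chance = (
        sum(v * (v - 1) for v in lg_sizes.values()) / (n_total * (n_total - 1))
        if n_total > 1
        else float("nan")
    )

    observed_share = share_frac(weights)
    rng = np.random.default_rng(seed)
    scaffold_list = sorted(weights)
    vectors = [weights[s] for s in scaffold_list]
    perm_vals = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(scaffold_list))
        wmap = {s: vectors[perm[i]] for i, s in enumerate(scaffold_list)}
        perm_vals.append(share_frac(wmap))
    perm_mean = float(np.mean(perm_vals))
    perm_se = float(np.std(perm_vals, ddof=1) / np.sqrt(len(perm_vals)))

    return ConcordanceResult(
        n_external_scaffolds_multi=n_multi,
        majority_fraction=majority_frac(weights),
        pair_share_fraction=observed_share,
        chance_expectation=float(chance),
        fold_enrichment=float(observed_share / chance) if chance else float("nan"),
        permutation_expectation=perm_mean,
        permutation_fold=float(observed_share / perm_mean) if perm_mean else float("nan"),
        permutation_se=perm_se,
        lg_pair_counts=shared_lg_pairs(orthologs, scaffold_weights),
    )


def shared_lg_pairs(
    orthologs: pd.DataFrame, scaffold_weights: pd.DataFrame
) -> pd.DataFrame:
    """For each external scaffold spanning >= 2 LGs, count its top-two LG pair.

    LG pairs are ordered by Roman-numeral rank; ties among LG weights are
    broken the same way, making the output deterministic.
    """
    weights = _lg_weights(scaffold_weights)
    df = orthologs[orthologs["scaffold_b"].isin(weights)]
    counts: dict[tuple[str, str], int] = {}
    for ext, sub in df.groupby("scaffold_a"):
        lg_tot: dict[str, float] = {}
        for s in set(sub["scaffold_b"]):
            for lg, w in weights.get(s, []):
                lg_tot[lg] = lg_tot.get(lg, 0.0) + w
        if len(lg_tot) < 2:
            continue
        ranked = sorted(lg_tot.items(), key=lambda kv: (-kv[1], roman_rank(kv[0])))
        top2 = sorted((ranked[0][0], ranked[1][0]), key=roman_rank)
        counts[tuple(top2)] = counts.get(tuple(top2), 0) + 1
    rows = [(a, b, c) for (a, b), c in counts.items()]
    out = pd.DataFrame(rows, columns=["lg_1", "lg_2", "n_external_scaffolds"])
    return out.sort_values(
        ["n_external_scaffolds", "lg_1", "lg_2"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
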