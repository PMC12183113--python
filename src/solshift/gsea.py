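"""Preranked gene-set enrichment with a permutation null, plus redundancy
reduction of enriched terms.

The enrichment score (ES) of a set is the extreme of the weighted
Kolmogorov-Smirnov running sum along the ranking: walking down the list
sorted by the ranking statistic, hits increment the sum by |r|^w / N_R
(N_R the sum of |r|^w over set members, w the weight exponent) and misses
decrement by 1/(N - N_hit).  The null distribution comes from gene-label
permutation (random same-size sets), which is the standard choice for
preranked mode and the only feasible one at n = 5 samples per group.
Normalized ES divides by the mean |ES| of same-sign null draws; q-values
are BH across sets.  ``simplify_terms`` collapses near-duplicate terms by
Jaccard similarity of their member lists, keeping the better-scoring term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SolshiftError
from .model import bh_adjust

MIN_SET_SIZE = 5


def enrichment_score(
    ranking: pd.Series, members, weight_exponent: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score of one gene set.

    ``ranking`` maps gene -> statistic (no missing values); the list is
    walked in descending-statistic order.  Returns the signed extreme of
    the running sum; a set containing every ranked gene scores 0.
    """
    if ranking.isna().any():
        raise SolshiftError("ranking contains missing values")
    order = ranking.sort_values(ascending=False, kind="stable")
    stats_abs = np.abs(order.to_numpy()) ** weight_exponent
    hit = order.index.isin(set(members))
    n = len(order)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    nr = stats_abs[hit].sum()
    if nr == 0:
        # all member stats zero: hits carry equal weight
        steps_hit = np.where(hit, 1.0 / n_hit, 0.0)
    else:
        steps_hit = np.where(hit, stats_abs / nr, 0.0)
    steps_miss = np.where(hit, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(steps_hit - steps_miss)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: size, es, nes, p, q, leading_edge
    n_perm: int
    weight_exponent: float

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]


def _leading_edge(ranking: pd.Series, members, es: float, weight_exponent: float):
    order = ranking.sort_values(ascending=False, kind="stable")
    stats_abs = np.abs(order.to_numpy()) ** weight_exponent
    hit = order.index.isin(set(members))
    n, n_hit = len(order), int(hit.sum())
    nr = stats_abs[hit].sum()
    steps_hit = np.where(hit, (stats_abs / nr) if nr else (1.0 / n_hit), 0.0)
    running = np.cumsum(steps_hit - np.where(hit, 0.0, 1.0 / (n - n_hit)))
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        idx = order.index[: peak + 1]
    else:
        idx = order.index[peak:]
    return [g for g in idx if g in set(members)]


def gsea_preranked(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    min_size: int = MIN_SET_SIZE,
    seed: int | None = None,
) -> EnrichmentResult:
    """Preranked GSEA over a collection of gene sets.

    Sets are intersected with the ranked universe; sets below ``min_size``
    (or covering the whole universe) are skipped.  The permutation null
    draws random same-size member sets from the universe (gene-label
    permutation); p is the fraction of same-sign null ES at least as
    extreme, with a +1 continuity correction; q is BH across sets.
    """
    if ranking.isna().any():
        raise SolshiftError("ranking contains missing values")
    rng = np.random.default_rng(seed)
    universe = list(ranking.index)
    n = len(universe)

    # precompute the sorted walk once; per-set work is then O(n)
    order = ranking.sort_values(ascending=False, kind="stable")
    pos_of = {g: i for i, g in enumerate(order.index)}
    stats_abs = np.abs(order.to_numpy()) ** weight_exponent

    def es_for_positions(pos: np.ndarray) -> float:
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        nr = stats_abs[hit].sum()
        n_hit = len(pos)
        if nr == 0:
            steps_hit = np.where(hit, 1.0 / n_hit, 0.0)
        else:
            steps_hit = np.where(hit, stats_abs / nr, 0.0)
        running = np.cumsum(steps_hit - np.where(hit, 0.0, 1.0 / (n - n_hit)))
        return float(running[np.argmax(np.abs(running))])

    rows = []
    for name, members in gene_sets.items():
        inset = sorted(set(members) & set(universe))
        size = len(inset)
        if size < min_size or size >= n:
            continue
        pos = np.array([pos_of[g] for g in inset])
        es = es_for_positions(pos)
        null_es = np.array(
            [
                es_for_positions(rng.choice(n, size=size, replace=False))
                for _ in range(n_perm)
            ]
        )
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same_sign):
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            nes = es / np.mean(np.abs(same_sign))
        else:
            p, nes = 1.0 / (n_perm + 1), 0.0
        rows.append(
            {
                "set": name,
                "size": size,
                "es": es,
                "nes": nes,
                "p": float(min(p, 1.0)),
                "leading_edge": _leading_edge(ranking, inset, es, weight_exponent),
                "members": inset,
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "p", "leading_edge", "members"]
    )
    if len(table):
        table["q"] = np.maximum(bh_adjust(table["p"].to_numpy()), table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    table = table.set_index("set")
    return EnrichmentResult(table=table, n_perm=n_perm, weight_exponent=weight_exponent)


def simplify_terms(
    result: EnrichmentResult, similarity_threshold: float = 0.7
) -> EnrichmentResult:
    """Collapse redundant terms by Jaccard similarity of member lists.

    Pairs above the threshold are resolved by dropping the set with the
    larger q (ties: larger |ES| wins, then lexicographic id), scanning
    pairs in order of descending similarity then id for determinism.
    """
    table = result.table
    names = list(table.index)
    members = {name: set(table.loc[name, "members"]) for name in names}
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(members[a] & members[b])
            union = len(members[a] | members[b])
            sim = inter / union if union else 0.0
            if sim > similarity_threshold:
                pairs.append((sim, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    for _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        qa, qb = table.loc[a, "q"], table.loc[b, "q"]
        if qa < qb:
            dropped.add(b)
        elif qb < qa:
            dropped.add(a)
        else:
            ea, eb = abs(table.loc[a, "es"]), abs(table.loc[b, "es"])
            if ea != eb:
                dropped.add(a if ea < eb else b)
            else:
                dropped.add(max(a, b))
    kept = table.loc[[name for name in names if name not in dropped]]
    return EnrichmentResult(
        table=kept, n_perm=result.n_perm, weight_exponent=result.weight_exponent
    )
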