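"""Gene-set enrichment: hypergeometric over-representation and rank-based GSEA.

Over-representation analysis (ORA) tests whether a hit list overlaps a gene
set more than expected under hypergeometric sampling from the screened
universe, reporting the upper-tail p (optionally doubled for a two-sided
report, or with the conservative EASE k-1 adjustment) and the gene ratio
k / K (hits in set over set size).

The rank-based mode computes the GSEA running-sum enrichment score on a gene
list ranked by a per-gene score (here typically the per-cell viability
measure): member genes push the sum up in proportion to |score|^weight,
non-members push it down uniformly, and the enrichment score (ES) is the
maximum deviation from zero. Significance and the normalized score (NES) come
from gene-label permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = [
    "hypergeometric_enrichment",
    "enrichment_score",
    "gsea_enrichment",
    "gsea_table",
]


def hypergeometric_enrichment(
    hit_genes,
    universe,
    sets: dict[str, tuple[str, tuple[str, ...]]],
    two_sided: bool = True,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each gene set.

    Sets are intersected with the universe first; sets left empty are
    dropped. The upper-tail p is P(X >= k) for the observed overlap k (EASE
    mode scores P(X >= k-1), the DAVID-style conservative variant); the
    two-sided report is min(1, 2 * min(upper, lower)).
    """
    universe = set(universe)
    if not universe:
        raise ConfigError("empty universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ConfigError("hit_genes must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, (_desc, members) in sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & hits)
        k_eff = max(k - 1, 0) if ease else k
        upper = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        lower = float(stats.hypergeom.cdf(k, N, K, n))
        p = min(1.0, 2.0 * min(upper, lower)) if two_sided else upper
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "gene_ratio": k / K,
                "p_value": p,
                "p_upper": upper,
            }
        )
    return pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "gene_ratio", "p_value", "p_upper"])


def enrichment_score(
    scores: np.ndarray, member_mask: np.ndarray, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """GSEA running-sum enrichment score for one set on a ranked list.

    ``scores`` must already be in ranking order (descending by convention);
    ``member_mask`` marks set members. Member steps are |score|^weight
    normalized over members; non-member steps are -1/(N-K). Returns (ES,
    running sum); ES is the deviation of maximum magnitude, in [-1, 1].
    """
    scores = np.asarray(scores, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    N = scores.size
    K = int(member_mask.sum())
    if K == 0 or K == N:
        raise ConfigError("set must be a non-empty strict subset of the ranking")
    weights = np.abs(scores[member_mask]) ** weight
    total = weights.sum()
    increments = np.zeros(N)
    if total > 0:
        increments[member_mask] = weights / total
    else:  # all member scores zero: fall back to uniform member steps
        increments[member_mask] = 1.0 / K
    increments[~member_mask] = -1.0 / (N - K)
    running = np.cumsum(increments)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_enrichment(
    ranking: pd.Series,
    set_members,
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    set_name: str = "",
) -> dict | None:
    """GSEA statistic for one gene set on a score-ranked gene list.

    ``ranking`` maps gene -> score and is sorted descending internally; genes
    must be unique. Permutation p and NES use gene-label permutations:
    p = (1 + #{same-sign permutation ES at least as extreme}) / (1 + #{same
    sign}); NES = ES / mean(|permutation ES| with matching sign). Returns
    None (with a warning) when the set does not intersect the ranking.
    """
    if ranking.index.has_duplicates:
        raise ConfigError("ranking contains duplicate genes")
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    member_mask = ranking.index.isin(set(set_members))
    K = int(member_mask.sum())
    if K == 0:
        warnings.warn(f"gene set {set_name or '<unnamed>'} disjoint from ranking", stacklevel=2)
        return None
    N = len(ranking)
    if K == N:
        warnings.warn(f"gene set {set_name or '<unnamed>'} covers the whole ranking", stacklevel=2)
        return None
    scores = ranking.to_numpy()
    es, _ = enrichment_score(scores, member_mask, weight=weight)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm_es = np.empty(n_permutations)
    mask = np.zeros(N, dtype=bool)
    for i in range(n_permutations):
        mask[:] = False
        mask[rng.choice(N, size=K, replace=False)] = True
        perm_es[i], _ = enrichment_score(scores, mask, weight=weight)
    same_sign = perm_es * np.sign(es) > 0 if es != 0 else np.ones(n_permutations, bool)
    m = int(same_sign.sum())
    if m == 0:
        nes = float("nan")
        p = 1.0 / (n_permutations + 1)
    else:
        nes = es / np.abs(perm_es[same_sign]).mean()
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + m)
    return {
        "set_name": set_name,
        "k": K,
        "K": K,
        "n": N,
        "N": N,
        "es": es,
        "nes": float(nes),
        "p_value": float(p),
        "direction": "high" if es > 0 else "low",
        "n_permutations": n_permutations,
    }


def gsea_table(
    ranking: pd.Series,
    sets: dict[str, tuple[str, tuple[str, ...]]],
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`gsea_enrichment` for every set in a collection."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, (_desc, members) in sets.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = gsea_enrichment(
                ranking, members, weight=weight, n_permutations=n_permutations,
                seed=rng, set_name=name,
            )
        if result is not None:
            rows.append(result)
    return pd.DataFrame(rows)
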