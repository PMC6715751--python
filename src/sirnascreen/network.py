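"""Functional similarity network over hit genes from shared annotation terms.

Two genes are connected by the Tanimoto (Jaccard) score of their annotation
term sets — the size of the intersection over the size of the union. Genes
with no annotation participate with score 0 against every partner, so they
never pass a positive threshold.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["tanimoto", "build_similarity_network"]


def tanimoto(terms_a: Iterable, terms_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B| between two term sets; 0 when both are empty."""
    a, b = set(terms_a), set(terms_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def build_similarity_network(
    genes: Iterable[str],
    gene_terms: Mapping[str, Iterable],
    min_score: float = 0.2,
) -> pd.DataFrame:
    """All unordered gene pairs with Tanimoto similarity >= ``min_score``.

    ``gene_terms`` maps gene -> annotation term set (see
    :func:`sirnascreen.screen_io.invert_gene_sets`); genes absent from it are
    treated as unannotated. Self-pairs are excluded; each pair appears once,
    ordered (gene_a, gene_b) by the input gene order.
    """
    genes = list(dict.fromkeys(genes))
    rows = []
    term_sets = {g: frozenset(gene_terms.get(g, ())) for g in genes}
    for ga, gb in combinations(genes, 2):
        score = tanimoto(term_sets[ga], term_sets[gb])
        if score >= min_score:
            rows.append((ga, gb, score))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "tanimoto_score"])
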