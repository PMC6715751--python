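"""Hypergeometric over-representation and GSEA running-sum statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sirnascreen import enrichment_score, gsea_enrichment, hypergeometric_enrichment
from sirnascreen.enrich import gsea_table
from sirnascreen.errors import ConfigError


def _sets(**kwargs):
    return {name: ("desc", tuple(members)) for name, members in kwargs.items()}


class TestHypergeometric:
    def test_degenerate_universe_everything_is_a_hit(self):
        genes = [f"G{i}" for i in range(5)]
        result = hypergeometric_enrichment(genes, genes, _sets(S=genes))
        row = result.iloc[0]
        assert row["gene_ratio"] == 1.0
        assert row["p_upper"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"G{i}" for i in range(10)]
        result = hypergeometric_enrichment(
            universe[:3], universe, _sets(S=universe[5:])
        )
        row = result.iloc[0]
        assert row["k"] == 0 and row["gene_ratio"] == 0.0
        assert row["p_upper"] == pytest.approx(1.0)  # P(X >= 0) = 1

    def test_upper_tail_matches_exhaustive_enumeration(self):
        """All C(20,5) equally likely hit draws; count overlaps >= k."""
        universe = [f"G{i}" for i in range(20)]
        gene_set = set(universe[:5])
        hits = universe[1:5] + [universe[10]]  # overlap k = 4
        result = hypergeometric_enrichment(hits, universe, _sets(S=gene_set))
        total = more_extreme = 0
        for draw in combinations(universe, 5):
            total += 1
            if len(set(draw) & gene_set) >= 4:
                more_extreme += 1
        assert result.iloc[0]["p_upper"] == pytest.approx(more_extreme / total, rel=1e-12)

    def test_exhaustive_agreement_on_many_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            N = int(rng.integers(8, 26))
            universe = [f"G{i}" for i in range(N)]
            K = int(rng.integers(2, N - 1))
            n = int(rng.integers(2, N - 1))
            gene_set = set(rng.choice(universe, size=K, replace=False).tolist())
            hits = rng.choice(universe, size=n, replace=False).tolist()
            k = len(set(hits) & gene_set)
            row = hypergeometric_enrichment(hits, universe, _sets(S=gene_set)).iloc[0]
            total = upper = 0
            for draw in combinations(range(N), n):
                total += 1
                if len({universe[i] for i in draw} & gene_set) >= k:
                    upper += 1
            assert row["p_upper"] == pytest.approx(upper / total, rel=1e-9)

    def test_ease_mode_is_more_conservative(self):
        universe = [f"G{i}" for i in range(30)]
        gene_set = universe[:8]
        hits = universe[:6]
        plain = hypergeometric_enrichment(hits, universe, _sets(S=gene_set), two_sided=False)
        ease = hypergeometric_enrichment(hits, universe, _sets(S=gene_set), two_sided=False, ease=True)
        assert ease.iloc[0]["p_value"] > plain.iloc[0]["p_value"]

    def test_input_validation(self):
        with pytest.raises(ConfigError):
            hypergeometric_enrichment(["A"], [], _sets(S=["A"]))
        with pytest.raises(ConfigError):
            hypergeometric_enrichment(["Z"], ["A", "B"], _sets(S=["A"]))


class TestGSEA:
    def test_perfect_segregation_weight_zero_gives_es_one(self):
        # K=2 members occupy the top 2 of 4 ranks
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        member = np.array([True, True, False, False])
        es, running = enrichment_score(scores, member, weight=0.0)
        assert es == pytest.approx(1.0)
        assert running[1] == pytest.approx(1.0)

    def test_uniform_interleaving_gives_small_es(self):
        N = 40
        member = np.zeros(N, dtype=bool)
        member[::2] = True  # K = N/2, perfectly interleaved
        scores = np.linspace(2, 1, N)
        es, _ = enrichment_score(scores, member, weight=0.0)
        assert abs(es) <= 2.0 / N + 1e-12

    def test_running_sum_matches_brute_force(self):
        rng = np.random.default_rng(11)
        scores = np.sort(rng.normal(0, 1.5, 30))[::-1]
        member = np.zeros(30, dtype=bool)
        member[rng.choice(30, 5, replace=False)] = True
        es, running = enrichment_score(scores, member, weight=1.0)
        # independent step-by-step computation
        denom = sum(abs(s) for s, m in zip(scores, member) if m)
        total, best, path = 0.0, 0.0, []
        for s, m in zip(scores, member):
            total += abs(s) / denom if m else -1.0 / 25
            path.append(total)
            if abs(total) > abs(best):
                best = total
        assert np.allclose(running, path, atol=1e-12)
        assert es == pytest.approx(best, abs=1e-12)

    def test_permutation_p_close_to_exhaustive_enumeration(self):
        genes = [f"G{i}" for i in range(10)]
        rng = np.random.default_rng(13)
        ranking = pd.Series(np.sort(rng.normal(size=10))[::-1], index=genes)
        members = {"G0", "G3", "G7"}
        result = gsea_enrichment(ranking, members, weight=1.0,
                                 n_permutations=10000, seed=99)
        obs = result["es"]
        scores = ranking.to_numpy()
        same_sign = extreme = 0
        for mask_idx in combinations(range(10), 3):
            mask = np.zeros(10, dtype=bool)
            mask[list(mask_idx)] = True
            es, _ = enrichment_score(scores, mask, weight=1.0)
            if es * np.sign(obs) > 0:
                same_sign += 1
                if abs(es) >= abs(obs):
                    extreme += 1
        exact = extreme / same_sign
        se = np.sqrt(exact * (1 - exact) / same_sign + exact * (1 - exact) / 10000)
        assert result["p_value"] == pytest.approx(exact, abs=max(2 * se, 0.02))

    def test_nes_sign_matches_es_sign_and_determinism(self):
        rng = np.random.default_rng(17)
        genes = [f"G{i}" for i in range(50)]
        ranking = pd.Series(rng.normal(size=50), index=genes)
        for members in ([f"G{i}" for i in range(8)], [f"G{i}" for i in range(40, 48)]):
            a = gsea_enrichment(ranking, members, n_permutations=300, seed=5)
            b = gsea_enrichment(ranking, members, n_permutations=300, seed=5)
            assert a == b  # deterministic given seed
            assert np.sign(a["nes"]) == np.sign(a["es"])
            assert -1 <= a["es"] <= 1

    def test_disjoint_set_warns_and_returns_none(self):
        ranking = pd.Series([1.0, 0.5], index=["A", "B"])
        with pytest.warns(UserWarning):
            assert gsea_enrichment(ranking, {"Z"}, n_permutations=10) is None

    def test_duplicate_genes_rejected(self):
        ranking = pd.Series([1.0, 0.5], index=["A", "A"])
        with pytest.raises(ConfigError):
            gsea_enrichment(ranking, {"A"})

    def test_gsea_table_runs_collection(self):
        rng = np.random.default_rng(19)
        genes = [f"G{i}" for i in range(30)]
        ranking = pd.Series(rng.normal(size=30), index=genes)
        sets = _sets(TOP=genes[:6], BOTTOM=genes[-6:], ABSENT=["Z1", "Z2"])
        table = gsea_table(ranking, sets, n_permutations=200, seed=3)
        assert set(table["set_name"]) == {"TOP", "BOTTOM"}
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()
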