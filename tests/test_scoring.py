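"""Trie-constrained scoring: normalization schemes, oracle agreement, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fixed_lm
from targetrank.exceptions import ConfigurationError
from targetrank.lexicon import GeneEntry, GeneLexicon, build_trie
from targetrank.lm import NextTokenDistribution
from targetrank.scoring import (
    PromptTemplate,
    ScoringConfig,
    brute_force_score,
    build_prompt,
    final_normalize,
    rank,
    score_genes,
    step_normalize,
)

BEST = ScoringConfig(step_scheme="total_sum", final_scheme="length_division",
                     alpha=1.0)


class TestPromptTemplate:
    def test_default_prompt_text(self):
        assert PromptTemplate().fill("aging") == (
            "human gene targeted by a drug for treating aging is the"
        )

    def test_placeholder_required_exactly_once(self):
        with pytest.raises(ConfigurationError):
            PromptTemplate("no placeholder here")
        with pytest.raises(ConfigurationError):
            PromptTemplate("{DISEASE} twice {DISEASE}")

    def test_empty_disease_rejected(self):
        with pytest.raises(ValueError):
            PromptTemplate().fill("")

    def test_build_prompt_deterministic(self, toy_lm):
        t = PromptTemplate()
        assert build_prompt(t, "aging", toy_lm) == build_prompt(t, "aging", toy_lm)


class TestStepNormalize:
    def _dist(self, probs):
        return NextTokenDistribution(np.asarray(probs, dtype=float))

    def test_total_sum_renormalizes_allowed_set(self):
        dist = self._dist([0.2, 0.2, 0.6, 0.0])
        step = step_normalize(dist, {0}, {1}, "total_sum")
        assert step.completing[0] == pytest.approx(0.5)
        assert step.continuing[1] == pytest.approx(0.5)

    def test_separate_sum_per_class(self):
        # completing {a: 0.1}, continuing {b: 0.3, c: 0.1}
        dist = self._dist([0.1, 0.3, 0.1, 0.5])
        step = step_normalize(dist, {0}, {1, 2}, "separate_sum")
        assert step.completing[0] == pytest.approx(1.0)
        assert step.continuing[1] == pytest.approx(0.75)
        assert step.continuing[2] == pytest.approx(0.25)

    def test_none_restricts_without_scaling(self):
        dist = self._dist([0.1, 0.3, 0.1, 0.5])
        step = step_normalize(dist, {0}, {1}, "none")
        assert step.completing[0] == pytest.approx(0.1)
        assert step.continuing[1] == pytest.approx(0.3)

    def test_zero_allowed_mass_gives_zeros(self):
        dist = self._dist([0.0, 0.0, 0.5, 0.5])
        step = step_normalize(dist, {0}, {1}, "total_sum")
        assert step.completing[0] == 0.0 and step.continuing[1] == 0.0

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ValueError):
            step_normalize(self._dist([1.0]), set(), set(), "total_sum")

    @settings(derandomize=True, max_examples=100)
    @given(
        probs=st.lists(st.floats(1e-6, 1.0), min_size=4, max_size=12),
        split=st.integers(1, 3),
    )
    def test_total_sum_mass_conservation(self, probs, split):
        p = np.asarray(probs) / np.sum(probs)
        dist = NextTokenDistribution(p)
        completing = set(range(split))
        continuing = set(range(split, len(probs)))
        step = step_normalize(dist, completing, continuing, "total_sum")
        total = sum(step.completing.values()) + sum(step.continuing.values())
        assert total == pytest.approx(1.0, abs=1e-9)


class TestScoreGenes:
    def test_worked_three_gene_example(self, abc_setup):
        lm, lexicon, trie, prompt = abc_setup
        scores = {s.symbol: s for s in score_genes(lm, trie, prompt, BEST)}
        assert scores["A"].raw_probability == pytest.approx(0.5, rel=1e-12)
        assert scores["B"].raw_probability == pytest.approx(0.375, rel=1e-12)
        assert scores["C"].raw_probability == pytest.approx(0.125, rel=1e-12)
        assert scores["A"].final_score == pytest.approx(0.5, rel=1e-12)
        assert scores["B"].final_score == pytest.approx(0.1875, rel=1e-12)
        assert scores["C"].final_score == pytest.approx(0.0625, rel=1e-12)
        assert [scores[s].rank for s in "ABC"] == [1, 2, 3]

    def test_uniform_lm_single_token_genes_score_equally(self):
        lm = make_fixed_lm(10)
        lexicon = GeneLexicon(tuple(GeneEntry(f"G{i}", (i,)) for i in range(5)))
        trie = build_trie(lexicon)
        cfg = ScoringConfig(step_scheme="total_sum", final_scheme="none")
        scores = score_genes(lm, trie, (0,), cfg)
        assert all(s.final_score == pytest.approx(0.2) for s in scores)

    def test_zero_probability_token_scores_zero(self):
        lm = make_fixed_lm(4, distributions={(0,): [0.0, 0.5, 0.5, 0.0]})
        lexicon = GeneLexicon((GeneEntry("DEAD", (3,)), GeneEntry("OK", (1,))))
        trie = build_trie(lexicon)
        scores = {s.symbol: s for s in score_genes(lm, trie, (0,), BEST)}
        assert scores["DEAD"].final_score == 0.0
        assert scores["DEAD"].rank == 2

    def test_monotone_shrinkage_under_scheme_none(self, toy_lm):
        """A gene's raw probability never exceeds that of its proper prefixes."""
        cfg = ScoringConfig(step_scheme="none", final_scheme="none")
        trie = build_trie(toy_lm.lexicon)
        prompt = build_prompt(PromptTemplate(), "aging", toy_lm)
        raw = {s.symbol: s.raw_probability
               for s in score_genes(toy_lm, trie, prompt, cfg)}
        seqs = {e.symbol: e.token_ids for e in toy_lm.lexicon}
        prefix_pairs = [
            (a, b) for a in seqs for b in seqs
            if a != b and len(seqs[a]) < len(seqs[b])
            and seqs[b][: len(seqs[a])] == seqs[a]
        ]
        assert prefix_pairs, "toy lexicon should contain prefix genes"
        for short, long in prefix_pairs:
            assert raw[long] <= raw[short] + 1e-15

    def test_prefix_gene_scored_at_completing_step(self):
        # X=[1], Y=[1,2]: node 1 both terminal and continuing
        lm = make_fixed_lm(
            4,
            distributions={(0,): [0.1, 0.4, 0.3, 0.2], (0, 1): [0.1, 0.1, 0.6, 0.2]},
        )
        lexicon = GeneLexicon((GeneEntry("X", (1,)), GeneEntry("Y", (1, 2))))
        trie = build_trie(lexicon)
        cfg = ScoringConfig(step_scheme="none", final_scheme="none")
        scores = {s.symbol: s for s in score_genes(lm, trie, (0,), cfg)}
        assert scores["X"].raw_probability == pytest.approx(0.4)
        assert scores["Y"].raw_probability == pytest.approx(0.4 * 0.6)

    def test_log_domain_survives_tiny_probabilities(self):
        """Token probabilities of 1e-300 at length 7 still order correctly."""
        tiny = 1e-300
        dists = {}
        for i in range(7):
            p = np.zeros(6)
            p[1] = tiny
            p[2] = 2 * tiny
            p[0] = 1.0 - p.sum()
            dists[(5,) + (1,) * i] = p.copy()
            dists[(5,) + (2,) * i] = p.copy()
        lm = make_fixed_lm(6, distributions=dists)
        lexicon = GeneLexicon((
            GeneEntry("LOW", (1,) * 7), GeneEntry("HIGH", (2,) * 7),
        ))
        trie = build_trie(lexicon)
        cfg = ScoringConfig(step_scheme="none", final_scheme="geometric_mean")
        scores = score_genes(lm, trie, (5,), cfg)
        assert [s.symbol for s in scores] == ["HIGH", "LOW"]
        assert all(math.isfinite(s.log_raw) for s in scores)

    def test_max_token_length_equals_prefiltered_lexicon(self, toy_lm):
        from targetrank.lexicon import filter_by_token_length

        trie = build_trie(toy_lm.lexicon)
        prompt = build_prompt(PromptTemplate(), "aging", toy_lm)
        pruned = {
            s.symbol: s.raw_probability
            for s in score_genes(
                toy_lm, trie, prompt,
                ScoringConfig(max_token_length=5),
            )
        }
        filtered = build_trie(filter_by_token_length(toy_lm.lexicon, 5))
        direct = {
            s.symbol: s.raw_probability
            for s in score_genes(toy_lm, filtered, prompt, ScoringConfig())
        }
        assert pruned.keys() == direct.keys()
        for symbol in pruned:
            assert pruned[symbol] == pytest.approx(direct[symbol], rel=1e-12)


class TestBruteForceOracle:
    @pytest.mark.parametrize("step_scheme", ["none", "total_sum", "separate_sum"])
    def test_pipeline_matches_per_gene_walk(self, toy_lm, step_scheme):
        cfg = ScoringConfig(step_scheme=step_scheme, final_scheme="none")
        trie = build_trie(toy_lm.lexicon)
        prompt = build_prompt(PromptTemplate(), "aging", toy_lm)
        scores = {s.symbol: s for s in score_genes(toy_lm, trie, prompt, cfg)}
        for entry in toy_lm.lexicon:
            expected = brute_force_score(toy_lm, entry, trie, prompt, cfg)
            got = scores[entry.symbol].raw_probability
            assert got == pytest.approx(expected, rel=1e-12)

    def test_worked_example_gene_b(self, abc_setup):
        lm, lexicon, trie, prompt = abc_setup
        assert brute_force_score(lm, lexicon["B"], trie, prompt, BEST) == (
            pytest.approx(0.375, rel=1e-12)
        )

    def test_unknown_gene_rejected(self, abc_setup):
        lm, lexicon, trie, prompt = abc_setup
        with pytest.raises(ValueError):
            brute_force_score(lm, GeneEntry("Z", (5, 5)), trie, prompt, BEST)


class TestFinalNormalize:
    @pytest.mark.parametrize(
        "raw,L,scheme,alpha,expected",
        [
            (0.01, 2, "geometric_mean", 1.0, 0.1),
            (0.01, 2, "length_division", 1.0, 0.005),
            (0.01, 2, "length_division", 2.0, 0.0025),
            (0.3, 1, "geometric_mean", 1.0, 0.3),
            (0.3, 1, "length_division", 1.0, 0.3),
            (0.3, 5, "none", 1.0, 0.3),
        ],
    )
    def test_schemes(self, raw, L, scheme, alpha, expected):
        assert final_normalize(raw, L, scheme, alpha) == pytest.approx(expected)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            final_normalize(0.5, 0, "none")


class TestRank:
    def test_truncation_and_order(self, abc_setup):
        lm, lexicon, trie, prompt = abc_setup
        ranked = rank(score_genes(lm, trie, prompt, BEST), top_k=2)
        assert [s.symbol for s in ranked.top(2)] == ["A", "B"]
        assert len(ranked) == 3  # full ranking retained

    def test_ties_break_alphabetically(self):
        lm = make_fixed_lm(10)
        lexicon = GeneLexicon((GeneEntry("ZZ", (2,)), GeneEntry("AA", (1,))))
        trie = build_trie(lexicon)
        scores = score_genes(lm, trie, (0,), ScoringConfig(final_scheme="none"))
        assert [s.symbol for s in scores] == ["AA", "ZZ"]
        assert [s.rank for s in scores] == [1, 2]

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            rank([])
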