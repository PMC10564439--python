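"""Shared fixtures: a fixed-table stub LM and default toy-LM instances."""

from __future__ import annotations

import numpy as np
import pytest

from targetrank.lexicon import GeneEntry, GeneLexicon, build_trie
from targetrank.lm import NextTokenDistribution
from targetrank.synthetic import ToyLMSpec, make_toy_lm


class FixedLM:
    """Stub causal LM with explicit per-context distributions.

    ``distributions`` maps a context tuple to a full-vocabulary probability
    array; unlisted contexts fall back to uniform.  ``word_map`` drives the
    tokenizer (unknown words map to token 0).
    """

    def __init__(self, vocabulary_size, distributions=None, word_map=None,
                 embedding_dim=4):
        self._v = vocabulary_size
        self._dists = {
            tuple(k): np.asarray(v, dtype=float)
            for k, v in (distributions or {}).items()
        }
        self._word_map = dict(word_map or {})
        self._dim = embedding_dim

    @property
    def vocabulary_size(self):
        return self._v

    def tokenize(self, text):
        out = []
        for word in text.split():
            ids = self._word_map.get(word, (0,))
            out.extend(ids if isinstance(ids, tuple) else (ids,))
        return tuple(out)

    def next_token_distribution(self, context):
        key = tuple(int(t) for t in context)
        p = self._dists.get(key)
        if p is None:
            p = np.full(self._v, 1.0 / self._v)
        return NextTokenDistribution(p)

    def token_embeddings(self, tokens):
        rows = []
        for t in tokens:
            rng = np.random.default_rng(int(t) + 12345)
            rows.append(rng.standard_normal(self._dim))
        return np.vstack(rows)


@pytest.fixture
def abc_setup():
    """Three-gene worked example: A=[1], B=[2,3], C=[2,4] behind prompt (0,).

    Raw next-token probabilities: step 1 gives tokens 1 and 2 each 0.2;
    step 2 under prefix [2] gives token 3 -> 0.3 and token 4 -> 0.1.
    """
    lm = FixedLM(
        vocabulary_size=6,
        distributions={
            (0,): [0.3, 0.2, 0.2, 0.1, 0.1, 0.1],
            (0, 2): [0.2, 0.2, 0.1, 0.3, 0.1, 0.1],
        },
    )
    lexicon = GeneLexicon((
        GeneEntry("A", (1,)),
        GeneEntry("B", (2, 3)),
        GeneEntry("C", (2, 4)),
    ))
    return lm, lexicon, build_trie(lexicon), (0,)


@pytest.fixture(scope="session")
def toy_lm():
    """Default 200-gene toy LM with 20 planted aging targets (seed 1)."""
    return make_toy_lm(ToyLMSpec(seed=1))


@pytest.fixture(scope="session")
def toy_lm_no_planted():
    spec = ToyLMSpec(seed=2, planted={})
    return make_toy_lm(spec)


def make_fixed_lm(vocabulary_size, distributions=None, word_map=None):
    return FixedLM(vocabulary_size, distributions, word_map)
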