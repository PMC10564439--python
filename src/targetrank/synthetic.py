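"""Seeded synthetic test bed: toy lexicons, a deterministic toy causal LM
with planted disease-gene associations, and group-structured embeddings.

The toy LM emulates the structural features the pipeline depends on — a
closed vocabulary, gene names spanning 1-7 subword tokens with shared
prefixes, and a handful of "planted" genes whose name continuations receive
a boosted probability after a disease prompt — while remaining a pure
function of its seed, so every downstream result is exactly reproducible.

Planted targets are drawn prefix-isolated: no planted gene is a prefix of
(or extended by) another lexicon gene, and planted first tokens are pairwise
distinct.  A gene lying on another planted gene's boosted path would inherit
the boost, making the planted ground truth ill-defined; isolation keeps each
planted signal independent, which is what the recovery tests require of a
ground truth.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .graph import EmbeddingMatrix
from .lexicon import GeneEntry, GeneLexicon
from .lm import NextTokenDistribution
from .scoring import DEFAULT_TEMPLATE

#: Token-length mix over 1..7 resembling subword tokenization of gene
#: symbols: under 2% of names are single vocabulary tokens, the bulk spans
#: 2-4 tokens, with a thin tail out to 7.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    1: 0.02, 2: 0.33, 3: 0.30, 4: 0.18, 5: 0.10, 6: 0.05, 7: 0.02,
}

_BASE_TAG = 0x0B5E
_EMB_TAG = 0x0E3B
_PLANT_TAG = 0x0A17


def _word_hash(word: str) -> int:
    return int(hashlib.md5(word.encode("utf-8")).hexdigest()[:8], 16)


def make_toy_lexicon(
    n_genes: int,
    length_distribution: Mapping[int, float] | None = None,
    seed: int = 0,
    vocabulary_size: int = 600,
    prefix_share_fraction: float = 0.25,
) -> GeneLexicon:
    """Generate a tokenized lexicon of synthetic symbols G0001, G0002, ...

    Token-sequence lengths are drawn from ``length_distribution`` (over
    1..7); a ``prefix_share_fraction`` of multi-token genes copies a prefix
    from a previously generated gene, so the trie has shared paths, branch
    points, and genes that are proper prefixes of other genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    dist = dict(length_distribution or DEFAULT_LENGTH_DISTRIBUTION)
    lengths_support = sorted(dist)
    probs = np.array([dist[length] for length in lengths_support], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("length distribution must be non-negative and sum to 1")
    if min(lengths_support) < 1 or max(lengths_support) > 7:
        raise ValueError("length distribution support must lie in 1..7")
    rng = np.random.default_rng(seed)
    lengths = rng.choice(lengths_support, size=n_genes, p=probs)
    if int(np.sum(lengths == 1)) > vocabulary_size:
        raise ValueError(
            "infeasible vocabulary: more single-token genes than tokens"
        )
    used: set[tuple[int, ...]] = set()
    seqs: list[tuple[int, ...]] = []
    for length in lengths:
        length = int(length)
        seq: tuple[int, ...] | None = None
        for _ in range(10_000):
            share = (
                length >= 2
                and seqs
                and rng.random() < prefix_share_fraction
            )
            if share:
                # copy a prefix of a previous gene; d == length makes this
                # gene a proper prefix of its partner (duplicates retried)
                partner = seqs[int(rng.integers(0, len(seqs)))]
                d = int(rng.integers(1, min(len(partner), length) + 1))
                tail = tuple(
                    int(t) for t in rng.integers(0, vocabulary_size,
                                                 size=length - d)
                )
                seq = partner[:d] + tail
            if not share:
                seq = tuple(
                    int(t) for t in rng.integers(0, vocabulary_size, size=length)
                )
            if seq not in used:
                break
        else:
            raise RuntimeError("could not generate a unique token sequence")
        used.add(seq)
        seqs.append(seq)
    entries = tuple(
        GeneEntry(symbol=f"G{i + 1:04d}", token_ids=seq)
        for i, seq in enumerate(seqs)
    )
    return GeneLexicon(entries)


def choose_planted(
    lexicon: GeneLexicon, n_planted: int, seed: int = 0
) -> tuple[str, ...]:
    """Sample prefix-isolated planted target symbols from a tokenized lexicon.

    Eligible genes neither prefix nor extend any other gene, and chosen
    genes have pairwise distinct first tokens.
    """
    sequences = [tuple(e.token_ids) for e in lexicon]  # type: ignore[arg-type]
    eligible = []
    for i, entry in enumerate(lexicon):
        seq = sequences[i]
        isolated = True
        for j, other in enumerate(sequences):
            if i == j:
                continue
            d = min(len(seq), len(other))
            if seq[:d] == other[:d]:  # one is a prefix of the other
                isolated = False
                break
        if isolated:
            eligible.append(entry)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _PLANT_TAG]))
    order = rng.permutation(len(eligible))
    chosen: list[str] = []
    first_tokens: set[int] = set()
    for idx in order:
        entry = eligible[int(idx)]
        first = entry.token_ids[0]  # type: ignore[index]
        if first in first_tokens:
            continue
        chosen.append(entry.symbol)
        first_tokens.add(first)
        if len(chosen) == n_planted:
            break
    if len(chosen) < n_planted:
        raise ValueError(
            f"only {len(chosen)} prefix-isolated genes available, "
            f"{n_planted} requested"
        )
    return tuple(sorted(chosen))


@dataclass(frozen=True)
class ToyLMSpec:
    """Full description of a toy LM instance; a pure function of its fields.

    ``planted`` maps a disease label to either an explicit tuple of symbols
    or an integer count (symbols then drawn by :func:`choose_planted`).
    ``boost`` is the factor applied to each planted continuation token after
    the disease prompt; ``noise`` is the half-width of the uniform
    perturbation of the otherwise-flat base next-token weights.
    """

    n_genes: int = 200
    vocabulary_size: int = 600
    length_distribution: Mapping[int, float] | None = None
    prefix_share_fraction: float = 0.25
    planted: Mapping[str, int | Sequence[str]] = field(
        default_factory=lambda: {"aging": 20}
    )
    boost: float = 10.0
    noise: float = 0.05
    embedding_dim: int = 16
    template: str = DEFAULT_TEMPLATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boost <= 1.0:
            raise ValueError("boost factor must exceed 1")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "vocabulary_size": self.vocabulary_size,
            "length_distribution": dict(self.length_distribution)
            if self.length_distribution
            else None,
            "prefix_share_fraction": self.prefix_share_fraction,
            "planted": {
                d: (list(v) if not isinstance(v, int) else v)
                for d, v in self.planted.items()
            },
            "boost": self.boost,
            "noise": self.noise,
            "embedding_dim": self.embedding_dim,
            "template": self.template,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ToyLMSpec":
        data = dict(data)
        if data.get("length_distribution"):
            data["length_distribution"] = {
                int(k): float(v) for k, v in data["length_distribution"].items()
            }
        if "planted" in data:
            data["planted"] = {
                d: (int(v) if isinstance(v, int) else tuple(v))
                for d, v in data["planted"].items()
            }
        return cls(**data)


class ToyLM:
    """Deterministic causal LM over a closed toy vocabulary.

    The base next-token weights for a context are a fixed seeded function of
    the context (a different, arbitrary distribution per context — richer
    than a unigram model); when the context is a disease prompt followed by
    a planted gene's token prefix, the next planted token's weight is
    multiplied by the boost factor before normalization.
    """

    def __init__(self, spec: ToyLMSpec, lexicon: GeneLexicon,
                 planted: Mapping[str, tuple[str, ...]]):
        self.spec = spec
        self.lexicon = lexicon
        self.planted = dict(planted)
        self._symbol_tokens = {
            e.symbol: tuple(e.token_ids) for e in lexicon  # type: ignore[arg-type]
        }
        self._dist_cache: dict[tuple[int, ...], np.ndarray] = {}
        self._emb_cache: dict[int, np.ndarray] = {}
        # contexts at which a planted continuation is boosted
        self._boosted: dict[tuple[int, ...], set[int]] = {}
        for disease, symbols in self.planted.items():
            prompt = self.tokenize(spec.template.replace("{DISEASE}", disease))
            for symbol in symbols:
                tokens = self._symbol_tokens[symbol]
                for j in range(len(tokens)):
                    key = prompt + tokens[:j]
                    self._boosted.setdefault(key, set()).add(tokens[j])

    @property
    def vocabulary_size(self) -> int:
        return self.spec.vocabulary_size

    def tokenize(self, text: str) -> tuple[int, ...]:
        out: list[int] = []
        for word in text.split():
            tokens = self._symbol_tokens.get(word) or self._symbol_tokens.get(
                word.upper()
            )
            if tokens is not None:
                out.extend(tokens)
            else:
                out.append(_word_hash(word) % self.spec.vocabulary_size)
        return tuple(out)

    def next_token_distribution(
        self, context: Sequence[int]
    ) -> NextTokenDistribution:
        key = tuple(int(t) for t in context)
        cached = self._dist_cache.get(key)
        if cached is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.spec.seed, _BASE_TAG, *key])
            )
            noise = self.spec.noise
            weights = 1.0 - noise + 2.0 * noise * rng.random(
                self.spec.vocabulary_size
            )
            for token in self._boosted.get(key, ()):
                weights[token] *= self.spec.boost
            cached = weights / weights.sum()
            cached.setflags(write=False)
            self._dist_cache[key] = cached
        return NextTokenDistribution(cached)

    def token_embeddings(self, tokens: Sequence[int]) -> np.ndarray:
        rows = []
        for token in tokens:
            token = int(token)
            vec = self._emb_cache.get(token)
            if vec is None:
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.spec.seed, _EMB_TAG, token])
                )
                vec = rng.standard_normal(self.spec.embedding_dim)
                vec.setflags(write=False)
                self._emb_cache[token] = vec
            rows.append(vec)
        return np.vstack(rows)


def make_toy_lm(spec: ToyLMSpec) -> ToyLM:
    """Instantiate the toy LM (lexicon generated and planted sets resolved)."""
    lexicon = make_toy_lexicon(
        spec.n_genes,
        spec.length_distribution,
        seed=spec.seed,
        vocabulary_size=spec.vocabulary_size,
        prefix_share_fraction=spec.prefix_share_fraction,
    )
    planted: dict[str, tuple[str, ...]] = {}
    for disease, value in spec.planted.items():
        if isinstance(value, int):
            disease_seed = (spec.seed * 1_000_003 + zlib.crc32(
                disease.encode("utf-8"))) % (2**31)
            planted[disease] = choose_planted(lexicon, value, seed=disease_seed)
        else:
            unknown = set(value) - {e.symbol for e in lexicon}
            if unknown:
                raise ValueError(f"planted symbols not in lexicon: {sorted(unknown)}")
            planted[disease] = tuple(value)
    return ToyLM(spec, lexicon, planted)


def make_toy_embeddings(
    n_nodes: int,
    group_assignments: Sequence[int] | None = None,
    within_group_spread: float = 0.25,
    between_group_separation: float = 4.0,
    dimension: int = 8,
    seed: int = 0,
    symbols: Sequence[str] | None = None,
) -> EmbeddingMatrix:
    """Group-structured embeddings: members scatter around well-separated centers.

    Group centers sit on scaled orthogonal axes, so centers are at mutual
    Euclidean distance ``between_group_separation * sqrt(2)``; members are
    drawn isotropically around their center with the given spread.
    """
    if within_group_spread <= 0 or between_group_separation <= 0:
        raise ValueError("spread and separation must be positive")
    groups = list(group_assignments) if group_assignments is not None else [0] * n_nodes
    if len(groups) != n_nodes:
        raise ValueError("group_assignments length must equal n_nodes")
    unique = sorted(set(groups))
    if dimension < len(unique):
        raise ValueError("dimension must be at least the number of groups")
    rng = np.random.default_rng(seed)
    centers = {
        g: between_group_separation * np.eye(dimension)[i]
        for i, g in enumerate(unique)
    }
    vectors = np.vstack([
        centers[g] + within_group_spread * rng.standard_normal(dimension)
        for g in groups
    ])
    if symbols is None:
        symbols = tuple(f"N{i + 1:04d}" for i in range(n_nodes))
    return EmbeddingMatrix(tuple(symbols), vectors)


def make_toy_gene_lists(
    n_lists: int = 15,
    list_size: int = 200,
    n_core: int = 9,
    n_fill_symbols: int | None = None,
    partial_counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[dict[str, set], frozenset]:
    """Generate per-disease gene lists with a planted all-lists core.

    Every list contains the ``n_core`` core symbols (CORE01, ...); symbols in
    ``partial_counts`` are placed in exactly that many lists; the rest of
    each list is seeded random filler, repaired so that no filler symbol
    appears in every list.  Returns (lists, core symbols).
    """
    if n_lists < 2:
        raise ValueError("need at least two lists")
    if n_core > list_size:
        raise ValueError("core larger than list size")
    partial_counts = dict(partial_counts or {})
    for symbol, count in partial_counts.items():
        if not 0 < count < n_lists:
            raise ValueError(
                f"partial count for {symbol} must be in 1..{n_lists - 1}"
            )
    rng = np.random.default_rng(seed)
    core = [f"CORE{i + 1:02d}" for i in range(n_core)]
    if n_fill_symbols is None:
        n_fill_symbols = 4 * list_size
    fill_pool = np.array([f"F{i + 1:04d}" for i in range(n_fill_symbols)])
    labels = [f"list{i + 1:02d}" for i in range(n_lists)]
    lists: dict[str, set] = {label: set(core) for label in labels}
    for symbol, count in partial_counts.items():
        for idx in rng.choice(n_lists, size=count, replace=False):
            lists[labels[int(idx)]].add(symbol)
    for label in labels:
        needed = list_size - len(lists[label])
        if needed < 0:
            raise ValueError("partial symbols overfill a list")
        draw = rng.choice(fill_pool, size=needed, replace=False)
        lists[label].update(str(s) for s in draw)
    # repair: no filler may appear in every list
    counts: dict[str, int] = {}
    for members in lists.values():
        for s in members:
            if s.startswith("F"):
                counts[s] = counts.get(s, 0) + 1
    used = set(counts)
    spare = [s for s in fill_pool if s not in used]
    for symbol, count in sorted(counts.items()):
        if count == n_lists:
            lists[labels[-1]].discard(symbol)
            if spare:
                lists[labels[-1]].add(spare.pop())
    return lists, frozenset(core)
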