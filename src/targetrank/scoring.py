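"""Constrained next-token scoring over the gene-name token trie.

A gene's relevance to a disease is the probability that its name continues a
disease prompt.  Because most gene names span several subword tokens, the
score is built iteratively: at each trie prefix the model is queried for the
next-token distribution, the distribution is restricted (and optionally
renormalized) to the tokens that continue some gene name, and per-token
probabilities are multiplied along the path.  A final length normalization
corrects the systematic penalty that multiplication imposes on longer names.

Step schemes
    ``none``          raw probabilities restricted to the allowed set
    ``total_sum``     divide by the summed probability of all allowed tokens
    ``separate_sum``  name-completing and name-continuing tokens are each
                      renormalized to 1 within their own class

Final schemes
    ``none``             the raw product
    ``geometric_mean``   product ** (1/L)
    ``length_division``  product / L**alpha

The configuration that performs best in practice is ``total_sum`` steps with
``length_division`` (alpha = 1) and no token-length filter.

All accumulation is in the log domain; ranking compares log scores, so
per-token probabilities down to 1e-300 at name lengths up to 7 never
underflow the ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import ConfigurationError
from .lexicon import TokenTrie, TrieNode
from .lm import CausalLM, NextTokenDistribution

#: The default disease prompt. Ending in an article raises the probability
#: that the next word is a gene symbol.
DEFAULT_TEMPLATE = "human gene targeted by a drug for treating {DISEASE} is the"

STEP_SCHEMES = ("none", "total_sum", "separate_sum")
FINAL_SCHEMES = ("none", "geometric_mean", "length_division")

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class PromptTemplate:
    """A prompt with a single ``{DISEASE}`` placeholder."""

    template: str = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        if self.template.count("{DISEASE}") != 1:
            raise ConfigurationError(
                "prompt template must contain the {DISEASE} placeholder exactly once"
            )

    def fill(self, disease: str) -> str:
        if not disease:
            raise ValueError("disease name must be non-empty")
        return self.template.replace("{DISEASE}", disease).rstrip()


@dataclass(frozen=True)
class ScoringConfig:
    """Normalization scheme choices for a scoring run."""

    step_scheme: str = "total_sum"
    final_scheme: str = "length_division"
    alpha: float = 1.0
    max_token_length: int | None = None
    top_k: int = 200

    def __post_init__(self) -> None:
        if self.step_scheme not in STEP_SCHEMES:
            raise ConfigurationError(f"unknown step scheme {self.step_scheme!r}")
        if self.final_scheme not in FINAL_SCHEMES:
            raise ConfigurationError(f"unknown final scheme {self.final_scheme!r}")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.max_token_length is not None and self.max_token_length < 1:
            raise ConfigurationError("max_token_length must be >= 1")


@dataclass
class GeneScore:
    """Per-gene result of a scoring run.

    ``raw_probability`` is the product of (step-normalized) token
    probabilities; ``final_score`` the length-normalized value.  The log
    fields are the authoritative quantities for ordering.
    """

    symbol: str
    raw_probability: float
    final_score: float
    log_raw: float
    log_final: float
    token_length: int | None = None
    rank: int | None = None


@dataclass(frozen=True)
class RankedList:
    """An ordered per-disease gene ranking with the config that produced it."""

    label: str
    scores: tuple[GeneScore, ...]
    config: ScoringConfig | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def top(self, k: int) -> tuple[GeneScore, ...]:
        return self.scores[:k]

    def symbols(self) -> list[str]:
        return [s.symbol for s in self.scores]

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class StepProbabilities:
    """Step-normalized probabilities for one trie expansion step.

    A token can belong to both classes (one gene ends where another
    continues); under ``separate_sum`` its two normalized values differ, so
    the classes are kept separate.
    """

    completing: Mapping[int, float]
    continuing: Mapping[int, float]

    def merged(self) -> dict[int, float]:
        """Single mapping over the allowed set; requires consistent values."""
        out = dict(self.continuing)
        for tid, p in self.completing.items():
            if tid in out and out[tid] != p:
                raise ValueError(
                    f"token {tid} has distinct completing/continuing values"
                )
            out[tid] = p
        return out


def build_prompt(
    template: PromptTemplate, disease: str, lm: CausalLM
) -> tuple[int, ...]:
    """Tokenize the filled disease prompt."""
    return tuple(lm.tokenize(template.fill(disease)))


def step_normalize(
    dist: NextTokenDistribution,
    completing: Iterable[int],
    continuing: Iterable[int],
    scheme: str,
) -> StepProbabilities:
    """Restrict (and renormalize) a next-token distribution to the allowed set."""
    if scheme not in STEP_SCHEMES:
        raise ConfigurationError(f"unknown step scheme {scheme!r}")
    completing = set(completing)
    continuing = set(continuing)
    if not completing and not continuing:
        raise ValueError("allowed token set is empty")
    comp_raw = {t: dist.prob(t) for t in completing}
    cont_raw = {t: dist.prob(t) for t in continuing}
    if scheme == "none":
        return StepProbabilities(comp_raw, cont_raw)
    if scheme == "total_sum":
        allowed = completing | continuing
        total = sum(dist.prob(t) for t in allowed)
        if total <= 0.0:
            scale = 0.0
        else:
            scale = 1.0 / total
        return StepProbabilities(
            {t: p * scale for t, p in comp_raw.items()},
            {t: p * scale for t, p in cont_raw.items()},
        )
    # separate_sum: each non-empty class renormalized to 1 independently
    def _norm(raw: dict[int, float]) -> dict[int, float]:
        total = sum(raw.values())
        if total <= 0.0:
            return {t: 0.0 for t in raw}
        return {t: p / total for t, p in raw.items()}

    return StepProbabilities(_norm(comp_raw), _norm(cont_raw))


def final_normalize(raw: float, length: int, scheme: str, alpha: float = 1.0) -> float:
    """Length-normalize a gene's raw token-probability product."""
    if length < 1:
        raise ValueError(f"token length must be >= 1, got {length}")
    if scheme == "none":
        return raw
    if scheme == "geometric_mean":
        return raw ** (1.0 / length)
    if scheme == "length_division":
        return raw / length**alpha
    raise ConfigurationError(f"unknown final scheme {scheme!r}")


def _log_final(log_raw: float, length: int, scheme: str, alpha: float) -> float:
    if scheme == "none":
        return log_raw
    if scheme == "geometric_mean":
        return log_raw / length
    if scheme == "length_division":
        return log_raw - alpha * math.log(length)
    raise ConfigurationError(f"unknown final scheme {scheme!r}")


def _log(p: float) -> float:
    return math.log(p) if p > 0.0 else _NEG_INF


def _classify_children(
    node: TrieNode, limit: int
) -> tuple[list[TrieNode], set[int], set[int]]:
    """Allowed children of a prefix node under a token-length limit.

    A child is *completing* if it is a terminal within the limit, and
    *continuing* if its subtree holds a deeper terminal within the limit (a
    terminal child with such descendants is both).  Pruning by
    ``min_terminal_depth`` is exactly equivalent to scoring a lexicon
    pre-filtered to names of at most ``limit`` tokens.
    """
    allowed: list[TrieNode] = []
    completing: set[int] = set()
    continuing: set[int] = set()
    for tid, child in node.children.items():
        if child.min_terminal_depth > limit:
            continue
        is_completing = child.terminal and child.depth <= limit
        has_deeper = any(
            gc.min_terminal_depth <= limit for gc in child.children.values()
        )
        if not is_completing and not has_deeper:
            continue
        allowed.append(child)
        if is_completing:
            completing.add(tid)
        if has_deeper:
            continuing.add(tid)
    return allowed, completing, continuing


def score_genes(
    lm: CausalLM,
    trie: TokenTrie,
    prompt: Sequence[int],
    config: ScoringConfig,
) -> list[GeneScore]:
    """Score every lexicon gene by breadth-first trie expansion.

    At each frontier prefix the model is queried once; the allowed set is the
    trie children of the prefix, step-normalized per the config; log
    probabilities are accumulated along the path and recorded at terminals.
    Genes containing a zero-probability token score 0.  Returns the full
    scored list, final-normalized and ranked.
    """
    if trie.n_terminals == 0:
        raise ValueError("trie is empty")
    prompt = tuple(prompt)
    if not prompt:
        raise ValueError("prompt is empty")
    limit = config.max_token_length if config.max_token_length is not None else 10**9

    results: list[GeneScore] = []
    # frontier of (node, prefix tokens, accumulated log prob)
    frontier: list[tuple[TrieNode, tuple[int, ...], float]] = [(trie.root, (), 0.0)]
    while frontier:
        next_frontier: list[tuple[TrieNode, tuple[int, ...], float]] = []
        for node, prefix, logp in frontier:
            allowed, completing, continuing = _classify_children(node, limit)
            if not allowed:
                continue
            dist = lm.next_token_distribution(prompt + prefix)
            step = step_normalize(dist, completing, continuing, config.step_scheme)
            for child in allowed:
                tid = child.token_id
                if tid in completing:
                    log_raw = logp + _log(step.completing[tid])
                    length = child.depth
                    results.append(
                        GeneScore(
                            symbol=child.symbol,  # type: ignore[arg-type]
                            raw_probability=math.exp(log_raw)
                            if log_raw > _NEG_INF
                            else 0.0,
                            final_score=0.0,
                            log_raw=log_raw,
                            log_final=_log_final(
                                log_raw, length, config.final_scheme, config.alpha
                            ),
                            token_length=length,
                        )
                    )
                if tid in continuing:
                    next_frontier.append(
                        (child, prefix + (tid,), logp + _log(step.continuing[tid]))
                    )
        frontier = next_frontier

    for score in results:
        score.final_score = final_normalize(
            score.raw_probability,
            score.token_length,  # type: ignore[arg-type]
            config.final_scheme,
            config.alpha,
        )
    _sort_and_rank(results)
    return results


def brute_force_score(
    lm: CausalLM,
    entry,
    trie: TokenTrie,
    prompt: Sequence[int],
    config: ScoringConfig,
) -> float:
    """Independent per-gene recomputation of the raw probability.

    Walks the single gene's token sequence, re-deriving the allowed set from
    the trie at each prefix and applying the same step normalization, and
    returns the plain product — defined so :func:`score_genes` must agree.
    """
    token_ids = tuple(entry.token_ids)
    limit = config.max_token_length if config.max_token_length is not None else 10**9
    if len(token_ids) > limit:
        raise ValueError(
            f"{entry.symbol} exceeds the configured token-length limit"
        )
    prompt = tuple(prompt)
    product = 1.0
    for i, tid in enumerate(token_ids):
        node = trie.node_at(token_ids[:i])
        if node is None or tid not in node.children:
            raise ValueError(f"{entry.symbol} is not present in the trie")
        _, completing, continuing = _classify_children(node, limit)
        dist = lm.next_token_distribution(prompt + token_ids[:i])
        step = step_normalize(dist, completing, continuing, config.step_scheme)
        last = i == len(token_ids) - 1
        product *= step.completing[tid] if last else step.continuing[tid]
    return product


def _sort_and_rank(scores: list[GeneScore]) -> None:
    """Descending by log final score, ties broken by ascending symbol."""
    scores.sort(key=lambda s: (-s.log_final, s.symbol))
    for i, score in enumerate(scores, start=1):
        score.rank = i


def rank(
    scores: Sequence[GeneScore],
    top_k: int | None = None,
    label: str = "",
    config: ScoringConfig | None = None,
) -> RankedList:
    """Order scores into a ranked list (full ranking retained; ``top`` truncates)."""
    if not scores:
        raise ValueError("cannot rank an empty score list")
    ordered = [
        GeneScore(**{f: getattr(s, f) for f in (
            "symbol", "raw_probability", "final_score", "log_raw", "log_final",
            "token_length", "rank")})
        for s in scores
    ]
    _sort_and_rank(ordered)
    meta = {} if top_k is None else {"top_k": top_k}
    return RankedList(label=label, scores=tuple(ordered), config=config, metadata=meta)


def run_scoring(
    lm: CausalLM,
    lexicon,
    disease: str,
    config: ScoringConfig | None = None,
    template: PromptTemplate | None = None,
) -> RankedList:
    """End-to-end convenience: prompt, trie, score, rank for one disease."""
    from .lexicon import build_trie

    config = config or ScoringConfig()
    template = template or PromptTemplate()
    trie = build_trie(lexicon)
    prompt = build_prompt(template, disease, lm)
    scores = score_genes(lm, trie, prompt, config)
    return RankedList(label=disease, scores=tuple(scores), config=config)


def write_ranking_tsv(ranked: RankedList, path, top_k: int | None = None) -> None:
    """Write a ranking table: rank, symbol, raw_probability, final_score, token_length."""
    rows = ranked.scores if top_k is None else ranked.scores[:top_k]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tsymbol\traw_probability\tfinal_score\ttoken_length\n")
        for s in rows:
            fh.write(
                f"{s.rank}\t{s.symbol}\t{s.raw_probability:.10e}\t"
                f"{s.final_score:.10e}\t{s.token_length}\n"
            )


def read_ranking_tsv(path, label: str = "") -> RankedList:
    """Read a ranking table written by :func:`write_ranking_tsv`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    scores = []
    for row in frame.itertuples(index=False):
        final = float(row.final_score)
        raw = float(row.raw_probability)
        scores.append(
            GeneScore(
                symbol=str(row.symbol),
                raw_probability=raw,
                final_score=final,
                log_raw=_log(raw),
                log_final=_log(final),
                token_length=int(row.token_length)
                if not math.isnan(float(row.token_length))
                else None,
                rank=int(row.rank),
            )
        )
    return RankedList(label=label, scores=tuple(scores))
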