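"""Gene lexicon loading, tokenization, and the token trie.

The lexicon is the closed set of entities the pipeline can score — in
production an HGNC-style export of protein-coding gene symbols.  Each symbol
is tokenized by the language model (as a continuation, i.e. preceded by a
single space) and the resulting token-id sequences are indexed in a prefix
tree.  The children of a trie node define the "allowed set" of next tokens
during constrained scoring.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd

from .exceptions import ConfigurationError, EmptyLexiconError, UntokenizedLexiconError
from .lm import CausalLM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneEntry:
    """A single gene symbol, optionally with its model tokenization."""

    symbol: str
    token_ids: tuple[int, ...] | None = None

    @property
    def token_length(self) -> int:
        """Number of tokens L encoding the symbol (0 before tokenization)."""
        return 0 if self.token_ids is None else len(self.token_ids)

    @property
    def tokenized(self) -> bool:
        return self.token_ids is not None


@dataclass(frozen=True)
class GeneLexicon:
    """An ordered collection of unique gene symbols; the scoring universe."""

    entries: tuple[GeneEntry, ...]

    @property
    def universe_size(self) -> int:
        """Total number of genes N in the universe."""
        return len(self.entries)

    @property
    def tokenized(self) -> bool:
        return all(e.tokenized for e in self.entries)

    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GeneEntry]:
        return iter(self.entries)

    def __getitem__(self, symbol: str) -> GeneEntry:
        for e in self.entries:
            if e.symbol == symbol:
                return e
        raise KeyError(symbol)


class TrieNode:
    """One node of the token trie.

    ``token_id`` is the id on the incoming edge (None at the root).  A node
    may be both terminal (``symbol`` set) and have children — one gene name
    can be a prefix of another.  ``min_terminal_depth`` is the depth of the
    shallowest terminal in the subtree rooted here, used to prune the walk
    when a token-length filter is active.
    """

    __slots__ = ("token_id", "children", "symbol", "depth", "min_terminal_depth")

    def __init__(self, token_id: int | None, depth: int) -> None:
        self.token_id = token_id
        self.children: dict[int, TrieNode] = {}
        self.symbol: str | None = None
        self.depth = depth
        self.min_terminal_depth: int = 10**9

    @property
    def terminal(self) -> bool:
        return self.symbol is not None


class TokenTrie:
    """Prefix tree over the tokenized lexicon."""

    def __init__(self) -> None:
        self.root = TrieNode(None, 0)
        self.n_terminals = 0

    def insert(self, token_ids: Iterable[int], symbol: str) -> None:
        node = self.root
        for tid in token_ids:
            if tid not in node.children:
                node.children[tid] = TrieNode(tid, node.depth + 1)
            node = node.children[tid]
        if node.symbol is not None:
            raise ValueError(
                f"duplicate token sequence for {symbol!r} and {node.symbol!r}"
            )
        node.symbol = symbol
        self.n_terminals += 1
        # propagate shallowest-terminal depth back to the root
        depth = node.depth
        walk = self.root
        if depth < walk.min_terminal_depth:
            walk.min_terminal_depth = depth
        for tid in token_ids:
            walk = walk.children[tid]
            if depth < walk.min_terminal_depth:
                walk.min_terminal_depth = depth

    def node_at(self, prefix: Iterable[int]) -> TrieNode | None:
        node = self.root
        for tid in prefix:
            node = node.children.get(tid)
            if node is None:
                return None
        return node

    def iter_terminals(self) -> Iterator[tuple[str, tuple[int, ...]]]:
        """Yield (symbol, token_ids) for every terminal, depth-first."""
        stack: list[tuple[TrieNode, tuple[int, ...]]] = [(self.root, ())]
        while stack:
            node, path = stack.pop()
            if node.terminal:
                yield node.symbol, path  # type: ignore[misc]
            for tid, child in node.children.items():
                stack.append((child, path + (tid,)))

    def node_count(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            stack.extend(node.children.values())
        return count


def load_gene_list(
    source: str | Path | IO[str],
    symbol_column: str = "symbol",
) -> GeneLexicon:
    """Read a tab-separated gene table into a lexicon.

    Symbols are whitespace-trimmed and uppercased (HGNC symbols are
    canonically uppercase); duplicates collapse to the first occurrence with
    a logged warning.  File order is preserved.
    """
    try:
        frame = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyLexiconError("gene list source is empty") from None
    if symbol_column not in frame.columns:
        raise ConfigurationError(
            f"gene list lacks required column {symbol_column!r}; "
            f"found {list(frame.columns)}"
        )
    seen: set[str] = set()
    entries: list[GeneEntry] = []
    for value in frame[symbol_column]:
        if pd.isna(value):
            continue
        symbol = str(value).strip().upper()
        if not symbol:
            continue
        if symbol in seen:
            logger.warning("duplicate gene symbol %s: keeping first occurrence", symbol)
            continue
        seen.add(symbol)
        entries.append(GeneEntry(symbol))
    if not entries:
        raise EmptyLexiconError("gene list contains no usable symbols")
    return GeneLexicon(tuple(entries))


def tokenize_lexicon(
    lexicon: GeneLexicon, lm: CausalLM, leading_space: bool = True
) -> GeneLexicon:
    """Populate token ids for every entry using the model's tokenizer.

    The symbol is tokenized preceded by a single space by default — the
    continuation form expected after a prompt ending in an article.  Symbols
    tokenizing to zero tokens are dropped with a warning.
    """
    entries: list[GeneEntry] = []
    for entry in lexicon:
        text = (" " + entry.symbol) if leading_space else entry.symbol
        token_ids = tuple(lm.tokenize(text))
        if len(token_ids) == 0:
            logger.warning("symbol %s tokenizes to zero tokens: dropped", entry.symbol)
            continue
        entries.append(replace(entry, token_ids=token_ids))
    return GeneLexicon(tuple(entries))


def build_trie(lexicon: GeneLexicon) -> TokenTrie:
    """Index a tokenized lexicon in a prefix tree (one terminal per entry)."""
    if not lexicon.tokenized:
        raise UntokenizedLexiconError(
            "lexicon must be tokenized before building the trie"
        )
    trie = TokenTrie()
    for entry in lexicon:
        trie.insert(entry.token_ids, entry.symbol)  # type: ignore[arg-type]
    return trie


def filter_by_token_length(lexicon: GeneLexicon, max_length: int) -> GeneLexicon:
    """Restrict the lexicon to genes whose names use at most ``max_length`` tokens."""
    if max_length < 1:
        raise ValueError(f"max_length must be >= 1, got {max_length}")
    if not lexicon.tokenized:
        raise UntokenizedLexiconError("lexicon must be tokenized before filtering")
    kept = tuple(e for e in lexicon if e.token_length <= max_length)
    return GeneLexicon(kept)


def load_reference_set(source: str | Path | IO[str]) -> set[str]:
    """Read a reference target set: plain text, one symbol per line."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    return {
        line.strip().upper()
        for line in io.StringIO(text)
        if line.strip()
    }
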