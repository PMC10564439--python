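"""Protein-embedding similarity graph and shortest-path permutation test.

Each gene is represented by the mean-pooled token embeddings of a short
prompt followed by its symbol.  Pairwise cosine similarities define an
undirected graph after thresholding (a fixed cutoff, or the upper quartile
of the observed similarity distribution); each retained edge carries the
distance 1 - s, so that Dijkstra shortest paths measure how far apart two
proteins sit in the model's latent space.

The permutation test asks whether a query gene set lies closer (in mean
shortest-path length) to a set of anchor genes than randomly drawn node
sets of the same size do.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .exceptions import DegenerateResultError
from .lm import CausalLM

logger = logging.getLogger(__name__)

#: Default prompt prefix for protein representation retrieval.
EMBEDDING_PROMPT = "The human age-associated gene is the"

#: Default fixed cosine-similarity cutoff for edge retention.
DEFAULT_THRESHOLD = 0.507


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-gene embedding vectors (one fixed-dimension row per symbol)."""

    symbols: tuple[str, ...]
    vectors: np.ndarray  # shape (n, dim)

    def __post_init__(self) -> None:
        if len(self.symbols) != self.vectors.shape[0]:
            raise ValueError("symbol count and vector count differ")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate symbols in embedding matrix")

    @property
    def dimension(self) -> int:
        return int(self.vectors.shape[1])


@dataclass
class EmbeddingGraph:
    """Thresholded cosine-similarity graph over gene symbols."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class PathTestResult:
    """Observed vs permutation-null mean shortest-path statistic."""

    observed: float
    null: np.ndarray
    p_value: float
    observed_unreachable: int
    null_unreachable: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_iter(self) -> int:
        return int(self.null.shape[0])


def embed_genes(
    lm: CausalLM,
    genes: Sequence[str],
    prompt: str = EMBEDDING_PROMPT,
) -> EmbeddingMatrix:
    """Mean-pooled embedding of "<prompt> <symbol>" for each gene."""
    if not genes:
        raise ValueError("gene list is empty")
    rows = []
    for symbol in genes:
        tokens = lm.tokenize(f"{prompt} {symbol}")
        emb = np.asarray(lm.token_embeddings(tokens), dtype=float)
        rows.append(emb.mean(axis=0))
    return EmbeddingMatrix(tuple(genes), np.vstack(rows))


def cosine_matrix(emb: EmbeddingMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise cosine similarities (unit diagonal)."""
    if emb.vectors.shape[0] < 2:
        raise ValueError("need at least two vectors")
    norms = np.linalg.norm(emb.vectors, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"zero embedding vector for symbol {emb.symbols[zero[0]]!r}")
    unit = emb.vectors / norms[:, None]
    sim = unit @ unit.T
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def resolve_threshold(sim: np.ndarray, threshold: float | str) -> float:
    """A numeric cutoff, or "upper_quartile": the 75th percentile of the
    off-diagonal upper-triangle similarities (linear interpolation)."""
    if isinstance(threshold, str):
        if threshold != "upper_quartile":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        iu = np.triu_indices(sim.shape[0], k=1)
        return float(np.percentile(sim[iu], 75))
    return float(threshold)


def build_graph(
    sim: np.ndarray,
    symbols: Sequence[str] | None = None,
    threshold: float | str = DEFAULT_THRESHOLD,
) -> EmbeddingGraph:
    """Keep edges with similarity >= threshold; edge distance is 1 - s."""
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    n = sim.shape[0]
    if symbols is None:
        symbols = [f"N{i:04d}" for i in range(n)]
    cutoff = resolve_threshold(sim, threshold)
    g = nx.Graph()
    g.add_nodes_from(symbols)
    for i in range(n):
        for j in range(i + 1, n):
            s = float(sim[i, j])
            if s >= cutoff:
                g.add_edge(symbols[i], symbols[j], similarity=s, distance=1.0 - s)
    if g.number_of_edges() == 0:
        logger.warning("no similarity pair reached the threshold %.4f", cutoff)
    return EmbeddingGraph(graph=g, threshold=cutoff)


def shortest_paths(
    graph: EmbeddingGraph,
    sources: Iterable[str],
    targets: Iterable[str],
    weighted: bool = True,
) -> dict[tuple[str, str], float]:
    """Dijkstra shortest-path length for every (source, target) pair.

    Unreachable pairs map to ``inf``.  ``weighted=False`` uses hop counts on
    the thresholded graph instead of 1 - s edge distances.
    """
    sources = list(sources)
    targets = list(targets)
    for s in sources + targets:
        if s not in graph.graph:
            raise ValueError(f"unknown symbol {s!r}")
    weight = "distance" if weighted else None
    out: dict[tuple[str, str], float] = {}
    for src in sources:
        if weight:
            lengths = nx.single_source_dijkstra_path_length(
                graph.graph, src, weight=weight
            )
        else:
            lengths = nx.single_source_shortest_path_length(graph.graph, src)
        for tgt in targets:
            out[(src, tgt)] = float(lengths.get(tgt, math.inf))
    return out


def _mean_finite(values: Iterable[float]) -> tuple[float, int]:
    finite = []
    unreachable = 0
    for v in values:
        if math.isfinite(v):
            finite.append(v)
        else:
            unreachable += 1
    if not finite:
        return math.inf, unreachable
    return float(np.mean(finite)), unreachable


def permutation_path_test(
    graph: EmbeddingGraph,
    query: Iterable[str],
    anchors: Iterable[str],
    candidate_pool: Iterable[str],
    n_iter: int = 1000,
    seed: int | None = None,
    exclude_query_from_pool: bool = True,
    weighted: bool = True,
) -> PathTestResult:
    """Is the query set closer to the anchors than random same-size node sets?

    The statistic is the mean finite query-to-anchor shortest-path length.
    Each of ``n_iter`` null iterations draws ``|query|`` nodes uniformly
    without replacement from the candidate pool (anchors always excluded,
    the query itself excluded by default).  Null iterations with no finite
    path score ``inf`` (never closer than the observed set).  The p-value
    uses the add-one rule p = (1 + #{null <= observed}) / (1 + n_iter).
    """
    query = sorted(set(query))
    anchors = sorted(set(anchors))
    if not query or not anchors:
        raise ValueError("query and anchor sets must be non-empty")
    if set(query) & set(anchors):
        raise ValueError("query and anchor sets must be disjoint")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    pool = set(candidate_pool) - set(anchors)
    if exclude_query_from_pool:
        pool -= set(query)
    pool = sorted(pool)
    if len(pool) < len(query):
        raise ValueError(
            f"candidate pool ({len(pool)}) smaller than query set ({len(query)})"
        )
    for s in query + anchors + pool:
        if s not in graph.graph:
            raise ValueError(f"unknown symbol {s!r}")

    # one Dijkstra per anchor; every statistic then reads the cached lengths
    weight = "distance" if weighted else None
    anchor_lengths: dict[str, dict[str, float]] = {}
    for a in anchors:
        if weight:
            anchor_lengths[a] = nx.single_source_dijkstra_path_length(
                graph.graph, a, weight=weight
            )
        else:
            anchor_lengths[a] = dict(
                nx.single_source_shortest_path_length(graph.graph, a)
            )

    def statistic(nodes: Sequence[str]) -> tuple[float, int]:
        return _mean_finite(
            anchor_lengths[a].get(n, math.inf) for a in anchors for n in nodes
        )

    observed, observed_unreachable = statistic(query)
    if not math.isfinite(observed):
        raise DegenerateResultError(
            "no finite shortest path between query and anchor sets"
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    null_unreachable = np.empty(n_iter, dtype=int)
    pool_arr = np.asarray(pool, dtype=object)
    for i in range(n_iter):
        draw = rng.choice(pool_arr, size=len(query), replace=False)
        null[i], null_unreachable[i] = statistic(list(draw))
    p = (1 + int(np.sum(null <= observed))) / (1 + n_iter)
    return PathTestResult(
        observed=observed,
        null=null,
        p_value=p,
        observed_unreachable=observed_unreachable,
        null_unreachable=null_unreachable,
    )


def write_embeddings_tsv(emb: EmbeddingMatrix, path) -> None:
    """First column symbol, remaining columns vector components."""
    with open(path, "w", encoding="utf-8") as fh:
        dim = emb.dimension
        fh.write("symbol\t" + "\t".join(f"e{i}" for i in range(dim)) + "\n")
        for sym, vec in zip(emb.symbols, emb.vectors):
            fh.write(sym + "\t" + "\t".join(f"{v:.10g}" for v in vec) + "\n")


def read_embeddings_tsv(path) -> EmbeddingMatrix:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    symbols = tuple(str(s) for s in frame.iloc[:, 0])
    vectors = frame.iloc[:, 1:].to_numpy(dtype=float)
    return EmbeddingMatrix(symbols, vectors)


def write_edge_list(graph: EmbeddingGraph, path) -> None:
    """Edge list: symbol_a, symbol_b, similarity, distance."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("symbol_a\tsymbol_b\tsimilarity\tdistance\n")
        for a, b, data in sorted(graph.graph.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{data['similarity']:.10g}\t{data['distance']:.10g}\n"
            )
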