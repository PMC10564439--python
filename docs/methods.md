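# Methods

## Constrained next-token scoring

The scoring engine treats a causal language model as a conditional
probability oracle. A disease prompt (default: `human gene targeted by a
drug for treating {DISEASE} is the`; prompts ending in an article favour a
gene symbol as the next word) is tokenized once, and the tokenized gene
lexicon is laid out as a prefix trie. Expansion is breadth-first: each trie
prefix triggers exactly one model query, so the number of queries equals the
number of internal trie nodes, not the number of genes times name length.
Gene symbols are tokenized with a single leading space — the continuation
form after a prompt — and this is configurable.

At each step the full-vocabulary distribution is restricted to the trie
children of the current prefix. Children are classified as *completing*
(terminal at this depth) and/or *continuing* (subtree holds a deeper
terminal); a terminal child with descendants belongs to both classes, which
happens when one gene name is a prefix of another. The step schemes are:

- `none` — raw restricted probabilities;
- `total_sum` — all allowed tokens renormalized jointly to mass 1;
- `separate_sum` — the completing and continuing classes renormalized to 1
  independently. A token in both classes then carries two distinct values:
  its completing value is used when recording the shorter gene, its
  continuing value when extending toward longer ones. This is one admissible
  reading of per-class normalization; the joint `total_sum` variant is the
  recommended default in any case.

If the allowed set has zero probability mass, all step outputs are 0 and
affected genes score 0 (they sort to the bottom deterministically).

Final normalization corrects the length penalty of multiplying $L$
sub-unity probabilities: `geometric_mean` ($P^{1/L}$) or `length_division`
($P/L^\alpha$). The exponent family on $L$ is the simplest one-parameter
correction; $\alpha = 1$ is the default. An optional `max_token_length`
filter (names longer than ~5 tokens are rarely real drug targets, since
common symbols get dedicated subwords) is implemented by pruning the trie
walk to nodes whose subtree contains a terminal within the limit — provably
identical to filtering the lexicon and rebuilding the trie, so one trie
serves every configuration.

All accumulation is in the log domain. `GeneScore` exposes both probability
scale (`raw_probability`, `final_score`) and log scale (`log_raw`,
`log_final`); ordering always compares `log_final`, so per-token
probabilities down to 1e-300 at length 7 (log scores near −4800) never
underflow the ranking even when the probability-scale field prints as 0.
Ties break lexicographically on the symbol, making output deterministic.

`brute_force_score` recomputes a single gene's probability by walking its
token sequence and re-deriving the allowed set at each prefix. It shares
only the trie and the step-normalization definition with the pipeline, not
the breadth-first accumulator, and is the per-gene oracle in the test suite
(agreement demanded to 1e-12 relative, observed ~1e-15 — the residue of
`exp(Σ log p)` versus `Π p`).

## Validation statistics

For a ranking of a universe of $N$ genes containing $t_N$ known targets, of
which $t_k$ appear in the top $k$:

$$\mathrm{ELFC} = \log_2 \frac{t_k / k}{t_N / N}, \qquad
  \mathrm{HGPV} = -\log_{10} P(X \ge t_k),$$

with $X \sim \mathrm{Hypergeom}(N, t_N, k)$. When $t_k = 0$, ELFC
substitutes 0.1 for the count so the statistic stays finite. HGPV uses the
survival function ("$t_k$ or more"); a strict-inequality variant
($1 - \mathrm{CDF}(t_k)$) is available behind a flag for comparison with
conventions that use the literal complement of the CDF. The tail is
evaluated through `scipy.stats.hypergeom.logsf`, stable for p-values far
below double-precision underflow of `1 - cdf`; the result is floored at 0
and capped at $-\log_{10}$ of the smallest subnormal double. The same
hypergeometric machinery backs `overlap_test` for arbitrary set pairs, so
top-k validation and set-overlap testing provably coincide on the same
quadruple.

Default evaluation depths are k = 50, 100, 200 — the depths at which short
candidate lists are typically read.

## Embedding graph and permutation test

Protein representations are mean-pooled token embeddings of
`"<prompt> <symbol>"` (default prompt `The human age-associated gene is
the`); pooling is over all token positions of the input. Pairwise cosine
similarities above a threshold become undirected edges. The threshold is
either a fixed constant (default 0.507) or `upper_quartile`, resolved as
the 75th percentile (linear interpolation) of the off-diagonal
upper-triangle similarities — retaining by construction about a quarter of
all pairs.

Cosine similarity itself is not a cost, so Dijkstra runs on edge distances
$d = 1 - s$; an unweighted hop-count mode is also provided since both
conventions appear in the literature for thresholded similarity graphs.

The permutation test statistic is the mean of *finite* query→anchor
shortest-path lengths; unreachable pairs are counted and excluded, and a
null draw with no finite path scores $+\infty$ (never "closer" than the
observed set). Each of $n$ iterations redraws $|query|$ nodes uniformly
without replacement from a candidate pool that always excludes the anchors
and, by default, the query itself (the null models "random nodes" against
"selected nodes"; for calibration studies the query can be left in the
pool to make observed and null draws exchangeable). The p-value uses the
add-one rule $p = (1 + \#\{null \le obs\}) / (1 + n)$, so $p \ge 1/(n+1)$
and is never 0. One Dijkstra per anchor is cached and shared by all
iterations.

## The synthetic test bed

The toy generator emulates the structural features the pipeline exercises,
not the content of any real corpus or model:

- **Lexicon** — synthetic symbols `G0001…` with token-sequence lengths drawn
  from a distribution over 1–7 (default: 2% single-token, mode at 2–3,
  thin tail to 7 — the shape subword tokenizers produce for gene symbols);
  a fraction (default 0.25) of multi-token genes copies a prefix from an
  earlier gene, so the trie has branch points and genes that are proper
  prefixes of other genes. Sharing is pairwise: each shared pair contributes
  a single branch node on a gene's path.
- **Toy LM** — for each context, base next-token weights are
  $1 \pm \delta$ uniform noise (default $\delta = 0.05$), seeded by a hash
  of (seed, context), giving an arbitrary but fixed distribution per
  context — richer than a unigram table, cheap, and exactly reproducible.
  When the context equals a disease prompt followed by a prefix of a
  planted gene's tokens, the next planted token's weight is multiplied by
  the boost factor $\beta$ (default 10) before normalization. Embedding
  vectors are fixed seeded standard normals per token id.
- **Planted targets** are drawn prefix-isolated: no planted gene is a
  prefix of, or extended by, any other lexicon gene, and planted first
  tokens are pairwise distinct. A gene lying on another planted gene's
  boosted path would inherit the boost, making the planted ground truth
  ill-defined; isolation keeps each planted signal independent. Under these
  defaults a worst-case planted gene (length 7, noise against it, one
  branch node on its path) still outscores the best unplanted gene under
  `total_sum` + division by length, which is why planted recovery is exact
  rather than merely likely. The default 20 planted among 200 genes makes
  perfect top-50 recovery correspond to ELFC exactly 2.
- **Group embeddings** place group centers on orthogonal axes separated by
  `between_group_separation` (default 4) with isotropic member spread
  (default 0.25), reproducing the geometry of a query/anchor cluster versus
  a distant background.
- **Gene lists** for intersection analysis plant a core present in every
  list, optional symbols present in an exact number of lists, and random
  filler repaired so no filler appears in all lists — the common set is the
  core by construction.

What the test bed does *not* emulate: real token statistics (frequency,
morphology), semantic correlation between a model's probabilities and its
embeddings, and the open-ended vocabulary of a production model. Passing
tests therefore demonstrate correctness of the machinery — normalization,
trie accounting, statistics, graph algorithms — not predictive power on
real biomedical text, which depends entirely on the model supplied through
the adapter contract.

## Problem sizes and numerics

The bundled analyses use 200-gene lexicons (vocabulary 600), 999–1000
permutation iterations for significance calls, 99 iterations × 200 repeats
for the calibration screen, and exhaustive enumeration oracles up to
N = 12 (hypergeometric) and 8 nodes (shortest paths) — sizes at which the
independent oracles are exact and the full suite runs in seconds on one
core. Determinism is absolute: every generator and test statistic is a pure
function of its seed; repeated runs are byte-identical, which the CLI test
suite asserts on ranking files.

Known limitations: no batching interface in the model contract (adapters
for GPU models should cache per-prefix queries themselves); `separate_sum`
is one reading of per-class normalization; the co-mention baseline consumes
externally produced count tables and performs no text mining of its own.
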