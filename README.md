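# targetrank

Ranked therapeutic-target extraction from causal language models.

Modern biomedical language models internalize a great deal of gene–disease
knowledge, but sampling free text from them is a poor way to get it back
out. `targetrank` takes the direct route: it asks the model, token by token,
how probable each gene symbol is as the *continuation* of a disease prompt
such as

```
human gene targeted by a drug for treating {DISEASE} is the
```

and turns the answers into a ranked list of candidate targets over a closed
gene lexicon (e.g. an HGNC export of protein-coding symbols).

## The method

Gene symbols are mostly multi-token under subword tokenizers. For a gene
whose name tokenizes to $y_1,\dots,y_L$, the score is the product of
conditional next-token probabilities

$$P(\text{gene}) = \prod_{i=1}^{L} \tilde p(y_i \mid \text{prompt}, y_{<i}),$$

computed by expanding a prefix trie over the tokenized lexicon breadth-first
and querying the model once per trie prefix. Because only a small fraction
of the vocabulary continues some gene name, each step's probabilities can be
renormalized over the *allowed set* (the trie children of the current
prefix): either jointly (`total_sum`) or with name-completing and
name-continuing tokens renormalized separately (`separate_sum`). A final
normalization corrects the length penalty of the product — the geometric
mean $P^{1/L}$ or division by $L^\alpha$. The best-performing configuration
is per-step `total_sum` with final division by $L$ ($\alpha=1$).

Supporting analyses:

- **Validation** — for a reference set of known targets, the top-$k$ of a
  ranking is scored by the enrichment log fold change
  $\mathrm{ELFC} = \log_2\frac{t_k/k}{t_N/N}$ (0.1 substituted when
  $t_k = 0$) and by $\mathrm{HGPV} = -\log_{10} P(X \ge t_k)$ with $X$
  hypergeometric; plus a hypergeometric overlap test between arbitrary gene
  sets.
- **Embedding graph** — mean-pooled prompt+symbol token embeddings give
  per-protein vectors; pairs with cosine similarity above a cutoff (0.507 or
  the upper quartile) become edges with distance $1-s$; Dijkstra shortest
  paths and a permutation test ask whether a query gene set sits closer to
  anchor genes than random node sets do.
- **Baselines & intersections** — literature co-mention ranking (raw counts
  or normalized by total gene mentions) and upset-style intersection of
  per-disease top-$k$ lists, including the set of genes common to all lists.
- **Synthetic test bed** — a fully deterministic toy causal LM over a closed
  vocabulary with 1–7-token gene names, shared prefixes, and *planted*
  disease targets whose continuation probability is boosted by a factor
  $\beta$, providing exact ground truth for every pipeline stage.

Any model can be plugged in through a three-method contract (tokenize /
next-token distribution / token embeddings); the pipeline only ever queries
probabilities, it never samples.

## Worked example

```python
from targetrank import run_scoring, topk_validate
from targetrank.synthetic import ToyLMSpec, make_toy_lm

lm = make_toy_lm(ToyLMSpec(seed=1))          # 200 genes, 20 planted for "aging"
ranked = run_scoring(lm, lm.lexicon, "aging")
planted = set(lm.planted["aging"])
for s in ranked.top(5):
    print(s.rank, s.symbol, f"{s.final_score:.6e}", s.symbol in planted)
r = topk_validate(ranked, planted, ks=(50,), N=200)[0]
print(f"k={r.k} targets_k={r.targets_k} ELFC={r.elfc:.3f} HGPV={r.hgpv:.3f}")
```

prints

```
1 G0092 1.604444e-02 True
2 G0071 1.600910e-02 True
3 G0020 1.521490e-02 True
4 G0015 1.494723e-02 True
5 G0090 1.494301e-02 True
k=50 targets_k=20 ELFC=2.000 HGPV=13.535
```

All 20 planted genes occupy the top 20 ranks; with 20 of the 200-gene
universe planted, finding all 20 within the top 50 is a fourfold enrichment
(ELFC $=\log_2 4 = 2$) whose hypergeometric tail probability is
$10^{-13.5}$.

The same workflows are available from the shell:

```
targetrank rank --adapter toy --disease aging --out runs/aging
targetrank validate --ranking runs/aging/aging.tsv --reference ref.txt --out val.tsv
targetrank graph --embeddings emb.tsv --query q.txt --anchors a.txt --out runs/graph
targetrank intersect runs/*/aging.tsv runs/*/copd.tsv --out runs/ix
targetrank selfcheck
```

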