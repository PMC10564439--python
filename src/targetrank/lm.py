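"""The minimal causal-language-model contract.

Every other module talks to a language model exclusively through the
:class:`CausalLM` protocol: tokenize text, return the *full* next-token
probability distribution for a context, and return per-token embedding
vectors.  Distributions cross the contract as probabilities (never logits),
and adapters must be deterministic — the pipeline queries, it never samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .exceptions import ContractError

#: Tolerance on sum-to-one for a next-token distribution.
NORMALIZATION_TOL = 1e-6


@dataclass(frozen=True)
class NextTokenDistribution:
    """A probability distribution over the model vocabulary.

    ``probabilities[t]`` is the probability of token id ``t`` being the next
    token.  The array covers the full vocabulary; invariants (non-negative,
    sum to one within :data:`NORMALIZATION_TOL`) are enforced by
    :func:`validate_lm`, not on construction, so adapters stay cheap.
    """

    probabilities: np.ndarray

    def prob(self, token_id: int) -> float:
        return float(self.probabilities[token_id])

    @property
    def vocabulary_size(self) -> int:
        return int(self.probabilities.shape[0])


@runtime_checkable
class CausalLM(Protocol):
    """Behavioural contract for any language model used by the pipeline."""

    @property
    def vocabulary_size(self) -> int: ...

    def tokenize(self, text: str) -> tuple[int, ...]: ...

    def next_token_distribution(
        self, context: Sequence[int]
    ) -> NextTokenDistribution: ...

    def token_embeddings(self, tokens: Sequence[int]) -> np.ndarray:
        """Per-token embedding matrix of shape (len(tokens), dim)."""
        ...


@dataclass
class LMReport:
    """Diagnostic report produced by :func:`validate_lm`."""

    n_probes: int
    checks: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:  # a report only exists if every check passed
        return True


def validate_lm(
    lm: CausalLM,
    probe_sequences: Sequence[Sequence[int]],
    tol: float = NORMALIZATION_TOL,
    repeats: int = 2,
) -> LMReport:
    """Check an adapter against the contract on a set of probe contexts.

    For every probe the next-token distribution must be non-negative, sum to
    one within ``tol``, and be bit-identical across ``repeats`` calls
    (determinism); embeddings must likewise be deterministic and of constant
    dimension.  Raises :class:`ContractError` naming the failing property.
    """
    if len(probe_sequences) < 1:
        raise ValueError("at least one probe sequence is required")
    report = LMReport(n_probes=len(probe_sequences))
    emb_dim: int | None = None
    for probe in probe_sequences:
        probe = tuple(probe)
        dist = lm.next_token_distribution(probe)
        p = np.asarray(dist.probabilities, dtype=float)
        if np.any(p < 0):
            raise ContractError(
                f"negative probability for context {probe!r}"
            )
        total = float(p.sum())
        if abs(total - 1.0) > tol:
            raise ContractError(
                f"not normalized: distribution for context {probe!r} "
                f"sums to {total!r}"
            )
        for _ in range(repeats - 1):
            again = np.asarray(
                lm.next_token_distribution(probe).probabilities, dtype=float
            )
            if not np.array_equal(p, again):
                raise ContractError(
                    f"non-deterministic: repeated next_token_distribution "
                    f"calls differ for context {probe!r}"
                )
        emb = np.asarray(lm.token_embeddings(probe))
        if emb.shape[0] != len(probe):
            raise ContractError(
                f"embedding row count {emb.shape[0]} != context length "
                f"{len(probe)}"
            )
        if emb_dim is None:
            emb_dim = int(emb.shape[1])
        elif int(emb.shape[1]) != emb_dim:
            raise ContractError(
                f"embedding dimension changed from {emb_dim} to {emb.shape[1]}"
            )
        again_emb = np.asarray(lm.token_embeddings(probe))
        if not np.array_equal(emb, again_emb):
            raise ContractError(
                f"non-deterministic: repeated token_embeddings calls differ "
                f"for context {probe!r}"
            )
        report.checks.append(
            f"context len {len(probe)}: normalized, non-negative, deterministic"
        )
    return report
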