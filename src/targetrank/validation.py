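"""Top-k enrichment statistics for ranked target lists.

Given a ranked gene list and a reference set of known targets inside a
universe of N genes, the quality of the top of the list is summarized by

ELFC (enrichment log fold change)
    log2 of the ratio between the known-target fraction within the top k and
    the known-target fraction in the whole universe; when no known target
    lands in the top k, 0.1 is substituted for the zero count so the value
    stays finite.

HGPV
    -log10 of the hypergeometric upper-tail probability of drawing at least
    ``targets_k`` known targets in k draws from a universe of N genes that
    contains ``targets_N`` known targets.  Computed through the log survival
    function, which is stable when the p-value is near 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .scoring import RankedList

#: Default evaluation depths.
DEFAULT_KS = (50, 100, 200)

# -log10 floor: smallest positive double, so HGPV is always finite.
_MAX_HGPV = -math.log10(5e-324)


@dataclass(frozen=True)
class ValidationResult:
    """ELFC/HGPV at one evaluation depth k."""

    k: int
    targets_k: int
    targets_N: int
    N: int
    elfc: float
    hgpv: float


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric overlap between a candidate list and a reference set."""

    overlap: int
    size_a: int
    size_reference: int
    N: int
    p_value: float


def _check_quadruple(targets_k: int, k: int, targets_N: int, N: int) -> None:
    if targets_N < 1 or targets_N > N:
        raise ValueError(f"targets_N must be in [1, N], got {targets_N} with N={N}")
    if k < 1 or k > N:
        raise ValueError(f"k must be in [1, N], got {k} with N={N}")
    if targets_k < 0 or targets_k > min(k, targets_N):
        raise ValueError(
            f"targets_k must be in [0, min(k, targets_N)], got {targets_k}"
        )


def elfc(targets_k: int, k: int, targets_N: int, N: int) -> float:
    """Enrichment log fold change; 0.1 replaces a zero top-k count."""
    _check_quadruple(targets_k, k, targets_N, N)
    t_k = targets_k if targets_k > 0 else 0.1
    return math.log2((t_k / k) / (targets_N / N))


def hgpv(
    targets_k: int, k: int, targets_N: int, N: int, strict: bool = False
) -> float:
    """-log10 hypergeometric tail probability of the top-k target count.

    Default tail is P(X >= targets_k).  ``strict=True`` gives the literal
    1 - CDF(targets_k) variant, i.e. P(X > targets_k).
    """
    _check_quadruple(targets_k, k, targets_N, N)
    threshold = targets_k if strict else targets_k - 1
    log_sf = hypergeom.logsf(threshold, N, targets_N, k)
    value = -log_sf / math.log(10)
    if not np.isfinite(value):
        return _MAX_HGPV
    return float(min(max(value, 0.0), _MAX_HGPV))


def topk_validate(
    ranked: RankedList,
    reference: Iterable[str],
    ks: Sequence[int] = DEFAULT_KS,
    N: int | None = None,
) -> list[ValidationResult]:
    """Evaluate a ranked list against a reference target set at several depths."""
    if not ks:
        raise ValueError("ks must be non-empty")
    symbols = ranked.symbols()
    universe = set(symbols)
    reference = {s.upper() for s in reference} & universe
    n_universe = N if N is not None else len(symbols)
    targets_n = len(reference)
    results = []
    for k in ks:
        if k > len(symbols):
            raise ValueError(f"k={k} exceeds ranking length {len(symbols)}")
        targets_k = sum(1 for s in symbols[:k] if s in reference)
        results.append(
            ValidationResult(
                k=k,
                targets_k=targets_k,
                targets_N=targets_n,
                N=n_universe,
                elfc=elfc(targets_k, k, targets_n, n_universe),
                hgpv=hgpv(targets_k, k, targets_n, n_universe),
            )
        )
    return results


def overlap_test(
    list_a: Iterable[str], reference: Iterable[str], N: int
) -> OverlapTestResult:
    """Hypergeometric test of the overlap between two gene sets in a universe of N."""
    set_a = set(list_a)
    ref = set(reference)
    if N < len(set_a) or N < len(ref):
        raise ValueError("universe size N smaller than one of the sets")
    overlap = len(set_a & ref)
    p = float(hypergeom.sf(overlap - 1, N, len(ref), len(set_a)))
    p = min(max(p, 5e-324), 1.0)
    return OverlapTestResult(
        overlap=overlap,
        size_a=len(set_a),
        size_reference=len(ref),
        N=N,
        p_value=p,
    )


def write_validation_tsv(results: Sequence[ValidationResult], path) -> None:
    """Tab-separated report: k, targets_k, targets_N, N, ELFC, HGPV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("k\ttargets_k\ttargets_N\tN\tELFC\tHGPV\n")
        for r in results:
            fh.write(
                f"{r.k}\t{r.targets_k}\t{r.targets_N}\t{r.N}\t"
                f"{r.elfc:.6f}\t{r.hgpv:.6f}\n"
            )
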