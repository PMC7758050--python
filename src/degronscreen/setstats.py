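"""Shared enrichment statistics: chance expectation, enrichment bias,
and exact hypergeometric tail testing.

The core quantities, in the sampling-without-replacement frame:

- ``q`` — observed hits: selected items that carry the feature (e.g.
  differentially methylated CpGs in exons; truth-set substrates among
  candidates),
- ``m`` — universe items carrying the feature,
- ``n`` — universe items not carrying it,
- ``k`` — selected items in total.

From these: chance expectation ``e = (m / (m + n)) * k``, fold
enrichment ``q / e``, percentage enrichment bias
``((q - e) / k) * 100`` (the excess of observed over expected hits as a
percent of the selection), and the exact hypergeometric upper tail
``P(X >= q)`` for ``X ~ Hypergeometric(m, n, k)``.

The upper tail is the default because enrichment questions ask about
over-representation; a flag exposes the lower tail for depletion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger("degronscreen")


@dataclass(frozen=True)
class EnrichmentInput:
    q: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        for name in ("q", "m", "n", "k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.q > min(self.m, self.k):
            raise ValueError(f"q={self.q} exceeds min(m={self.m}, k={self.k})")
        if self.k > self.m + self.n:
            raise ValueError(f"k={self.k} exceeds universe m+n={self.m + self.n}")

    @property
    def universe(self) -> int:
        return self.m + self.n


@dataclass(frozen=True)
class EnrichmentBiasResult:
    q: int
    m: int
    n: int
    k: int
    e: float
    bias_percent: float
    fold: float  # math.inf flags q > 0 with e == 0
    p_hyper: float


@dataclass(frozen=True)
class RecoveryResult:
    candidate_set_id: str
    truth_set_id: str
    captured: int
    truth_size: int
    candidate_size: int
    universe_size: int
    expected: float
    fold: float
    p_hyper: float
    captured_members: tuple[str, ...] = ()


def expected_by_chance(m: int, n: int, k: int) -> float:
    """Expected feature hits under random selection: e = (m/(m+n))k."""
    if m + n == 0:
        raise ValueError("empty universe (m + n = 0)")
    if k > m + n:
        raise ValueError("k exceeds universe")
    return (m / (m + n)) * k


def enrichment_bias(q: float, e: float, k: int) -> float:
    """Percentage enrichment bias: ((q - e) / k) * 100.

    Positive values mean more feature hits than chance would give,
    negative values fewer.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    return ((q - e) / k) * 100.0


def hypergeom_tail(q: int, m: int, n: int, k: int, upper: bool = True) -> float:
    """Exact hypergeometric tail probability.

    Upper tail (default): P(X >= q), the probability of capturing at
    least ``q`` feature items when drawing ``k`` from ``m`` feature and
    ``n`` non-feature items.  ``upper=False`` gives P(X <= q) for
    depletion tests.  P(X >= 0) is exactly 1.
    """
    EnrichmentInput(q, m, n, k)  # validate bounds
    dist = hypergeom(m + n, m, k)
    if upper:
        if q == 0:
            return 1.0
        p = float(dist.sf(q - 1))
    else:
        p = float(dist.cdf(q))
    return min(max(p, 0.0), 1.0)


def enrichment_stats(q: int, m: int, n: int, k: int, upper: bool = True) -> EnrichmentBiasResult:
    """Full enrichment summary for one feature."""
    e = expected_by_chance(m, n, k)
    bias = enrichment_bias(q, e, k)
    if e > 0:
        fold = q / e
    else:
        fold = math.inf if q > 0 else float("nan")
    return EnrichmentBiasResult(q, m, n, k, e, bias, fold, hypergeom_tail(q, m, n, k, upper))


def recovery_stats(
    candidates: Iterable[str],
    truth_set: Iterable[str],
    universe_size: int,
    candidate_set_id: str = "candidates",
    truth_set_id: str = "truth",
) -> RecoveryResult:
    """Recovery of a truth set by a candidate set.

    ``q = |candidates ∩ truth|``; the hypergeometric frame draws
    ``k = |candidates|`` genes from a universe split into
    ``m = |truth|`` substrates and ``n = universe - m`` others.
    """
    cand = {str(g) for g in candidates}
    truth = {str(g) for g in truth_set}
    if not truth:
        raise ValueError("truth set is empty")
    if universe_size < len(cand | truth):
        raise ValueError(
            f"universe_size {universe_size} smaller than |candidates ∪ truth| "
            f"= {len(cand | truth)}"
        )
    captured = sorted(cand & truth)
    q = len(captured)
    m = len(truth)
    n = universe_size - m
    k = len(cand)
    e = expected_by_chance(m, n, k)
    if e > 0:
        fold = q / e
    else:
        fold = math.inf if q > 0 else float("nan")
    return RecoveryResult(
        candidate_set_id,
        truth_set_id,
        q,
        m,
        k,
        universe_size,
        e,
        fold,
        hypergeom_tail(q, m, n, k),
        tuple(captured),
    )


def compare_recovery(
    candidate_sets: Mapping[str, Iterable[str]],
    truth_set: Iterable[str],
    universe_size: int,
    truth_set_id: str = "truth",
) -> list[RecoveryResult]:
    """One RecoveryResult per named candidate set against a common truth set."""
    if not candidate_sets:
        raise ValueError("need at least one candidate set")
    truth = {str(g) for g in truth_set}
    return [
        recovery_stats(genes, truth, universe_size, name, truth_set_id)
        for name, genes in candidate_sets.items()
    ]


def recovery_to_frame(results: Iterable[RecoveryResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "candidate_set": r.candidate_set_id,
                "truth_set": r.truth_set_id,
                "captured": r.captured,
                "truth_size": r.truth_size,
                "candidate_size": r.candidate_size,
                "universe_size": r.universe_size,
                "expected": r.expected,
                "fold": r.fold,
                "p_hyper": r.p_hyper,
                "captured_members": ";".join(r.captured_members),
            }
        )
    return pd.DataFrame(rows)
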