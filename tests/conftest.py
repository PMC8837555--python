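"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by the dumbest correct
route (per-window rescoring, exhaustive enumeration, alternating
normalization) so the fast implementations are checked against code that
shares nothing with them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from loopgrammar.io_formats import PositionWeightMatrix
from loopgrammar.motif_scan import (
    ScoreDistribution,
    encode,
    log_odds_score,
    reverse_complement,
)


def naive_scan(
    pwm: PositionWeightMatrix,
    seq: str,
    dist: ScoreDistribution,
    p_cutoff: float,
) -> list[tuple[int, str, float, float]]:
    """O(L*K) per-window rescoring oracle: (start, strand, score, pvalue)."""
    K = len(pwm)
    out = []
    for i in range(len(seq) - K + 1):
        word = seq[i : i + K]
        if "N" in word:
            continue
        for strand in "+-":
            score = log_odds_score(pwm, word, strand)
            oriented = word if strand == "+" else reverse_complement(word)
            p = dist.pvalue_of_int(dist.word_int_score(encode(oriented)))
            if p <= p_cutoff:
                out.append((i, strand, score, p))
    out.sort()
    return out


def enumerate_score_distribution(
    pwm: PositionWeightMatrix, dist: ScoreDistribution
) -> dict[int, float]:
    """Exhaustive 4^K null: integer score -> P(S >= score)."""
    K = len(pwm)
    pmf: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=K):
        s = int(sum(dist.int_scores[k, b] for k, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        pmf[s] = pmf.get(s, 0.0) + p
    sf: dict[int, float] = {}
    acc = 0.0
    for s in sorted(pmf, reverse=True):
        acc += pmf[s]
        sf[s] = min(acc, 1.0)
    return sf


def sinkhorn_balance(counts: np.ndarray, n_iter: int = 20_000) -> np.ndarray:
    """Alternating row/column normalization oracle for symmetric matrices."""
    W = counts.astype(float).copy()
    for _ in range(n_iter):
        W = W / W.sum(axis=1, keepdims=True)
        W = W / W.sum(axis=0, keepdims=True)
    return 0.5 * (W + W.T)


def random_pwm(
    rng: np.random.Generator, length: int, concentration: float = 1.5
) -> PositionWeightMatrix:
    probs = rng.dirichlet(np.full(4, concentration), size=length)
    return PositionWeightMatrix(f"rand{length}", probs)


def random_sequence(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    alphabet = np.array(list("ACGTN"))
    p = [(1 - n_frac) / 4] * 4 + [n_frac]
    return "".join(rng.choice(alphabet, p=p, size=length))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
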