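"""PWM log-odds scanning with exact p-values.

Scores are log\\ :sub:`2` odds in bits against a fixed zero-order background,
and p-values come from the exact distribution of the discretized score of a
random background word, computed by a position-wise dynamic program (the
standard construction behind FIMO-style scanners).  Both strands are
scanned; a '-' strand hit means the reverse complement of the window
matches the motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import GenomicInterval, PositionWeightMatrix

logger = logging.getLogger(__name__)

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_INT_TO_BASE = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_P_CUTOFF = 1e-3
DEFAULT_GRANULARITY = 1e-3  # bits
MAX_CELLS = 100_000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (N -> 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for base, code in _BASE_TO_INT.items():
        lut[ord(base)] = code
        lut[ord(base.lower())] = code
    codes = lut[arr]
    if np.any(codes < 0):
        bad = chr(arr[np.argmax(codes < 0)])
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


@dataclass
class MotifHit:
    """A located, stranded, scored motif occurrence."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    motif: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("pvalue must lie in (0, 1]")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    ``int_scores[k, b]`` is the per-position integer score (bits divided by
    ``granularity``, rounded); ``sf[s - min_score]`` is P(S >= s) for a
    random background word, with S the sum of integer per-position scores.
    """

    granularity: float
    int_scores: np.ndarray
    min_score: int
    sf: np.ndarray

    def word_int_score(self, codes: np.ndarray) -> int:
        return int(self.int_scores[np.arange(len(codes)), codes].sum())

    def pvalue_of_int(self, s: int) -> float:
        idx = s - self.min_score
        if idx <= 0:
            return 1.0
        if idx >= len(self.sf):
            return float(self.sf[-1])
        return float(self.sf[idx])


def log_odds_matrix(pwm: PositionWeightMatrix) -> np.ndarray:
    """(K, 4) matrix of log2(p/bg) in bits."""
    return np.log2(pwm.probs / pwm.background[None, :])


def log_odds_score(
    pwm: PositionWeightMatrix, word: str, strand: str = "+"
) -> float:
    """Score one K-length word in bits; '-' scores the reverse complement."""
    if len(word) != len(pwm):
        raise ValueError(f"word length {len(word)} != motif length {len(pwm)}")
    if strand == "-":
        word = reverse_complement(word)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    codes = encode(word)
    if np.any(codes == 4):
        raise ValueError("ambiguous base N in word; no score defined")
    lo = log_odds_matrix(pwm)
    return float(lo[np.arange(len(pwm)), codes].sum())


def score_pvalue_table(
    pwm: PositionWeightMatrix, granularity: float | None = None
) -> ScoreDistribution:
    """Exact p-value table by DP convolution over motif positions.

    The score is discretized to a grid of at most ``MAX_CELLS`` cells (the
    requested granularity is coarsened when the score range demands it);
    the resulting distribution is exact for the discretized score.
    """
    lo = log_odds_matrix(pwm)
    span = float((lo.max(axis=1) - lo.min(axis=1)).sum())
    if granularity is None:
        granularity = DEFAULT_GRANULARITY
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    if span / granularity > MAX_CELLS:
        granularity = span / MAX_CELLS
    int_scores = np.round(lo / granularity).astype(np.int64)
    lo_sum = int(int_scores.min(axis=1).sum())
    hi_sum = int(int_scores.max(axis=1).sum())
    n_cells = hi_sum - lo_sum + 1
    if n_cells <= 1:
        raise ValueError(
            "granularity too coarse: all scores collapse to one cell"
        )
    pmf = np.zeros(n_cells)
    pmf[0] = 1.0  # offset relative to running minimum sum
    cur_lo = 0
    for k in range(len(pwm)):
        row = int_scores[k]
        row_lo = int(row.min())
        new = np.zeros(n_cells)
        for b in range(4):
            shift = int(row[b]) - row_lo
            if shift == 0:
                new += pwm.background[b] * pmf
            else:
                new[shift:] += pwm.background[b] * pmf[:-shift]
        pmf = new
        cur_lo += row_lo
    assert cur_lo == lo_sum
    sf = np.cumsum(pmf[::-1])[::-1]
    sf = np.clip(sf, 0.0, 1.0)
    sf[0] = 1.0  # total mass at the minimum score
    return ScoreDistribution(
        granularity=granularity,
        int_scores=int_scores,
        min_score=lo_sum,
        sf=sf,
    )


def _window_scores(
    codes_intp: np.ndarray, table: np.ndarray, n_win: int
) -> np.ndarray:
    """Sliding-window sums of ``table[k, codes[i+k]]`` over all offsets.

    ``codes_intp`` must be intp-typed with N already clipped into 0-3;
    the caller masks windows containing N separately.
    """
    K = table.shape[0]
    out = np.zeros(n_win)
    for k in range(K):
        out += table[k][codes_intp[k : k + n_win]]
    return out


def scan_sequence(
    pwm: PositionWeightMatrix,
    seq: str,
    chrom: str = "seq",
    p_cutoff: float = DEFAULT_P_CUTOFF,
    dist: ScoreDistribution | None = None,
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of ``seq``; return hits with p-value <= cutoff.

    Windows containing N are skipped.  Hits are sorted by start, '+'
    before '-' at equal start.  ``offset`` shifts reported coordinates
    (scanning an extracted subsequence in genome coordinates).
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must lie in (0, 1]")
    K = len(pwm)
    if len(seq) < K:
        return []
    if dist is None:
        dist = score_pvalue_table(pwm)
    codes = encode(seq)
    lo = log_odds_matrix(pwm)
    # '-' strand at the same window = '+' scoring of the reverse complement,
    # equivalently the complement-reversed log-odds table on the forward codes
    lo_rc = lo[::-1, ::-1]
    int_rc = dist.int_scores[::-1, ::-1]

    passing = np.nonzero(dist.sf <= p_cutoff)[0]
    if len(passing) == 0:
        return []
    # minimal integer score whose p-value passes; candidate windows are
    # pre-filtered on the float score with a K/2-cell rounding margin, then
    # rescored exactly on the integer grid
    s_star = dist.min_score + int(passing[0])
    margin = (0.5 * K + 1e-6) * dist.granularity

    n_win = len(codes) - K + 1
    has_n = codes == 4
    codes_intp = np.where(has_n, 0, codes).astype(np.intp)
    if has_n.any():
        # window contains an N iff the cumulative N count changes across it
        cum = np.concatenate([[0], np.cumsum(has_n)])
        window_ok = (cum[K:] - cum[:-K]) == 0
        logger.debug(
            "%s: %d windows containing N dropped",
            chrom, int((~window_ok).sum()),
        )
    else:
        window_ok = np.ones(n_win, dtype=bool)

    float_plus = _window_scores(codes_intp, lo, n_win)
    float_minus = _window_scores(codes_intp, lo_rc, n_win)

    hits: list[MotifHit] = []
    for strand, fscores, int_table in (
        ("+", float_plus, dist.int_scores),
        ("-", float_minus, int_rc),
    ):
        cand = window_ok & (fscores >= s_star * dist.granularity - margin)
        idx = np.nonzero(cand)[0]
        if len(idx) == 0:
            continue
        iscores = np.zeros(len(idx), dtype=np.int64)
        for k in range(K):
            iscores += int_table[k, codes_intp[idx + k]]
        cells = iscores - dist.min_score
        pvals = np.where(
            cells <= 0,
            1.0,
            dist.sf[np.clip(cells, 0, len(dist.sf) - 1)],
        )
        keep = pvals <= p_cutoff
        for i, p in zip(idx[keep], pvals[keep]):
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=offset + int(i),
                    end=offset + int(i) + K,
                    strand=strand,
                    score=float(fscores[i]),
                    pvalue=float(p),
                    motif=pwm.name,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def best_hit_in_interval(
    hits: list[MotifHit], interval: GenomicInterval
) -> MotifHit | None:
    """Highest-scoring hit fully contained in ``interval``.

    Ties break to the lowest start, then '+' strand.
    """
    best: MotifHit | None = None
    for h in hits:
        if h.chrom != interval.chrom:
            continue
        if h.start < interval.start or h.end > interval.end:
            continue
        if (
            best is None
            or h.score > best.score
            or (
                h.score == best.score
                and (h.start, h.strand) < (best.start, best.strand)
            )
        ):
            best = h
    return best


def consensus_scan(
    seq: str, consensus: str, chrom: str = "seq", offset: int = 0
) -> list[MotifHit]:
    """Exact-match scan for a consensus word on both strands.

    Overlapping matches are all reported; score is the match length and
    the p-value is fixed at 1 (no statistical model implied).
    """
    if not consensus or set(consensus) - set("ACGT"):
        raise ValueError("consensus must be a non-empty ACGT word")
    K = len(consensus)
    hits: list[MotifHit] = []
    rc = reverse_complement(consensus)
    for strand, word in (("+", consensus), ("-", rc)):
        pos = seq.find(word)
        while pos != -1:
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=offset + pos,
                    end=offset + pos + K,
                    strand=strand,
                    score=float(K),
                    pvalue=1.0,
                )
            )
            pos = seq.find(word, pos + 1)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hits_to_bed(path, hits: list[MotifHit]) -> None:
    """Write hits as BED6 (score column = bits x 100, rounded)."""
    with open(path, "w") as fh:
        for h in hits:
            name = h.motif if h.motif is not None else "."
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{name}\t"
                f"{round(h.score * 100)}\t{h.strand}\n"
            )
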