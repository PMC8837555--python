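"""Contact-matrix computations.

Implements the Hi-C side of the pipeline: pair binning with the >=25-kb
cis-distance filter, iterative-correction (ICE) balancing, per-distance
expected profiles, aggregate peak analysis (APA) with the Peak-to-Lower-
Left (P2LL) statistic at 5-kb resolution, insulation-style boundary
scores ("ratio" method: contacts crossing a bin divided by flanking
intra-window contacts, so boundaries score LOW), TAD calling and
intra-TAD activity, CPM-normalized differential loop/TAD activity with
BH correction, and a deliberately simple Poisson loop caller used only
to close the loop on fully synthetic pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ContactMatrix, GenomicInterval, Loop

logger = logging.getLogger(__name__)

BOUNDARY_WINDOWS = (250_000, 500_000, 1_000_000)
DEFAULT_BOUNDARY_WINDOW = 500_000
APA_RESOLUTION = 5_000
LOOP_FDR_CUTOFF = 0.005
LOOP_LFC_CUTOFF = 1.5
TAD_FDR_CUTOFF = 0.05


class BalanceError(RuntimeError):
    """ICE failed to converge; carries the last row-sum deviation."""

    def __init__(self, deviation: float, n_iter: int):
        self.deviation = deviation
        self.n_iter = n_iter
        super().__init__(
            f"ICE did not converge in {n_iter} iterations "
            f"(last max relative row-sum deviation {deviation:.3g})"
        )


# ---------------------------------------------------------------------------
# binning and balancing
# ---------------------------------------------------------------------------


def bin_contacts(
    pairs,
    chrom_length: int,
    bin_size: int = 20_000,
    min_pair_distance: int = 25_000,
    chrom: str | None = None,
) -> ContactMatrix:
    """Tabulate cis read pairs into a symmetric binned count matrix.

    ``pairs`` is an iterable of (chrom, pos1, pos2); pairs closer than
    ``min_pair_distance`` are dropped (self-ligation range).
    """
    n_bins = int(np.ceil(chrom_length / bin_size))
    mat = np.zeros((n_bins, n_bins))
    name = chrom
    for c, p1, p2 in pairs:
        if name is None:
            name = c
        elif c != name:
            raise ValueError(f"pairs span chromosomes {name!r} and {c!r}")
        if p1 < 0 or p2 < 0:
            raise ValueError("negative position")
        if p1 >= chrom_length or p2 >= chrom_length:
            raise ValueError("position beyond chromosome length")
        if abs(p2 - p1) < min_pair_distance:
            continue
        i, j = p1 // bin_size, p2 // bin_size
        mat[i, j] += 1
        if i != j:
            mat[j, i] += 1
    return ContactMatrix(chrom=name or "chr", bin_size=bin_size, counts=mat)


def ice_balance(
    matrix: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 500,
    mask_fraction: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: multiplicative per-bin biases equalizing
    visibility.

    All-zero bins plus the lowest-coverage ``mask_fraction`` of nonzero
    bins are masked.  On return, ``balanced`` has every unmasked row
    summing to 1 (within ``tol`` relative) and ``biases`` satisfies
    ``balanced = counts / (biases x biases^T)`` off the mask.
    """
    n = matrix.n_bins
    coverage = matrix.counts.sum(axis=1)
    masked = coverage == 0
    nonzero = np.nonzero(~masked)[0]
    n_extra = int(np.floor(mask_fraction * len(nonzero)))
    if n_extra > 0:
        order = nonzero[np.argsort(coverage[nonzero], kind="stable")]
        masked[order[:n_extra]] = True
    if masked.all():
        raise BalanceError(np.inf, 0)

    W = matrix.counts.copy()
    W[masked, :] = 0.0
    W[:, masked] = 0.0
    biases = np.ones(n)
    deviation = np.inf
    for it in range(max_iter):
        s = W.sum(axis=1)
        mean_s = s[~masked].mean()
        if mean_s == 0:
            raise BalanceError(np.inf, it)
        delta = s / mean_s
        delta[masked] = 1.0
        deviation = float(np.abs(delta[~masked] - 1.0).max())
        if deviation < tol:
            break
        biases *= delta
        W /= np.outer(delta, delta)
    else:
        raise BalanceError(deviation, max_iter)

    # rescale so unmasked rows sum to exactly ~1
    row_sum = W.sum(axis=1)[~masked].mean()
    W /= row_sum
    biases = biases * np.sqrt(row_sum)
    W = 0.5 * (W + W.T)
    logger.info(
        "ICE converged after %d iterations (deviation %.2g, %d bins masked)",
        it + 1, deviation, int(masked.sum()),
    )
    return ContactMatrix(
        chrom=matrix.chrom,
        bin_size=matrix.bin_size,
        counts=matrix.counts,
        balanced=W,
        biases=np.where(masked, np.nan, biases),
        masked=masked,
    )


def expected_by_distance(
    matrix: ContactMatrix, smooth: bool = False
) -> np.ndarray:
    """Mean contact over unmasked pixels at each bin distance.

    Uses the balanced layer when present (raw otherwise, logged).  With
    ``smooth=True`` the profile is made non-increasing in distance
    (isotonic from the diagonal outward).
    """
    masked = matrix.mask()
    if masked.all():
        raise ValueError("all bins masked: cannot form an expected profile")
    if matrix.balanced is not None:
        layer = matrix.balanced
    else:
        layer = matrix.counts
        logger.info("expected_by_distance: no balanced layer, using raw counts")
    n = matrix.n_bins
    keep = ~masked
    expected = np.full(n, np.nan)
    for d in range(n):
        i = np.arange(0, n - d)
        j = i + d
        ok = keep[i] & keep[j]
        if ok.any():
            expected[d] = layer[i[ok], j[ok]].mean()
    if smooth:
        valid = ~np.isnan(expected)
        expected[valid] = np.minimum.accumulate(expected[valid])
    return expected


def oe_matrix(matrix: ContactMatrix, expected: np.ndarray | None = None) -> np.ndarray:
    """Observed/expected matrix; masked bins and zero-expected pixels are NaN."""
    if expected is None:
        expected = expected_by_distance(matrix)
    layer = matrix.balanced if matrix.balanced is not None else matrix.counts
    n = matrix.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp2d = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = layer / exp2d
    oe[~np.isfinite(oe)] = np.nan
    masked = matrix.mask()
    oe[masked, :] = np.nan
    oe[:, masked] = np.nan
    return oe


# ---------------------------------------------------------------------------
# APA / P2LL
# ---------------------------------------------------------------------------


@dataclass
class APAResult:
    """Aggregate submatrix over loop pixels (row = upstream anchor)."""

    aggregate: np.ndarray
    n_loops_used: int
    n_loops_skipped: int
    resolution: int

    @property
    def flank_bins(self) -> int:
        return (self.aggregate.shape[0] - 1) // 2

    @property
    def p2ll(self) -> float:
        return p2ll(self.aggregate)


def apa(
    matrix: ContactMatrix,
    loops: list[Loop],
    resolution: int = APA_RESOLUTION,
    flank_bins: int = 10,
    mode: str = "oe",
) -> APAResult:
    """Aggregate peak analysis over the given loops.

    The matrix must already be binned at ``resolution`` (no silent
    re-binning).  Each loop contributes the (2N+1)^2 observed/expected
    window centered on its anchor-midpoint pixel; windows crossing the
    diagonal (distance < (2N+2) bins) or the matrix edge are skipped.
    ``mode='raw'`` aggregates the un-normalized layer instead.
    """
    if matrix.bin_size != resolution:
        raise ValueError(
            f"matrix bin size {matrix.bin_size} != APA resolution "
            f"{resolution}; re-bin upstream"
        )
    N = flank_bins
    if mode == "oe":
        layer = oe_matrix(matrix)
    elif mode == "raw":
        layer = (
            matrix.balanced if matrix.balanced is not None else matrix.counts
        ).astype(float)
    else:
        raise ValueError("mode must be 'oe' or 'raw'")
    n = matrix.n_bins
    size = 2 * N + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    used = skipped = 0
    min_dist_bp = (2 * N + 2) * resolution
    for lp in loops:
        if lp.chrom != matrix.chrom:
            skipped += 1
            continue
        b1 = int(lp.anchor5.midpoint // resolution)
        b2 = int(lp.anchor3.midpoint // resolution)
        if lp.distance < min_dist_bp:
            skipped += 1
            continue
        if b1 - N < 0 or b1 + N >= n or b2 - N < 0 or b2 + N >= n:
            skipped += 1
            continue
        sub = layer[b1 - N : b1 + N + 1, b2 - N : b2 + N + 1]
        ok = np.isfinite(sub)
        acc[ok] += sub[ok]
        cnt += ok
        used += 1
    if used == 0:
        raise ValueError("no loops after filtering")
    with np.errstate(invalid="ignore"):
        aggregate = acc / cnt
    return APAResult(
        aggregate=aggregate,
        n_loops_used=used,
        n_loops_skipped=skipped,
        resolution=resolution,
    )


def p2ll(
    aggregate: np.ndarray,
    corner_bins: int | None = None,
    corner: str = "lower_left",
) -> float:
    """Peak-to-Lower-Left: central pixel over the mean of a corner block.

    With row = upstream anchor (rows drawn top-to-bottom), the displayed
    lower-left corner — high row indices, low column indices — is the
    corner nearest the diagonal and is the default background block.
    ``corner`` picks another corner ('upper_left', 'lower_right',
    'upper_right') if a different orientation convention is in force.
    """
    agg = np.asarray(aggregate, dtype=float)
    if agg.ndim != 2 or agg.shape[0] != agg.shape[1] or agg.shape[0] % 2 == 0:
        raise ValueError("aggregate must be square with odd size")
    size = agg.shape[0]
    N = (size - 1) // 2
    if corner_bins is None:
        corner_bins = max(1, size // 3)
    if not 0 < corner_bins <= N:
        raise ValueError("corner_bins must lie in (0, half-width]")
    c = corner_bins
    blocks = {
        "lower_left": agg[size - c :, :c],
        "upper_left": agg[:c, :c],
        "lower_right": agg[size - c :, size - c :],
        "upper_right": agg[:c, size - c :],
    }
    if corner not in blocks:
        raise ValueError(f"corner must be one of {sorted(blocks)}")
    block = blocks[corner]
    mean = np.nanmean(block)
    center = agg[N, N]
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("corner mean is zero or undefined")
    if not np.isfinite(center):
        raise ValueError("central pixel undefined")
    return float(center / mean)


def loop_distance_histogram(
    loops: list[Loop],
    bin_edges: np.ndarray | None = None,
    threshold_bp: int = 2_000_000,
) -> tuple[pd.DataFrame, float]:
    """Histogram of anchor-midpoint distances plus the fraction below
    ``threshold_bp`` (NaN for an empty loop list)."""
    distances = np.array([lp.distance for lp in loops], dtype=float)
    if bin_edges is None:
        top = max(threshold_bp * 2.5, distances.max() if len(distances) else 0)
        bin_edges = np.arange(0, top + 100_000, 100_000, dtype=float)
    counts, edges = np.histogram(distances, bins=bin_edges)
    table = pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )
    if len(distances) == 0:
        logger.warning("loop_distance_histogram: empty loop list")
        return table, float("nan")
    frac = float((distances < threshold_bp).mean())
    return table, frac


# ---------------------------------------------------------------------------
# boundary scores, TADs
# ---------------------------------------------------------------------------


@dataclass
class BoundaryScoreTrack:
    chrom: str
    bin_size: int
    window_bp: int
    scores: np.ndarray  # NaN where the flanking windows are incomplete


@dataclass
class TAD:
    interval: GenomicInterval
    activity: float | None = None
    flagged: bool = False


def boundary_score(
    matrix: ContactMatrix, window_bp: int = DEFAULT_BOUNDARY_WINDOW
) -> BoundaryScoreTrack:
    """Insulation 'ratio' score per bin: cross-window contacts over
    flanking intra-window contacts; boundaries score low.

    For bin i with W = window/bin_size, the numerator is the mean over
    pixels {(a, b): i-W <= a < i < b <= i+W} and the denominator the mean
    of the two flanking intra-window triangle means.  Bins without a full
    window on both sides are NaN.
    """
    if window_bp % matrix.bin_size:
        raise ValueError("window_bp must be a multiple of the bin size")
    W = window_bp // matrix.bin_size
    n = matrix.n_bins
    if 2 * W + 1 > n:
        raise ValueError("window larger than chromosome")
    layer = (
        matrix.balanced if matrix.balanced is not None else matrix.counts
    ).astype(float)
    masked = matrix.mask()
    M = layer.copy()
    M[masked, :] = np.nan
    M[:, masked] = np.nan

    tri = np.triu(np.ones((W + 1, W + 1), dtype=bool), k=1)
    scores = np.full(n, np.nan)
    for i in range(W, n - W):
        cross = M[i - W : i, i + 1 : i + W + 1]
        cross_mean = np.nanmean(cross) if np.isfinite(cross).any() else np.nan
        left = M[i - W : i + 1, i - W : i + 1][tri]
        right = M[i : i + W + 1, i : i + W + 1][tri]
        lmean = np.nanmean(left) if np.isfinite(left).any() else np.nan
        rmean = np.nanmean(right) if np.isfinite(right).any() else np.nan
        denom = 0.5 * (lmean + rmean)
        if np.isfinite(denom) and denom > 0 and np.isfinite(cross_mean):
            scores[i] = cross_mean / denom
    return BoundaryScoreTrack(
        chrom=matrix.chrom,
        bin_size=matrix.bin_size,
        window_bp=window_bp,
        scores=scores,
    )


def call_boundaries(
    track: BoundaryScoreTrack,
    z_cutoff: float = 1.0,
    min_relative_depth: float = 0.05,
) -> list[int]:
    """Bins that are local score minima with z <= -z_cutoff.

    z is computed against the mean of the defined part of the track and a
    dispersion floored at ``min_relative_depth`` of the mean, so counting
    noise on an unstructured (flat or pure-decay) track cannot satisfy the
    cutoff: a boundary must dip by at least ~``min_relative_depth`` x
    ``z_cutoff`` relative to the track average.  Plateau minima collapse
    to their first bin.
    """
    s = track.scores
    valid = np.isfinite(s)
    if valid.sum() < 3:
        return []
    mu = float(s[valid].mean())
    sd = max(float(s[valid].std()), min_relative_depth * abs(mu))
    if sd < 1e-12:
        return []
    out: list[int] = []
    n = len(s)
    for i in range(n):
        if not valid[i]:
            continue
        # local minimum of the defined track; at a masked edge the test is
        # one-sided against the available neighbor
        neigh = [
            s[j]
            for j in (i - 1, i + 1)
            if 0 <= j < n and valid[j]
        ]
        if not neigh:
            continue
        if not all(s[i] <= v for v in neigh):
            continue
        if not any(s[i] < v for v in neigh):
            continue
        if (s[i] - mu) / sd > -z_cutoff:
            continue
        if out and i - out[-1] == 1 and s[i] == s[out[-1]]:
            continue  # plateau: keep the first bin
        out.append(i)
    return out


def tads_from_boundaries(
    boundaries: list[int],
    chrom: str,
    n_bins: int,
    bin_size: int,
) -> list[TAD]:
    """Intervals between consecutive boundaries, clipped to the chromosome."""
    cuts = [0] + sorted(b for b in boundaries if 0 < b < n_bins) + [n_bins]
    tads = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi <= lo:
            continue
        tads.append(
            TAD(
                interval=GenomicInterval(chrom, lo * bin_size, hi * bin_size)
            )
        )
    return tads


def intra_tad_activity(
    matrix: ContactMatrix,
    tads: list[TAD],
    expected: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean observed/expected over all intra-TAD pixels, per TAD.

    TADs spanning fewer than 3 bins are flagged.  Activity 1 means the
    TAD is exactly at the chromosome-wide distance expectation.
    """
    oe = oe_matrix(matrix, expected)
    rows = []
    for t in tads:
        lo = t.interval.start // matrix.bin_size
        hi = min(
            int(np.ceil(t.interval.end / matrix.bin_size)), matrix.n_bins
        )
        sub = oe[lo:hi, lo:hi]
        vals = sub[np.isfinite(sub)]
        activity = float(vals.mean()) if len(vals) else float("nan")
        flagged = (hi - lo) < 3
        t.activity = activity
        t.flagged = flagged
        rows.append(
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "n_bins": hi - lo,
                "activity": activity,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def loop_pixel_counts(
    matrix: ContactMatrix, loops: list[Loop], pad: int = 0
) -> np.ndarray:
    """Raw counts at each loop's anchor-midpoint pixel.

    ``pad`` extends the readout to a (2*pad+1)^2 window sum.  Out-of-range
    windows yield 0.
    """
    n = matrix.n_bins
    bs = matrix.bin_size
    out = np.zeros(len(loops))
    for k, lp in enumerate(loops):
        if lp.chrom != matrix.chrom:
            continue
        b1 = int(lp.anchor5.midpoint // bs)
        b2 = int(lp.anchor3.midpoint // bs)
        lo1, hi1 = max(0, b1 - pad), min(n, b1 + pad + 1)
        lo2, hi2 = max(0, b2 - pad), min(n, b2 + pad + 1)
        if lo1 >= hi1 or lo2 >= hi2:
            continue
        out[k] = matrix.counts[lo1:hi1, lo2:hi2].sum()
    return out


# ---------------------------------------------------------------------------
# differential activity
# ---------------------------------------------------------------------------


def differential_activity(
    feature_ids: list,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    fdr_cutoff: float = LOOP_FDR_CUTOFF,
    lfc_cutoff: float = LOOP_LFC_CUTOFF,
    cpm_prior: float = 0.5,
    lib_a: np.ndarray | None = None,
    lib_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """CPM-normalized differential activity of loops or TADs, B versus A.

    Counts are (n_features, n_replicates) per condition.  CPM divides by
    the per-replicate library size — the total mapped read pairs of the
    experiment (``lib_a``/``lib_b``), falling back to the per-condition
    column sums of the feature table when totals are not supplied.  The
    log2 fold change compares mean CPMs with a ``cpm_prior`` offset; the
    p-value is the two-sided conditional Poisson (binomial) rate test on
    pooled counts with library-size weighting; BH correction across
    features.  Significance requires both fdr <= ``fdr_cutoff`` and
    |log2FC| >= ``lfc_cutoff``.
    """
    A = np.atleast_2d(np.asarray(counts_a, dtype=float))
    B = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if A.shape[0] != len(feature_ids) or B.shape[0] != len(feature_ids):
        raise ValueError("counts must have one row per feature")
    if np.any(A < 0) or np.any(B < 0):
        raise ValueError("counts must be non-negative")
    lib_a = A.sum(axis=0) if lib_a is None else np.asarray(lib_a, dtype=float)
    lib_b = B.sum(axis=0) if lib_b is None else np.asarray(lib_b, dtype=float)
    if len(lib_a) != A.shape[1] or len(lib_b) != B.shape[1]:
        raise ValueError("library sizes must match replicate counts")
    if lib_a.sum() == 0 or lib_b.sum() == 0:
        raise ValueError("a condition has zero total counts")
    cpm_a = A / lib_a[None, :] * 1e6
    cpm_b = B / lib_b[None, :] * 1e6
    mean_a = cpm_a.mean(axis=1)
    mean_b = cpm_b.mean(axis=1)
    log2fc = np.log2(mean_b + cpm_prior) - np.log2(mean_a + cpm_prior)

    ka = A.sum(axis=1).round().astype(int)
    kb = B.sum(axis=1).round().astype(int)
    p_b = lib_b.sum() / (lib_a.sum() + lib_b.sum())
    pvals = np.ones(len(feature_ids))
    for i in range(len(feature_ids)):
        n = ka[i] + kb[i]
        if n > 0:
            pvals[i] = stats.binomtest(int(kb[i]), int(n), p_b).pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "feature": feature_ids,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": (fdr <= fdr_cutoff) & (np.abs(log2fc) >= lfc_cutoff),
        }
    )
    for r in range(A.shape[1]):
        df[f"cpm_a{r + 1}"] = cpm_a[:, r]
    for r in range(B.shape[1]):
        df[f"cpm_b{r + 1}"] = cpm_b[:, r]
    return df


# ---------------------------------------------------------------------------
# simple loop caller (synthetic pipelines only)
# ---------------------------------------------------------------------------


def simple_loop_call(
    matrix: ContactMatrix,
    fdr_cutoff: float = 0.05,
    min_distance_bins: int = 2,
) -> list[Loop]:
    """Minimal Poisson loop caller for synthetic end-to-end runs.

    Each raw pixel beyond the distance filter is tested one-sided against
    the raw per-distance expectation; BH-significant pixels are merged
    into 8-connected clusters and each cluster's maximum-count pixel is
    reported as a loop.  This is a deliberately simple caller for
    generated data, not a production Hi-C loop caller.
    """
    raw = ContactMatrix(
        chrom=matrix.chrom, bin_size=matrix.bin_size, counts=matrix.counts,
        masked=matrix.masked,
    )
    expected = expected_by_distance(raw)
    n = matrix.n_bins
    masked = matrix.mask()
    iu, ju = np.triu_indices(n, k=min_distance_bins)
    keep = ~(masked[iu] | masked[ju])
    iu, ju = iu[keep], ju[keep]
    mu = expected[ju - iu]
    obs = matrix.counts[iu, ju]
    ok = np.isfinite(mu) & (mu > 0)
    iu, ju, mu, obs = iu[ok], ju[ok], mu[ok], obs[ok]
    if len(obs) == 0:
        raise ValueError("no testable pixels")
    pvals = stats.poisson.sf(obs - 1, mu)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    sig = fdr <= fdr_cutoff
    if not sig.any():
        return []
    grid = np.zeros((n, n), dtype=bool)
    grid[iu[sig], ju[sig]] = True
    labels, n_lab = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    loops = []
    for lab in range(1, n_lab + 1):
        ii, jj = np.nonzero(labels == lab)
        k = np.lexsort((jj, ii, -matrix.counts[ii, jj]))[0]
        bi, bj = int(ii[k]), int(jj[k])
        bs = matrix.bin_size
        loops.append(
            Loop(
                GenomicInterval(matrix.chrom, bi * bs, (bi + 1) * bs),
                GenomicInterval(matrix.chrom, bj * bs, (bj + 1) * bs),
            )
        )
    loops.sort(key=lambda lp: (lp.anchor5.start, lp.anchor3.start))
    return loops
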