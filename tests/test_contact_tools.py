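"""Contact-matrix computations: balancing, APA, boundaries, differential."""

import numpy as np
import pandas as pd
import pytest

from loopgrammar import contact_tools as ct
from loopgrammar.io_formats import ContactMatrix, GenomicInterval, Loop

from conftest import sinkhorn_balance


def _matrix(counts, bin_size=20000, chrom="c"):
    return ContactMatrix(chrom, bin_size, np.asarray(counts, dtype=float))


def _loop(b1, b2, bs=5000, chrom="c"):
    return Loop(
        GenomicInterval(chrom, b1 * bs, (b1 + 1) * bs),
        GenomicInterval(chrom, b2 * bs, (b2 + 1) * bs),
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def test_bin_contacts_distance_filter_and_binning():
    pairs = [("c", 100000, 110000), ("c", 0, 50000)]
    m = ct.bin_contacts(pairs, chrom_length=200000)
    # the 10-kb pair is below the 25-kb filter
    assert m.counts.sum() == 2
    assert m.counts[0, 2] == 1 and m.counts[2, 0] == 1


def test_bin_contacts_matches_brute_force(rng):
    L = 1_000_000
    pairs = [
        ("c", int(a), int(b))
        for a, b in rng.integers(0, L, size=(500, 2))
    ]
    m = ct.bin_contacts(pairs, chrom_length=L)
    expected = sum(1 for _, a, b in pairs if abs(b - a) >= 25000)
    iu = np.triu_indices(m.n_bins)
    assert m.counts[iu].sum() == expected


def test_bin_contacts_rejects_negative_position():
    with pytest.raises(ValueError):
        ct.bin_contacts([("c", -5, 100000)], chrom_length=200000)


# ---------------------------------------------------------------------------
# ICE
# ---------------------------------------------------------------------------


def test_ice_constant_matrix_fixed_point():
    m = _matrix(np.ones((10, 10)))
    b = ct.ice_balance(m, mask_fraction=0.0)
    np.testing.assert_allclose(b.biases, b.biases[0])
    rows = b.balanced.sum(axis=1)
    np.testing.assert_allclose(rows, 1.0, rtol=1e-5)


def test_ice_matches_alternating_normalization_oracle(rng):
    a = rng.poisson(8, size=(6, 6)).astype(float)
    m = _matrix(a + a.T)
    b = ct.ice_balance(m, mask_fraction=0.0)
    oracle = sinkhorn_balance(m.counts)
    np.testing.assert_allclose(b.balanced, oracle, atol=1e-6)


def test_ice_masks_zero_rows(rng):
    a = rng.poisson(5, size=(8, 8)).astype(float)
    a = a + a.T
    a[3, :] = 0
    a[:, 3] = 0
    b = ct.ice_balance(_matrix(a), mask_fraction=0.0)
    assert b.masked[3]
    assert np.all(b.balanced[3, :] == 0)
    rows = b.balanced.sum(axis=1)[~b.masked]
    np.testing.assert_allclose(rows, 1.0, rtol=1e-5)


def test_ice_idempotent(rng):
    a = rng.poisson(6, size=(20, 20)).astype(float)
    b = ct.ice_balance(_matrix(a + a.T), mask_fraction=0.0)
    again = ct.ice_balance(
        ContactMatrix("c", 20000, b.balanced), mask_fraction=0.0
    )
    np.testing.assert_allclose(again.biases, 1.0, atol=1e-4)


def test_ice_nonconvergence_raises(rng):
    a = rng.poisson(5, size=(6, 6)).astype(float)
    with pytest.raises(ct.BalanceError) as err:
        ct.ice_balance(_matrix(a + a.T), max_iter=1, tol=1e-12)
    assert err.value.deviation > 0


# ---------------------------------------------------------------------------
# expected profile
# ---------------------------------------------------------------------------


def test_expected_constant_matrix_flat():
    e = ct.expected_by_distance(_matrix(np.ones((12, 12))))
    np.testing.assert_allclose(e, 1.0)


def test_expected_distance_zero_is_diagonal_mean():
    a = np.diag([2.0, 4.0, 6.0]) + 1.0
    e = ct.expected_by_distance(_matrix(0.5 * (a + a.T)))
    assert e[0] == pytest.approx(np.mean([3.0, 5.0, 7.0]))


def test_expected_recovers_decay_exponent():
    n = 200
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    m = _matrix(1000.0 * (d + 1.0) ** -1.0)
    e = ct.expected_by_distance(m)
    ds = np.arange(5, 100)
    slope = np.polyfit(np.log(ds + 1), np.log(e[ds]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.1)


def test_expected_all_zero_matrix_raises():
    with pytest.raises(ValueError, match="masked"):
        ct.expected_by_distance(_matrix(np.zeros((5, 5))))


# ---------------------------------------------------------------------------
# APA and P2LL
# ---------------------------------------------------------------------------


def test_apa_rejects_resolution_mismatch():
    m = _matrix(np.ones((50, 50)), bin_size=20000)
    with pytest.raises(ValueError, match="resolution"):
        ct.apa(m, [_loop(10, 40, bs=20000)], resolution=5000)


def test_apa_no_usable_loops_raises():
    m = _matrix(np.ones((50, 50)), bin_size=5000)
    with pytest.raises(ValueError, match="no loops"):
        ct.apa(m, [_loop(10, 12)], resolution=5000)  # crosses the diagonal


def test_apa_constant_matrix_gives_unit_aggregate():
    m = _matrix(np.ones((80, 80)), bin_size=5000)
    res = ct.apa(m, [_loop(20, 60)], resolution=5000)
    np.testing.assert_allclose(res.aggregate, 1.0)
    assert res.n_loops_used == 1
    assert res.p2ll == pytest.approx(1.0)


def test_apa_translation_invariance(rng):
    n = 120
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    base = 500.0 * (d + 1.0) ** -0.8
    m = _matrix(base, bin_size=5000)
    loops = [_loop(20, 60), _loop(30, 85)]
    r1 = ct.apa(m, loops, resolution=5000)
    shifted = [_loop(25, 65), _loop(35, 90)]
    r2 = ct.apa(m, shifted, resolution=5000)
    np.testing.assert_allclose(r1.aggregate, r2.aggregate, rtol=1e-9)


def test_p2ll_ratio_identity_and_scaling():
    agg = np.ones((21, 21))
    assert ct.p2ll(agg) == pytest.approx(1.0)
    agg[10, 10] = 5.0
    assert ct.p2ll(agg) == pytest.approx(5.0)
    agg[10, 10] = 10.0
    assert ct.p2ll(agg) == pytest.approx(10.0)


def test_p2ll_uses_near_diagonal_corner():
    agg = np.ones((21, 21))
    agg[14:, :7] = 2.0  # the lower-left (near-diagonal) block
    assert ct.p2ll(agg, corner_bins=7) == pytest.approx(0.5)
    assert ct.p2ll(agg, corner_bins=7, corner="upper_right") == pytest.approx(1.0)


def test_p2ll_rejects_zero_corner():
    agg = np.zeros((11, 11))
    agg[5, 5] = 1.0
    with pytest.raises(ValueError, match="corner"):
        ct.p2ll(agg)


# ---------------------------------------------------------------------------
# loop distances
# ---------------------------------------------------------------------------


def test_loop_distance_fraction_below_2mb():
    loops = [
        _loop(0, 50, bs=20000),   # 1 Mb
        _loop(0, 50, bs=20000),
        _loop(0, 150, bs=20000),  # 3 Mb
    ]
    _, frac = ct.loop_distance_histogram(loops)
    assert frac == pytest.approx(2 / 3)


def test_loop_distance_empty_flagged():
    table, frac = ct.loop_distance_histogram([])
    assert np.isnan(frac) and table["count"].sum() == 0


def test_loop_distance_sampling_check(rng):
    # 90% of mass below 2 Mb by construction
    dists = np.where(
        rng.random(4000) < 0.9,
        rng.uniform(100_000, 1_900_000, 4000),
        rng.uniform(2_100_000, 4_000_000, 4000),
    )
    loops = [
        Loop(
            GenomicInterval("c", 0, 100),
            GenomicInterval("c", int(d), int(d) + 100),
        )
        for d in dists
    ]
    _, frac = ct.loop_distance_histogram(loops)
    assert frac == pytest.approx(0.9, abs=0.03)


# ---------------------------------------------------------------------------
# boundary scores and TADs
# ---------------------------------------------------------------------------


def test_boundary_score_zero_at_perfect_junction():
    n, W = 60, 5
    a = np.zeros((n, n))
    a[:30, :30] = 1.0
    a[30:, 30:] = 1.0
    track = ct.boundary_score(_matrix(a), window_bp=W * 20000)
    assert track.scores[30] == pytest.approx(0.0)


def test_boundary_score_constant_matrix_flat_interior():
    track = ct.boundary_score(_matrix(np.ones((60, 60))), window_bp=100000)
    interior = track.scores[np.isfinite(track.scores)]
    np.testing.assert_allclose(interior, interior[0])


def test_boundary_score_rejects_oversized_window():
    with pytest.raises(ValueError, match="window"):
        ct.boundary_score(_matrix(np.ones((10, 10))), window_bp=500000)


def test_call_boundaries_flat_track_none():
    track = ct.BoundaryScoreTrack("c", 20000, 100000, np.ones(50))
    assert ct.call_boundaries(track) == []


def test_call_boundaries_single_minimum_two_tads():
    scores = np.full(50, 0.8)
    scores[:5] = np.nan
    scores[-5:] = np.nan
    scores[25] = 0.1
    track = ct.BoundaryScoreTrack("c", 20000, 100000, scores)
    bounds = ct.call_boundaries(track, z_cutoff=1.0)
    assert bounds == [25]
    tads = ct.tads_from_boundaries(bounds, "c", 50, 20000)
    assert len(tads) == 2
    assert tads[0].interval.end == tads[1].interval.start == 25 * 20000


def test_intra_tad_activity_oe_identity_and_doubling():
    n = 60
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    base = 100.0 * (d + 1.0) ** -1.0
    m = _matrix(base)
    tads = [
        ct.TAD(GenomicInterval("c", 0, 20 * 20000)),
        ct.TAD(GenomicInterval("c", 20 * 20000, 21 * 20000)),
    ]
    table = ct.intra_tad_activity(m, tads)
    assert table.iloc[0].activity == pytest.approx(1.0)
    assert bool(table.iloc[1].flagged)  # < 3 bins

    doubled = base.copy()
    doubled[:20, :20] *= 2.0
    # activity of the doubled TAD relative to its own expectation rises
    t2 = ct.intra_tad_activity(_matrix(doubled), tads)
    assert t2.iloc[0].activity > 1.5


# ---------------------------------------------------------------------------
# differential activity
# ---------------------------------------------------------------------------


def test_differential_identical_conditions_null():
    counts = np.arange(1, 21).reshape(10, 2) * 5
    df = ct.differential_activity(list(range(10)), counts, counts.copy())
    np.testing.assert_allclose(df["log2fc"], 0.0)
    assert not df["significant"].any()


def test_differential_fdr_above_cutoff_not_significant():
    df = pd.DataFrame(
        {
            "feature": [0],
            "log2fc": [-2.0],
            "pvalue": [0.01],
            "fdr": [0.01],
        }
    )
    # the loop-level rule: FDR 0.01 fails a 0.005 cutoff
    sig = (df["fdr"] <= 0.005) & (df["log2fc"].abs() >= 1.5)
    assert not sig.any()
    # and through the implementation: a feature whose test lands above the
    # cutoff must not be flagged even at huge fold change
    counts_a = np.array([[12, 9], [1000, 1100]])
    counts_b = np.array([[3, 4], [1000, 950]])
    out = ct.differential_activity(
        [0, 1], counts_a, counts_b, fdr_cutoff=0.005, lfc_cutoff=1.5
    )
    assert out.loc[out["fdr"] > 0.005, "significant"].eq(False).all()


def test_differential_label_swap_negates_lfc(rng):
    A = rng.poisson(30, size=(40, 2))
    B = rng.poisson(18, size=(40, 2))
    fwd = ct.differential_activity(list(range(40)), A, B)
    rev = ct.differential_activity(list(range(40)), B, A)
    np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
    np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)


def test_differential_zero_condition_raises():
    with pytest.raises(ValueError, match="zero total"):
        ct.differential_activity(
            [0], np.array([[5, 5]]), np.array([[0, 0]])
        )


# ---------------------------------------------------------------------------
# simple loop caller
# ---------------------------------------------------------------------------


def test_simple_loop_call_recovers_strong_pixel(rng):
    n = 100
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mu = 200.0 * (d + 1.0) ** -1.0
    counts = rng.poisson(mu)
    counts[20, 60] = counts[60, 20] = int(10 * mu[20, 60]) + 50
    m = _matrix(0.5 * (counts + counts.T) * 2, bin_size=20000)
    loops = ct.simple_loop_call(m, fdr_cutoff=0.01)
    assert any(
        lp.anchor5.start // 20000 == 20 and lp.anchor3.start // 20000 == 60
        for lp in loops
    )


def test_simple_loop_call_null_calibration():
    n = 100
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mu = 100.0 * (d + 1.0) ** -1.0
    false_runs = 0
    for seed in range(10):
        counts = np.random.default_rng(seed).poisson(mu)
        m = _matrix(np.triu(counts) + np.triu(counts, 1).T, bin_size=20000)
        if ct.simple_loop_call(m, fdr_cutoff=0.05):
            false_runs += 1
    assert false_runs == 0


def test_simple_loop_call_empty_matrix_propagates_error():
    with pytest.raises(ValueError):
        ct.simple_loop_call(_matrix(np.zeros((20, 20))))
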