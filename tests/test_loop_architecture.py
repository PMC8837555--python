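"""Anchor annotation, orientation classification and spacing analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopgrammar import loop_architecture as la
from loopgrammar.io_formats import GenomicInterval, Loop
from loopgrammar.motif_scan import MotifHit
from loopgrammar.synthetic_data import default_maz_pwm


def _loop(chrom="c", a5=(0, 5000), a3=(20000, 25000)):
    return Loop(
        GenomicInterval(chrom, *a5), GenomicInterval(chrom, *a3)
    )


def _hit(start, strand, score=10.0, chrom="c", length=7, p=1e-4):
    return MotifHit(chrom, start, start + length, strand, score, p)


# ---------------------------------------------------------------------------
# search regions and signal filter
# ---------------------------------------------------------------------------


def test_anchor_search_regions_intersections():
    lp = _loop()
    peaks = [
        GenomicInterval("c", 4000, 6000),
        GenomicInterval("c", 21000, 21500),
        GenomicInterval("c", 23000, 23800),
    ]
    r5, r3 = la.anchor_search_regions(lp, peaks)
    assert [(r.start, r.end) for r in r5] == [(4000, 5000)]
    assert [(r.start, r.end) for r in r3] == [(21000, 21500), (23000, 23800)]


def test_anchor_search_regions_no_overlap_empty():
    r5, r3 = la.anchor_search_regions(
        _loop(), [GenomicInterval("c", 50000, 51000)]
    )
    assert r5 == [] and r3 == []


def test_filter_loops_by_signal_binary_rule(rng):
    loops = [
        _loop(a5=(i * 100000, i * 100000 + 5000),
              a3=(i * 100000 + 50000, i * 100000 + 55000))
        for i in range(20)
    ]
    signals = rng.uniform(0, 10, size=(20, 2))
    peaks = []
    for lp, (s5, s3) in zip(loops, signals):
        peaks.append(
            GenomicInterval("c", lp.anchor5.start, lp.anchor5.end, signal=s5)
        )
        peaks.append(
            GenomicInterval("c", lp.anchor3.start, lp.anchor3.end, signal=s3)
        )
    tracks = {"CTCF": peaks}
    # vacuous cutoff keeps everything
    assert len(la.filter_loops_by_signal(loops, tracks, {"CTCF": 0.0})) == 20
    # brute-force oracle at a real cutoff
    cutoff = 4.0
    expected = [lp for lp, (s5, s3) in zip(loops, signals)
                if s5 >= cutoff and s3 >= cutoff]
    got = la.filter_loops_by_signal(loops, tracks, {"CTCF": cutoff})
    assert got == expected
    with pytest.raises(KeyError):
        la.filter_loops_by_signal(loops, tracks, {"MAZ": 1.0})


# ---------------------------------------------------------------------------
# motif assignment
# ---------------------------------------------------------------------------


def test_assign_requires_hit_inside_peak():
    lp = _loop()
    peaks = {"CTCF": [GenomicInterval("c", 4000, 4500)]}
    inside = _hit(4100, "+")
    outside_peak = _hit(1000, "+", score=99.0)  # in anchor, outside peaks
    anns = la.assign_anchor_motifs(
        [lp], {"CTCF": [inside, outside_peak]}, peaks
    )
    assert anns[0].hits5["CTCF"].start == 4100
    assert anns[0].hits3["CTCF"] is None


def test_assign_keeps_highest_scoring_hit():
    lp = _loop()
    peaks = {"CTCF": [GenomicInterval("c", 4000, 5000)]}
    anns = la.assign_anchor_motifs(
        [lp],
        {"CTCF": [_hit(4100, "+", 8.2), _hit(4200, "-", 11.5)]},
        peaks,
    )
    assert anns[0].hits5["CTCF"].score == 11.5


def test_assign_respects_p_cutoff():
    lp = _loop()
    peaks = {"CTCF": [GenomicInterval("c", 4000, 5000)]}
    weak = _hit(4100, "+", p=0.5)
    anns = la.assign_anchor_motifs([lp], {"CTCF": [weak]}, peaks, p_cutoff=1e-3)
    assert anns[0].hits5["CTCF"] is None


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "s5,s3,expected",
    [
        ("+", "-", "convergent"),
        ("-", "+", "divergent"),
        ("+", "+", "tandem"),
        ("-", "-", "tandem"),
    ],
)
def test_classify_orientation_strand_table(s5, s3, expected):
    ann = la.AnchorAnnotation(
        loop=_loop(),
        hits5={"CTCF": _hit(1000, s5)},
        hits3={"CTCF": _hit(21000, s3)},
    )
    assert la.classify_orientation(ann, "CTCF").call == expected


def test_classify_orientation_missing_hit_unclassified():
    ann = la.AnchorAnnotation(
        loop=_loop(), hits5={"CTCF": _hit(1000, "+")}, hits3={"CTCF": None}
    )
    assert la.classify_orientation(ann, "CTCF").call == "unclassified"


def _calls(seq):
    return [
        la.OrientationCall(loop=_loop(), factor="CTCF", call=c) for c in seq
    ]


def test_orientation_proportions_counting():
    props = la.orientation_proportions(
        _calls(["convergent", "convergent", "tandem", "divergent"])
    )
    row = props.iloc[0]
    assert (row.prop_convergent, row.prop_tandem, row.prop_divergent) == (
        0.5, 0.25, 0.25,
    )
    assert row.n_classified == 4 and not row.flagged


def test_orientation_proportions_sum_to_one(rng):
    seq = list(
        rng.choice(["convergent", "tandem", "divergent", "unclassified"], 50)
    )
    props = la.orientation_proportions(_calls(seq))
    row = props.iloc[0]
    if row.n_classified:
        total = row.prop_convergent + row.prop_tandem + row.prop_divergent
        assert total == pytest.approx(1.0, abs=1e-12)


def test_orientation_proportions_flags_empty_group():
    props = la.orientation_proportions(_calls(["unclassified"] * 3))
    assert bool(props.iloc[0].flagged)
    assert np.isnan(props.iloc[0].prop_convergent)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.permutations(["convergent"] * 3 + ["tandem"] * 2 + ["divergent"]))
def test_orientation_proportions_order_invariant(perm):
    props = la.orientation_proportions(_calls(list(perm)))
    row = props.iloc[0]
    assert (row.n_convergent, row.n_tandem, row.n_divergent) == (3, 2, 1)


# ---------------------------------------------------------------------------
# relative orientation and spacing
# ---------------------------------------------------------------------------


def test_relative_orientation_positional():
    ctcf = _hit(990, "+", length=20)  # mid 1000
    maz_in = _hit(1076, "+")  # mid 1079.5
    assert la.relative_orientation(ctcf, maz_in, "5") == "inside"
    ctcf3 = _hit(4990, "+", length=20)  # mid 5000
    maz_out = _hit(5076, "+")
    assert la.relative_orientation(ctcf3, maz_out, "3") == "outside"
    # identical midpoints tie to outside
    a = _hit(100, "+", length=7)
    b = _hit(100, "-", length=7)
    assert la.relative_orientation(a, b, "5") == "outside"


def test_relative_orientation_strand_mode():
    ctcf = _hit(1000, "+")
    assert la.relative_orientation(ctcf, _hit(1100, "+"), "5", mode="strand") == "inside"
    assert la.relative_orientation(ctcf, _hit(1100, "-"), "3", mode="strand") == "inside"


def test_relative_orientation_rejects_trans():
    with pytest.raises(ValueError):
        la.relative_orientation(
            _hit(0, "+", chrom="c1"), _hit(0, "+", chrom="c2"), "5"
        )


def test_dedupe_primary_hits_keeps_best_overlap():
    hits = [_hit(100, "+", 5.0), _hit(103, "-", 9.0), _hit(300, "+", 2.0)]
    kept = la.dedupe_primary_hits(hits)
    assert [(h.start, h.score) for h in kept] == [(103, 9.0), (300, 2.0)]


def test_spacing_no_secondary_hits():
    rng = np.random.default_rng(0)
    # AT-only genome cannot contain the GC-rich motif
    genome = {"c": "".join(rng.choice(["A", "T"], 5000))}
    primaries = [_hit(1000, "+", length=19, chrom="c"),
                 _hit(3000, "-", length=19, chrom="c")]
    res = la.spacing_analysis(primaries, default_maz_pwm(), genome)
    assert res.n_sites_used == 0 and res.n_sites_no_hit == 2
    assert res.table["count"].sum() == 0
    assert (res.table["pvalue"] == 1.0).all()


def test_spacing_recovers_planted_offset():
    rng = np.random.default_rng(1)
    seq = list(rng.choice(["A", "T"], 120000))
    primaries = []
    for k in range(60):
        center = 1000 + k * 2000
        primaries.append(
            _hit(center - 9, "+", length=19, chrom="c", score=30.0)
        )
        # plant GGGAGGG centered at +85 from the primary midpoint
        m_start = int(center + 0.5 + 85 - 3.5)
        seq[m_start : m_start + 7] = list("GGGAGGG")
    genome = {"c": "".join(seq)}
    res = la.spacing_analysis(primaries, default_maz_pwm(), genome)
    assert res.n_sites_used == 60
    lo = res.table.loc[res.table["count"].idxmax(), "bin_lo"]
    assert lo <= 85 <= lo + res.bin_width
    assert res.table["fdr"].min() < 0.05


def test_spacing_skips_sites_at_chromosome_bounds():
    genome = {"c": "A" * 600}
    res = la.spacing_analysis(
        [_hit(10, "+", length=19, chrom="c")], default_maz_pwm(), genome
    )
    assert res.n_sites_skipped == 1


def test_spacing_rejects_odd_window():
    with pytest.raises(ValueError):
        la.spacing_analysis([], default_maz_pwm(), {}, window_bp=501)
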