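import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagegrn.bidirectional import (
    annotate_nearest_gene,
    balance_score,
    call_bidirectional,
    categorize_regions,
    filter_bidirectional,
    normalize_width,
    overlap_upset,
)
from cagegrn.formats_io import AnnotationRecord, intervals_from_tuples
from tests.conftest import profile_from_positions


def ideal_enhancer(mid, tags=50.0, arm=60):
    """Balanced divergent site: minus tags upstream, plus tags downstream."""
    return [
        ("chr1", mid - arm, "-", tags),
        ("chr1", mid + arm, "+", tags),
    ]


# -- balance_score --------------------------------------------------------


def test_balance_perfectly_balanced():
    pooled = profile_from_positions(ideal_enhancer(1000))
    assert balance_score(pooled, "chr1", 1000) == pytest.approx(1.0)


def test_balance_unidirectional_is_sqrt_half():
    pooled = profile_from_positions([("chr1", 1060, "+", 100.0)])
    b = balance_score(pooled, "chr1", 1000)
    assert b == pytest.approx(math.sqrt(0.5))
    assert b < 0.95  # rejected at the calling threshold


def test_balance_zero_signal():
    pooled = profile_from_positions([("chr1", 5000, "+", 1.0)])
    assert balance_score(pooled, "chr1", 1000) == 0.0


def test_balance_even_window_errors():
    pooled = profile_from_positions(ideal_enhancer(1000))
    with pytest.raises(ValueError):
        balance_score(pooled, "chr1", 1000, window=200)


def test_balance_wrong_arm_signal_lowers_score():
    # plus-strand signal on the upstream arm contributes to T only
    pooled = profile_from_positions(
        ideal_enhancer(1000) + [("chr1", 940, "+", 100.0)]
    )
    assert balance_score(pooled, "chr1", 1000) < 1.0


def test_balance_scale_invariance():
    pooled = profile_from_positions(
        [("chr1", 950, "-", 3.0), ("chr1", 1070, "+", 9.0)]
    )
    scaled = pooled.scale(17.3)
    assert balance_score(pooled, "chr1", 1000) == pytest.approx(
        balance_score(scaled, "chr1", 1000)
    )


def test_balance_mirror_symmetry():
    # mirroring the window (strand and orientation flipped) preserves B
    mid = 1000
    entries = [("chr1", 950, "-", 3.0), ("chr1", 1080, "+", 5.0), ("chr1", 990, "-", 2.0)]
    mirrored = [
        ("chr1", 2 * mid - p, {"+": "-", "-": "+"}[s], v) for _, p, s, v in entries
    ]
    b1 = balance_score(profile_from_positions(entries), "chr1", mid)
    b2 = balance_score(profile_from_positions(mirrored), "chr1", mid)
    assert b1 == pytest.approx(b2)


# -- call_bidirectional: brute-force oracle -------------------------------


def oracle_call(pooled, window=201, threshold=0.95, max_gap=20, span=(0, 3000)):
    """Exhaustive per-base scan + explicit merge loop."""
    qualifying = [
        (m, balance_score(pooled, "chr1", m, window))
        for m in range(span[0], span[1])
    ]
    qualifying = [(m, b) for m, b in qualifying if b >= threshold]
    regions = []
    for m, b in qualifying:
        if regions and m - regions[-1][-1][0] <= max_gap:
            regions[-1].append((m, b))
        else:
            regions.append([(m, b)])
    out = []
    for run in regions:
        best_b = max(b for _, b in run)
        best_m = min(m for m, b in run if b == best_b)
        out.append((run[0][0], run[-1][0] + 1, best_m, best_b))
    return out


def test_single_ideal_enhancer_called_once():
    pooled = profile_from_positions(ideal_enhancer(1000))
    regions = call_bidirectional(pooled)
    assert len(regions) == 1
    r = regions[0]
    oracle = oracle_call(pooled)
    assert len(oracle) == 1
    assert (r.start, r.end, r.mid, r.balance) == pytest.approx(oracle[0])
    assert abs(r.mid - 1000) <= 50


def test_pure_tss_cluster_not_called():
    pooled = profile_from_positions(
        [("chr1", 1000 + o, "+", v) for o, v in [(0, 40.0), (2, 30.0), (5, 20.0)]]
    )
    assert call_bidirectional(pooled) == []


def test_two_enhancers_one_kb_apart():
    pooled = profile_from_positions(ideal_enhancer(1000) + ideal_enhancer(2000))
    regions = call_bidirectional(pooled)
    assert len(regions) == 2
    assert oracle_call(pooled) == [
        (r.start, r.end, r.mid, pytest.approx(r.balance)) for r in regions
    ]


def test_regions_never_overlap():
    pooled = profile_from_positions(
        ideal_enhancer(1000) + ideal_enhancer(1400) + ideal_enhancer(2500)
    )
    regions = call_bidirectional(pooled)
    for a, b in zip(regions, regions[1:]):
        assert a.end <= b.start


@settings(max_examples=30, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.integers(100, 900),  # position
            st.sampled_from(["+", "-"]),
            st.floats(0.5, 50.0),
        ),
        min_size=1,
        max_size=40,
        unique_by=lambda t: (t[0], t[1]),
    ),
    threshold=st.sampled_from([0.8, 0.95]),
)
def test_call_matches_exhaustive_scan(data, threshold):
    pooled = profile_from_positions([("chr1", p, s, v) for p, s, v in data])
    got = call_bidirectional(pooled, balance_threshold=threshold)
    expected = oracle_call(pooled, threshold=threshold, span=(0, 1100))
    assert [(r.start, r.end, r.mid) for r in got] == [e[:3] for e in expected]
    for r, e in zip(got, expected):
        assert r.balance == pytest.approx(e[3])


# -- filter_bidirectional -------------------------------------------------


def test_support_filter():
    pooled = profile_from_positions(ideal_enhancer(1000))
    (region,) = call_bidirectional(pooled)
    with_tags = profile_from_positions(ideal_enhancer(1000))
    empty = profile_from_positions([("chr1", 90000, "+", 1.0)])
    assert filter_bidirectional([region], [with_tags, empty, empty]) == []
    kept = filter_bidirectional([region], [with_tags, with_tags, empty])
    assert len(kept) == 1 and kept[0].support == 2


def test_support_filter_min1_identity():
    pooled = profile_from_positions(ideal_enhancer(1000))
    regions = call_bidirectional(pooled)
    assert (
        filter_bidirectional(regions, [profile_from_positions(ideal_enhancer(1000))], 1)
        == regions
    )


# -- normalize_width ------------------------------------------------------


def _region(mid, chrom="chr1"):
    from cagegrn.bidirectional import BidirectionalRegion

    return BidirectionalRegion(chrom, mid, mid - 5, mid + 5, 1.0, 10.0, 3)


def test_normalize_width_interior():
    (r,) = normalize_width([_region(1000)])
    assert (r.norm_start, r.norm_end) == (900, 1100)


def test_normalize_width_clipped_with_warning():
    with pytest.warns(UserWarning, match="clipped"):
        (r,) = normalize_width([_region(50)], chrom_lengths={"chr1": 10_000})
    assert (r.norm_start, r.norm_end) == (0, 150)


def test_normalize_width_preserved_for_interior():
    regions = normalize_width([_region(m) for m in (500, 5000, 7777)])
    assert all(r.norm_end - r.norm_start == 200 for r in regions)


# -- annotate_nearest_gene ------------------------------------------------


GENES = [
    AnnotationRecord("GA", "chr1", "+", 10_000, 10_000, 12_000),
    AnnotationRecord("GB", "chr1", "+", 40_000, 40_000, 42_000),
    AnnotationRecord("GC", "chr1", "-", 90_000, 88_000, 90_001),
]


def test_region_at_tss():
    (ann,) = annotate_nearest_gene([_region(10_000)], GENES)
    assert (ann.gene, ann.signed_distance, ann.distance_bin) == ("GA", 0, 0)


def test_region_in_second_bin():
    (ann,) = annotate_nearest_gene([_region(17_300)], GENES)
    assert ann.gene == "GA"
    assert ann.distance_bin == 1  # [5, 10) kb


def test_nearest_gene_matches_bruteforce():
    rng = np.random.default_rng(0)
    regions = [_region(int(m)) for m in rng.integers(0, 100_000, size=5)]
    anns = annotate_nearest_gene(regions, GENES)
    for r, a in zip(regions, anns):
        d_oracle = min(abs(r.mid - g.tss) for g in GENES)
        assert abs(a.signed_distance) == d_oracle


def test_unassociated_region_flagged():
    (ann,) = annotate_nearest_gene([_region(10_000)], GENES, max_distance=0)
    assert ann.gene == "GA"
    (far,) = annotate_nearest_gene([_region(20_000)], GENES, max_distance=1000)
    assert far.gene is None


# -- categorize_regions ---------------------------------------------------


def test_promoter_precedence_over_gene_body():
    genes = [
        AnnotationRecord("GA", "chr1", "+", 10_000, 10_000, 12_000),
        AnnotationRecord("GB", "chr1", "+", 5_000, 5_000, 50_000),  # big host gene
    ]
    counts = categorize_regions([_region(10_200)], genes)
    assert counts == Counter({"promoter": 1})


def test_categories_partition():
    regions = [_region(m) for m in (10_000, 13_000, 11_500, 300_000)]
    counts = categorize_regions(regions, GENES)
    assert sum(counts.values()) == len(regions)


def test_distal_category():
    counts = categorize_regions([_region(170_000)], GENES)
    assert counts == Counter({"distal": 1})


# -- overlap_upset --------------------------------------------------------


def test_upset_no_peaks():
    regions = [_region(1000), _region(2000)]
    table = overlap_upset(regions, {})
    assert table == {(): 2}


def test_upset_pairwise_cell_only():
    regions = normalize_width([_region(1000)])
    peaks = {
        "h3k27ac": intervals_from_tuples({"chr1": [(900, 1100)]}),
        "h3k4me1": intervals_from_tuples({"chr1": [(950, 1050)]}),
    }
    table = overlap_upset(regions, peaks)
    assert table[("h3k27ac", "h3k4me1")] == 1
    assert table[("h3k27ac",)] == 0 and table[("h3k4me1",)] == 0


def test_upset_matches_bruteforce_membership():
    rng = np.random.default_rng(1)
    regions = normalize_width([_region(int(m)) for m in rng.integers(500, 50_000, 20)])
    peak_sets = {}
    for name in ("a", "b", "c"):
        ivs = sorted(
            (int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 50_000, 15), rng.integers(50, 800, 15))
        )
        peak_sets[name] = intervals_from_tuples({"chr1": ivs})
    table = overlap_upset(regions, peak_sets)
    oracle = Counter()
    for r in regions:
        start, end = r.interval
        members = tuple(
            n
            for n in sorted(peak_sets)
            if any(s < end and e > start for s, e in peak_sets[n]["chr1"].tolist())
        )
        oracle[members] += 1
    assert {k: v for k, v in table.items() if v} == dict(oracle)
    assert sum(table.values()) == len(regions)
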