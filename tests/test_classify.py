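"""WW/SS counting, Type 1-4 assignment, dNPS and the dyad frequency profile."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucpattern._seq import encode, revcomp
from nucpattern.classify import (
    EmptyInputError,
    NCPFragment,
    NPSSummary,
    PatternCounts,
    classify_counts,
    classify_fragment,
    classify_fragments,
    count_dinucleotides,
    dyad_frequency_profile,
    summarize,
)
from .conftest import naive_site_counts, random_dna

dna_fragment = st.text(alphabet="ACGT", min_size=147, max_size=147)


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("A" * 147, dict(ww_minor=36, ww_major=32, ss_minor=0, ss_major=0)),
        ("G" * 147, dict(ww_minor=0, ww_major=0, ss_minor=36, ss_major=32)),
        ("AC" * 73 + "A", dict(ww_minor=0, ww_major=0, ss_minor=0, ss_major=0)),
    ],
)
def test_count_dinucleotides_extremes(gbs_map, sequence, expected):
    counts = count_dinucleotides(NCPFragment("chr1", 0, sequence), gbs_map)
    assert counts == PatternCounts(**expected)


def test_fragment_validation_rejects_bad_input():
    with pytest.raises(ValueError, match="147"):
        NCPFragment("chr1", 0, "A" * 150)
    with pytest.raises(ValueError, match="non-ACGT"):
        NCPFragment("chr1", 0, "N" * 147)


@pytest.mark.parametrize(
    "counts,expected_type",
    [
        ((36, 32, 0, 0), 1),  # all-A fragment: both predicates tie
        ((0, 32, 36, 0), 4),  # constructed anti-pattern fragment
        ((30, 20, 30, 20), 2),  # both classes minor-enriched
        ((0, 20, 0, 20), 3),
    ],
)
def test_classification_predicates(counts, expected_type):
    assert classify_counts(*counts) == expected_type


def test_classify_fragment_wrapper(gbs_map):
    frag = NCPFragment("chr1", 0, "A" * 147)
    assert classify_fragment(count_dinucleotides(frag, gbs_map)) == 1


def test_partition_exhaustive_grid():
    """The four predicate rows partition the whole count space."""
    coef = 1.125
    ww_minor, ww_major, ss_minor, ss_major = np.meshgrid(
        np.arange(37), np.arange(33), np.arange(0, 37, 3), np.arange(0, 33, 3), indexing="ij"
    )
    # independently written predicates, one per row of the table
    t1 = (ww_minor >= ww_major * coef) & (ss_minor <= ss_major * coef)
    t2 = (ww_minor >= ww_major * coef) & (ss_minor > ss_major * coef)
    t3 = (ww_minor < ww_major * coef) & (ss_minor <= ss_major * coef)
    t4 = (ww_minor < ww_major * coef) & (ss_minor > ss_major * coef)
    fired = t1.astype(int) + t2 + t3 + t4
    assert (fired == 1).all()
    expected = np.select([t1, t2, t3, t4], [1, 2, 3, 4])
    assert (classify_counts(ww_minor, ww_major, ss_minor, ss_major) == expected).all()


def test_count_matches_naive_scan(gbs_map, rng):
    """Vectorised site counting equals a 146-position membership scan."""
    for _ in range(200):
        seq = random_dna(rng, 147, gc=rng.uniform(0.2, 0.8))
        got = count_dinucleotides(NCPFragment("c", 0, seq), gbs_map)
        want = naive_site_counts(seq, gbs_map)
        assert got == PatternCounts(**want)


@settings(max_examples=60, deadline=None)
@given(dna_fragment)
def test_revcomp_invariance(gbs_map, sequence):
    """WW and SS are closed under reverse complement and the map is
    mirror-symmetric, so classification is strand-independent."""
    a = classify_fragment(count_dinucleotides(NCPFragment("c", 0, sequence), gbs_map))
    b = classify_fragment(count_dinucleotides(NCPFragment("c", 0, revcomp(sequence)), gbs_map))
    assert a == b


@settings(max_examples=60, deadline=None)
@given(dna_fragment)
def test_ws_swap_exchanges_counts_and_types(gbs_map, sequence):
    """A<->G, T<->C swaps W and S bases, hence the WW and SS counts."""
    swapped = sequence.translate(str.maketrans("AGTC", "GACT"))
    c1 = count_dinucleotides(NCPFragment("c", 0, sequence), gbs_map)
    c2 = count_dinucleotides(NCPFragment("c", 0, swapped), gbs_map)
    assert (c2.ss_minor, c2.ss_major) == (c1.ww_minor, c1.ww_major)
    assert (c2.ww_minor, c2.ww_major) == (c1.ss_minor, c1.ss_major)
    coef = 1.125
    tie_free = (
        c1.ww_minor != c1.ww_major * coef
        and c1.ss_minor != c1.ss_major * coef
        and c2.ww_minor != c2.ww_major * coef
        and c2.ss_minor != c2.ss_major * coef
    )
    if tie_free:
        # exchanging WW and SS counts inverts Type 1 <-> Type 4; Types 2 and 3
        # ("both classes in the same groove") are fixed points of the swap
        mapping = {1: 4, 2: 2, 3: 3, 4: 1}
        assert classify_fragment(c2) == mapping[classify_fragment(c1)]


def test_summary_dnps_from_fractions():
    s = NPSSummary(n_fragments=100, fraction_type=(41.0, 20.0, 15.0, 24.0))
    assert s.dnps == pytest.approx(17.0)


def test_summarize_all_identical(gbs_map):
    frags = [NCPFragment("c", 0, "A" * 147)] * 5
    s = summarize(frags, gbs_map)
    assert s.fraction_type == (100.0, 0.0, 0.0, 0.0)
    assert s.dnps == 100.0


def test_summarize_balanced_types_cancel(gbs_map, rng):
    from nucpattern.synth import synth_fragment

    frags = [synth_fragment(1, 1.0, gbs_map, seed=i) for i in range(10)]
    frags += [synth_fragment(4, 1.0, gbs_map, seed=i + 100) for i in range(10)]
    s = summarize(frags, gbs_map)
    assert s.dnps == pytest.approx(0.0)
    assert sum(s.fraction_type) == pytest.approx(100.0, abs=1e-9)


def test_summarize_empty_errors(gbs_map):
    with pytest.raises(EmptyInputError):
        summarize([], gbs_map)


def test_summarize_fractions_sum_100(gbs_map, rng):
    frags = np.vstack([encode(random_dna(rng, 147)) for _ in range(500)])
    s = summarize(frags, gbs_map)
    assert sum(s.fraction_type) == pytest.approx(100.0, abs=1e-9)


def test_pattern_counts_capacity_guard():
    with pytest.raises(ValueError):
        PatternCounts(ww_minor=30, ww_major=0, ss_minor=30, ss_major=0)


class TestDyadFrequencyProfile:
    def test_all_a_fragments(self, gbs_map):
        prof = dyad_frequency_profile([NCPFragment("c", 0, "A" * 147)] * 3)
        assert np.allclose(prof.ww_freq, 1.0)
        assert np.allclose(prof.ss_freq, 0.0)

    def test_symmetrized_profile_is_mirror_symmetric(self, rng):
        frags = np.vstack([encode(random_dna(rng, 147, gc=0.4)) for _ in range(50)])
        prof = dyad_frequency_profile(frags)
        assert np.allclose(prof.ww_freq, prof.ww_freq[::-1])
        assert np.allclose(prof.ss_freq, prof.ss_freq[::-1])

    def test_position_reversal_invariance(self, rng):
        seqs = [random_dna(rng, 147) for _ in range(20)]
        a = dyad_frequency_profile(np.vstack([encode(s) for s in seqs]))
        # reversing every fragment about the dyad gives the same profile
        b = dyad_frequency_profile(np.vstack([encode(s) for s in seqs])[:, ::-1].copy())
        # WW occurrences reverse onto WW occurrences shifted by one; after
        # symmetrization the profiles coincide
        assert np.allclose(a.ww_raw + a.ww_raw[::-1], b.ww_raw + b.ww_raw[::-1])

    def test_planted_type1_peaks_at_minor_sites(self, gbs_map):
        from nucpattern.synth import planted_fragment_batch

        rng = np.random.default_rng(7)
        codes = planted_fragment_batch(np.full(2000, 1), 1.0, gbs_map, rng)
        prof = dyad_frequency_profile(codes)
        peaks = [
            i
            for i in range(1, 145)
            if prof.ww_freq[i] >= prof.ww_freq[i - 1]
            and prof.ww_freq[i] >= prof.ww_freq[i + 1]
            and prof.ww_freq[i] > 0.5
        ]
        centers = sorted(
            round(sum(range(s.start, s.end - 1)) / (s.length - 1)) for s in gbs_map.minor_sites
        )
        assert peaks == centers
        # successive peaks ~10 bp apart within each half
        gaps = np.diff(peaks)
        assert set(gaps[gaps < 20]) <= {10, 11}

    def test_even_window_rejected(self, gbs_map):
        with pytest.raises(ValueError, match="odd"):
            dyad_frequency_profile([NCPFragment("c", 0, "A" * 147)], smooth_window=4)
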