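"""Peak I/O and the fraction-overlap set algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meripeak.annotation import GenomicInterval, segment_transcript
from meripeak.intervals import (
    BedParseError,
    Peak,
    assign_peaks_to_transcripts,
    classify_common_unique,
    consolidate_recurrent,
    overlap_fraction,
    read_bed,
    write_bed,
)
from conftest import make_transcript
from oracles import (
    brute_classify_intervals,
    brute_consolidate_intervals,
    brute_overlap_fraction,
)


def peak(start, end, seqid="chr1", **kw):
    return Peak(interval=GenomicInterval(seqid, start, end), **kw)


class TestBedIO:
    def test_read_example(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t200\tp1\t0\t+\t3.5\t1e-6\n")
        (pk,) = read_bed(str(p))
        assert (pk.start, pk.end, pk.fold_change, pk.p_value) == (100, 200, 3.5, 1e-6)

    def test_round_trip_100_peaks(self, tmp_path, rng):
        peaks = []
        for i in range(100):
            start = int(rng.integers(0, 10000))
            peaks.append(
                peak(
                    start,
                    start + int(rng.integers(50, 400)),
                    fold_change=float(rng.uniform(1, 50)),
                    p_value=float(rng.uniform(0, 1)),
                    name=f"p{i}",
                )
            )
        path = tmp_path / "rt.bed"
        write_bed(peaks, str(path))
        back = read_bed(str(path))
        assert [(p.start, p.end, p.name) for p in back] == [
            (p.start, p.end, p.name) for p in peaks
        ]
        assert np.allclose([p.fold_change for p in back], [p.fold_change for p in peaks])
        assert np.allclose([p.p_value for p in back], [p.p_value for p in peaks])

    def test_missing_columns_default_with_warning(self, tmp_path, caplog):
        p = tmp_path / "short.bed"
        p.write_text("chr1\t10\t90\n")
        (pk,) = read_bed(str(p))
        assert (pk.fold_change, pk.p_value) == (1.0, 1.0)
        assert "defaulting" in caplog.text

    def test_invalid_interval_errors_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\tx\t0\t+\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(str(p))


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100), (0, 100), 1.0),
            ((0, 100), (200, 300), 0.0),
            ((0, 100), (50, 250), 0.5),  # overlap 50 over shorter length 100
        ],
    )
    def test_examples(self, a, b, expected):
        ia = GenomicInterval("chr1", *a)
        ib = GenomicInterval("chr1", *b)
        assert overlap_fraction(ia, ib) == pytest.approx(expected)
        assert overlap_fraction(ia, ib) == pytest.approx(brute_overlap_fraction(ia, ib))

    def test_different_seqid_is_zero(self):
        assert overlap_fraction(
            GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)
        ) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(
        a0=st.integers(0, 500), al=st.integers(1, 300),
        b0=st.integers(0, 500), bl=st.integers(1, 300),
        shift=st.integers(1, 50),
    )
    def test_properties(self, a0, al, b0, bl, shift):
        """Symmetric under the shorter basis; in [0, 1]; never decreases
        when one interval is extended toward the other."""
        a = GenomicInterval("c", a0, a0 + al)
        b = GenomicInterval("c", b0, b0 + bl)
        f = overlap_fraction(a, b)
        assert 0.0 <= f <= 1.0
        assert f == pytest.approx(overlap_fraction(b, a))
        # with a's length as the fixed basis, widening b never lowers the fraction
        widened = GenomicInterval("c", max(b.start - shift, 0), b.end + shift)
        assert overlap_fraction(a, widened, basis="either") >= overlap_fraction(
            a, b, basis="either"
        )

    def test_symmetry_and_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            a = sorted(rng.integers(0, 300, 2).tolist())
            b = sorted(rng.integers(0, 300, 2).tolist())
            if a[0] == a[1] or b[0] == b[1]:
                continue
            ia, ib = GenomicInterval("c", *a), GenomicInterval("c", *b)
            assert overlap_fraction(ia, ib) == pytest.approx(overlap_fraction(ib, ia))
            assert overlap_fraction(ia, ib) == pytest.approx(
                brute_overlap_fraction(ia, ib)
            )


def _random_interval_sets(rng, n_reps=3, max_peaks=15, span=3000):
    sets = []
    for _ in range(n_reps):
        ivs = []
        for _ in range(int(rng.integers(1, max_peaks))):
            start = int(rng.integers(0, span))
            ivs.append((start, start + int(rng.integers(30, 250))))
        sets.append(ivs)
    return sets


class TestConsolidateRecurrent:
    def test_identical_replicates(self):
        sets = [[peak(100, 200)] for _ in range(3)]
        (rec,) = consolidate_recurrent(sets)
        assert (rec.start, rec.end) == (100, 200)

    def test_peak_in_two_of_three_dropped_at_min_three(self):
        sets = [[peak(100, 200)], [peak(110, 210)], [peak(5000, 5100)]]
        assert consolidate_recurrent(sets) == []
        assert len(consolidate_recurrent(sets, min_replicates=2)) >= 1

    def test_derived_chain_intersection(self):
        sets = [[peak(100, 200)], [peak(150, 260)], [peak(120, 210)]]
        (rec,) = consolidate_recurrent(sets)
        assert (rec.start, rec.end) == (150, 200)

    def test_summit_and_fold_change_aggregation(self):
        sets = [
            [peak(100, 200, summit=120, fold_change=2.0)],
            [peak(100, 200, summit=150, fold_change=4.0)],
            [peak(100, 200, summit=180, fold_change=6.0)],
        ]
        (rec,) = consolidate_recurrent(sets)
        assert rec.summit == 150  # median
        assert rec.fold_change == pytest.approx(4.0)  # mean

    def test_empty_replicate_with_all_required(self, caplog):
        assert consolidate_recurrent([[peak(0, 10)], []]) == []
        assert "empty replicate" in caplog.text

    def test_output_never_exceeds_smallest_replicate(self, rng):
        for _ in range(30):
            sets = _random_interval_sets(rng)
            peaks = [[peak(a, b) for a, b in s] for s in sets]
            out = consolidate_recurrent(peaks)
            assert len(out) <= min(len(s) for s in sets)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(100):
            sets = _random_interval_sets(rng, n_reps=int(rng.integers(2, 4)))
            peaks = [[peak(a, b) for a, b in s] for s in sets]
            got = sorted((p.start, p.end) for p in consolidate_recurrent(peaks))
            expected = brute_consolidate_intervals(sets)
            assert got == expected


class TestClassifyCommonUnique:
    def test_identical_sets_all_common(self):
        a = [peak(0, 100), peak(500, 600)]
        b = [peak(0, 100), peak(500, 600)]
        cmp = classify_common_unique(a, b)
        assert cmp.n_common_a == 2 and not cmp.unique_a and not cmp.unique_b

    def test_disjoint_sets_zero_common(self):
        cmp = classify_common_unique([peak(0, 100)], [peak(500, 600)])
        assert cmp.n_common_a == 0
        assert len(cmp.unique_a) == 1 and len(cmp.unique_b) == 1

    def test_derived_example(self):
        cmp = classify_common_unique(
            [peak(0, 100)], [peak(40, 140), peak(400, 500)]
        )
        assert cmp.n_common_a == 1  # fraction 60/100 >= 0.5
        assert [(p.start, p.end) for p in cmp.unique_b] == [(400, 500)]

    def test_count_conservation_and_symmetry(self, rng):
        for _ in range(50):
            sa, sb = _random_interval_sets(rng, n_reps=2)
            a = [peak(x, y) for x, y in sa]
            b = [peak(x, y) for x, y in sb]
            cmp = classify_common_unique(a, b)
            assert cmp.n_common_a + len(cmp.unique_a) == len(a)
            assert cmp.n_common_b + len(cmp.unique_b) == len(b)
            swapped = classify_common_unique(b, a)
            assert swapped.n_common_a == cmp.n_common_b
            assert swapped.n_common_b == cmp.n_common_a

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            sa, sb = _random_interval_sets(rng, n_reps=2)
            cmp = classify_common_unique(
                [peak(x, y) for x, y in sa], [peak(x, y) for x, y in sb]
            )
            expected_common, expected_unique = brute_classify_intervals(sa, sb)
            assert sorted((p.start, p.end) for p, _ in cmp.common) == sorted(
                expected_common
            )
            assert sorted((p.start, p.end) for p in cmp.unique_a) == sorted(
                expected_unique
            )


class TestAssignment:
    def test_summit_in_single_transcript(self):
        tm = make_transcript([(100, 500)], cds=(150, 400))
        st = {"t1": segment_transcript(tm)}
        (hit,) = assign_peaks_to_transcripts([peak(200, 300)], st)
        assert hit == ["t1"]

    def test_intronic_summit_is_intergenic(self):
        tm = make_transcript([(100, 200), (400, 500)], cds=(120, 450))
        st = {"t1": segment_transcript(tm)}
        (hit,) = assign_peaks_to_transcripts([peak(250, 350)], st)
        assert hit == []

    def test_shared_exon_lists_both_isoforms(self):
        iso1 = make_transcript([(100, 500)], cds=(150, 400), tid="t1")
        iso2 = make_transcript([(100, 600)], cds=(150, 400), tid="t2")
        st = {
            "t1": segment_transcript(iso1),
            "t2": segment_transcript(iso2),
        }
        (hit,) = assign_peaks_to_transcripts([peak(200, 300)], st)
        assert hit == ["t1", "t2"]
        # base-containment scan oracle
        summit = 250
        expected = sorted(
            t.transcript_id
            for t in (iso1, iso2)
            if any(e.start <= summit < e.end for e in t.exons)
        )
        assert hit == expected
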