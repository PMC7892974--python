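"""Motif windows, shuffles, and k-mer enrichment."""

from collections import Counter

import numpy as np
import pytest

from meripeak.annotation import GenomicInterval
from meripeak.intervals import Peak
from meripeak.motif import (
    MotifWindow,
    count_matches,
    expand_iupac,
    extract_windows,
    kmer_enrichment,
    rank_kmers,
    reverse_complement,
    select_top_peaks,
    shuffle_controls,
    write_fasta,
)


def peak(start, end, fc=5.0, p=1e-8, summit=None, strand="+"):
    return Peak(
        interval=GenomicInterval("chr1", start, end, strand),
        summit=summit if summit is not None else (start + end) // 2,
        fold_change=fc,
        p_value=p,
    )


def random_seq(rng, n=101):
    return "".join(rng.choice(list("ACGT"), n))


class TestSelectTopPeaks:
    def test_takes_smallest_p_among_qualifiers(self):
        peaks = [peak(i * 1000, i * 1000 + 100, fc=3, p=10 ** -(6 + i)) for i in range(5)]
        top = select_top_peaks(peaks, n=3)
        assert [p.p_value for p in top] == sorted(p.p_value for p in peaks)[:3]

    def test_low_fold_change_excluded_regardless_of_p(self):
        weak = peak(0, 100, fc=1.5, p=1e-300)
        assert select_top_peaks([weak], n=5) == []

    def test_invariant_to_input_order(self, rng):
        peaks = [
            peak(i * 500, i * 500 + 100, fc=float(rng.uniform(2.1, 9)),
                 p=float(10 ** -rng.uniform(5.1, 12)))
            for i in range(40)
        ]
        # force p ties to exercise the fc/coordinate tie-breaks
        for i in range(0, 40, 4):
            peaks[i].p_value = 1e-7
        ref = select_top_peaks(list(peaks), n=10)
        for _ in range(5):
            shuffled = list(peaks)
            rng.shuffle(shuffled)
            got = select_top_peaks(shuffled, n=10)
            assert [(p.start, p.p_value) for p in got] == [
                (p.start, p.p_value) for p in ref
            ]

    def test_warns_when_fewer_than_n(self, caplog):
        select_top_peaks([peak(0, 100)], n=10)
        assert "qualify" in caplog.text


class TestExtractWindows:
    def test_plus_strand_coordinates(self, rng):
        seq = random_seq(rng, 1000)
        (w,) = extract_windows([peak(450, 550, summit=500)], {"chr1": seq})
        assert w.sequence == seq[450:551].upper()
        assert len(w.sequence) == 101 and not w.truncated

    def test_minus_strand_is_reverse_complement(self, rng):
        seq = random_seq(rng, 1000)
        (wp,) = extract_windows([peak(450, 550, summit=500)], {"chr1": seq})
        (wm,) = extract_windows(
            [peak(450, 550, summit=500, strand="-")], {"chr1": seq}
        )
        assert wm.sequence == reverse_complement(wp.sequence)

    def test_truncation_near_contig_start(self, rng):
        seq = random_seq(rng, 500)
        (w,) = extract_windows([peak(0, 60, summit=20)], {"chr1": seq})
        assert w.truncated and len(w.sequence) == 71

    def test_missing_contig_errors(self):
        with pytest.raises(KeyError, match="chr1"):
            extract_windows([peak(0, 100)], {"chr2": "ACGT" * 100})


class TestShuffles:
    def test_mono_preserves_base_counts(self, rng):
        windows = [MotifWindow("w", random_seq(rng)) for _ in range(20)]
        controls = shuffle_controls(windows, mode="mono", seed=1)
        for w, c in zip(windows, controls):
            assert Counter(w.sequence) == Counter(c.sequence)
            assert c.origin == "shuffled-control"

    def test_dinucleotide_preserves_dinucleotide_multiset(self, rng):
        for i in range(100):
            seq = random_seq(rng, int(rng.integers(20, 150)))
            (c,) = shuffle_controls([MotifWindow("w", seq)], seed=i)
            orig = Counter(zip(seq, seq[1:]))
            shuf = Counter(zip(c.sequence, c.sequence[1:]))
            assert orig == shuf

    def test_deterministic_under_seed(self, rng):
        windows = [MotifWindow("w", random_seq(rng)) for _ in range(5)]
        a = [w.sequence for w in shuffle_controls(windows, seed=7)]
        b = [w.sequence for w in shuffle_controls(windows, seed=7)]
        c = [w.sequence for w in shuffle_controls(windows, seed=8)]
        assert a == b
        assert a != c


class TestCounting:
    @pytest.mark.parametrize(
        "seq,pattern,expected",
        [
            ("GGACT", "RRACH", 1),
            ("GGACTGGACT", "GGACU", 2),
            ("GGACUGGACU", "GGACU", 2),  # RNA alphabet input
            ("AAAAA", "GGACU", 0),
            ("AAAA", "AAA", 2),  # overlapping matches
        ],
    )
    def test_match_counts(self, seq, pattern, expected):
        assert count_matches(seq, pattern) == expected

    def test_invalid_iupac_code_errors(self):
        with pytest.raises(ValueError, match="IUPAC"):
            expand_iupac("GGAXT")

    def test_expansion_size(self):
        assert len(expand_iupac("RRACH")) == 2 * 2 * 1 * 1 * 3


class TestEnrichment:
    def embedded_windows(self, rng, n=500, prob=0.8):
        windows = []
        for _ in range(n):
            seq = list(random_seq(rng))
            if rng.random() < prob:
                seq[48:53] = list("GGACT")
            windows.append(MotifWindow("w", "".join(seq)))
        return windows

    def test_embedded_motif_strongly_enriched(self, rng):
        targets = self.embedded_windows(rng)
        controls = shuffle_controls(targets, seed=3)
        enr = kmer_enrichment(targets, controls, ["GGACU", "RRACH"])
        assert enr[0].z > 5
        assert enr[0].target_rate > enr[0].control_rate

    def test_self_comparison_is_null(self, rng):
        targets = self.embedded_windows(rng, n=300)
        enr = kmer_enrichment(targets, targets, ["GGACU", "RRACH", "AAAAA"])
        assert all(abs(e.z) < 2 for e in enr)

    def test_empirical_p_from_extra_shuffles(self, rng):
        targets = self.embedded_windows(rng, n=60)
        controls = shuffle_controls(targets, seed=5)
        (enr,) = kmer_enrichment(
            targets, controls, ["GGACU"], n_extra_shuffles=19, seed=11
        )
        assert enr.p_value == pytest.approx(1 / 20)

    def test_ggact_ranks_first_among_all_5mers(self, rng):
        targets = self.embedded_windows(rng, n=400, prob=0.6)
        controls = shuffle_controls(targets, seed=9)
        ranked = rank_kmers(targets, controls, k=5)
        assert ranked[0][0] == "GGACT"
        assert len(ranked) == 4**5

    def test_requires_sequences(self):
        with pytest.raises(ValueError):
            kmer_enrichment([], [], ["GGACU"])


def test_fasta_writer(tmp_path):
    windows = [MotifWindow("a", "ACGT"), MotifWindow("b", "GGGG")]
    path = tmp_path / "w.fa"
    write_fasta(windows, str(path))
    assert path.read_text() == ">a\nACGT\n>b\nGGGG\n"
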