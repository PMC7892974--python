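"""FPKM/NNFPKM, correlation, quadrants, summaries, gene-set tests."""

import numpy as np
import pytest

from meripeak.integration import (
    ExpressionRecord,
    aggregate_dynamic_directions,
    expression_methylation_correlation,
    fpkm,
    geneset_overrepresentation,
    methylation_summary,
    quadrant_classify,
    quadrant_shares,
    read_gmt,
    share_pct,
    summarize_counts,
)
from oracles import hypergeom_upper_tail


class TestFpkm:
    @pytest.mark.parametrize(
        "frags,length,total,expected",
        [(100, 1000, 10**6, 100.0), (0, 1000, 10**6, 0.0), (100, 1000, 2 * 10**6, 50.0)],
    )
    def test_values(self, frags, length, total, expected):
        assert fpkm(frags, length, total) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 10)
        with pytest.raises(ValueError):
            fpkm(1, 10, 0)


class TestCorrelation:
    def records(self, fin, nn):
        return [
            ExpressionRecord(f"g{i}", float(x), float(x * y))
            for i, (x, y) in enumerate(zip(fin, nn))
        ]

    def test_exact_inverse_relation_gives_minus_one(self, rng):
        fin = rng.lognormal(2, 1, 50)
        recs = self.records(fin, 7.0 / fin)
        for bins in (None, 10):
            r, _ = expression_methylation_correlation(recs, n_bins=bins)
            assert r == pytest.approx(-1.0)

    def test_independent_inputs_near_zero(self, rng):
        fin = rng.lognormal(2, 1, 10_000)
        nn = rng.lognormal(0, 0.7, 10_000)
        r, _ = expression_methylation_correlation(self.records(fin, nn), n_bins=None)
        assert abs(r) < 0.05

    def test_attenuated_closed_form(self, rng):
        slope, noise = -0.8, 0.3
        x = rng.normal(0, 1, 20_000)
        y = slope * x + rng.normal(0, noise, 20_000)
        recs = self.records(2.0**x, 2.0**y)
        r, _ = expression_methylation_correlation(recs, n_bins=None)
        r_theory = slope / np.sqrt(slope**2 + noise**2)
        assert abs(r - r_theory) < 0.05

    def test_binned_mode_strengthens_noisy_trend(self, rng):
        slope, noise = -0.5, 1.0
        x = rng.normal(0, 1, 5000)
        y = slope * x + rng.normal(0, noise, 5000)
        recs = self.records(2.0**x, 2.0**y)
        r_gene, _ = expression_methylation_correlation(recs, n_bins=None)
        r_binned, _ = expression_methylation_correlation(recs, n_bins=50)
        assert r_binned < r_gene < 0

    def test_scale_invariance(self, rng):
        fin = rng.lognormal(2, 1, 500)
        nn = rng.lognormal(0, 1, 500)
        r1, _ = expression_methylation_correlation(self.records(fin, nn))
        r2, _ = expression_methylation_correlation(self.records(fin * 37.5, nn))
        assert r1 == pytest.approx(r2)

    def test_undefined_cases(self):
        recs = self.records([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            expression_methylation_correlation(recs)
        const = self.records([4.0, 4.0, 4.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        r, p = expression_methylation_correlation(const, n_bins=None)
        assert np.isnan(r)

    def test_nnfpkm_undefined_when_unexpressed(self):
        rec = ExpressionRecord("g", 0.0, 5.0)
        assert rec.nnfpkm is None


class TestQuadrants:
    def test_concordant_and_discordant_labels(self):
        calls, counts, _ = quadrant_classify(
            {"g1": "high", "g2": "low", "g3": "high", "g4": "ns"},
            {"g1": "up", "g2": "down", "g3": "down", "g4": "up"},
        )
        assert counts == {
            "hyper-up": 1, "hyper-down": 1, "hypo-up": 0, "hypo-down": 1
        }
        assert {c.gene_id: c.label for c in calls}["g1"] == "hyper-up"

    def test_conflict_exclusion_and_partition(self):
        dyn = aggregate_dynamic_directions(
            {"a": ["high", "high"], "b": ["high", "low"], "c": ["low"], "d": ["ns"]}
        )
        assert dyn == {"a": "high", "b": "conflict", "c": "low", "d": "ns"}
        calls, counts, n_conflict = quadrant_classify(
            dyn, {"a": "up", "b": "up", "c": "down", "d": "down"}
        )
        assert n_conflict == 1
        assert sum(counts.values()) == len(calls) == 2

    def test_empty_intersection(self):
        calls, counts, _ = quadrant_classify({"g": "high"}, {"g": "ns"})
        assert not calls and sum(counts.values()) == 0

    def test_printed_precision_shares(self):
        counts = {"hyper-up": 52, "hyper-down": 3, "hypo-up": 7, "hypo-down": 84}
        shares = quadrant_shares(counts)
        assert shares["hyper_up_pct"] == 95
        assert shares["hypo_down_pct"] == 92
        assert shares["discordant_pct"] == 7
        assert shares["concordant_frac_pct"] == 93.2


class TestSummaries:
    def test_table_style_worked_counts(self):
        lean = summarize_counts(5965, 4615, 7097)
        assert lean["peaks_per_methylated_transcript"] == 1.54
        assert lean["peaks_per_transcript"] == 1.19
        assert lean["percent_methylated"] == 77
        fat = summarize_counts(6654, 4438, 6966)
        assert fat["peaks_per_methylated_transcript"] == 1.57
        assert fat["peaks_per_transcript"] == 1.05
        assert fat["percent_methylated"] == 67

    def test_degenerate_all_methylated(self):
        out = summarize_counts(10, 10, 10)
        assert out["percent_methylated"] == 100
        assert out["peaks_per_transcript"] == 1.0

    def test_from_assignments(self):
        assignments = [["t1"], ["t1"], ["t2"], []]
        out = methylation_summary(assignments, 4)
        assert out["n_methylated"] == 2 and out["n_peaks"] == 3
        assert out["percent_methylated"] == 50

    def test_share_pct_half_up(self):
        assert share_pct(146, 1172, 1) == 12.5
        assert share_pct(1069, 1504, 1) == 71.1
        assert share_pct(1, 200) == 1.0  # 0.5 rounds up


class TestGeneSets:
    def test_exact_tail_matches_comb_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        hits = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 65)}
        frame = geneset_overrepresentation(hits, universe, {"s": gene_set})
        expected = hypergeom_upper_tail(5, 100, 10, 20)
        assert frame.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.0254645, rel=1e-4)

    def test_extreme_and_null_overlap(self):
        universe = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(8)}
        exact = geneset_overrepresentation(set(gene_set), universe, {"s": gene_set})
        assert exact.loc[0, "p_value"] == pytest.approx(
            hypergeom_upper_tail(8, 50, 8, 8), rel=1e-9
        )
        none = geneset_overrepresentation(
            {f"g{i}" for i in range(20, 30)}, universe, {"s": gene_set}
        )
        assert none.loc[0, "p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_small_sets_skipped_and_empty_universe_errors(self, caplog):
        frame = geneset_overrepresentation({"a"}, {"a", "b"}, {"tiny": {"a"}})
        assert frame.empty
        with pytest.raises(ValueError):
            geneset_overrepresentation({"a"}, set(), {"s": {"a"}})

    def test_read_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc\tg1\tg2\ng_short\tdesc\n")
        sets = read_gmt(str(path))
        assert sets == {"s1": {"g1", "g2"}}
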