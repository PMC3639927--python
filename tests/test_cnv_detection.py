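import itertools

import numpy as np
import pandas as pd
import pytest

from lce_cnvpop.cnv_detection import (
    DetectionParams,
    annotate_overlaps,
    call_rule_based,
    call_window,
    combined_signal,
    consensus,
    reciprocal_overlap,
)
from lce_cnvpop.core import CNVRegion

from .conftest import flat_probes, make_probe_table


def brute_force_rule(table, params):
    """Independent O(n^2) enumeration of maximal qualifying runs."""

    def qualifies(row):
        d, s = row.log2_direct, row.log2_swap
        if pd.isna(d) or abs(d) < params.log2_threshold:
            return None
        if params.require_dye_swap:
            if pd.isna(s) or abs(s) < params.log2_threshold or d * s >= 0:
                return None
        return "loss" if d < 0 else "gain"

    rows = list(table.probes.itertuples(index=False))
    dirs = [qualifies(r) for r in rows]
    found = []
    n = len(rows)
    for i, j in itertools.combinations(range(n + 1), 2):
        segment = dirs[i:j]
        if any(d is None for d in segment) or len(set(segment)) != 1:
            continue
        # maximality
        if i > 0 and dirs[i - 1] == segment[0]:
            continue
        if j < n and dirs[j] == segment[0]:
            continue
        span = rows[j - 1].end - rows[i].start
        if len(segment) >= params.min_consecutive_probes and span >= params.min_span:
            found.append((rows[i].start, rows[j - 1].end, segment[0], j - i))
    return found


class TestRuleBased:
    def test_constructed_pass_case(self):
        table = flat_probes(-0.6, 5)  # 5 probes x 10 kb = 50 kb run
        regions = call_rule_based(table, DetectionParams())
        assert len(regions) == 1
        region = regions[0]
        assert region.direction == "loss"
        assert region.n_probes == 5
        assert region.span == 50_000

    def test_two_consecutive_probes_insufficient(self):
        table = flat_probes(-0.6, 2, spacing=20_000)  # span OK, count not
        assert call_rule_based(table, DetectionParams()) == []

    def test_short_span_filtered(self):
        table = flat_probes(-0.6, 4, spacing=5_000)  # 4 probes but only 20 kb
        assert call_rule_based(table, DetectionParams()) == []

    def test_same_sign_swap_probe_splits_run(self):
        signals = [(-0.6, 0.6)] * 4 + [(-0.6, -0.6)] + [(-0.6, 0.6)] * 4
        table = make_probe_table(signals)
        params = DetectionParams()
        regions = call_rule_based(table, params)
        assert len(regions) == 2
        assert all(r.n_probes == 4 for r in regions)
        # runs separated by the failing probe are not merged
        assert regions[0].end <= regions[1].start

    def test_threshold_is_per_label(self):
        # direct passes, swap misses the threshold -> probe fails
        signals = [(-0.6, 0.6)] * 2 + [(-0.6, 0.2)] + [(-0.6, 0.6)] * 2
        table = make_probe_table(signals)
        assert call_rule_based(table, DetectionParams()) == []
        # without the dye-swap requirement the run survives
        relaxed = DetectionParams(require_dye_swap=False)
        assert len(call_rule_based(table, relaxed)) == 1

    def test_missing_swap_terminates_run_when_required(self):
        signals = [(-0.6, 0.6)] * 2 + [(-0.6, None)] + [(-0.6, 0.6)] * 2
        table = make_probe_table(signals)
        assert call_rule_based(table, DetectionParams()) == []

    def test_empty_table_empty_list(self):
        table = make_probe_table([(0.0, 0.0)]).probes.iloc[:0]
        from lce_cnvpop.io_formats import ProbeTable

        empty = ProbeTable(probes=table, comparison_id="x")
        assert call_rule_based(empty, DetectionParams()) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        signals = []
        for _ in range(10):
            d = rng.choice([-0.6, -0.3, 0.0, 0.3, 0.6])
            s = -d if rng.random() < 0.8 else d
            signals.append((d, s + rng.normal(0, 0.05)))
        table = make_probe_table(signals)
        params = DetectionParams(min_span=20_000)
        got = [(r.start, r.end, r.direction, r.n_probes) for r in call_rule_based(table, params)]
        assert got == brute_force_rule(table, params)


class TestWindowCaller:
    def test_all_zero_signal_empty(self):
        table = flat_probes(0.0, 20)
        assert call_window(table, DetectionParams()) == []

    def test_single_outlier_no_region(self):
        signals = [(0.0, 0.0)] * 2 + [(-5.0, 5.0)] + [(0.0, 0.0)] * 2
        table = make_probe_table(signals)
        params = DetectionParams(window_size=3)
        assert call_window(table, params) == []

    def test_clean_deletion_matches_rule_caller(self):
        signals = [(0.0, 0.0)] * 5 + [(-0.7, 0.7)] * 4 + [(0.0, 0.0)] * 5
        table = make_probe_table(signals)
        params = DetectionParams()
        rule = call_rule_based(table, params)
        window = call_window(table, params)
        assert len(rule) == len(window) == 1
        assert abs(rule[0].start - window[0].start) <= 10_000
        assert abs(rule[0].end - window[0].end) <= 10_000

    def test_fewer_probes_than_window_empty(self):
        table = flat_probes(-0.7, 3)
        assert call_window(table, DetectionParams(window_size=5)) == []

    def test_missing_label_uses_available_one(self):
        signals = [(-0.7, None)] * 5
        table = make_probe_table(signals)
        regions = call_window(table, DetectionParams(window_size=3))
        assert len(regions) == 1
        assert regions[0].direction == "loss"


class TestCombinedSignal:
    def test_both_labels(self):
        assert combined_signal(-0.6, 0.4) == pytest.approx(-0.5)

    def test_one_label_missing(self):
        assert combined_signal(-0.6, None) == -0.6
        assert combined_signal(None, 0.6) == -0.6
        assert combined_signal(None, None) == 0.0


def _region(start, end, direction="loss", comparison="c"):
    return CNVRegion("chr1", start, end, direction, 3, -0.5 if direction == "loss" else 0.5,
                     "rule", comparison)


class TestConsensus:
    def test_identical_lists_idempotent(self):
        regions = [_region(0, 40_000), _region(100_000, 140_000)]
        result = consensus(regions, regions, 0.5)
        assert [(r.start, r.end) for r in result] == [(r.start, r.end) for r in regions]
        assert all(r.caller == "consensus" for r in result)

    def test_disjoint_lists_empty(self):
        assert consensus([_region(0, 40_000)], [_region(100_000, 140_000)], 0.5) == []

    def test_overlap_threshold_boundary(self):
        # 60 % reciprocal overlap of two 100 kb regions
        a = [_region(0, 100_000)]
        b = [_region(40_000, 140_000)]
        assert reciprocal_overlap(a[0], b[0]) == pytest.approx(0.6)
        assert len(consensus(a, b, 0.5)) == 1
        assert consensus(a, b, 0.7) == []

    def test_direction_must_match(self):
        a = [_region(0, 100_000, "loss")]
        b = [_region(0, 100_000, "gain")]
        assert consensus(a, b, 0.5) == []

    def test_anti_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        a = [_region(int(s), int(s) + 50_000) for s in rng.integers(0, 1_000_000, 5)]
        b = [_region(int(s) + 20_000, int(s) + 70_000) for s in rng.integers(0, 1_000_000, 5)]
        counts = [len(consensus(a, b, f)) for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestAnnotateOverlaps:
    def _features(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_region_equal_to_feature(self):
        region = _region(1000, 41_000)
        features = self._features([("chr1", 1000, 41_000, "geneA")])
        [[(name, frac)]] = annotate_overlaps([region], features)
        assert name == "geneA" and frac == 1.0

    def test_adjacent_half_open_no_overlap(self):
        region = _region(1000, 41_000)
        features = self._features([("chr1", 41_000, 50_000, "geneA")])
        assert annotate_overlaps([region], features) == [[]]

    def test_chromosome_mismatch_warns_empty(self, caplog):
        region = _region(1000, 41_000)
        features = self._features([("chr2", 1000, 41_000, "geneA")])
        with caplog.at_level("WARNING"):
            result = annotate_overlaps([region], features)
        assert result == [[]]
        assert "absent" in caplog.text

    def test_matches_exhaustive_pairwise_check(self):
        regions = [_region(0, 40_000), _region(50_000, 90_000), _region(200_000, 240_000)]
        features = self._features(
            [
                ("chr1", 10_000, 20_000, "f1"),
                ("chr1", 35_000, 60_000, "f2"),
                ("chr1", 90_000, 95_000, "f3"),
                ("chr1", 150_000, 400_000, "f4"),
            ]
        )
        result = annotate_overlaps(regions, features)
        expected = []
        for r in regions:
            hits = []
            for f in features.itertuples(index=False):
                ov = max(0, min(r.end, f.end) - max(r.start, f.start))
                if ov >= 1:
                    hits.append((f.name, ov / (r.end - r.start)))
            expected.append(hits)
        assert result == expected


def random_table(seed, n=30):
    rng = np.random.default_rng(seed)
    signals = []
    for _ in range(n):
        d = rng.normal(0, 0.4)
        signals.append((d, -d + rng.normal(0, 0.1)))
    return make_probe_table(signals)


def covered_span(regions):
    return sum(r.span for r in regions)


class TestMonotonicity:
    """Stricter parameters never admit more called territory."""

    @pytest.mark.parametrize("seed", range(20))
    def test_threshold_monotone_span(self, seed):
        table = random_table(seed)
        spans = [
            covered_span(call_rule_based(table, DetectionParams(log2_threshold=t, min_span=0)))
            for t in (0.1, 0.25, 0.4, 0.6)
        ]
        assert spans == sorted(spans, reverse=True)

    @pytest.mark.parametrize("seed", range(20))
    def test_min_probes_monotone_count_and_span(self, seed):
        table = random_table(seed)
        results = [
            call_rule_based(table, DetectionParams(min_consecutive_probes=k, min_span=0))
            for k in (1, 2, 3, 5)
        ]
        counts = [len(r) for r in results]
        spans = [covered_span(r) for r in results]
        assert counts == sorted(counts, reverse=True)
        assert spans == sorted(spans, reverse=True)

    @pytest.mark.parametrize("seed", range(20))
    def test_min_span_monotone_count_and_span(self, seed):
        table = random_table(seed)
        results = [
            call_rule_based(table, DetectionParams(min_span=s)) for s in (0, 20_000, 40_000, 80_000)
        ]
        counts = [len(r) for r in results]
        spans = [covered_span(r) for r in results]
        assert counts == sorted(counts, reverse=True)
        assert spans == sorted(spans, reverse=True)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_overlapping_output_regions(self, seed):
        table = random_table(seed, n=50)
        for caller in (call_rule_based, call_window):
            regions = sorted(
                caller(table, DetectionParams(min_span=0)), key=lambda r: r.start
            )
            for a, b in zip(regions, regions[1:]):
                assert a.end <= b.start


class TestNoisyRecall:
    def test_recall_at_published_thresholds(self):
        # regression guard, not a published claim: with sd = 0.1 noise and the
        # default thresholds the consensus caller recovers nearly every
        # simulated deletion
        from lce_cnvpop.synthetic_data import ACGHSimParams, PopulationModel, simulate_pool_acgh

        ref = PopulationModel("REF", 50, (0.33, 0.33, 0.0, 0.34))
        test = PopulationModel("T1", 50, (0.04, 0.06, 0.0, 0.90))
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            sim = simulate_pool_acgh(
                [test], ref, ACGHSimParams(seed=seed, noise_sd=0.1, attenuation=0.5)
            )
            truth = sim.truth_regions[0]
            table = sim.probe_tables[truth.comparison_id]
            regions = consensus(
                call_rule_based(table, DetectionParams()),
                call_window(table, DetectionParams()),
                0.5,
            )
            if any(
                r.direction == truth.direction and reciprocal_overlap(r, truth) > 0.4
                for r in regions
            ):
                hits += 1
        assert hits / n_rep >= 0.95
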