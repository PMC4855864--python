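"""Sample QC, caller-call filters and dual-algorithm consensus matching."""

import numpy as np
import pytest

from cnvrtool.core import CnvType, GenomicInterval
from cnvrtool.io_formats import SampleRecord
from cnvrtool.qc_consensus import (
    FilterThresholds,
    consensus_calls,
    filter_calls_alg_a,
    filter_calls_alg_b,
    filter_samples,
)

from _util import make_call_a, make_call_b


class TestFilterSamples:
    @pytest.mark.parametrize(
        "call_rate, lrr_sd, passes, reason",
        [
            (0.98, 0.3, True, None),      # boundary values pass (strict < / >)
            (1.0, 0.0, True, None),
            (0.979, 0.1, False, "call_rate"),
            (0.99, 0.31, False, "lrr_sd"),
            (0.9, 0.5, False, "call_rate"),
        ],
    )
    def test_thresholds(self, call_rate, lrr_sd, passes, reason):
        s = SampleRecord("S1", "A", call_rate, lrr_sd)
        passed, excluded = filter_samples([s])
        if passes:
            assert passed == [s] and not excluded
        else:
            assert not passed
            assert reason in excluded[0].reasons


class TestFilterCallsAlgA:
    def test_all_boundaries_kept(self):
        c = make_call_a(n_probes=7, max_log_bf=30.0, sd_lrr=0.1, sd_baf=0.039)
        assert filter_calls_alg_a([c]) == [c]
        c2 = make_call_a(n_probes=7, max_log_bf=30.0, sd_lrr=0.25, sd_baf=0.0)
        assert filter_calls_alg_a([c2]) == [c2]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_probes=6, max_log_bf=100.0, sd_lrr=0.2, sd_baf=0.01),
            dict(n_probes=10, max_log_bf=29.9, sd_lrr=0.2, sd_baf=0.01),
            dict(n_probes=10, max_log_bf=50.0, sd_lrr=0.09, sd_baf=0.01),
            dict(n_probes=10, max_log_bf=50.0, sd_lrr=0.26, sd_baf=0.01),
            dict(n_probes=10, max_log_bf=50.0, sd_lrr=0.2, sd_baf=0.04),
        ],
    )
    def test_single_failing_metric_drops_call(self, kwargs):
        assert filter_calls_alg_a([make_call_a(**kwargs)]) == []

    def test_wrong_dialect_is_hard_error(self):
        with pytest.raises(ValueError, match="max_log_bf"):
            filter_calls_alg_a([make_call_b()])

    def test_oracle_equivalence_on_random_calls(self):
        rng = np.random.default_rng(11)
        calls = [
            make_call_a(
                n_probes=int(rng.integers(3, 15)),
                max_log_bf=float(rng.uniform(0, 60)),
                sd_lrr=float(rng.uniform(0.0, 0.4)),
                sd_baf=float(rng.uniform(0.0, 0.08)),
            )
            for _ in range(200)
        ]
        expected = [
            c for c in calls
            if c.n_probes >= 7 and c.max_log_bf >= 30
            and 0.1 <= c.sd_lrr <= 0.25 and c.sd_baf < 0.04
        ]
        assert filter_calls_alg_a(calls) == expected


class TestFilterCallsAlgB:
    def test_boundaries(self):
        kept = make_call_b(confidence=35.0, n_probes=7)
        assert filter_calls_alg_b([kept]) == [kept]
        assert filter_calls_alg_b([make_call_b(confidence=34.9, n_probes=50)]) == []

    def test_wrong_dialect_is_hard_error(self):
        with pytest.raises(ValueError, match="confidence"):
            filter_calls_alg_b([make_call_a()])

    def test_oracle_equivalence_on_random_calls(self):
        rng = np.random.default_rng(12)
        calls = [
            make_call_b(
                n_probes=int(rng.integers(3, 15)),
                confidence=float(rng.uniform(0, 70)),
            )
            for _ in range(100)
        ]
        expected = [c for c in calls if c.confidence >= 35 and c.n_probes >= 7]
        assert filter_calls_alg_b(calls) == expected


class TestConsensus:
    def test_identical_calls_give_one_consensus(self):
        cons = consensus_calls([make_call_a()], [make_call_b()])
        assert len(cons) == 1
        c = cons[0]
        assert c.interval == GenomicInterval("1", 100, 200)
        assert c.cnv_type is CnvType.DEL

    def test_type_mismatch_rejected(self):
        a = make_call_a(start=1, end=100, cn=1)     # DEL
        b = make_call_b(start=1, end=100, cn=3)     # DUP
        assert consensus_calls([a], [b]) == []

    def test_reciprocal_rule_rejects_one_sided_overlap(self):
        # overlap 101 bp is 100% of b but only ~10% of a
        a = make_call_a(start=1, end=1000)
        b = make_call_b(start=900, end=1000)
        assert consensus_calls([a], [b]) == []

    def test_single_sided_mode_accepts_one_sided_overlap(self):
        t = FilterThresholds(reciprocal_overlap=False)
        a = make_call_a(start=1, end=1000)
        b = make_call_b(start=900, end=1000)
        assert len(consensus_calls([a], [b], t)) == 1

    def test_consensus_interval_is_intersection(self):
        a = make_call_a(chrom="2", start=100, end=300)
        b = make_call_b(chrom="2", start=150, end=400)
        (c,) = consensus_calls([a], [b])
        assert c.interval == GenomicInterval("2", 150, 300)

    def test_union_boundary_mode(self):
        t = FilterThresholds(consensus_boundary="union")
        a = make_call_a(chrom="2", start=100, end=300)
        b = make_call_b(chrom="2", start=150, end=400)
        (c,) = consensus_calls([a], [b], t)
        assert c.interval == GenomicInterval("2", 100, 400)

    def test_chrx_calls_removed(self):
        a = make_call_a(chrom="X")
        b = make_call_b(chrom="X")
        assert consensus_calls([a], [b]) == []

    def test_calls_not_matched_across_samples(self):
        a = make_call_a(sample="S1")
        b = make_call_b(sample="S2")
        assert consensus_calls([a], [b]) == []

    def test_each_call_supports_one_consensus(self):
        # two A calls both overlap one B call; only the larger overlap wins
        a1 = make_call_a(start=100, end=200)
        a2 = make_call_a(start=120, end=220)
        b = make_call_b(start=100, end=200)
        cons = consensus_calls([a1, a2], [b])
        assert len(cons) == 1
        assert cons[0].source_a is a1  # larger overlap (101 vs 81)

    def test_identity_limit(self):
        # identical per-sample call sets, zero noise -> consensus == input
        rng = np.random.default_rng(3)
        calls_a, calls_b = [], []
        for s in range(10):
            pos = 1
            for _ in range(int(rng.integers(1, 5))):
                pos += int(rng.integers(1000, 50_000))
                end = pos + int(rng.integers(5000, 20_000))
                cn = 1 if rng.random() < 0.5 else 3
                calls_a.append(make_call_a(f"S{s}", "4", pos, end, cn))
                calls_b.append(make_call_b(f"S{s}", "4", pos, end, cn))
                pos = end + 1
        cons = consensus_calls(calls_a, calls_b)
        assert {(c.sample_id, c.interval, c.cnv_type) for c in cons} == {
            (c.sample_id, c.interval, c.cnv_type) for c in calls_a
        }

    def test_consensus_bounded_by_either_input(self):
        rng = np.random.default_rng(4)
        calls_a = [
            make_call_a("S1", "1", s, s + int(rng.integers(100, 5000)))
            for s in rng.integers(1, 100_000, size=20)
        ]
        calls_b = [
            make_call_b("S1", "1", s, s + int(rng.integers(100, 5000)))
            for s in rng.integers(1, 100_000, size=15)
        ]
        cons = consensus_calls(calls_a, calls_b)
        assert len(cons) <= min(len(calls_a), len(calls_b))


class TestThresholdMonotonicity:
    def _random_calls(self, rng, n=150):
        calls_a = [
            make_call_a(
                sample=f"S{int(rng.integers(5))}",
                start=(s := int(rng.integers(1, 500_000))),
                end=s + int(rng.integers(2000, 30_000)),
                n_probes=int(rng.integers(3, 15)),
                max_log_bf=float(rng.uniform(0, 60)),
                sd_lrr=float(rng.uniform(0, 0.4)),
                sd_baf=float(rng.uniform(0, 0.08)),
            )
            for _ in range(n)
        ]
        calls_b = [
            make_call_b(
                sample=f"S{int(rng.integers(5))}",
                start=(s := int(rng.integers(1, 500_000))),
                end=s + int(rng.integers(2000, 30_000)),
                n_probes=int(rng.integers(3, 15)),
                confidence=float(rng.uniform(0, 70)),
            )
            for _ in range(n)
        ]
        return calls_a, calls_b

    def test_raising_thresholds_never_increases_counts(self):
        rng = np.random.default_rng(21)
        calls_a, calls_b = self._random_calls(rng)
        for param, values in [
            ("min_max_log_bf", [0, 10, 30, 45, 60]),
            ("min_confidence", [0, 20, 35, 50, 70]),
            ("min_probes", [3, 5, 7, 10, 14]),
            ("min_overlap_fraction", [0.1, 0.3, 0.5, 0.8, 1.0]),
        ]:
            prev_filtered = None
            prev_cons = None
            for v in values:
                t = FilterThresholds(**{param: v})
                fa = filter_calls_alg_a(calls_a, t)
                fb = filter_calls_alg_b(calls_b, t)
                n_filtered = len(fa) + len(fb)
                n_cons = len(consensus_calls(fa, fb, t))
                if prev_filtered is not None:
                    assert n_filtered <= prev_filtered
                    assert n_cons <= prev_cons
                prev_filtered, prev_cons = n_filtered, n_cons
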