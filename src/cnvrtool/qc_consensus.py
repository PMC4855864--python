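"""Sample QC, per-caller call filtering and dual-algorithm consensus.

The filtering thresholds reproduce the strict dual-caller workflow used for
Illumina SNP-array CNV discovery: samples must genotype well (call rate,
genome-wide LRR SD); QuantiSNP-style calls must span at least seven probes
with a high Bayes factor and clean per-call LRR/BAF noise; cnvPartition-style
calls need the same probe support and a confidence score of at least 35.  A
CNV is accepted only when both callers report an event of the same type at
the same locus with at least 50% overlapping length (reciprocal by default),
and chromosome X is excluded entirely because of its high false-positive
rate on arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .core import (
    CHROM_X,
    CnvType,
    GenomicInterval,
    intersect,
    overlap_fraction,
    overlap_length,
    span,
)
from .io_formats import ALG_A, ALG_B, CnvCall, SampleRecord


@dataclass
class FilterThresholds:
    """Every numeric QC threshold of the workflow, user-overridable.

    Boundary inclusivity follows the printed comparators of the source
    protocol exactly: samples are *excluded* for call rate < 0.98 or LRR SD
    > 0.3 (so the boundary values pass); calls are kept for MaxLogBF >= 30,
    confidence >= 35, probes >= 7, SD(LRR) in the closed range [0.1, 0.25]
    and SD(BAF) < 0.04.
    """

    min_call_rate: float = 0.98
    max_sample_lrr_sd: float = 0.3
    min_probes: int = 7
    min_max_log_bf: float = 30.0
    call_sd_lrr_range: tuple[float, float] = (0.1, 0.25)
    max_call_sd_baf: float = 0.04
    min_confidence: float = 35.0
    min_overlap_fraction: float = 0.5
    reciprocal_overlap: bool = True
    consensus_boundary: Literal["intersection", "union", "alg_a", "alg_b"] = (
        "intersection"
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overlap_fraction <= 1.0):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        lo, hi = self.call_sd_lrr_range
        if lo > hi:
            raise ValueError("call_sd_lrr_range must be (low, high)")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterThresholds":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "call_sd_lrr_range" in known:
            known["call_sd_lrr_range"] = tuple(known["call_sd_lrr_range"])
        return cls(**known)


@dataclass(frozen=True)
class ConsensusCnv:
    """A CNV supported by both callers for one sample.

    The reported interval is the intersection of the two source calls by
    default (the conservative high-confidence span); union or either
    caller's boundaries are available via
    :attr:`FilterThresholds.consensus_boundary`.
    """

    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    source_a: CnvCall
    source_b: CnvCall


@dataclass
class ExcludedSample:
    record: SampleRecord
    reasons: list[str] = field(default_factory=list)


def filter_samples(
    samples: Sequence[SampleRecord], t: FilterThresholds | None = None
) -> tuple[list[SampleRecord], list[ExcludedSample]]:
    """Split samples into QC-passed and excluded (with reason codes)."""
    t = t or FilterThresholds()
    passed: list[SampleRecord] = []
    excluded: list[ExcludedSample] = []
    for s in samples:
        reasons = []
        if s.call_rate < t.min_call_rate:
            reasons.append("call_rate")
        if s.lrr_sd > t.max_sample_lrr_sd:
            reasons.append("lrr_sd")
        if reasons:
            excluded.append(ExcludedSample(s, reasons))
        else:
            passed.append(s)
    return passed, excluded


def filter_calls_alg_a(
    calls: Sequence[CnvCall], t: FilterThresholds | None = None
) -> list[CnvCall]:
    """QuantiSNP-style filter: probes, MaxLogBF, per-call LRR/BAF SD."""
    t = t or FilterThresholds()
    lo, hi = t.call_sd_lrr_range
    kept = []
    for c in calls:
        if c.max_log_bf is None:
            raise ValueError(
                f"call {c.sample_id} {c.interval}: max_log_bf absent "
                "(wrong dialect for ALG_A filter?)"
            )
        if (
            c.n_probes >= t.min_probes
            and c.max_log_bf >= t.min_max_log_bf
            and c.sd_lrr is not None
            and lo <= c.sd_lrr <= hi
            and c.sd_baf is not None
            and c.sd_baf < t.max_call_sd_baf
        ):
            kept.append(c)
    return kept


def filter_calls_alg_b(
    calls: Sequence[CnvCall], t: FilterThresholds | None = None
) -> list[CnvCall]:
    """cnvPartition-style filter: confidence and probe count."""
    t = t or FilterThresholds()
    kept = []
    for c in calls:
        if c.confidence is None:
            raise ValueError(
                f"call {c.sample_id} {c.interval}: confidence absent "
                "(wrong dialect for ALG_B filter?)"
            )
        if c.confidence >= t.min_confidence and c.n_probes >= t.min_probes:
            kept.append(c)
    return kept


def _pair_matches(a: CnvCall, b: CnvCall, t: FilterThresholds) -> bool:
    if a.interval.chrom != b.interval.chrom:
        return False
    if a.cnv_type != b.cnv_type:
        return False
    fa, fb = overlap_fraction(a.interval, b.interval)
    if t.reciprocal_overlap:
        return fa >= t.min_overlap_fraction and fb >= t.min_overlap_fraction
    return max(fa, fb) >= t.min_overlap_fraction


def _consensus_interval(
    a: CnvCall, b: CnvCall, t: FilterThresholds
) -> GenomicInterval:
    if t.consensus_boundary == "intersection":
        iv = intersect(a.interval, b.interval)
        assert iv is not None  # matched pairs always overlap
        return iv
    if t.consensus_boundary == "union":
        return span([a.interval, b.interval])
    if t.consensus_boundary == "alg_a":
        return a.interval
    return b.interval


def consensus_calls(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    t: FilterThresholds | None = None,
) -> list[ConsensusCnv]:
    """Match filtered calls from the two callers into consensus CNVs.

    Per sample, a pair matches when it lies on the same chromosome, has a
    consistent CNV type, and satisfies the 50%-overlap rule (reciprocal by
    default).  Matching is greedy by descending overlap length with a
    deterministic tie-break (lower start, then ALG_A input order); each call
    supports at most one consensus CNV.  Chromosome-X calls are removed
    before matching.
    """
    t = t or FilterThresholds()
    calls_a = [c for c in calls_a if c.interval.chrom != CHROM_X]
    calls_b = [c for c in calls_b if c.interval.chrom != CHROM_X]

    by_sample_a: dict[str, list[tuple[int, CnvCall]]] = {}
    for i, c in enumerate(calls_a):
        by_sample_a.setdefault(c.sample_id, []).append((i, c))
    by_sample_b: dict[str, list[tuple[int, CnvCall]]] = {}
    for j, c in enumerate(calls_b):
        by_sample_b.setdefault(c.sample_id, []).append((j, c))

    out: list[ConsensusCnv] = []
    for sample in sorted(set(by_sample_a) & set(by_sample_b)):
        cand: list[tuple[int, int, int, int]] = []
        for i, a in by_sample_a[sample]:
            for j, b in by_sample_b[sample]:
                if _pair_matches(a, b, t):
                    ov = overlap_length(a.interval, b.interval)
                    start = max(a.interval.start, b.interval.start)
                    cand.append((-ov, start, i, j))
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _neg_ov, _start, i, j in cand:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            a, b = calls_a[i], calls_b[j]
            out.append(
                ConsensusCnv(
                    sample_id=sample,
                    interval=_consensus_interval(a, b, t),
                    cnv_type=a.cnv_type,
                    source_a=a,
                    source_b=b,
                )
            )
    out.sort(key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start))
    return out


@dataclass
class RunLog:
    """Machine-readable counts of records in/out at each pipeline stage."""

    n_samples_in: int = 0
    n_samples_passed: int = 0
    n_calls_a_in: int = 0
    n_calls_a_filtered: int = 0
    n_calls_b_in: int = 0
    n_calls_b_filtered: int = 0
    n_consensus: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def run_consensus_pipeline(
    samples: Sequence[SampleRecord],
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    t: FilterThresholds | None = None,
) -> tuple[list[SampleRecord], list[ConsensusCnv], RunLog]:
    """Sample QC + per-caller filters + consensus, with stage counts.

    Calls from QC-failed samples are dropped before filtering.
    """
    t = t or FilterThresholds()
    log = RunLog(n_samples_in=len(samples), n_calls_a_in=len(calls_a),
                 n_calls_b_in=len(calls_b))
    passed, _excluded = filter_samples(samples, t)
    log.n_samples_passed = len(passed)
    ok = {s.sample_id for s in passed}
    fa = filter_calls_alg_a([c for c in calls_a if c.sample_id in ok], t)
    fb = filter_calls_alg_b([c for c in calls_b if c.sample_id in ok], t)
    log.n_calls_a_filtered = len(fa)
    log.n_calls_b_filtered = len(fb)
    cons = consensus_calls(fa, fb, t)
    log.n_consensus = len(cons)
    return passed, cons, log
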