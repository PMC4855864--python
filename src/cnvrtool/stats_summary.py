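"""Cohort summary statistics and nonparametric group comparisons.

Summaries follow the conventions of population CNV surveys: percentages
rounded half-up to 1 decimal place (singleton split to integer percent),
per-person rates to 2 decimals, sizes reported in kb (call/region means and
medians to 1 decimal), genome coverage in Mb to 1 decimal.

Group comparisons are the standard nonparametric pair used when CNV size
and frequency data are not normally distributed: the two-sided
Mann-Whitney-Wilcoxon rank-sum test for size differences and Kendall's
tau-b rank correlation for paired region frequencies, both at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cnvr_analysis import Cnvr
from .core import CnvType, GenomicInterval
from .io_formats import SampleRecord
from .qc_consensus import ConsensusCnv

ALPHA = 0.05


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (5 rounds up), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def size_kb(interval: GenomicInterval) -> float:
    """Interval length in kb, rounded half-up to 2 decimals."""
    return round_half_up(interval.length_bp / 1000.0, 2)


@dataclass
class CohortSummary:
    """The per-cohort statistics block of a population CNV survey table."""

    n_samples: int
    n_carriers: int
    carrier_pct: float
    n_cnvs: int
    cnvs_per_person: float
    n_dup: int
    dup_pct: float
    n_del: int
    del_pct: float
    mean_cnv_kb: float | None
    median_cnv_kb: float | None
    n_cnvrs: int
    mean_cnvr_kb: float | None
    median_cnvr_kb: float | None
    genome_coverage_mb: float


def _size_stats_kb(intervals: Sequence[GenomicInterval]) -> tuple[float | None, float | None]:
    if not intervals:
        return None, None
    sizes = np.array([iv.length_bp for iv in intervals], dtype=float) / 1000.0
    return round_half_up(float(sizes.mean()), 1), round_half_up(float(np.median(sizes)), 1)


def cohort_summary(
    cnvs: Sequence[ConsensusCnv],
    cnvrs: Sequence[Cnvr],
    samples: Sequence[SampleRecord],
) -> CohortSummary:
    """Compute every cohort-table field from the raw records."""
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("cohort_summary requires at least one sample")
    n_cnvs = len(cnvs)
    carriers = {c.sample_id for c in cnvs}
    n_dup = sum(1 for c in cnvs if c.cnv_type is CnvType.DUP)
    n_del = n_cnvs - n_dup
    mean_kb, median_kb = _size_stats_kb([c.interval for c in cnvs])
    mean_r_kb, median_r_kb = _size_stats_kb([r.interval for r in cnvrs])
    coverage_bp = sum(r.interval.length_bp for r in cnvrs)
    return CohortSummary(
        n_samples=n_samples,
        n_carriers=len(carriers),
        carrier_pct=round_half_up(100.0 * len(carriers) / n_samples, 1),
        n_cnvs=n_cnvs,
        cnvs_per_person=round_half_up(n_cnvs / n_samples, 2),
        n_dup=n_dup,
        dup_pct=round_half_up(100.0 * n_dup / n_cnvs, 1) if n_cnvs else 0.0,
        n_del=n_del,
        del_pct=round_half_up(100.0 * n_del / n_cnvs, 1) if n_cnvs else 0.0,
        mean_cnv_kb=mean_kb,
        median_cnv_kb=median_kb,
        n_cnvrs=len(cnvrs),
        mean_cnvr_kb=mean_r_kb,
        median_cnvr_kb=median_r_kb,
        genome_coverage_mb=round_half_up(coverage_bp / 1e6, 1),
    )


def singleton_split(
    carrier_counts: Iterable[int],
) -> tuple[int, int, int]:
    """Split items into singletons (one carrier) vs non-singletons.

    Accepts the per-item carrier counts; returns
    ``(n_singleton, n_non_singleton, pct_singleton)`` with the percentage
    rounded half-up to the nearest integer.
    """
    counts = list(carrier_counts)
    n_singleton = sum(1 for k in counts if k == 1)
    n_non = len(counts) - n_singleton
    pct = int(round_half_up(100.0 * n_singleton / len(counts), 0)) if counts else 0
    return n_singleton, n_non, pct


def cnv_carrier_counts(
    cnvs: Sequence[ConsensusCnv], cnvrs: Sequence[Cnvr]
) -> list[int]:
    """Carrier count of each CNV's region, for the CNV-level singleton split.

    A CNV is a singleton when no other individual carries a CNV at its
    locus, i.e. when its CNVR has exactly one carrier.
    """
    owner: dict[int, int] = {}
    for ridx, r in enumerate(cnvrs):
        for m in r.members:
            owner[id(m)] = ridx
    out = []
    for c in cnvs:
        if id(c) not in owner:
            raise ValueError("CNV not a member of any provided CNVR")
        out.append(len(cnvrs[owner[id(c)]].carriers))
    return out


@dataclass
class TestResult:
    statistic: float
    p_value: float
    significant: bool
    method: str


def mann_whitney_size_test(
    sizes_a: Sequence[float], sizes_b: Sequence[float], alpha: float = ALPHA
) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Uses the exact null distribution for small samples (both n <= 20,
    no ties) and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return TestResult(float(res.statistic), p, p < alpha, f"mann-whitney-{method}")


def kendall_tau_b(
    freq_a: Sequence[float], freq_b: Sequence[float], alpha: float = ALPHA
) -> TestResult:
    """Kendall's tau-b rank correlation with tie adjustment.

    The p-value comes from the standard normal approximation to the tau
    null distribution.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    res = stats.kendalltau(a, b, variant="b", method="asymptotic")
    p = float(res.pvalue)
    return TestResult(float(res.statistic), p, p < alpha, "kendall-tau-b")


def group_frequency_pairs(
    cnvrs: Sequence[Cnvr],
    groups: Mapping[str, str],
    include_singletons: bool = False,
) -> tuple[list[float], list[float], tuple[str, str]]:
    """Per-CNVR carrier frequencies in each group, over a common region set.

    Frequencies are paired over the union of (by default non-singleton)
    CNVRs; a region absent from one group gets frequency 0 there.  Group
    denominators are the group sample counts.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    ga, gb = labels
    n_ga = sum(1 for g in groups.values() if g == ga)
    n_gb = sum(1 for g in groups.values() if g == gb)
    fa: list[float] = []
    fb: list[float] = []
    for r in cnvrs:
        if r.is_singleton and not include_singletons:
            continue
        ka = sum(1 for s in r.carriers if groups[s] == ga)
        kb = sum(1 for s in r.carriers if groups[s] == gb)
        fa.append(ka / n_ga if n_ga else 0.0)
        fb.append(kb / n_gb if n_gb else 0.0)
    return fa, fb, (ga, gb)
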