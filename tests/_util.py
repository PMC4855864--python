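"""Shared builders and brute-force oracles for the test suite.

The oracles here are deliberately naive (position sets, all-pairs scans,
exhaustive enumeration) and independent of the library code paths they
check.
"""

from __future__ import annotations

import itertools

import numpy as np

from cnvrtool.core import CnvType, GenomicInterval
from cnvrtool.io_formats import ALG_A, ALG_B, CnvCall
from cnvrtool.qc_consensus import ConsensusCnv


def make_call_a(
    sample="S1", chrom="1", start=100, end=200, cn=1,
    n_probes=10, max_log_bf=50.0, sd_lrr=0.2, sd_baf=0.01,
) -> CnvCall:
    return CnvCall(
        sample_id=sample, caller=ALG_A,
        interval=GenomicInterval(chrom, start, end), copy_number=cn,
        n_probes=n_probes, max_log_bf=max_log_bf, sd_lrr=sd_lrr, sd_baf=sd_baf,
    )


def make_call_b(
    sample="S1", chrom="1", start=100, end=200, cn=1,
    n_probes=10, confidence=50.0,
) -> CnvCall:
    return CnvCall(
        sample_id=sample, caller=ALG_B,
        interval=GenomicInterval(chrom, start, end), copy_number=cn,
        n_probes=n_probes, confidence=confidence,
    )


def make_consensus(sample="S1", chrom="1", start=100, end=200,
                   cnv_type=CnvType.DEL) -> ConsensusCnv:
    cn = 1 if cnv_type is CnvType.DEL else 3
    return ConsensusCnv(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, end),
        cnv_type=cnv_type,
        source_a=make_call_a(sample, chrom, start, end, cn),
        source_b=make_call_b(sample, chrom, start, end, cn),
    )


def random_intervals(rng: np.random.Generator, n, max_coord=10_000,
                     chroms=("1", "2")) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(1, max_coord))
        end = start + int(rng.integers(0, max(2, max_coord // 10)))
        out.append(GenomicInterval(chrom, start, end))
    return out


# ----------------------------------------------------------------- oracles

def position_set(iv: GenomicInterval) -> set[tuple[str, int]]:
    return {(iv.chrom, p) for p in range(iv.start, iv.end + 1)}


def union_positions(intervals) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        out |= position_set(iv)
    return out


def overlaps_any_bruteforce(iv, regions) -> bool:
    return any(
        r.chrom == iv.chrom and not (r.end < iv.start or r.start > iv.end)
        for r in regions
    )


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of labelings.

    Returns (U of sample a, p).  Only feasible for tiny samples; assumes no
    ties across the pooled data.
    """
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    n_extreme = 0
    n_total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        n_total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs:
            n_extreme += 1
    return float(u_obs), n_extreme / n_total


def kendall_tau_b_oracle(x, y) -> float:
    """O(n^2) concordant/discordant/tie counting for tau-b."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) / 2
    # pair-level tie counts: ties in x (incl. both) and in y (incl. both)
    n1 = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if x[i] == x[j]
    )
    n2 = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if y[i] == y[j]
    )
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    return (nc - nd) / denom
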