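"""CNVR construction, frequency classes, group sharing and annotation.

A copy-number-variable region (CNVR) is the maximal genomic region obtained
by transitively merging CNVs, across individuals, that overlap by at least
one base position (the Redon-style region definition).  CNVR carrier
frequency is the number of distinct carrier samples divided by the number
of QC-passed samples in the analysed cohort; group-level frequencies use
group denominators.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import CnvType, GenomicInterval, merge_groups, overlap_length, span
from .io_formats import ReferenceRegionSet
from .qc_consensus import ConsensusCnv

logger = logging.getLogger(__name__)

RARE_FREQUENCY = 0.01     # carrier frequency below this is "rare"
COMMON_FREQUENCY = 0.05   # carrier frequency at or above this is "common"

DEL_ONLY = "DEL_ONLY"
DUP_ONLY = "DUP_ONLY"
MIXED = "MIXED"


class SharingClass(enum.Enum):
    SHARED = "SHARED"
    GROUP_A_ONLY = "GROUP_A_ONLY"
    GROUP_B_ONLY = "GROUP_B_ONLY"


class FrequencyClass(enum.Enum):
    RARE = "RARE"
    INTERMEDIATE = "INTERMEDIATE"
    COMMON = "COMMON"


@dataclass
class Cnvr:
    """A merged region of overlapping consensus CNVs."""

    interval: GenomicInterval
    members: list[ConsensusCnv]
    carriers: set[str]
    type_class: str
    frequency: float
    is_singleton: bool
    novel: bool | None = None

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def build_cnvrs(
    cnvs: Sequence[ConsensusCnv], n_cohort: int
) -> list[Cnvr]:
    """Cluster consensus CNVs into CNVRs by transitive one-base overlap.

    ``n_cohort`` is the QC-passed cohort size used as the frequency
    denominator.  Output is sorted by (chrom, start) and independent of the
    input order.
    """
    if n_cohort < 1:
        raise ValueError("n_cohort must be >= 1")
    cnvs = list(cnvs)
    groups = merge_groups([c.interval for c in cnvs])
    out: list[Cnvr] = []
    for idxs in groups:
        members = [cnvs[i] for i in idxs]
        members.sort(key=lambda c: (c.interval.start, c.interval.end, c.sample_id))
        carriers = {c.sample_id for c in members}
        types = {c.cnv_type for c in members}
        if types == {CnvType.DEL}:
            type_class = DEL_ONLY
        elif types == {CnvType.DUP}:
            type_class = DUP_ONLY
        else:
            type_class = MIXED
        out.append(
            Cnvr(
                interval=span([c.interval for c in members]),
                members=members,
                carriers=carriers,
                type_class=type_class,
                frequency=len(carriers) / n_cohort,
                is_singleton=len(carriers) == 1,
            )
        )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def classify_frequency(
    frequency: float | Cnvr,
    rare: float = RARE_FREQUENCY,
    common: float = COMMON_FREQUENCY,
) -> FrequencyClass:
    """Rare (<1%), common (>=5%) or intermediate carrier frequency."""
    f = frequency.frequency if isinstance(frequency, Cnvr) else float(frequency)
    if f < rare:
        return FrequencyClass.RARE
    if f >= common:
        return FrequencyClass.COMMON
    return FrequencyClass.INTERMEDIATE


@dataclass
class SharingResult:
    assignments: list[tuple[Cnvr, SharingClass]]
    shared_fraction: float
    group_labels: tuple[str, str]

    def counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in SharingClass}
        for _, cls in self.assignments:
            out[cls.value] += 1
        return out


def shared_cnvrs(
    cnvrs: Sequence[Cnvr], groups: Mapping[str, str]
) -> SharingResult:
    """Classify non-singleton CNVRs as shared or group-specific.

    A CNVR is shared when its member CNVs come from samples of both groups
    (totally or partially overlapping CNVs from both groups, by
    construction of the region).  Exactly two group labels are required.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(
            f"sharing analysis is pairwise; got group labels {labels}"
        )
    ga, gb = labels
    assignments: list[tuple[Cnvr, SharingClass]] = []
    n_shared = 0
    for r in cnvrs:
        if r.is_singleton:
            continue
        present = {groups[s] for s in r.carriers}
        if present == {ga, gb}:
            cls = SharingClass.SHARED
            n_shared += 1
        elif present == {ga}:
            cls = SharingClass.GROUP_A_ONLY
        else:
            cls = SharingClass.GROUP_B_ONLY
        assignments.append((r, cls))
    frac = n_shared / len(assignments) if assignments else 0.0
    return SharingResult(assignments, frac, (ga, gb))


def _overlaps_any(iv: GenomicInterval, by_chrom: dict[str, list[GenomicInterval]]) -> bool:
    for r in by_chrom.get(iv.chrom, ()):
        if r.start > iv.end:
            break  # per-chrom lists are sorted by start
        if overlap_length(iv, r) > 0:
            return True
    return False


@dataclass
class NoveltyResult:
    novel_flags: list[bool]
    novel_fraction: float
    mode: str = "any-overlap"


def annotate_novelty(
    items: Sequence[ConsensusCnv] | Sequence[Cnvr],
    reference: ReferenceRegionSet,
) -> NoveltyResult:
    """Flag items absent from a known-variant reference set as novel.

    An item is *known* when it overlaps any reference region by at least
    one base (any-overlap criterion); otherwise novel.  ``Cnvr`` items get
    their ``novel`` attribute set in place.
    """
    if len(reference) == 0:
        logger.warning(
            "novelty reference %r is EMPTY: every item will be flagged novel",
            reference.name,
        )
    by_chrom = reference.by_chrom()
    flags: list[bool] = []
    for it in items:
        novel = not _overlaps_any(it.interval, by_chrom)
        flags.append(novel)
        if isinstance(it, Cnvr):
            it.novel = novel
    frac = sum(flags) / len(flags) if flags else 0.0
    return NoveltyResult(flags, frac)


@dataclass
class GeneOverlapResult:
    fraction: float
    by_type: dict[str, float]
    n_overlapping: int


def gene_overlap_fraction(
    cnvs: Sequence[ConsensusCnv], genes: ReferenceRegionSet
) -> GeneOverlapResult:
    """Fraction of CNVs overlapping any gene region, with DEL/DUP split."""
    if len(genes) == 0:
        logger.warning("gene region set %r is empty", genes.name)
    by_chrom = genes.by_chrom()
    n_hit = 0
    hits_by_type = {CnvType.DEL: 0, CnvType.DUP: 0}
    tot_by_type = {CnvType.DEL: 0, CnvType.DUP: 0}
    for c in cnvs:
        tot_by_type[c.cnv_type] += 1
        if _overlaps_any(c.interval, by_chrom):
            n_hit += 1
            hits_by_type[c.cnv_type] += 1
    frac = n_hit / len(cnvs) if cnvs else 0.0
    by_type = {
        t.value: (hits_by_type[t] / tot_by_type[t] if tot_by_type[t] else 0.0)
        for t in (CnvType.DEL, CnvType.DUP)
    }
    return GeneOverlapResult(frac, by_type, n_hit)


def genome_coverage_bp(cnvrs: Iterable[Cnvr]) -> int:
    """Total bases covered by CNVRs (disjoint by construction)."""
    return sum(r.interval.length_bp for r in cnvrs)
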