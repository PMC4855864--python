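"""Readers and writers for caller tables, manifests, BED sets and results.

Two caller dialects are supported, mirroring the tab-delimited exports of
the common Illumina SNP-array CNV callers:

``quantisnp``
    Per-call table with a maximum log Bayes factor (``max_log_bf``) and
    per-call LRR/BAF standard deviations.
``genomestudio``
    cnvPartition-style export with a ``confidence`` score.

Column names vary across caller versions, so each dialect carries a column
map that can be overridden from the YAML config file.

All genomic records are held internally in 1-based inclusive coordinates;
BED I/O converts to/from 0-based half-open at this boundary and nowhere
else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .core import (
    CnvType,
    GenomicInterval,
    cnv_type_from_copy_number,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

ALG_A = "ALG_A"  # QuantiSNP-style caller
ALG_B = "ALG_B"  # cnvPartition / GenomeStudio-style caller

#: default column maps per dialect: internal field -> column name in file
DIALECTS: dict[str, dict[str, str]] = {
    "quantisnp": {
        "sample_id": "sample",
        "chrom": "chrom",
        "start": "start",
        "end": "end",
        "copy_number": "copy_number",
        "n_probes": "n_probes",
        "max_log_bf": "max_log_bf",
        "sd_lrr": "sd_lrr",
        "sd_baf": "sd_baf",
    },
    "genomestudio": {
        "sample_id": "sample",
        "chrom": "chrom",
        "start": "start",
        "end": "end",
        "copy_number": "value",
        "n_probes": "n_probes",
        "confidence": "confidence",
    },
}

DIALECT_CALLER = {"quantisnp": ALG_A, "genomestudio": ALG_B}


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV call for one sample.

    Exactly one of ``max_log_bf`` (ALG_A) / ``confidence`` (ALG_B) is set,
    matching ``caller``.
    """

    sample_id: str
    caller: str
    interval: GenomicInterval
    copy_number: int
    n_probes: int
    max_log_bf: float | None = None
    confidence: float | None = None
    sd_lrr: float | None = None
    sd_baf: float | None = None

    def __post_init__(self) -> None:
        if self.caller == ALG_A and self.max_log_bf is None:
            raise ValueError("ALG_A call requires max_log_bf")
        if self.caller == ALG_B and self.confidence is None:
            raise ValueError("ALG_B call requires confidence")

    @property
    def cnv_type(self) -> CnvType:
        return cnv_type_from_copy_number(self.copy_number)


@dataclass(frozen=True)
class SampleRecord:
    """Array QC metrics and group label for one cohort sample."""

    sample_id: str
    group: str
    call_rate: float
    lrr_sd: float


@dataclass
class ReferenceRegionSet:
    """A named set of reference regions (DGV-like catalogue, gene spans)."""

    name: str
    regions: list[GenomicInterval] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        for rs in out.values():
            rs.sort(key=lambda iv: (iv.start, iv.end))
        return out

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class ParseResult:
    """Calls plus counters for every skipped input row."""

    calls: list[CnvCall]
    n_skipped_cn_neutral: int = 0
    n_skipped_malformed: int = 0

    def __iter__(self):
        return iter(self.calls)


def _require_columns(df: pd.DataFrame, needed: Iterable[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def read_caller_table(
    path,
    caller: str | None = None,
    dialect: str = "quantisnp",
    column_map: dict[str, str] | None = None,
) -> ParseResult:
    """Parse a tab-delimited caller export into :class:`CnvCall` records.

    Rows with copy number 2 (copy-neutral, e.g. LOH) or unparsable
    coordinates are skipped, logged, and counted in the result.  A missing
    required column is a hard error naming the column.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if caller is None:
        caller = DIALECT_CALLER[dialect]
    cmap = dict(DIALECTS[dialect])
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    _require_columns(df, cmap.values(), path)

    result = ParseResult(calls=[])
    for idx, row in df.iterrows():
        try:
            chrom = normalize_chrom(row[cmap["chrom"]])
            start = int(row[cmap["start"]])
            end = int(row[cmap["end"]])
            cn = int(float(row[cmap["copy_number"]]))
            n_probes = int(float(row[cmap["n_probes"]]))
            interval = GenomicInterval(chrom, start, end)
        except (ValueError, TypeError):
            result.n_skipped_malformed += 1
            logger.warning("%s row %d: unparsable record, skipped", path, idx)
            continue
        if cn == 2:
            result.n_skipped_cn_neutral += 1
            logger.warning(
                "%s row %d: copy-neutral call (CN=2) dropped", path, idx
            )
            continue
        kwargs: dict = {}
        if caller == ALG_A:
            kwargs["max_log_bf"] = float(row[cmap["max_log_bf"]])
            if "sd_lrr" in cmap and cmap["sd_lrr"] in row:
                kwargs["sd_lrr"] = float(row[cmap["sd_lrr"]])
            if "sd_baf" in cmap and cmap["sd_baf"] in row:
                kwargs["sd_baf"] = float(row[cmap["sd_baf"]])
        else:
            kwargs["confidence"] = float(row[cmap["confidence"]])
        result.calls.append(
            CnvCall(
                sample_id=str(row[cmap["sample_id"]]),
                caller=caller,
                interval=interval,
                copy_number=cn,
                n_probes=n_probes,
                **kwargs,
            )
        )
    if result.n_skipped_cn_neutral or result.n_skipped_malformed:
        logger.info(
            "%s: %d calls parsed, %d copy-neutral skipped, %d malformed skipped",
            path,
            len(result.calls),
            result.n_skipped_cn_neutral,
            result.n_skipped_malformed,
        )
    return result


_CALLER_COLUMNS = {
    ALG_A: [
        "sample", "chrom", "start", "end", "copy_number", "n_probes",
        "max_log_bf", "sd_lrr", "sd_baf",
    ],
    ALG_B: ["sample", "chrom", "start", "end", "value", "n_probes", "confidence"],
}


def write_caller_table(calls: Sequence[CnvCall], path, caller: str) -> None:
    """Write calls in the default column layout of the caller's dialect."""
    rows = []
    for c in calls:
        base = {
            "sample": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "n_probes": c.n_probes,
        }
        if caller == ALG_A:
            base.update(
                copy_number=c.copy_number,
                max_log_bf=c.max_log_bf,
                sd_lrr=c.sd_lrr,
                sd_baf=c.sd_baf,
            )
        else:
            base.update(value=c.copy_number, confidence=c.confidence)
        rows.append(base)
    pd.DataFrame(rows, columns=_CALLER_COLUMNS[caller]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path) -> list[SampleRecord]:
    """Read the sample manifest TSV (sample_id, group, call_rate, lrr_sd)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    _require_columns(df, ["sample_id", "group", "call_rate", "lrr_sd"], path)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dups}")
    return [
        SampleRecord(
            sample_id=str(r.sample_id),
            group=str(r.group),
            call_rate=float(r.call_rate),
            lrr_sd=float(r.lrr_sd),
        )
        for r in df.itertuples()
    ]


def write_manifest(samples: Sequence[SampleRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "call_rate": s.call_rate,
                "lrr_sd": s.lrr_sd,
            }
            for s in samples
        ],
        columns=["sample_id", "group", "call_rate", "lrr_sd"],
    ).to_csv(path, sep="\t", index=False)


def read_bed(path, name: str | None = None) -> ReferenceRegionSet:
    """Load a 3+ column BED file (0-based half-open) as reference regions.

    Internal coordinates become ``start_bed + 1 .. end_bed`` (1-based
    inclusive).  Zero-length and inverted records are skipped with a
    warning; malformed lines likewise.
    """
    name = name or Path(path).stem
    regions: list[GenomicInterval] = []
    n_skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                n_skipped += 1
                logger.warning("%s:%d: <3 columns, skipped", path, lineno)
                continue
            try:
                chrom = normalize_chrom(parts[0])
                start_bed = int(parts[1])
                end_bed = int(parts[2])
            except ValueError:
                n_skipped += 1
                logger.warning("%s:%d: unparsable BED record", path, lineno)
                continue
            if end_bed <= start_bed:
                n_skipped += 1
                logger.warning(
                    "%s:%d: zero-length or inverted record skipped",
                    path,
                    lineno,
                )
                continue
            regions.append(GenomicInterval(chrom, start_bed + 1, end_bed))
    if n_skipped:
        logger.info("%s: %d records loaded, %d skipped", path, len(regions), n_skipped)
    return ReferenceRegionSet(name=name, regions=regions)


def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    """Write intervals as BED (inverse of :func:`read_bed`'s conversion)."""
    intervals = list(intervals)
    if names is None:
        names = [None] * len(intervals)
    with open(path, "w", encoding="utf-8") as fh:
        for iv, nm in zip(intervals, names):
            cols = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if nm is not None:
                cols.append(str(nm))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# result tables

_CNV_COLS = [
    "sample_id", "chrom", "start", "end", "cnv_type",
    "copy_number_a", "copy_number_b",
]


def write_consensus_cnvs(cnvs, path) -> None:
    """Write consensus CNVs as a TSV with a stable column order."""
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "cnv_type": c.cnv_type.value,
            "copy_number_a": c.source_a.copy_number,
            "copy_number_b": c.source_b.copy_number,
        }
        for c in cnvs
    ]
    pd.DataFrame(rows, columns=_CNV_COLS).to_csv(path, sep="\t", index=False)


def read_consensus_cnvs(path):
    """Read back a consensus-CNV TSV written by :func:`write_consensus_cnvs`.

    Source calls are reconstructed as minimal placeholders (the per-caller
    quality metrics are not round-tripped).
    """
    from .qc_consensus import ConsensusCnv  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    _require_columns(df, _CNV_COLS, path)
    out = []
    for r in df.itertuples():
        iv = GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        a = CnvCall(str(r.sample_id), ALG_A, iv, int(r.copy_number_a), 7, max_log_bf=float("nan"))
        b = CnvCall(str(r.sample_id), ALG_B, iv, int(r.copy_number_b), 7, confidence=float("nan"))
        out.append(
            ConsensusCnv(
                sample_id=str(r.sample_id),
                interval=iv,
                cnv_type=CnvType(r.cnv_type),
                source_a=a,
                source_b=b,
            )
        )
    return out


_CNVR_COLS = [
    "chrom", "start", "end", "n_carriers", "carriers", "type_class",
    "frequency", "is_singleton", "novel",
]


def write_cnvrs(cnvrs, path) -> None:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "n_carriers": len(r.carriers),
            "carriers": ",".join(sorted(r.carriers)),
            "type_class": r.type_class,
            "frequency": r.frequency,
            "is_singleton": r.is_singleton,
            "novel": "" if r.novel is None else r.novel,
        }
        for r in cnvrs
    ]
    pd.DataFrame(rows, columns=_CNVR_COLS).to_csv(path, sep="\t", index=False)


def read_cnvr_table(path) -> pd.DataFrame:
    """Read a CNVR TSV back as a DataFrame (coordinates as written)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "start", "end"], path)
    return df


def write_phenogram(cnvrs, sharing, path) -> None:
    """PhenoGram-compatible table: chrom, pos, phenotype = sharing class."""
    rows = [
        {
            "chrom": r.interval.chrom,
            "pos": r.interval.start,
            "end": r.interval.end,
            "phenotype": cls.value,
        }
        for r, cls in sharing
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "end", "phenotype"]).to_csv(
        path, sep="\t", index=False
    )


def load_config(path) -> dict:
    """Load the YAML config holding thresholds and dialect column maps."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
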