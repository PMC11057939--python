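"""Regulatory peak consolidation, variant overlap and aggregation.

Peak files (narrowPeak = BED6+4, broadPeak = BED6+3) are declared in a
manifest together with their metadata (accession, target, biosample, output
type) and assay group. The default assay groups mirror the eight regulatory
evidence classes used for variant annotation: transcription-factor ChIP-seq,
histone ChIP-seq, DNase-seq, Mint-ChIP-seq, ATAC-seq, eCLIP, ChIA-PET and
GM DNase-seq. For each group the variant is overlapped against an interval
index and the matching peaks' signal values, -log10 p-values, -log10
q-values and summit offsets are aggregated into min/max/mean/range columns
(the -1 sentinel marking an unavailable value is excluded, not averaged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from snvfeat.core import MISSING, FeatureBlock, VariantRecord

DEFAULT_ASSAY_GROUPS = [
    "tf_chip",
    "histone_chip",
    "dnase",
    "mint_chip",
    "atac",
    "eclip",
    "chia_pet",
    "gm_dnase",
]

AGGREGATED_FIELDS = ("signalValue", "pValue", "qValue", "peak_offset")
STATISTICS = ("min", "max", "mean", "range")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    signal_value: float
    p_value: float  # -log10 scale; -1 = unavailable
    q_value: float  # -log10 scale; -1 = unavailable
    peak: int  # summit offset from start; -1 = unavailable
    accession: str = ""
    target: str = ""
    biosample: str = ""
    output_type: str = ""
    order: int = 0  # file order then line order, for deterministic output

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end} has start >= end")
        if self.peak != -1 and not 0 <= self.peak < self.end - self.start:
            raise ValueError(f"summit offset {self.peak} outside peak of length {self.end - self.start}")

    def field_value(self, name: str) -> float | int:
        return {
            "signalValue": self.signal_value,
            "pValue": self.p_value,
            "qValue": self.q_value,
            "peak_offset": self.peak,
        }[name]


@dataclass
class PeakManifest:
    """Rows of (path, format, accession, target, biosample, output_type, group)."""

    rows: list[tuple[Path, str, str, str, str, str, str]]
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_ASSAY_GROUPS))

    def __post_init__(self) -> None:
        for row in self.rows:
            if row[6] not in self.groups:
                raise ValueError(f"manifest group {row[6]!r} not in configured groups {self.groups}")


@dataclass
class PeakDB:
    """Interval-indexed peak collection for one assay group."""

    group: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)
    n_peaks: int = 0

    def add(self, peak: Peak) -> None:
        self.trees.setdefault(peak.chrom, IntervalTree()).addi(peak.start, peak.end, peak)
        self.n_peaks += 1


def read_peaks(path: str | Path, format: str) -> list[Peak]:
    """Read a narrowPeak (10 columns) or broadPeak (9 columns) file.

    broadPeak rows get summit offset -1; the strand column is ignored.
    """
    if format not in ("narrowPeak", "broadPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    want = 10 if format == "narrowPeak" else 9
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != want:
                raise ValueError(f"{path}:{lineno}: expected {want} columns for {format}, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                if start < 0:
                    raise ValueError("negative coordinate")
                peak = Peak(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    signal_value=float(fields[6]),
                    p_value=float(fields[7]),
                    q_value=float(fields[8]),
                    peak=int(fields[9]) if format == "narrowPeak" else -1,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            peaks.append(peak)
    return peaks


def load_peak_manifest(path: str | Path, groups: list[str] | None = None) -> PeakManifest:
    """Read a manifest TSV: file, format, accession, target, biosample,
    output_type, group. Paths resolve relative to the manifest directory."""
    base = Path(path).parent
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("file\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            rows.append((base / fields[0], fields[1], fields[2], fields[3], fields[4], fields[5], fields[6]))
    return PeakManifest(rows=rows, groups=groups or list(DEFAULT_ASSAY_GROUPS))


def build_peakdb(manifest: PeakManifest) -> dict[str, PeakDB]:
    """Consolidate every manifest file into per-group interval indexes; each
    peak carries its manifest metadata. Duplicate accessions are replicates
    and all get indexed."""
    dbs: dict[str, PeakDB] = {}
    order = 0
    for fpath, fmt, accession, target, biosample, output_type, group in manifest.rows:
        db = dbs.setdefault(group, PeakDB(group=group))
        for peak in read_peaks(fpath, fmt):
            peak.accession = accession
            peak.target = target
            peak.biosample = biosample
            peak.output_type = output_type
            peak.order = order
            order += 1
            db.add(peak)
    return dbs


def overlap_query(db: PeakDB, variant: VariantRecord) -> list[Peak]:
    """All peaks whose [start, end) contains the variant position, in file
    order then line order."""
    tree = db.trees.get(variant.chrom)
    if tree is None:
        return []
    hits = [iv.data for iv in tree.at(variant.start)]
    return sorted(hits, key=lambda p: p.order)


def aggregate_block(matches: list[Peak], group: str, variant_key: tuple = ()) -> FeatureBlock:
    """min/max/mean/range per aggregated field plus a peak count.

    -1 sentinels (unavailable p/q/summit) are excluded from the aggregates;
    a field with no available values, or no matches at all, yields missing
    statistics (the count column is always present and 0 when no peak hits).
    """
    values: dict[str, object] = {}
    for fname in AGGREGATED_FIELDS:
        obs = [p.field_value(fname) for p in matches if p.field_value(fname) != -1]
        if obs:
            stats = {
                "min": min(obs),
                "max": max(obs),
                "mean": math.fsum(obs) / len(obs),  # order-independent mean
                "range": max(obs) - min(obs),
            }
        else:
            stats = {s: MISSING for s in STATISTICS}
        for s in STATISTICS:
            values[f"{group}_{fname}_{s}"] = stats[s]
    values[f"{group}_n_peaks"] = len(matches)
    return FeatureBlock(variant_key=variant_key, values=values)
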