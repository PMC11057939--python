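"""Variant data model, variant I/O and the final feature-table merge.

Coordinates are 0-based half-open (BED convention) throughout the package;
VCF-style 1-based input is shifted on read. A missing annotation is always an
explicit ``None`` (rendered ``NA`` on disk), never a silently dropped column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

#: sentinel used for absent values inside feature blocks
MISSING = None

#: string written to (and read from) TSV output for a missing value
NA_TOKEN = "NA"


class VariantError(ValueError):
    """Raised for malformed or non-SNV variant input."""


@dataclass(frozen=True)
class VariantRecord:
    """One single-nucleotide variant.

    ``ref == alt`` is permitted: annotating all four possible nucleotides at a
    position is a supported use, and the identity substitution simply yields
    wild-type == mutant features downstream.
    """

    chrom: str
    start: int  # 0-based
    end: int  # 0-based exclusive
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.end - self.start != 1:
            raise VariantError(
                f"not a single-nucleotide variant: {self.chrom}:{self.start}-{self.end}"
            )
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if len(allele) != 1 or allele not in NUCLEOTIDES:
                raise VariantError(
                    f"not a single-nucleotide variant: {label} allele {allele!r} "
                    f"at {self.chrom}:{self.start}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.start, self.ref, self.alt)


class VariantSet:
    """Ordered collection of unique variants; input order is preserved."""

    def __init__(self, records: Iterable[VariantRecord]):
        self.records: list[VariantRecord] = []
        seen: set[tuple] = set()
        for rec in records:
            if rec.key in seen:
                raise VariantError(f"duplicate variant key {rec.key}")
            seen.add(rec.key)
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> VariantRecord:
        return self.records[i]

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [r.key for r in self.records]


@dataclass
class FeatureBlock:
    """Named column -> value mapping for one variant from one feature group."""

    variant_key: tuple[str, int, str, str]
    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.values) != len(set(self.values)):
            raise ValueError("duplicate column names within a feature block")

    def __getitem__(self, column: str) -> object:
        return self.values[column]


def read_variants(path: str | Path, dialect: str = "bed_like") -> VariantSet:
    """Read a variant list from a BED-like or minimal VCF-like TSV.

    bed_like lines carry ``chrom  start  end  ref  alt`` (0-based half-open);
    vcf_like lines carry ``chrom  pos  id  ref  alt`` with a 1-based POS that
    is converted to a 0-based start on read.
    """
    if dialect not in ("bed_like", "vcf_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise VariantError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
            try:
                if dialect == "bed_like":
                    chrom, start, end, ref, alt = fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4]
                else:
                    chrom, pos, _id, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
                    start, end = pos - 1, pos
            except ValueError as exc:
                raise VariantError(f"{path}:{lineno}: {exc}") from None
            try:
                records.append(VariantRecord(chrom, start, end, ref, alt))
            except VariantError as exc:
                raise VariantError(f"{path}:{lineno}: {exc}") from None
    return VariantSet(records)


class FeatureTable:
    """Wide per-variant feature table: one row per variant, merged columns."""

    KEY_COLUMNS = ("chrom", "start", "end", "ref", "alt")

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


def merge_feature_blocks(
    variants: VariantSet,
    blocks: Sequence[tuple[str, Mapping[tuple, FeatureBlock]]],
) -> FeatureTable:
    """Outer-merge per-group feature blocks into one table.

    ``blocks`` is a list of ``(group_name, {variant_key: FeatureBlock})``.
    Variants absent from a group's mapping get missing markers for every
    column that group emits. Column names colliding between groups are
    disambiguated by prefixing with the group name; non-colliding names are
    kept verbatim so domain-specified names (e.g. ``1_Propeller_Twist``)
    survive the merge.
    """
    keys = set(variants.keys())
    group_columns: dict[str, list[str]] = {}
    for group, mapping in blocks:
        if group in group_columns:
            raise ValueError(f"duplicate feature-group name {group!r}")
        cols: list[str] = []
        seen_cols: set[str] = set()
        for key, block in mapping.items():
            if key not in keys:
                raise ValueError(f"feature block for unknown variant {key} in group {group!r}")
            for col in block.values:
                if col not in seen_cols:
                    seen_cols.add(col)
                    cols.append(col)
        group_columns[group] = cols

    # resolve cross-group collisions by prefixing both sides
    counts: dict[str, int] = {}
    for cols in group_columns.values():
        for col in cols:
            counts[col] = counts.get(col, 0) + 1
    renamed: dict[str, dict[str, str]] = {}
    final_cols: list[str] = []
    for group, cols in group_columns.items():
        ren = {}
        for col in cols:
            out = f"{group}_{col}" if counts[col] > 1 else col
            ren[col] = out
            final_cols.append(out)
        renamed[group] = ren
    if len(final_cols) != len(set(final_cols)):
        dupes = sorted({c for c in final_cols if final_cols.count(c) > 1})
        raise ValueError(f"duplicate columns after merge: {dupes}")

    rows = []
    for rec in variants:
        row: dict[str, object] = {
            "chrom": rec.chrom,
            "start": rec.start,
            "end": rec.end,
            "ref": rec.ref,
            "alt": rec.alt,
        }
        for group, mapping in blocks:
            ren = renamed[group]
            block = mapping.get(rec.key)
            for col in group_columns[group]:
                value = block.values.get(col, MISSING) if block is not None else MISSING
                row[ren[col]] = value
        rows.append(row)

    frame = pd.DataFrame(rows, columns=list(FeatureTable.KEY_COLUMNS) + final_cols)
    return FeatureTable(frame)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write the table as TSV with a header row; missing values become ``NA``."""
    table.frame.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read back a TSV written by :func:`write_feature_table`."""
    frame = pd.read_csv(
        path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False, dtype={"chrom": str, "ref": str, "alt": str}
    )
    return FeatureTable(frame)
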