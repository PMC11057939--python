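"""Dinucleotide property features over four variant-centred configurations.

Each variant defines four dinucleotides: (1) left neighbour + wild-type
allele, (2) wild-type allele + right neighbour, (3) left neighbour + mutant
allele, (4) mutant allele + right neighbour. Every configuration is annotated
with all properties of a DiProDB-style table (125 conformational and
thermodynamic properties in the reference export), producing columns such as
``1_Propeller_Twist``. Dinucleotides are read on the + strand as written.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import pandas as pd

from snvfeat.core import MISSING, FeatureBlock, VariantRecord
from snvfeat.sequence import ReferenceGenome

ALL_DINUCLEOTIDES = ["".join(p) for p in product("ACGT", repeat=2)]


@dataclass
class DiPropTable:
    """Ordered property names + per-dinucleotide value vectors (all 16 rows)."""

    properties: list[str]
    values: dict[str, list[float]]

    def lookup(self, dinucleotide: str, prop: str) -> float:
        return self.values[dinucleotide][self.properties.index(prop)]


@dataclass
class ConfigQuad:
    """The four configuration dinucleotides; None where a neighbour is absent."""

    c1: str | None  # left + ref
    c2: str | None  # ref + right
    c3: str | None  # left + alt
    c4: str | None  # alt + right


def load_diprop_table(path: str | Path) -> DiPropTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "dinucleotide":
        raise ValueError(f"{path}: first column must be 'dinucleotide'")
    props = header[1:]
    if len(props) != len(set(props)):
        raise ValueError(f"{path}: duplicate property names")
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.isna().any().any():
        raise ValueError(f"{path}: ragged or non-numeric rows")
    values: dict[str, list[float]] = {}
    for _, row in frame.iterrows():
        values[str(row.iloc[0]).upper()] = [float(v) for v in row.iloc[1:]]
    missing = [d for d in ALL_DINUCLEOTIDES if d not in values]
    if missing:
        raise ValueError(f"{path}: missing dinucleotide rows {missing}")
    return DiPropTable(properties=props, values=values)


def dinucleotide_configs(genome: ReferenceGenome, variant: VariantRecord) -> ConfigQuad:
    """Build the four configurations from the flank-1 wild-type window.

    A variant at a contig edge lacks one neighbour: the affected
    configurations are None rather than errors.
    """
    length = genome.length(variant.chrom)
    left = genome.fetch(variant.chrom, variant.start - 1, variant.start) if variant.start > 0 else None
    right = genome.fetch(variant.chrom, variant.end, variant.end + 1) if variant.end < length else None
    return ConfigQuad(
        c1=left + variant.ref if left else None,
        c2=variant.ref + right if right else None,
        c3=left + variant.alt if left else None,
        c4=variant.alt + right if right else None,
    )


def diprop_block(
    genome: ReferenceGenome, variant: VariantRecord, table: DiPropTable
) -> FeatureBlock:
    """Columns ``{i}_{property}`` for configuration i in 1..4.

    Missing configurations (contig edge) and dinucleotides containing N emit
    missing markers for all their properties.
    """
    quad = dinucleotide_configs(genome, variant)
    values: dict[str, object] = {}
    for i, dinuc in enumerate((quad.c1, quad.c2, quad.c3, quad.c4), start=1):
        usable = dinuc is not None and dinuc in table.values
        vec = table.values[dinuc] if usable else None
        for j, prop in enumerate(table.properties):
            values[f"{i}_{prop}"] = vec[j] if vec is not None else MISSING
    return FeatureBlock(variant_key=variant.key, values=values)
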