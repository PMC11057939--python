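"""Table-driven pentamer DNA-shape profiles around a variant.

Five local structural descriptors of the double helix are predicted from
sequence by pentamer lookup: minor groove width (MGW), propeller twist
(ProT) and electrostatic potential (EP) are defined per base pair, while
helix twist (HelT) and roll (Roll) are defined per base-pair step. A sliding
window moves a pentamer along the sequence; the pentamer centred at position
i contributes the per-base value to i and the two per-step values to the
steps (i-1, i) and (i, i+1). Step values contributed by the two overlapping
pentamers are averaged.

Profiles are computed for both the wild-type and the mutant window; with the
default flank of 10 the window spans 21 positions and the variant sits at
position 11 (positions are numbered 1-based left to right). Step-defined
properties are reported at the position of the step's left base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from snvfeat.core import MISSING, FeatureBlock, VariantRecord
from snvfeat.sequence import ReferenceGenome, fetch_context

PER_BASE_PROPERTIES = ("MGW", "ProT", "EP")
PER_STEP_PROPERTIES = ("HelT", "Roll")
SHAPE_PROPERTIES = PER_BASE_PROPERTIES + PER_STEP_PROPERTIES

DEFAULT_FLANK = 10


@dataclass
class ShapeTable:
    """Pentamer lookup tables: per-base props map to one value, per-step to two."""

    per_base_props: dict[str, dict[str, float]] = field(default_factory=dict)
    per_step_props: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    @property
    def properties(self) -> list[str]:
        return list(self.per_base_props) + list(self.per_step_props)


@dataclass
class ShapeProfile:
    """Per-property position -> value maps over a window of length ``length``.

    Positions are 1-based; positions without a defined value (no covering
    pentamer, or an unknown pentamer) are absent from the maps.
    """

    length: int
    values: dict[str, dict[int, float]]

    def get(self, prop: str, position: int):
        return self.values.get(prop, {}).get(position, MISSING)


def load_shape_table(path: str | Path) -> ShapeTable:
    """Read TSV rows ``property  pentamer  value1 [value2]``.

    Known per-step properties (HelT, Roll) require two values; all others are
    per-base with one value.
    """
    table = ShapeTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            prop, pentamer = fields[0], fields[1].upper()
            if len(pentamer) != 5:
                raise ValueError(f"{path}:{lineno}: pentamer {pentamer!r} is not length 5")
            if prop in PER_STEP_PROPERTIES:
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: per-step property {prop} needs two values")
                table.per_step_props.setdefault(prop, {})[pentamer] = (
                    float(fields[2]),
                    float(fields[3]),
                )
            else:
                table.per_base_props.setdefault(prop, {})[pentamer] = float(fields[2])
    return table


def shape_profile(s: str, table: ShapeTable) -> ShapeProfile:
    """Slide a pentamer along ``s`` and collect shape values per position."""
    s = s.upper()
    length = len(s)
    values: dict[str, dict[int, float]] = {p: {} for p in table.properties}
    step_sums: dict[str, dict[int, list[float]]] = {p: {} for p in table.per_step_props}
    # pentamer centred at 1-based position c covers positions c-2 .. c+2
    for c in range(3, length - 1):
        pentamer = s[c - 3 : c + 2]
        for prop, lut in table.per_base_props.items():
            if pentamer in lut:
                values[prop][c] = lut[pentamer]
        for prop, lut in table.per_step_props.items():
            if pentamer in lut:
                v_left, v_right = lut[pentamer]
                # steps keyed by their left base: (c-1, c) -> c-1, (c, c+1) -> c
                step_sums[prop].setdefault(c - 1, []).append(v_left)
                step_sums[prop].setdefault(c, []).append(v_right)
    for prop, sums in step_sums.items():
        for step, contributions in sums.items():
            values[prop][step] = sum(contributions) / len(contributions)
    return ShapeProfile(length=length, values=values)


def shape_block(
    genome: ReferenceGenome,
    variant: VariantRecord,
    table: ShapeTable,
    flank: int = DEFAULT_FLANK,
) -> FeatureBlock:
    """Shape profiles for wild-type and mutant windows of the given flank.

    Columns ``{wt|mut}_{property}_pos{i}`` for i in 1..2*flank+1; with the
    default flank the variant's own values live in the ``*_pos11`` columns.
    """
    ctx = fetch_context(genome, variant, flank=flank, clamp=True)
    width = 2 * flank + 1
    # left clamping shifts positions: keep the variant at flank+1 by padding
    pad = flank - ctx.offset
    values: dict[str, object] = {}
    for label, seq in (("wt", ctx.wt_seq), ("mut", ctx.mut_seq)):
        profile = shape_profile(seq, table)
        for prop in SHAPE_PROPERTIES:
            for i in range(1, width + 1):
                values[f"{label}_{prop}_pos{i}"] = profile.get(prop, i - pad)
    return FeatureBlock(variant_key=variant.key, values=values)
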