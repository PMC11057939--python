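"""Point lookups in scored genomic tracks (conservation and mappability).

Tracks are consumed from local bedGraph-style files declared in a manifest
(``name  path  group``). The conservation feature group defaults to PhyloP
and PhastCons scores over seven alignments each plus Umap/Bismap mappability
over four read lengths each — 22 columns — but the manifest fully defines
which tracks exist. A variant's value is the score of the unique interval
containing its position (point query; no windowed aggregation).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

from snvfeat.core import MISSING, FeatureBlock, VariantRecord

TRACK_GROUPS = ("phylop", "phastcons", "umap", "bismap")


@dataclass
class ScoredTrack:
    """Sorted non-overlapping (start, end, value) intervals per chromosome."""

    name: str
    intervals: dict[str, tuple[list[int], list[int], list[float]]]  # starts, ends, values


@dataclass
class TrackManifest:
    entries: list[tuple[str, Path, str]]  # (track name, file path, group)


def load_track(path: str | Path, name: str) -> ScoredTrack:
    """Load a 4-column bedGraph-style TSV; intervals are sorted and must not overlap."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            per_chrom.setdefault(chrom, []).append((start, end, value))
    intervals: dict[str, tuple[list[int], list[int], list[float]]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping intervals on {chrom}: [{s1},{e1}) and starting {s2}"
                )
        intervals[chrom] = (
            [iv[0] for iv in ivs],
            [iv[1] for iv in ivs],
            [iv[2] for iv in ivs],
        )
    return ScoredTrack(name=name, intervals=intervals)


def query_track(track: ScoredTrack, chrom: str, pos: int):
    """Value of the interval containing ``pos`` (binary search), else missing."""
    if chrom not in track.intervals:
        return MISSING
    starts, ends, values = track.intervals[chrom]
    i = bisect_right(starts, pos) - 1
    if i >= 0 and pos < ends[i]:
        return values[i]
    return MISSING


def load_manifest(path: str | Path) -> TrackManifest:
    """Read a manifest TSV of (track name, file path, group); paths are
    resolved relative to the manifest's directory."""
    base = Path(path).parent
    entries = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (name, path, group)")
            name, fpath, group = fields[0], fields[1], fields[2]
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate track name {name!r}")
            names.add(name)
            entries.append((name, base / fpath, group))
    return TrackManifest(entries=entries)


def load_tracks(manifest: TrackManifest) -> list[tuple[str, str, ScoredTrack]]:
    """Load every manifest entry up front: a bad file fails at startup, not
    per variant. Returns (group, name, track) in manifest order."""
    return [(group, name, load_track(path, name)) for name, path, group in manifest.entries]


def conservation_block(
    variant: VariantRecord, tracks: list[tuple[str, str, ScoredTrack]]
) -> FeatureBlock:
    """One column per track, named ``{group}_{track name}``."""
    values: dict[str, object] = {}
    for group, name, track in tracks:
        values[f"{group}_{name}"] = query_track(track, variant.chrom, variant.start)
    return FeatureBlock(variant_key=variant.key, values=values)
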