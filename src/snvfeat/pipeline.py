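"""Feature-group registry, run configuration and the end-to-end runner.

Ten feature groups are registered; a run enables any subset, validates that
every required resource is present up front, extracts blocks per variant,
outer-merges them and writes one wide TSV. A failure inside one group for
one variant degrades to missing markers with a logged warning — a single bad
annotation must not abort a genome-scale run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from snvfeat import diprop, gccpg, kernel, peaks, protein, shape, tracks, vep
from snvfeat.core import (
    MISSING,
    FeatureBlock,
    FeatureTable,
    VariantSet,
    merge_feature_blocks,
    read_variants,
    write_feature_table,
)
from snvfeat.sequence import load_reference

logger = logging.getLogger(__name__)

#: registry: group name -> (required resource keys, description)
FEATURE_GROUPS: dict[str, tuple[tuple[str, ...], str]] = {
    "conservation": (("track_manifest",), "PhyloP/PhastCons conservation and Umap/Bismap mappability point lookups"),
    "vep": (("vep",), "consequence one-hot, wild-type/mutant amino-acid one-hot and transcript-distance statistics"),
    "dinucleotide": (("reference", "diprop_table"), "dinucleotide properties over four wild-type/mutant x left/right configurations"),
    "dna_shape": (("reference", "shape_table"), "pentamer DNA-shape profiles (MGW, HelT, ProT, Roll, EP) around the variant"),
    "gc_cpg": (("reference",), "GC content, CpG counts and observed/expected CpG ratios over nine windows"),
    "kernel": (("reference",), "p-spectrum kernels between wild-type and mutant windows plus their diagonals"),
    "subst_matrices": (("vep", "matrix_dir"), "amino-acid substitution scores from ten matrices"),
    "aa_properties": (("vep", "aa_property_table"), "amino-acid physicochemical properties for both residues"),
    "encode": (("peak_manifest",), "regulatory peak overlap statistics across eight assay groups"),
    "structure": (("vep", "uniprot_map", "structure_dir"), "mmCIF coordinates, IADP and secondary-structure one-hot"),
}


@dataclass
class RunConfig:
    """Paths to resources plus the enabled groups and per-group overrides."""

    variants: Path
    output: Path
    resources: dict[str, Path] = field(default_factory=dict)
    groups: list[str] = field(default_factory=lambda: list(FEATURE_GROUPS))
    variant_dialect: str = "bed_like"
    overrides: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, groups: list[str] | None = None,
                  output: str | Path | None = None) -> "RunConfig":
        """Load a YAML config; all paths are relative to the config's directory."""
        path = Path(path)
        base = path.parent
        doc = yaml.safe_load(path.read_text()) or {}
        resource_keys = sorted({k for req, _ in FEATURE_GROUPS.values() for k in req})
        resources = {k: base / doc[k] for k in resource_keys if k in doc}
        return cls(
            variants=base / doc["variants"],
            output=Path(output) if output else base / doc.get("output", "features.tsv"),
            resources=resources,
            groups=groups or doc.get("groups", list(FEATURE_GROUPS)),
            variant_dialect=doc.get("variant_dialect", "bed_like"),
            overrides=doc.get("overrides", {}),
        )

    def validate(self) -> list[str]:
        """Collect every configuration problem (empty list = valid)."""
        problems = []
        unknown = [g for g in self.groups if g not in FEATURE_GROUPS]
        for g in unknown:
            problems.append(f"unknown feature group {g!r}")
        if not Path(self.variants).exists():
            problems.append(f"variants file {self.variants} does not exist")
        for g in self.groups:
            if g in FEATURE_GROUPS:
                for key in FEATURE_GROUPS[g][0]:
                    if key not in self.resources:
                        problems.append(f"group {g!r} requires resource {key!r} which is not configured")
                    elif not Path(self.resources[key]).exists():
                        problems.append(f"group {g!r}: resource {key!r} path {self.resources[key]} does not exist")
        return problems


def list_groups() -> list[dict]:
    """Registry listing: name, required resources, description (sorted)."""
    return [
        {"name": name, "resources": list(req), "description": desc}
        for name, (req, desc) in sorted(FEATURE_GROUPS.items())
    ]


class _Extractors:
    """Loads resources once and exposes one per-variant callable per group."""

    def __init__(self, config: RunConfig):
        self.config = config
        r = config.resources
        ov = config.overrides
        need = {k for g in config.groups for k in FEATURE_GROUPS[g][0]}
        self.genome = load_reference(r["reference"]) if "reference" in need else None
        self.tracks = tracks.load_tracks(tracks.load_manifest(r["track_manifest"])) if "track_manifest" in need else None
        self.peakdbs = peaks.build_peakdb(peaks.load_peak_manifest(r["peak_manifest"])) if "peak_manifest" in need else None
        self.vep_records = vep.parse_vep(r["vep"]) if "vep" in need else None
        self.diprop_table = diprop.load_diprop_table(r["diprop_table"]) if "diprop_table" in need else None
        self.shape_table = shape.load_shape_table(r["shape_table"]) if "shape_table" in need else None
        self.matrices = protein.load_matrices(r["matrix_dir"]) if "matrix_dir" in need else None
        self.aa_table = protein.load_aa_property_table(r["aa_property_table"]) if "aa_property_table" in need else None
        self.uniprot_map = protein.load_uniprot_map(r["uniprot_map"]) if "uniprot_map" in need else None
        self.structure_dir = r.get("structure_dir")
        self.vocab = vep.ConsequenceVocabulary(ov["vep"]["vocabulary"]) if "vocabulary" in ov.get("vep", {}) else vep.ConsequenceVocabulary()
        self.gc_config = gccpg.GcCpgConfig(ov["gc_cpg"]["window_sizes"]) if "window_sizes" in ov.get("gc_cpg", {}) else gccpg.GcCpgConfig()
        kov = ov.get("kernel", {})
        self.kernel_windows = kov.get("window_sizes")
        self.kernel_kmers = kov.get("kmer_sizes")
        self.shape_flank = ov.get("dna_shape", {}).get("flank", shape.DEFAULT_FLANK)
        self._cif_cache: dict = {}

    def _vep_for(self, variant):
        return vep.records_for_variant(self.vep_records, variant)

    def extract(self, group: str, variant) -> FeatureBlock:
        if group == "conservation":
            return tracks.conservation_block(variant, self.tracks)
        if group == "vep":
            recs = self._vep_for(variant)
            values = dict(vep.consequence_onehot(recs, variant.key, self.vocab).values)
            _, aa_block = vep.amino_acid_block(recs, variant)
            values.update(aa_block.values)
            values.update(vep.distance_stats(recs, variant.key).values)
            return FeatureBlock(variant_key=variant.key, values=values)
        if group == "dinucleotide":
            return diprop.diprop_block(self.genome, variant, self.diprop_table)
        if group == "dna_shape":
            return shape.shape_block(self.genome, variant, self.shape_table, flank=self.shape_flank)
        if group == "gc_cpg":
            return gccpg.gc_cpg_block(self.genome, variant, self.gc_config)
        if group == "kernel":
            return kernel.kernel_block(self.genome, variant, self.kernel_windows, self.kernel_kmers)
        if group == "subst_matrices":
            wt, mut = vep.resolve_amino_acids(self._vep_for(variant))
            return protein.substitution_block(wt, mut, self.matrices, variant.key)
        if group == "aa_properties":
            wt, mut = vep.resolve_amino_acids(self._vep_for(variant))
            return protein.aa_property_block(wt, mut, self.aa_table, variant.key)
        if group == "encode":
            values: dict[str, object] = {}
            for gname in peaks.DEFAULT_ASSAY_GROUPS:
                db = self.peakdbs.get(gname, peaks.PeakDB(group=gname))
                matches = peaks.overlap_query(db, variant)
                values.update(peaks.aggregate_block(matches, gname, variant.key).values)
            return FeatureBlock(variant_key=variant.key, values=values)
        if group == "structure":
            recs = self._vep_for(variant)
            coding = [rec for rec in recs if rec.gene and rec.protein_pos]
            chosen = next((rec for rec in coding if rec.canonical), coding[0] if coding else None)
            gene = chosen.gene if chosen else None
            ppos = chosen.protein_pos if chosen else None
            return protein.structure_block(
                gene, ppos, self.uniprot_map, self.structure_dir,
                variant_key=variant.key, _cache=self._cif_cache,
            )
        raise ValueError(f"unknown feature group {group!r}")


def extract_features(config: RunConfig, variants: VariantSet | None = None) -> FeatureTable:
    """Extract all enabled groups for all variants and merge into one table."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))
    if variants is None:
        variants = read_variants(config.variants, dialect=config.variant_dialect)
    ex = _Extractors(config)
    blocks: list[tuple[str, dict]] = []
    counters: dict[str, int] = {}
    for group in config.groups:
        mapping: dict[tuple, FeatureBlock] = {}
        failures = 0
        for variant in variants:
            try:
                mapping[variant.key] = ex.extract(group, variant)
            except Exception:
                failures += 1
                logger.warning("group %r failed for variant %s; emitting missing values",
                               group, variant.key, exc_info=True)
        counters[group] = failures
        blocks.append((group, mapping))
    for group, failures in counters.items():
        logger.info("group %-16s variants annotated: %d, degraded to missing: %d",
                    group, len(variants) - failures, failures)
    return merge_feature_blocks(variants, blocks)


def run(config: RunConfig) -> FeatureTable:
    """Validate, extract, merge and write the feature table to the output path."""
    table = extract_features(config)
    write_feature_table(table, config.output)
    logger.info("wrote %d variants x %d columns to %s", len(table), len(table.columns), config.output)
    return table
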