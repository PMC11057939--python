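"""Deterministic synthetic inputs for the whole annotation pipeline.

Every external resource the extractors consume — reference FASTA, variant
list, scored tracks, peak collections, consequence-predictor output, the
dinucleotide / DNA-shape / amino-acid property tables, substitution matrices,
gene-to-UniProt mapping and mmCIF structures — can be generated offline from
one seed, so the full pipeline runs and is testable with no downloads.

Alongside the bundle a ``truth.json`` sidecar records expected feature values
for a sample of (variant, column) cells. The generator computes these
independently of the extraction code paths: track values come from its own
tiling arithmetic, peak aggregates from a linear scan, kernels from explicit
enumeration of all k-mers, shape values from direct pentamer lookup. End-to-
end tests compare the pipeline output against this sidecar.

All randomness flows from one seed through named substreams, so each
generator is individually reproducible; identical config + seed yields
byte-identical files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from snvfeat.peaks import DEFAULT_ASSAY_GROUPS
from snvfeat.protein import DEFAULT_MATRIX_NAMES, STANDARD_RESIDUES
from snvfeat.shape import PER_BASE_PROPERTIES, PER_STEP_PROPERTIES

TRACK_LAYOUT = {"phylop": 7, "phastcons": 7, "umap": 4, "bismap": 4}
TILE = 100  # track interval width (bp)


@dataclass
class FixtureConfig:
    seed: int = 0
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 12000})
    n_variants: int = 20
    peaks_per_file: int = 30
    structure_residues: int = 60
    n_diprop_properties: int = 125
    n_aa_properties: int = 532
    shape_flank: int = 10


def _rng(cfg: FixtureConfig, name: str) -> np.random.Generator:
    """Named substream: independent, reproducible per generator."""
    return np.random.default_rng([cfg.seed, zlib.crc32(name.encode())])


def make_genome(cfg: FixtureConfig, path: Path) -> dict[str, str]:
    rng = _rng(cfg, "genome")
    contigs = {}
    with open(path, "w") as fh:
        for name, length in cfg.contig_lengths.items():
            seq = "".join(rng.choice(list("ACGT"), size=length))
            contigs[name] = seq
            fh.write(f">{name}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    return contigs


def make_variants(cfg: FixtureConfig, contigs: dict[str, str], path: Path) -> list[tuple]:
    """SNVs at random positions (>=100 bp from contig ends), ref from the
    genome, alt != ref, sorted by position. Returns (chrom, start, ref, alt)."""
    rng = _rng(cfg, "variants")
    chroms = list(contigs)
    variants: list[tuple] = []
    seen: set[tuple] = set()
    while len(variants) < cfg.n_variants:
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = len(contigs[chrom])
        pos = int(rng.integers(100, length - 100))
        ref = contigs[chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if (chrom, pos, ref, alt) in seen:
            continue
        seen.add((chrom, pos, ref, alt))
        variants.append((chrom, pos, ref, alt))
    variants.sort(key=lambda v: (v[0], v[1], v[3]))
    with open(path, "w") as fh:
        for chrom, pos, ref, alt in variants:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{ref}\t{alt}\n")
    return variants


def _make_tracks(cfg: FixtureConfig, contigs, variants, outdir: Path, truth):
    """Full-coverage tiled tracks; truth value at a variant = its tile value."""
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    manifest_lines = ["name\tpath\tgroup"]
    for group, count in TRACK_LAYOUT.items():
        for i in range(1, count + 1):
            name = f"{group}{i}"
            rng = _rng(cfg, f"track:{name}")
            fname = f"{name}.bedgraph"
            with open(tracks_dir / fname, "w") as fh:
                tile_values = {}
                for chrom, seq in contigs.items():
                    values = np.round(rng.normal(0, 2, size=(len(seq) + TILE - 1) // TILE), 3)
                    tile_values[chrom] = values
                    for t, v in enumerate(values):
                        fh.write(f"{chrom}\t{t * TILE}\t{min((t + 1) * TILE, len(seq))}\t{v}\n")
            for chrom, pos, ref, alt in variants:
                truth[f"{chrom}:{pos}:{ref}:{alt}"][f"{group}_{name}"] = float(
                    tile_values[chrom][pos // TILE]
                )
            manifest_lines.append(f"{name}\ttracks/{fname}\t{group}")
    (outdir / "track_manifest.tsv").write_text("\n".join(manifest_lines) + "\n")


def _make_peaks(cfg: FixtureConfig, contigs, variants, outdir: Path, truth):
    """Random peaks per assay group plus one planted peak over the first
    variant; truth aggregates come from a linear scan in this function."""
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    manifest_lines = ["file\tformat\taccession\ttarget\tbiosample\toutput_type\tgroup"]
    chrom0, pos0 = variants[0][0], variants[0][1]
    for gi, group in enumerate(DEFAULT_ASSAY_GROUPS):
        rng = _rng(cfg, f"peaks:{group}")
        fmt = "narrowPeak" if gi % 2 == 0 else "broadPeak"
        group_peaks = []  # (chrom, start, end, signal, p, q, summit)
        for chrom, seq in contigs.items():
            for _ in range(cfg.peaks_per_file):
                width = int(rng.integers(50, 200))
                start = int(rng.integers(0, len(seq) - width))
                signal = round(float(rng.uniform(0.5, 20)), 3)
                p = round(float(rng.uniform(1, 10)), 3) if rng.random() > 0.2 else -1.0
                q = round(float(rng.uniform(0.5, 8)), 3) if rng.random() > 0.2 else -1.0
                summit = int(rng.integers(0, width)) if fmt == "narrowPeak" else -1
                group_peaks.append((chrom, start, start + width, signal, p, q, summit))
        # planted replicate pair over the first variant
        for signal in (4.0, 8.0):
            width = 120
            start = max(0, pos0 - 60)
            summit = 60 if fmt == "narrowPeak" else -1
            group_peaks.append((chrom0, start, start + width, signal, 2.5, 1.5, summit))
        fname = f"{group}.{fmt}"
        with open(peaks_dir / fname, "w") as fh:
            for chrom, start, end, signal, p, q, summit in group_peaks:
                row = [chrom, start, end, ".", 0, ".", signal, p, q]
                if fmt == "narrowPeak":
                    row.append(summit)
                fh.write("\t".join(str(x) for x in row) + "\n")
        manifest_lines.append(f"peaks/{fname}\t{fmt}\tACC{gi:04d}\ttarget{gi}\tcellA\t{fmt}\t{group}")
        # truth: linear scan per variant
        for chrom, pos, ref, alt in variants:
            hits = [p for p in group_peaks if p[0] == chrom and p[1] <= pos < p[2]]
            key = f"{chrom}:{pos}:{ref}:{alt}"
            truth[key][f"{group}_n_peaks"] = len(hits)
            for idx, fname_field in ((3, "signalValue"), (4, "pValue"), (5, "qValue"), (6, "peak_offset")):
                obs = [h[idx] for h in hits if h[idx] != -1]
                if obs:
                    truth[key][f"{group}_{fname_field}_min"] = min(obs)
                    truth[key][f"{group}_{fname_field}_max"] = max(obs)
                    truth[key][f"{group}_{fname_field}_mean"] = sum(obs) / len(obs)
                    truth[key][f"{group}_{fname_field}_range"] = max(obs) - min(obs)
    (outdir / "peak_manifest.tsv").write_text("\n".join(manifest_lines) + "\n")


def _make_vep(cfg: FixtureConfig, variants, outdir: Path, truth):
    """Predictor-style TSV: coding variants (even index) get one canonical
    missense transcript plus extras; odd-index variants are intronic with
    transcript distances."""
    rng = _rng(cfg, "vep")
    header = [
        "#Uploaded_variation", "Location", "Allele", "Gene", "Feature",
        "Consequence", "Amino_acids", "Protein_position", "DISTANCE", "CANONICAL",
    ]
    lines = ["\t".join(header)]
    coding_info = {}
    for vi, (chrom, pos, ref, alt) in enumerate(variants):
        key = f"{chrom}:{pos}:{ref}:{alt}"
        location = f"{chrom}:{pos + 1}"
        uploaded = f"var{vi}"
        if vi % 2 == 0:  # coding
            wt, mut = (str(r) for r in rng.choice(STANDARD_RESIDUES, size=2))
            gene = f"GENE{vi % 5}"
            ppos = int(rng.integers(1, cfg.structure_residues + 1))
            lines.append("\t".join([
                uploaded, location, alt, gene, f"ENST{vi:08d}",
                "missense_variant", f"{wt}/{mut}", str(ppos), "-", "YES",
            ]))
            lines.append("\t".join([
                uploaded, location, alt, gene, f"ENST{vi:08d}_alt",
                "missense_variant,splice_region_variant", f"{wt}/{mut}", str(ppos), "-", "",
            ]))
            coding_info[key] = (wt, mut, gene, ppos)
            truth[key]["missense_variant"] = 1
            truth[key]["splice_region_variant"] = 1
            truth[key]["intron_variant"] = 0
            truth[key][f"wt_aa_{wt}"] = 1
            truth[key][f"mut_aa_{mut}"] = 1
            truth[key]["dist_mean"] = None
        else:  # non-coding
            dists = sorted(int(d) for d in rng.integers(50, 5000, size=int(rng.integers(1, 4))))
            for di, dist in enumerate(dists):
                lines.append("\t".join([
                    uploaded, location, alt, "-", f"ENST{vi:08d}_{di}",
                    "intron_variant", "-", "-", str(dist), "",
                ]))
            truth[key]["intron_variant"] = 1
            truth[key]["missense_variant"] = 0
            truth[key]["dist_mean"] = sum(dists) / len(dists)
            truth[key]["dist_max"] = max(dists)
            truth[key]["dist_min"] = min(dists)
    (outdir / "vep.tsv").write_text("\n".join(lines) + "\n")
    return coding_info


def _make_diprop(cfg: FixtureConfig, contigs, variants, outdir: Path, truth):
    rng = _rng(cfg, "diprop")
    props = ["Propeller_Twist"] + [f"dp_prop_{i:03d}" for i in range(2, cfg.n_diprop_properties + 1)]
    dinucs = ["".join(p) for p in product("ACGT", repeat=2)]
    values = {d: np.round(rng.normal(0, 1, size=len(props)), 4) for d in dinucs}
    lines = ["dinucleotide\t" + "\t".join(props)]
    for d in dinucs:
        lines.append(d + "\t" + "\t".join(f"{v}" for v in values[d]))
    (outdir / "diprop.tsv").write_text("\n".join(lines) + "\n")
    # truth: first property for all four configurations of the first variants
    for chrom, pos, ref, alt in variants[:3]:
        key = f"{chrom}:{pos}:{ref}:{alt}"
        left, right = contigs[chrom][pos - 1], contigs[chrom][pos + 1]
        for i, d in enumerate((left + ref, ref + right, left + alt, alt + right), start=1):
            truth[key][f"{i}_Propeller_Twist"] = float(values[d][0])


def _make_shape_table(cfg: FixtureConfig, contigs, variants, outdir: Path, truth):
    rng = _rng(cfg, "shape")
    pentamers = ["".join(p) for p in product("ACGT", repeat=5)]
    per_base = {p: {} for p in PER_BASE_PROPERTIES}
    per_step = {p: {} for p in PER_STEP_PROPERTIES}
    lines = []
    for prop in PER_BASE_PROPERTIES:
        vals = np.round(rng.uniform(2, 6, size=len(pentamers)), 3)
        for pent, v in zip(pentamers, vals):
            per_base[prop][pent] = float(v)
            lines.append(f"{prop}\t{pent}\t{v}")
    for prop in PER_STEP_PROPERTIES:
        vals = np.round(rng.uniform(25, 40, size=(len(pentamers), 2)), 3)
        for pent, (v1, v2) in zip(pentamers, vals):
            per_step[prop][pent] = (float(v1), float(v2))
            lines.append(f"{prop}\t{pent}\t{v1}\t{v2}")
    (outdir / "shape.tsv").write_text("\n".join(lines) + "\n")
    # truth: wild-type per-base values at the variant position (window pos 11)
    for chrom, pos, ref, alt in variants[:3]:
        key = f"{chrom}:{pos}:{ref}:{alt}"
        pent = contigs[chrom][pos - 2 : pos + 3]
        for prop in PER_BASE_PROPERTIES:
            truth[key][f"wt_{prop}_pos{cfg.shape_flank + 1}"] = per_base[prop][pent]


def _make_matrices(cfg: FixtureConfig, outdir: Path, coding_info, variants, truth):
    mat_dir = outdir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    luts = {}
    for name in DEFAULT_MATRIX_NAMES:
        rng = _rng(cfg, f"matrix:{name}")
        raw = rng.integers(-8, 12, size=(20, 20))
        if name not in ("JTT_TM", "PHAT"):  # most published matrices are symmetric
            raw = np.tril(raw) + np.tril(raw, -1).T
        lut = {
            (a, b): int(raw[i, j])
            for i, a in enumerate(STANDARD_RESIDUES)
            for j, b in enumerate(STANDARD_RESIDUES)
        }
        luts[name] = lut
        lines = ["# synthetic substitution matrix", "   " + "  ".join(STANDARD_RESIDUES)]
        for i, a in enumerate(STANDARD_RESIDUES):
            lines.append(a + " " + " ".join(str(raw[i, j]) for j in range(20)))
        (mat_dir / f"{name}.txt").write_text("\n".join(lines) + "\n")
    for chrom, pos, ref, alt in variants:
        key = f"{chrom}:{pos}:{ref}:{alt}"
        if key in coding_info:
            wt, mut, _, _ = coding_info[key]
            for name in DEFAULT_MATRIX_NAMES:
                truth[key][f"subst_{name}"] = luts[name][(wt, mut)]


def _make_aa_table(cfg: FixtureConfig, outdir: Path, coding_info, variants, truth):
    rng = _rng(cfg, "aaprops")
    props = [f"aa_prop_{i:04d}" for i in range(1, cfg.n_aa_properties + 1)]
    values = {r: np.round(rng.normal(0, 1, size=len(props)), 4) for r in STANDARD_RESIDUES}
    lines = ["residue\t" + "\t".join(props)]
    for r in STANDARD_RESIDUES:
        lines.append(r + "\t" + "\t".join(str(v) for v in values[r]))
    (outdir / "aa_properties.tsv").write_text("\n".join(lines) + "\n")
    for chrom, pos, ref, alt in variants:
        key = f"{chrom}:{pos}:{ref}:{alt}"
        if key in coding_info:
            wt, mut, _, _ = coding_info[key]
            truth[key][f"wt_{props[0]}"] = float(values[wt][0])
            truth[key][f"mut_{props[0]}"] = float(values[mut][0])


def _make_structures(cfg: FixtureConfig, outdir: Path, coding_info, variants, truth):
    struct_dir = outdir / "structures"
    struct_dir.mkdir(exist_ok=True)
    genes = sorted({info[2] for info in coding_info.values()})
    mapping_lines = ["gene\taccession"]
    models = {}
    for gi, gene in enumerate(genes):
        accession = f"Q{gi:05d}"
        mapping_lines.append(f"{gene}\t{accession}")
        rng = _rng(cfg, f"cif:{accession}")
        n = cfg.structure_residues
        coords = np.round(rng.uniform(-50, 50, size=(n, 3)), 3)
        iadp = np.round(rng.uniform(30, 95, size=n), 2)
        helix_end = n // 3
        strand_beg, strand_end = n // 2, n // 2 + n // 4
        models[gene] = (coords, iadp, helix_end, strand_beg, strand_end)
        lines = [
            f"data_{accession}",
            "loop_",
            "_atom_site.group_PDB",
            "_atom_site.id",
            "_atom_site.label_atom_id",
            "_atom_site.auth_seq_id",
            "_atom_site.Cartn_x",
            "_atom_site.Cartn_y",
            "_atom_site.Cartn_z",
            "_atom_site.B_iso_or_equiv",
        ]
        atom_id = 1
        for ri in range(1, n + 1):
            x, y, z = coords[ri - 1]
            lines.append(f"ATOM {atom_id} N {ri} {x + 0.5} {y} {z} {iadp[ri - 1]}")
            atom_id += 1
            lines.append(f"ATOM {atom_id} CA {ri} {x} {y} {z} {iadp[ri - 1]}")
            atom_id += 1
        lines += [
            "loop_",
            "_struct_conf.id",
            "_struct_conf.conf_type_id",
            "_struct_conf.beg_auth_seq_id",
            "_struct_conf.end_auth_seq_id",
            f"c1 HELX_P 1 {helix_end}",
            f"c2 STRN {strand_beg} {strand_end}",
        ]
        (struct_dir / f"{accession}.cif").write_text("\n".join(lines) + "\n")
    (outdir / "uniprot_map.tsv").write_text("\n".join(mapping_lines) + "\n")
    for chrom, pos, ref, alt in variants:
        key = f"{chrom}:{pos}:{ref}:{alt}"
        if key in coding_info:
            _, _, gene, ppos = coding_info[key]
            coords, iadp, helix_end, strand_beg, strand_end = models[gene]
            truth[key]["X"], truth[key]["Y"], truth[key]["Z"] = (float(c) for c in coords[ppos - 1])
            truth[key]["IADP"] = float(iadp[ppos - 1])
            truth[key]["conf_HELX_P"] = 1 if 1 <= ppos <= helix_end else 0
            truth[key]["conf_STRN"] = 1 if strand_beg <= ppos <= strand_end else 0


def _kernel_truth(cfg: FixtureConfig, contigs, variants, truth):
    """Brute-force spectrum kernels for the first variant: enumerate every
    k-mer of the alphabet explicitly."""
    chrom, pos, ref, alt = variants[0]
    key = f"{chrom}:{pos}:{ref}:{alt}"
    for w, p in ((2, 1), (3, 2), (5, 3)):
        wt = contigs[chrom][pos - w : pos + w + 1]
        mut = wt[:w] + alt + wt[w + 1 :]
        kernel = diag_wt = diag_mut = 0
        for u in ("".join(t) for t in product("ACGT", repeat=p)):
            cs = sum(1 for i in range(len(wt) - p + 1) if wt[i : i + p] == u)
            ct = sum(1 for i in range(len(mut) - p + 1) if mut[i : i + p] == u)
            kernel += cs * ct
            diag_wt += cs * cs
            diag_mut += ct * ct
        truth[key][f"kernel_w{w}_k{p}"] = kernel
        truth[key][f"diag_wt_w{w}_k{p}"] = diag_wt
        truth[key][f"diag_mut_w{w}_k{p}"] = diag_mut


def _gc_truth(contigs, variants, truth):
    """Direct recount of GC / CpG statistics on the raw genome string."""
    chrom, pos, ref, alt = variants[0]
    key = f"{chrom}:{pos}:{ref}:{alt}"
    w = 50
    s = contigs[chrom][max(0, pos - w) : pos + w + 1]
    truth[key][f"gc_w{w}"] = (s.count("G") + s.count("C")) / len(s)
    cpg = sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG")
    truth[key][f"cpg_count_w{w}"] = cpg
    n_c, n_g = s.count("C"), s.count("G")
    truth[key][f"cpg_obs_exp_w{w}"] = cpg * len(s) / (n_c * n_g) if n_c and n_g else None


def make_annotation_bundle(cfg: FixtureConfig, outdir: str | Path) -> Path:
    """Generate the complete input bundle plus truth.json and a ready-to-run
    pipeline config; returns the bundle directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = make_genome(cfg, outdir / "genome.fa")
    variants = make_variants(cfg, contigs, outdir / "variants.tsv")
    truth: dict[str, dict] = {f"{c}:{p}:{r}:{a}": {} for c, p, r, a in variants}
    _make_tracks(cfg, contigs, variants, outdir, truth)
    _make_peaks(cfg, contigs, variants, outdir, truth)
    coding_info = _make_vep(cfg, variants, outdir, truth)
    _make_diprop(cfg, contigs, variants, outdir, truth)
    _make_shape_table(cfg, contigs, variants, outdir, truth)
    _make_matrices(cfg, outdir, coding_info, variants, truth)
    _make_aa_table(cfg, outdir, coding_info, variants, truth)
    _make_structures(cfg, outdir, coding_info, variants, truth)
    _kernel_truth(cfg, contigs, variants, truth)
    _gc_truth(contigs, variants, truth)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    config = "\n".join([
        "reference: genome.fa",
        "variants: variants.tsv",
        "track_manifest: track_manifest.tsv",
        "peak_manifest: peak_manifest.tsv",
        "vep: vep.tsv",
        "diprop_table: diprop.tsv",
        "shape_table: shape.tsv",
        "matrix_dir: matrices",
        "aa_property_table: aa_properties.tsv",
        "uniprot_map: uniprot_map.tsv",
        "structure_dir: structures",
        "output: features.tsv",
    ])
    (outdir / "config.yaml").write_text(config + "\n")
    return outdir
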