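"""Protein-level features for a coding variant.

From predictor output the affected gene, protein position and residue change
are known; the package then scores the substitution against ten matrices and
pulls the residue's coordinates, displacement parameter and secondary-
structure class from a local mmCIF file.
"""

from pathlib import Path
import tempfile

from snvfeat import fixtures
from snvfeat.protein import (
    load_matrices,
    load_uniprot_map,
    structure_block,
    substitution_block,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = fixtures.make_annotation_bundle(
        fixtures.FixtureConfig(seed=5, n_variants=4), Path(tmp) / "b"
    )
    matrices = load_matrices(bundle / "matrices")
    sub = substitution_block("R", "W", matrices)
    print("R->W substitution scores across the matrix set:")
    for name, value in sub.values.items():
        print(f"  {name:16s} {value}")

    umap = load_uniprot_map(bundle / "uniprot_map.tsv")
    gene = next(iter(umap.mapping))
    block = structure_block(gene, 5, umap, bundle / "structures")
    print(f"\nresidue 5 of {gene} ({umap.mapping[gene]}):")
    print(f"  coordinates ({block['X']}, {block['Y']}, {block['Z']}), IADP {block['IADP']}")
    conf = [c for c, v in block.values.items() if c.startswith("conf_") and v == 1]
    print(f"  conformation one-hot: {conf or 'none (coil)'}")
    print("negative matrix scores mark disfavoured substitutions; the structural")
    print("columns localise the residue in 3D and in secondary-structure context.")
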