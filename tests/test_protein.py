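"""Substitution matrices, amino-acid properties and mmCIF structural features."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from snvfeat.protein import (
    DEFAULT_MATRIX_NAMES,
    STANDARD_RESIDUES,
    SubstMatrixSet,
    UniProtMap,
    aa_property_block,
    load_aa_property_table,
    load_matrices,
    load_uniprot_map,
    parse_cif,
    parse_matrix_file,
    structure_block,
    substitution_block,
)


def write_matrix(path, values=None, residues=STANDARD_RESIDUES):
    rng = np.random.default_rng(5)
    n = len(residues)
    if values is None:
        values = rng.integers(-5, 10, size=(n, n))
    lines = ["# comment", "  " + " ".join(residues)]
    for i, r in enumerate(residues):
        lines.append(r + " " + " ".join(str(values[i, j]) for j in range(n)))
    path.write_text("\n".join(lines) + "\n")
    return values


class TestMatrices:
    def test_round_trip_against_reference_blosum62(self, tmp_path):
        """Serialise Biopython's BLOSUM62 into the text layout and re-parse:
        every (wt, mut) score must survive, both orientations defined."""
        ref = substitution_matrices.load("BLOSUM62")
        idx = {r: ref.alphabet.index(r) for r in STANDARD_RESIDUES}
        values = np.array([[int(ref[idx[a], idx[b]]) for b in STANDARD_RESIDUES] for a in STANDARD_RESIDUES])
        write_matrix(tmp_path / "BLOSUM62.txt", values)
        lut = parse_matrix_file(tmp_path / "BLOSUM62.txt")
        for a in STANDARD_RESIDUES:
            for b in STANDARD_RESIDUES:
                assert lut[(a, b)] == ref[idx[a], idx[b]]
        assert lut[("R", "W")] == lut[("W", "R")]  # BLOSUM62 is symmetric

    def test_ten_default_files_load(self, tmp_path):
        for name in DEFAULT_MATRIX_NAMES:
            write_matrix(tmp_path / f"{name}.txt")
        mset = load_matrices(tmp_path)
        assert mset.names() == DEFAULT_MATRIX_NAMES

    def test_incomplete_residue_set_rejected(self, tmp_path):
        write_matrix(tmp_path / "BAD.txt", residues=STANDARD_RESIDUES[:19])
        with pytest.raises(ValueError, match="missing residues"):
            parse_matrix_file(tmp_path / "BAD.txt")

    def test_block_values_are_exact_lookups(self, tmp_path):
        values = write_matrix(tmp_path / "M.txt")
        mset = load_matrices(tmp_path, names=["M"])
        rng = np.random.default_rng(1)
        for _ in range(50):
            wt, mut = rng.choice(STANDARD_RESIDUES, size=2)
            block = substitution_block(str(wt), str(mut), mset)
            i, j = STANDARD_RESIDUES.index(wt), STANDARD_RESIDUES.index(mut)
            assert block["subst_M"] == values[i, j]

    def test_identity_substitution_hits_diagonal(self, tmp_path):
        values = write_matrix(tmp_path / "M.txt")
        mset = load_matrices(tmp_path, names=["M"])
        i = STANDARD_RESIDUES.index("L")
        assert substitution_block("L", "L", mset)["subst_M"] == values[i, i]

    def test_undefined_residue_gives_missing(self, tmp_path):
        write_matrix(tmp_path / "M.txt")
        mset = load_matrices(tmp_path, names=["M"])
        assert substitution_block(None, "W", mset)["subst_M"] is None
        assert substitution_block("B", "W", mset)["subst_M"] is None


class TestAaProperties:
    def write_table(self, path, n_props=3):
        props = [f"q{i}" for i in range(n_props)]
        lines = ["residue\t" + "\t".join(props)]
        for i, r in enumerate(STANDARD_RESIDUES):
            lines.append(r + "\t" + "\t".join(str(i + j) for j in range(n_props)))
        path.write_text("\n".join(lines) + "\n")

    def test_columns_per_side(self, tmp_path):
        self.write_table(tmp_path / "aa.tsv")
        table = load_aa_property_table(tmp_path / "aa.tsv")
        block = aa_property_block("R", "W", table)
        assert len(block.values) == 6
        assert block["wt_q0"] == table.values["R"][0]
        assert block["mut_q2"] == table.values["W"][2]

    def test_identity_pairs_equal(self, tmp_path):
        self.write_table(tmp_path / "aa.tsv")
        table = load_aa_property_table(tmp_path / "aa.tsv")
        block = aa_property_block("G", "G", table)
        for p in table.properties:
            assert block[f"wt_{p}"] == block[f"mut_{p}"]

    def test_missing_residue_row_rejected(self, tmp_path):
        props = "residue\tq0\n" + "".join(f"{r}\t1\n" for r in STANDARD_RESIDUES[:10])
        (tmp_path / "aa.tsv").write_text(props)
        with pytest.raises(ValueError, match="missing residues"):
            load_aa_property_table(tmp_path / "aa.tsv")


CIF = """data_TEST
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.label_atom_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.B_iso_or_equiv
ATOM 1 N 5 0.9 1.9 2.9 40.0
ATOM 2 CA 5 1.0 2.0 3.0 50.0
ATOM 3 CA 6 4.0 5.0 6.0 60.0
loop_
_struct_conf.id
_struct_conf.conf_type_id
_struct_conf.beg_auth_seq_id
_struct_conf.end_auth_seq_id
c1 HELX_P 3 9
"""


class TestCif:
    def test_representative_atom_round_trip(self, tmp_path):
        (tmp_path / "x.cif").write_text(CIF)
        model = parse_cif(tmp_path / "x.cif")
        assert model.coords[5] == (1.0, 2.0, 3.0)
        assert model.iadp[5] == 50.0
        assert 4 not in model.coords  # no CA for residue 4

    def test_conformation_spans(self, tmp_path):
        (tmp_path / "x.cif").write_text(CIF)
        model = parse_cif(tmp_path / "x.cif")
        assert model.conf_spans == [("HELX_P", 3, 9)]
        assert model.conformation(5) == "HELX_P"
        assert model.conformation(10) is None

    def test_no_conformation_loop_still_parses(self, tmp_path):
        cif = CIF.split("loop_\n_struct_conf")[0]
        (tmp_path / "x.cif").write_text(cif)
        model = parse_cif(tmp_path / "x.cif")
        assert model.conf_spans == [] and model.coords[6] == (4.0, 5.0, 6.0)

    def test_no_atom_loop_rejected(self, tmp_path):
        (tmp_path / "x.cif").write_text("data_EMPTY\n_cell.length_a 1.0\n")
        with pytest.raises(ValueError, match="atom-site"):
            parse_cif(tmp_path / "x.cif")


class TestStructureBlock:
    @pytest.fixture
    def setup(self, tmp_path):
        (tmp_path / "Q12345.cif").write_text(CIF)
        return UniProtMap({"GENE1": "Q12345"}), tmp_path

    def test_helix_residue(self, setup):
        umap, sdir = setup
        block = structure_block("GENE1", 5, umap, sdir)
        assert (block["X"], block["Y"], block["Z"], block["IADP"]) == (1.0, 2.0, 3.0, 50.0)
        assert block["conf_HELX_P"] == 1 and block["conf_STRN"] == 0

    def test_unmapped_gene_all_missing(self, setup, caplog):
        umap, sdir = setup
        with caplog.at_level("WARNING"):
            block = structure_block("NOPE", 5, umap, sdir)
        assert all(v is None for v in block.values.values())

    def test_absent_file_degrades_not_raises(self, tmp_path):
        umap = UniProtMap({"GENE2": "P99999"})
        block = structure_block("GENE2", 1, umap, tmp_path)
        assert all(v is None for v in block.values.values())

    def test_at_most_one_conformation_hot(self, setup):
        umap, sdir = setup
        for pos in (1, 5, 6, 20):
            block = structure_block("GENE1", pos, umap, sdir)
            hot = sum(v for c, v in block.values.items() if c.startswith("conf_") and v == 1)
            assert hot <= 1


def test_uniprot_map_validates_accessions(tmp_path):
    (tmp_path / "map.tsv").write_text("gene\taccession\nG1\tQ12345\n")
    assert load_uniprot_map(tmp_path / "map.tsv").mapping == {"G1": "Q12345"}
    with pytest.raises(ValueError, match="accession"):
        UniProtMap({"G1": "notvalid!"})
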