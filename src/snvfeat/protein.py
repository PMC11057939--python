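"""Protein-level features: substitution-matrix scores, amino-acid properties
and structural descriptors from mmCIF files.

Substitution scores are looked up as matrix[wt][mut] (row = wild-type,
column = mutant) across a configurable set of matrices; the default set is
PAM40/160/250, BLOSUM30/45/62, GONNET, JTT, JTT_TM and PHAT. Amino-acid
property features annotate both residues with every property of an
AAindex-style table (532 properties in the reference export). Structural
features resolve a gene to a UniProt accession, open ``{accession}.cif`` in a
local directory and report the alpha-carbon X/Y/Z coordinates, the isotropic
atomic displacement parameter (IADP; predicted-structure files repurpose this
field for per-residue confidence, and it is reported as read) and a one-hot
encoding of the secondary-structure conformation type covering the residue.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import pandas as pd

from snvfeat.core import MISSING, FeatureBlock

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = list("ARNDCQEGHILKMFPSTWYV")

DEFAULT_MATRIX_NAMES = [
    "PAM40", "PAM160", "PAM250",
    "BLOSUM30", "BLOSUM45", "BLOSUM62",
    "GONNET", "JTT", "JTT_TM", "PHAT",
]

#: mmCIF struct_conf type labels used for the one-hot conformation encoding
DEFAULT_CONF_TYPES = ["HELX_P", "STRN", "TURN_P", "BEND"]

_ACCESSION_RE = re.compile(r"^[A-Z0-9]{6}([A-Z0-9]{4})?$")

REPRESENTATIVE_ATOM = "CA"


@dataclass
class SubstMatrixSet:
    """Ordered name -> {(wt, mut): score} lookups covering the 20 residues."""

    matrices: dict[str, dict[tuple[str, str], float]]

    def names(self) -> list[str]:
        return list(self.matrices)


@dataclass
class AaPropertyTable:
    properties: list[str]
    values: dict[str, list[float]]  # residue -> vector


@dataclass
class StructureModel:
    """Per-residue structural records parsed from one mmCIF file."""

    coords: dict[int, tuple[float, float, float]]  # residue index -> (x, y, z)
    iadp: dict[int, float]
    conf_spans: list[tuple[str, int, int]]  # (type label, start residue, end residue)

    def conformation(self, residue: int) -> str | None:
        """First span (file order) covering the residue; overlaps logged."""
        covering = [s for s in self.conf_spans if s[1] <= residue <= s[2]]
        if len(covering) > 1:
            logger.warning("residue %d covered by %d conformation spans; first wins", residue, len(covering))
        return covering[0][0] if covering else None


@dataclass
class UniProtMap:
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for gene, acc in self.mapping.items():
            if not _ACCESSION_RE.match(acc):
                raise ValueError(f"invalid UniProt accession {acc!r} for gene {gene!r}")


def parse_matrix_file(path: str | Path) -> dict[tuple[str, str], float]:
    """Parse a square substitution matrix in the standard text layout: a
    header row of residues, then one row per residue. Lines starting with
    '#' are comments. Row and column residue sets must match and cover the
    20 standard residues."""
    rows: dict[str, dict[str, float]] = {}
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if header is None:
                header = [f.upper() for f in fields]
                continue
            residue = fields[0].upper()
            if len(fields) - 1 != len(header):
                raise ValueError(f"{path}: row {residue} has {len(fields)-1} values, expected {len(header)}")
            rows[residue] = {col: float(v) for col, v in zip(header, fields[1:])}
    if header is None:
        raise ValueError(f"{path}: empty matrix file")
    if set(rows) != set(header):
        raise ValueError(f"{path}: row labels do not match column labels")
    missing = set(STANDARD_RESIDUES) - set(header)
    if missing:
        raise ValueError(f"{path}: matrix missing residues {sorted(missing)}")
    return {(r, c): rows[r][c] for r in header for c in header}


def load_matrices(directory: str | Path, names: list[str] | None = None) -> SubstMatrixSet:
    """Load matrix files from a directory; names default to the file stems of
    every file present, sorted by the default matrix order then alphabetically."""
    directory = Path(directory)
    files = {p.stem: p for p in sorted(directory.iterdir()) if p.is_file()}
    if names is None:
        order = [n for n in DEFAULT_MATRIX_NAMES if n in files]
        order += [n for n in sorted(files) if n not in order]
        names = order
    matrices = {}
    for name in names:
        if name not in files:
            raise FileNotFoundError(f"matrix file for {name!r} not found in {directory}")
        matrices[name] = parse_matrix_file(files[name])
    return SubstMatrixSet(matrices=matrices)


def substitution_block(
    wt_aa: str | None, mut_aa: str | None, matrices: SubstMatrixSet, variant_key: tuple = ()
) -> FeatureBlock:
    """One column per matrix: ``subst_{name}`` = score of the wt->mut change.

    Non-coding variants (either residue undefined) and residues outside a
    matrix's alphabet yield missing markers.
    """
    values: dict[str, object] = {}
    for name, lut in matrices.matrices.items():
        if wt_aa is None or mut_aa is None:
            values[f"subst_{name}"] = MISSING
        elif (wt_aa, mut_aa) not in lut:
            logger.warning("residue pair (%s, %s) outside matrix %s", wt_aa, mut_aa, name)
            values[f"subst_{name}"] = MISSING
        else:
            values[f"subst_{name}"] = lut[(wt_aa, mut_aa)]
    return FeatureBlock(variant_key=variant_key, values=values)


def load_aa_property_table(path: str | Path) -> AaPropertyTable:
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.columns[0] != "residue":
        raise ValueError(f"{path}: first column must be 'residue'")
    props = list(frame.columns[1:])
    values = {str(row.iloc[0]).upper(): [float(v) for v in row.iloc[1:]] for _, row in frame.iterrows()}
    missing = set(STANDARD_RESIDUES) - set(values)
    if missing:
        raise ValueError(f"{path}: missing residues {sorted(missing)}")
    return AaPropertyTable(properties=props, values=values)


def aa_property_block(
    wt_aa: str | None, mut_aa: str | None, table: AaPropertyTable, variant_key: tuple = ()
) -> FeatureBlock:
    """Columns ``wt_{prop}`` and ``mut_{prop}`` for every table property."""
    values: dict[str, object] = {}
    for side, aa in (("wt", wt_aa), ("mut", mut_aa)):
        vec = table.values.get(aa) if aa is not None else None
        for j, prop in enumerate(table.properties):
            values[f"{side}_{prop}"] = vec[j] if vec is not None else MISSING
    return FeatureBlock(variant_key=variant_key, values=values)


def parse_cif(path: str | Path, representative_atom: str = REPRESENTATIVE_ATOM) -> StructureModel:
    """Extract per-residue coordinates, IADP and conformation spans.

    The representative atom (alpha-carbon by default) supplies one X/Y/Z/IADP
    record per residue (author numbering); residues lacking it are absent.
    Conformation spans come from the struct_conf loop when present.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    atom_table = block.find(
        "_atom_site.",
        ["label_atom_id", "auth_seq_id", "Cartn_x", "Cartn_y", "Cartn_z", "B_iso_or_equiv"],
    )
    if len(atom_table) == 0:
        raise ValueError(f"{path}: no atom-site loop")
    coords: dict[int, tuple[float, float, float]] = {}
    iadp: dict[int, float] = {}
    for row in atom_table:
        if row[0].strip('"') != representative_atom:
            continue
        residue = int(row[1])
        if residue in coords:
            continue  # first model / altloc wins
        coords[residue] = (float(row[2]), float(row[3]), float(row[4]))
        iadp[residue] = float(row[5])
    conf_spans: list[tuple[str, int, int]] = []
    conf_table = block.find(
        "_struct_conf.", ["conf_type_id", "beg_auth_seq_id", "end_auth_seq_id"]
    )
    for row in conf_table:
        conf_spans.append((row[0], int(row[1]), int(row[2])))
    return StructureModel(coords=coords, iadp=iadp, conf_spans=conf_spans)


def load_uniprot_map(path: str | Path) -> UniProtMap:
    """Read a gene -> UniProt accession TSV (columns: gene, accession)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, acc = line.split("\t")[:2]
            mapping[gene] = acc
    return UniProtMap(mapping=mapping)


def structure_block(
    gene: str | None,
    protein_pos: int | None,
    uniprot_map: UniProtMap,
    structure_dir: str | Path,
    conf_types: list[str] | None = None,
    variant_key: tuple = (),
    _cache: dict | None = None,
) -> FeatureBlock:
    """Columns X, Y, Z, IADP plus one-hot ``conf_{type}`` for the residue.

    An unmapped gene, an absent structure file or an uncovered residue never
    aborts a run: coordinates degrade to missing markers and the conformation
    one-hots to all zeros (all missing when the whole structure is absent).
    """
    conf_types = conf_types if conf_types is not None else list(DEFAULT_CONF_TYPES)
    cols = ["X", "Y", "Z", "IADP"] + [f"conf_{t}" for t in conf_types]
    model: StructureModel | None = None
    if gene is not None and protein_pos is not None and protein_pos >= 1:
        accession = uniprot_map.mapping.get(gene)
        if accession is None:
            logger.warning("gene %r has no UniProt mapping", gene)
        else:
            cif_path = Path(structure_dir) / f"{accession}.cif"
            if _cache is not None and accession in _cache:
                model = _cache[accession]
            elif cif_path.exists():
                model = parse_cif(cif_path)
                if _cache is not None:
                    _cache[accession] = model
            else:
                logger.warning("structure file %s absent", cif_path)
    if model is None:
        values: dict[str, object] = {c: MISSING for c in cols}
        return FeatureBlock(variant_key=variant_key, values=values)
    values = {}
    xyz = model.coords.get(protein_pos)
    values["X"], values["Y"], values["Z"] = xyz if xyz else (MISSING, MISSING, MISSING)
    values["IADP"] = model.iadp.get(protein_pos, MISSING)
    conf = model.conformation(protein_pos)
    if conf is not None and conf not in conf_types:
        logger.warning("conformation type %r outside configured vocabulary", conf)
    for t in conf_types:
        values[f"conf_{t}"] = 1 if conf == t else 0
    return FeatureBlock(variant_key=variant_key, values=values)
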