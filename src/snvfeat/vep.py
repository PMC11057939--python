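"""Consequence-predictor (VEP-style) output parsing and derived features.

The predictor itself is not run (it needs a large external cache); its
standard tab-delimited output is consumed. Three feature families are
derived per variant:

* a multi-hot encoding of predicted transcript consequence terms — a column
  per Sequence Ontology term in the vocabulary, 1 if any transcript of the
  variant carries the term;
* wild-type / mutant amino acids, as a BED+2 row (chrom, start, end, wt, mut)
  and as one-hot columns over the 22-letter alphabet (20 standard residues,
  '*' stop, 'X' unknown);
* summary statistics (mean, max, min) of the variant's distances to
  transcripts when several transcripts are affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from snvfeat.core import MISSING, NA_TOKEN, FeatureBlock

logger = logging.getLogger(__name__)

AA_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY") + ["*", "X"]

#: Sequence Ontology consequence terms commonly emitted for SNVs
DEFAULT_CONSEQUENCE_TERMS = [
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "stop_retained_variant",
    "start_retained_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TF_binding_site_variant",
    "regulatory_region_variant",
    "intergenic_variant",
]


@dataclass
class VepRecord:
    """One (variant, transcript) row of predictor output."""

    variant_key: tuple[str, int, str] | tuple  # (chrom, start, alt) join key
    transcript: str
    consequences: list[str]
    wt_aa: str | None
    mut_aa: str | None
    distance: int | None
    gene: str | None = None
    protein_pos: int | None = None
    canonical: bool = False


@dataclass
class ConsequenceVocabulary:
    terms: list[str] = field(default_factory=lambda: list(DEFAULT_CONSEQUENCE_TERMS))

    def __post_init__(self) -> None:
        if not self.terms or len(self.terms) != len(set(self.terms)):
            raise ValueError("vocabulary must be non-empty and unique")


def _parse_location(location: str) -> tuple[str, int]:
    """'chrom:pos' or 'chrom:start-end' (1-based) -> (chrom, 0-based start)."""
    chrom, _, span = location.partition(":")
    pos = span.split("-")[0]
    return chrom, int(pos) - 1


def parse_vep(path: str | Path) -> list[VepRecord]:
    """Parse predictor tab output into one record per (variant, transcript).

    Required columns: Location, Allele, Consequence, Amino_acids, DISTANCE,
    Feature; Gene, Protein_position and CANONICAL are used when present.
    '-' fields are missing; 'R/W'-style Amino_acids split into wt/mut and a
    single letter (synonymous) maps to wt == mut.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment=None)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    required = ["Location", "Allele", "Consequence", "Amino_acids", "DISTANCE", "Feature"]
    absent = [c for c in required if c not in frame.columns]
    if absent:
        raise ValueError(f"{path}: missing required columns {absent}")
    records: list[VepRecord] = []
    bad: list[int] = []
    for idx, row in frame.iterrows():
        try:
            chrom, start = _parse_location(row["Location"])
        except (ValueError, AttributeError):
            bad.append(idx + 2)  # 1-based line number incl. header
            continue
        aa = row["Amino_acids"]
        wt_aa = mut_aa = None
        if aa and aa != "-":
            parts = aa.split("/")
            wt_aa = parts[0] or None
            mut_aa = (parts[1] if len(parts) > 1 else parts[0]) or None
        dist = row["DISTANCE"]
        distance = int(dist) if dist not in ("", "-") else None
        ppos_raw = row.get("Protein_position", "-")
        protein_pos = None
        if ppos_raw not in ("", "-"):
            protein_pos = int(str(ppos_raw).split("-")[0])
        gene = row.get("Gene", "-")
        records.append(
            VepRecord(
                variant_key=(chrom, start, row["Allele"].upper()),
                transcript=row["Feature"],
                consequences=[t for t in row["Consequence"].split(",") if t],
                wt_aa=wt_aa,
                mut_aa=mut_aa,
                distance=distance,
                gene=gene if gene not in ("", "-") else None,
                protein_pos=protein_pos,
                canonical=str(row.get("CANONICAL", "")).upper() == "YES",
            )
        )
    if bad:
        raise ValueError(f"{path}: unmappable variant keys on lines {bad}")
    return records


def records_for_variant(records: list[VepRecord], variant) -> list[VepRecord]:
    """Select the records matching a variant's (chrom, start, alt) key."""
    key = (variant.chrom, variant.start, variant.alt)
    return [r for r in records if r.variant_key == key]


def consequence_onehot(
    records: list[VepRecord],
    variant_key: tuple,
    vocab: ConsequenceVocabulary | None = None,
) -> FeatureBlock:
    """Multi-hot encoding: 1 per vocabulary term carried by ANY transcript."""
    vocab = vocab or ConsequenceVocabulary()
    present: set[str] = set()
    for rec in records:
        for term in rec.consequences:
            if term in vocab.terms:
                present.add(term)
            else:
                logger.warning("unknown consequence term %r ignored", term)
    values = {term: (1 if term in present else 0) for term in vocab.terms}
    return FeatureBlock(variant_key=variant_key, values=values)


def resolve_amino_acids(records: list[VepRecord]) -> tuple[str | None, str | None]:
    """Pick one (wt, mut) pair: the canonical transcript's if flagged, else
    the first coding record's. Conflicts are resolved deterministically and
    logged."""
    coding = [r for r in records if r.wt_aa is not None]
    if not coding:
        return None, None
    chosen = next((r for r in coding if r.canonical), coding[0])
    pairs = {(r.wt_aa, r.mut_aa) for r in coding}
    if len(pairs) > 1:
        logger.warning(
            "conflicting amino acids %s; using transcript %s", sorted(pairs), chosen.transcript
        )
    return chosen.wt_aa, chosen.mut_aa


def amino_acid_block(
    records: list[VepRecord], variant
) -> tuple[tuple, FeatureBlock]:
    """BED+2 row (chrom, start, end, wt_aa, mut_aa) plus one-hot columns
    ``wt_aa_{X}`` / ``mut_aa_{X}`` over the 22-letter alphabet. Non-coding
    variants get 'NA' amino acids and all-zero one-hots."""
    wt, mut = resolve_amino_acids(records)
    bed2 = (variant.chrom, variant.start, variant.end, wt or NA_TOKEN, mut or NA_TOKEN)
    values: dict[str, object] = {}
    for side, aa in (("wt", wt), ("mut", mut)):
        for letter in AA_ALPHABET:
            col = f"{side}_aa_{'stop' if letter == '*' else letter}"
            values[col] = 1 if aa == letter else 0
    return bed2, FeatureBlock(variant_key=variant.key, values=values)


def distance_stats(records: list[VepRecord], variant_key: tuple) -> FeatureBlock:
    """Mean/max/min distance to transcript over records with a distance."""
    dists = [r.distance for r in records if r.distance is not None]
    if dists:
        values = {
            "dist_mean": sum(dists) / len(dists),
            "dist_max": max(dists),
            "dist_min": min(dists),
        }
    else:
        values = {"dist_mean": MISSING, "dist_max": MISSING, "dist_min": MISSING}
    return FeatureBlock(variant_key=variant_key, values=values)
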