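"""Reference-genome access and wild-type/mutant context windows.

All sequence features are computed on the + (reference) strand. N bases are
preserved in windows; each downstream extractor decides how to handle them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from snvfeat.core import VariantRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ReferenceError(ValueError):
    """Raised for genome-lookup problems, including ref-allele mismatches."""


@dataclass
class ReferenceGenome:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    contigs: dict[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); out-of-bounds is an error, not truncation."""
        if chrom not in self.contigs:
            raise ReferenceError(f"unknown contig {chrom!r}")
        seq = self.contigs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ReferenceError(
                f"window [{start}, {end}) outside contig {chrom!r} of length {len(seq)}"
            )
        return seq[start:end]

    def length(self, chrom: str) -> int:
        if chrom not in self.contigs:
            raise ReferenceError(f"unknown contig {chrom!r}")
        return len(self.contigs[chrom])


@dataclass
class ContextPair:
    """A window around a variant in wild-type and mutant form.

    ``offset`` is the 0-based index of the variant base inside the window;
    the two sequences are equal everywhere except (possibly) that index.
    """

    wt_seq: str
    mut_seq: str
    offset: int


def load_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file; sequences are uppercased (soft-masking folded).

    The contig name is the first whitespace-delimited token of the header.
    Duplicate headers and empty files are errors.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ReferenceError(f"duplicate contig {record.id!r} in {path}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ReferenceError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs)


def fetch_context(
    genome: ReferenceGenome,
    variant: VariantRecord,
    flank: int,
    clamp: bool = True,
) -> ContextPair:
    """Build the wild-type/mutant pair for a window of ``flank`` bp per side.

    The window is ``[start - flank, start + flank + 1)``, intersected with the
    contig bounds when ``clamp`` is true (the reported offset reflects any
    left clamping). The genome base at the variant position must equal the
    declared ref allele; a mismatch is the primary user-facing sanity check.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    length = genome.length(variant.chrom)
    if not 0 <= variant.start < length:
        raise ReferenceError(
            f"variant position {variant.start} outside contig {variant.chrom!r}"
        )
    lo, hi = variant.start - flank, variant.start + flank + 1
    if clamp:
        lo, hi = max(lo, 0), min(hi, length)
    elif lo < 0 or hi > length:
        raise ReferenceError(
            f"window [{lo}, {hi}) outside contig {variant.chrom!r} and clamp=False"
        )
    wt = genome.fetch(variant.chrom, lo, hi)
    offset = variant.start - lo
    if wt[offset] != variant.ref:
        raise ReferenceError(
            f"reference allele mismatch at {variant.chrom}:{variant.start}: "
            f"genome has {wt[offset]!r}, variant declares {variant.ref!r}"
        )
    mut = wt[:offset] + variant.alt + wt[offset + 1 :]
    return ContextPair(wt_seq=wt, mut_seq=mut, offset=offset)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; other characters are errors."""
    seq = seq.upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters {bad} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]
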