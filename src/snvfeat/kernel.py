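"""p-spectrum kernel features comparing wild-type and mutant windows.

The p-spectrum of a sequence s is the vector of counts of every length-p
substring u (occurrences may overlap):

    Phi_u(s) = |{(v1, v2) : s = v1 u v2}|

The kernel between two sequences is the inner product of their spectra,

    K_p(s, t) = sum_u Phi_u(s) * Phi_u(t)

and the diagonal K_p(s, s) is the sum of squared counts. For each window
size w (flank width: w bases each side of the variant, total 2w+1) and each
k-mer size p the feature block carries the kernel between wild-type and
mutant windows plus both diagonals.
"""

from __future__ import annotations

from collections import Counter

from snvfeat.core import MISSING, FeatureBlock, VariantRecord
from snvfeat.sequence import ReferenceGenome, fetch_context

DEFAULT_WINDOW_SIZES = list(range(2, 21))  # flank widths w = 2..20
DEFAULT_KMER_SIZES = list(range(1, 21))  # p = 1..20


def kmer_spectrum(s: str, p: int) -> Counter:
    """Count all (overlapping) length-p substrings of s; empty if p > len(s)."""
    if p < 1:
        raise ValueError("k-mer size must be >= 1")
    return Counter(s[i : i + p] for i in range(len(s) - p + 1))


def spectrum_kernel(s: str, t: str, p: int) -> int:
    """K_p(s, t): inner product of the two p-spectra."""
    cs, ct = kmer_spectrum(s, p), kmer_spectrum(t, p)
    if len(ct) < len(cs):
        cs, ct = ct, cs
    return sum(n * ct[u] for u, n in cs.items())


def spectrum_diagonal(s: str, p: int) -> int:
    """K_p(s, s): sum of squared k-mer counts."""
    return sum(n * n for n in kmer_spectrum(s, p).values())


def kernel_block(
    genome: ReferenceGenome,
    variant: VariantRecord,
    window_sizes: list[int] | None = None,
    kmer_sizes: list[int] | None = None,
) -> FeatureBlock:
    """Kernel/diagonal features for every (window size, k-mer size) pair.

    Columns: ``kernel_w{w}_k{p}``, ``diag_wt_w{w}_k{p}``, ``diag_mut_w{w}_k{p}``.
    A p exceeding the (possibly clamped) window length is undefined, not an
    orthogonal spectrum, and yields missing markers; so does any window
    containing N, whose k-mer counts would be silently wrong.
    """
    windows = window_sizes if window_sizes is not None else DEFAULT_WINDOW_SIZES
    kmers = kmer_sizes if kmer_sizes is not None else DEFAULT_KMER_SIZES
    if not windows or not kmers or min(windows) < 1 or min(kmers) < 1:
        raise ValueError("window and k-mer size lists must be non-empty and positive")
    values: dict[str, object] = {}
    for w in windows:
        ctx = fetch_context(genome, variant, flank=w, clamp=True)
        has_n = "N" in ctx.wt_seq or "N" in ctx.mut_seq
        for p in kmers:
            cols = (f"kernel_w{w}_k{p}", f"diag_wt_w{w}_k{p}", f"diag_mut_w{w}_k{p}")
            if has_n or p > len(ctx.wt_seq):
                triple = (MISSING, MISSING, MISSING)
            else:
                triple = (
                    spectrum_kernel(ctx.wt_seq, ctx.mut_seq, p),
                    spectrum_diagonal(ctx.wt_seq, p),
                    spectrum_diagonal(ctx.mut_seq, p),
                )
            for col, val in zip(cols, triple):
                values[col] = val
    return FeatureBlock(variant_key=variant.key, values=values)
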