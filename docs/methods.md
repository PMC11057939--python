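# Methods

## Data model and coordinates

Variants are single-nucleotide substitutions held as (chrom, start, end,
ref, alt) with 0-based half-open coordinates; VCF-style 1-based input is
shifted on read. `ref == alt` is deliberately legal: annotating all four
nucleotides at a position is a supported workflow, and the identity
substitution flows through every extractor producing wild-type == mutant
features. Duplicate (chrom, start, ref, alt) keys are rejected. Every
feature group returns a named column→value block per variant; blocks are
outer-merged so a variant missing from one group gets explicit `NA`s, never
a dropped column. Column names are kept verbatim unless two groups emit the
same name, in which case both are prefixed with their group name — this
preserves the domain naming conventions (e.g. `1_Propeller_Twist`) while
guaranteeing uniqueness.

All sequence features are computed on the + strand as written; no strand
column is consumed. Windows are clamped at contig edges by default (with the
variant's true offset tracked) so telomeric variants degrade gracefully
rather than aborting a run. N bases are preserved at the sequence layer;
each extractor decides: the kernel refuses windows containing N (spurious
k-mer counts would be silently wrong), GC/CpG statistics exclude N from both
numerator and denominator, dinucleotide configurations containing N emit
missing markers.

## Feature groups

**Spectrum kernels.** Φᵖ_u(s) counts possibly-overlapping occurrences of
each k-mer u; K_p(s,t) is the inner product of count vectors, computed over
the union of observed k-mers (never the 4ᵖ alphabet). "Window size" w is
interpreted as flank width: the window spans 2w+1 bases with the variant
centred, which keeps the variant inside every window; defaults w ∈ 2..20,
p ∈ 1..20 give 19·20·3 = 1140 columns. A p larger than the window length is
undefined — reported missing, distinct from a legitimate kernel of 0
(orthogonal spectra). Only the raw kernel and the two diagonals are emitted;
normalisation is left to the consumer.

**GC/CpG.** Observed/expected CpG uses the Gardiner-Garden & Frommer form
N_CpG·L/(N_C·N_G) with L the N-free length; the ratio is undefined (missing)
when a window lacks C or G. Default flanks [50, 100, 200, 300, 400, 500,
1000, 2500, 5000] bp span local context up to CpG-island scale and are fully
configurable (exactly nine by default). Statistics use the wild-type window
only: one substitution is negligible at these scales and the alt identity is
carried by other groups.

**Dinucleotide properties.** The four configurations are
(left+ref, ref+right, left+alt, alt+right), read left-to-right on the +
strand; a property table must cover all 16 dinucleotides. Swapping ref and
alt swaps configuration pairs (1,2)↔(3,4), which the tests exploit.

**DNA shape.** Pentamer lookup with a sliding window: MGW/ProT/EP are
per-base (one value at the pentamer centre), HelT/Roll per-step (two values,
assigned to the steps flanking the centre; contributions of the two
overlapping pentamers to a shared step are averaged). Step values are
reported at the step's left base position. Both wild-type and mutant
profiles are emitted — the union subsumes either single choice — giving
5 × 2 × (2·flank+1) columns; flank defaults to 10 so the variant occupies
position 11. Shape values are data, not algorithm: the package ships no
table and accepts any pentamer TSV (the fixture generator produces a random
full 1024-pentamer table for tests, which exercises the mechanism, not the
biophysics).

**Conservation/mappability.** Point queries by binary search over sorted,
overlap-checked bedGraph-style intervals declared in a manifest; the
manifest defines the track inventory (conventionally 7 PhyloP + 7 PhastCons
+ 4 Umap + 4 Bismap = 22 columns), since the alignment identities are a user
choice. Files are loaded once at startup so a bad file fails fast.

**Predictor-derived features.** Consequence encoding is the union over
transcripts (multi-hot); unknown terms are warned about and ignored. The
amino-acid alphabet is the 20 standard residues plus `*` (stop, column
suffix `_stop`) and `X`, so stop-gain/readthrough is representable.
Conflicting per-transcript amino acids resolve to the transcript flagged
canonical, else the first record — deterministic and logged. Records join to
variants on (chrom, 0-based position, alt allele).

**Substitution matrices and residue properties.** Scores are looked up as
matrix[wt][mut] (row = wild-type); symmetric matrices make the orientation
moot, and the convention is stated here for the asymmetric ones (JTT_TM,
PHAT). Matrix files use the standard square text layout with residue header
row/column and must cover the 20 standard residues. Property tables are
residue × property TSVs; both residues are annotated (2 × 532 columns with
the reference-sized table).

**Peak overlap.** narrowPeak (BED6+4) and broadPeak (BED6+3) files carry
signal, −log10 p, −log10 q and (narrowPeak) a summit offset; −1 sentinels
are excluded from aggregation rather than averaged. Overlap uses an interval
tree with results ordered by file-then-line order; aggregates are
min/max/mean/range per field plus a count, with the mean computed by
compensated summation so it is permutation-invariant. Summits are aggregated
as offsets from peak start, not absolute coordinates, for replicate
comparability. Metadata (target, biosample) tags each peak but is not
expanded into per-biosample columns, avoiding column explosion.

**Structure.** The representative atom is the alpha-carbon (configurable);
the B-factor field is reported as IADP exactly as read — predicted-structure
files that store per-residue confidence there are not reinterpreted.
Conformation one-hots use the mmCIF struct_conf type vocabulary (default
HELX_P, STRN, TURN_P, BEND); overlapping spans resolve to the first in file
order, logged. A missing mapping, file or residue degrades to missing
values, never a mid-run failure.

## Synthetic data

The fixture generator emulates every input format: a uniform-random genome,
SNVs consistent with it, full-coverage tiled score tracks, random peak sets
plus a planted replicate pair over the first variant, predictor output with
coding (missense, canonical-flagged) and intronic records, full-size
property tables (16×125, 20×532, 1024-pentamer, ten 20×20 matrices) and
minimal mmCIF files with atom-site and struct_conf loops. All randomness
derives from one seed through named substreams (seed ⊕ CRC32 of the
generator name), so identical config+seed yields byte-identical bundles. A
`truth.json` sidecar records ~1600 expected feature values computed
*independently of the extraction code*: tile arithmetic for tracks, linear
scans for peak aggregates, explicit 4ᵖ enumeration for kernels, direct
recounts for GC/CpG, direct lookups for properties and structures. What the
synthetic bundle does **not** emulate: isochore/repeat structure, realistic
conservation autocorrelation, linkage between consequence terms and actual
codon changes, or real shape/property values — so passing tests demonstrate
extraction correctness and determinism, not biological calibration.

Default problem sizes — a 12 kb contig, 20 variants, ~30 peaks per assay
group, 60-residue structures — are chosen so the complete ten-group run and
the oracle-equivalence suites (1000 random instances each for the kernel and
the overlap query) finish in seconds on one core while still exercising
every code path, including clamped windows and missing annotations.

## Numerical and degenerate-input choices

Missing is always an explicit marker (`None` in memory, `NA` on disk);
0 and missing are never conflated (e.g. kernel p > window length vs kernel
0). Means use `math.fsum`. Interval and window boundaries are half-open
throughout; a position equal to an interval's end is outside it. Per-variant
extraction failures inside one group log a warning and yield missing values
for that group, because a genome-scale annotation run must not abort on one
bad record; configuration problems, by contrast, are all collected and
reported before any computation starts.

## Known limitations

Only SNVs are supported (no indels or rearrangements) and only one assembly
per run (no liftover). The consequence predictor is consumed, not run.
Strand-specific dinucleotide properties are read on the + strand; users
wanting reverse-complement folding should fold their property table.
Normalised kernels, CpG-island segmentation, per-biosample peak columns and
solvent-accessibility-style derived geometry are intentionally out of scope.
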