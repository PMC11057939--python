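# snvfeat

Feature extraction for single-nucleotide variants (SNVs). Machine-learning
models that predict whether a human SNV drives disease — as opposed to being
a neutral passenger — are only as good as the features behind them, and
assembling those features means navigating many heterogeneous resources.
`snvfeat` takes a variant list and a directory of local annotation resources
and computes **ten feature groups** per variant, merged into one wide TSV
(one row per variant, one column per feature, `NA` for unavailable values)
ready for direct use as model input:

1. **conservation** — PhyloP / PhastCons scores (seven alignments each) and
   Umap / Bismap mappability (four read lengths each) from local scored tracks;
2. **vep** — consequence-predictor output parsed into a multi-hot encoding of
   Sequence Ontology terms, wild-type/mutant amino-acid one-hots (plus a
   BED+2 file) and mean/max/min distances to affected transcripts;
3. **dinucleotide** — 125 conformational/thermodynamic dinucleotide
   properties over four configurations (wild-type and mutant allele, each
   paired with the left and right neighbour), columns `1_Propeller_Twist` …
   `4_…`;
4. **dna_shape** — pentamer-lookup DNA-shape profiles (MGW, HelT, ProT,
   Roll, EP) over ±10 bp for the wild-type and mutant window, with the
   variant at position 11;
5. **gc_cpg** — GC content, CpG counts and observed/expected CpG ratios over
   nine window sizes;
6. **kernel** — p-spectrum kernels between wild-type and mutant windows for
   window sizes 2–20 and k-mer sizes 1–20, with both diagonals;
7. **subst_matrices** — amino-acid substitution scores from ten matrices
   (PAM40/160/250, BLOSUM30/45/62, GONNET, JTT, JTT_TM, PHAT);
8. **aa_properties** — 532 physicochemical amino-acid properties for the
   wild-type and mutant residue;
9. **encode** — overlap statistics (min/max/mean/range of signal, p, q,
   summit, plus a peak count) against regulatory peak collections in eight
   assay groups (TF ChIP-seq, histone ChIP-seq, DNase-seq, Mint-ChIP-seq,
   ATAC-seq, eCLIP, ChIA-PET, GM DNase-seq);
10. **structure** — per-residue X/Y/Z coordinates, the isotropic atomic
    displacement parameter (IADP) and a secondary-structure one-hot from
    mmCIF files resolved via a gene→UniProt mapping.

The p-spectrum kernel at the package's core counts every length-p substring
u of a sequence s,

    Φᵖ_u(s) = |{(v₁, v₂) : s = v₁ u v₂}| ,

and compares wild-type window s with mutant window t through the inner
product K_p(s, t) = Σ_{u∈Σᵖ} Φᵖ_u(s) Φᵖ_u(t), together with the diagonals
K_p(s, s) and K_p(t, t).

All inputs are plain local files (FASTA, bedGraph-style TSV,
narrowPeak/broadPeak, predictor TSV, property tables, mmCIF); nothing is
downloaded at run time. A built-in fixture generator emits a complete
synthetic bundle so the full pipeline runs offline.

## Worked example

```python
from snvfeat.kernel import spectrum_kernel, spectrum_diagonal

wt  = "ACGTACGTACG"
mut = "ACGTAGGTACG"   # single C>G change at the centre
for p in (1, 2, 4, 6):
    print(p, spectrum_kernel(wt, mut, p),
             spectrum_diagonal(wt, p), spectrum_diagonal(mut, p))
```

prints

```
1 31 31 33
2 20 26 18
4 8 16 8
6 0 10 6
```

At p=1 the kernel (31) almost matches the diagonals — single-base
composition barely changes. By p=6 no 6-mer survives the substitution and
the kernel drops to 0 while the self-similarities stay positive: the gap
quantifies how strongly the variant disrupts local sequence structure.

Each script in `examples/` demonstrates one capability end to end
(`01_end_to_end.py` runs all ten groups on a synthetic bundle and prints the
20 × 3192 table it produces). The command-line interface mirrors the
library:

```bash
snvfeat fixtures --out bundle --seed 1        # synthetic input bundle
snvfeat list-groups                           # the ten groups + resources
snvfeat run --config bundle/config.yaml       # extract and write features.tsv
```

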