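"""Run the whole ten-group feature extraction on a synthetic bundle.

Generates a seeded input bundle (genome, variants and every annotation
resource), runs the pipeline and prints the resulting table shape plus one
variant's row excerpt. The output table has one row per variant; each column
is one numeric or one-hot feature, with NA marking unavailable annotations.
"""

from pathlib import Path
import tempfile

from snvfeat import fixtures, pipeline

with tempfile.TemporaryDirectory() as tmp:
    bundle = fixtures.make_annotation_bundle(fixtures.FixtureConfig(seed=1), Path(tmp) / "bundle")
    config = pipeline.RunConfig.from_yaml(bundle / "config.yaml")
    table = pipeline.run(config)
    print(f"feature table: {len(table)} variants x {len(table.columns)} columns")
    row = table.frame.iloc[0]
    sample = ["chrom", "start", "ref", "alt", "gc_w50", "kernel_w2_k1",
              "1_Propeller_Twist", "dist_mean", "tf_chip_n_peaks"]
    for col in sample:
        print(f"  {col:20s} {row[col]}")
    print("each value above is one feature of the first variant: GC content in a")
    print("101 bp window, a 1-mer spectrum kernel, a dinucleotide property for the")
    print("left-neighbour+ref configuration, the mean transcript distance, and the")
    print("number of overlapping TF ChIP-seq peaks.")
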