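"""Overlap a variant against a regulatory peak collection and aggregate.

Peaks carry a signal value, -log10 p/q values and a summit offset; when
several peaks (e.g. replicate assays) cover a variant the block reports
min/max/mean/range per field plus the peak count.
"""

from snvfeat.core import VariantRecord
from snvfeat.peaks import Peak, PeakDB, aggregate_block, overlap_query

db = PeakDB(group="tf_chip")
for i, (start, end, signal) in enumerate([(100, 400, 6.0), (250, 500, 10.0), (900, 950, 3.0)]):
    db.add(Peak("chr1", start, end, signal, p_value=4.0, q_value=2.0, peak=-1, order=i))

variant = VariantRecord("chr1", 300, 301, "A", "T")
hits = overlap_query(db, variant)
block = aggregate_block(hits, "tf_chip")
print(f"variant at chr1:300 overlaps {block['tf_chip_n_peaks']} of {db.n_peaks} peaks")
for stat in ("min", "max", "mean", "range"):
    print(f"  signal {stat:5s} = {block[f'tf_chip_signalValue_{stat}']}")
print("the two covering peaks have signals 6 and 10; the third lies elsewhere,")
print("so the aggregates summarise replicate evidence at this position only.")
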