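"""Classify peaks into genomic categories against an annotation.

Builds a tiny annotation (one coding gene with derived UTRs, one
non-coding RNA gene), then classifies peaks on both strands: sense
overlap gives CDS/5UTR/3UTR/RNA, opposite-strand overlap the antisense
(as-) counterparts, and no overlap is intergenic.  Assignment is by
maximal overlap, so a peak straddling a UTR/CDS junction goes to the
side it covers more.
"""

import crafdseq as cs

features = [
    cs.Feature(feature_id="glgC_cds", kind="CDS", strand="F", start=201,
               end=800, parent_gene="glgC", functional_category="carbon"),
    cs.Feature(feature_id="ncr1_rna", kind="RNA_gene", strand="R", start=1000,
               end=1120, parent_gene="ncr1"),
]
fs = cs.derive_utrs(cs.FeatureSet("demo", 2000, features))
print("features:")
for f in fs.features:
    print(f"  {f.feature_id:>10} {f.kind:>15} {f.strand} [{f.start}, {f.end}]")

peaks = [
    cs.Peak(peak_id=1, strand="F", start=300, end=380, mean_coverage=50.0),
    cs.Peak(peak_id=2, strand="R", start=320, end=400, mean_coverage=40.0),
    cs.Peak(peak_id=3, strand="F", start=120, end=230, mean_coverage=30.0),
    cs.Peak(peak_id=4, strand="R", start=1010, end=1100, mean_coverage=60.0),
    cs.Peak(peak_id=5, strand="F", start=1500, end=1550, mean_coverage=20.0),
]
annotations = cs.annotate_peaks(peaks, fs)
for a in annotations:
    print(f"peak {a.peak_id}: {a.category:>10}  "
          f"(feature {a.assigned_feature}, overlap {a.overlap_nt} nt)")

genes = cs.peaks_to_genes(annotations, fs)
print("sense targets:", genes.sense, "| antisense targets:", genes.antisense)
print("distribution:", cs.category_distribution(annotations))
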