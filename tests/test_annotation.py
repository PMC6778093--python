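import numpy as np
import pytest

import crafdseq as cs
from crafdseq.errors import CoordinateError, CrafdValidationError
from oracles import brute_classify


def feat(fid, kind, strand, start, end, parent=None, category=None):
    return cs.Feature(feature_id=fid, kind=kind, strand=strand, start=start,
                      end=end, parent_gene=parent, functional_category=category)


def peak(start, end, strand="F", pid=1):
    return cs.Peak(peak_id=pid, strand=strand, start=start, end=end,
                   mean_coverage=0.0)


GFF_SMALL = """##gff-version 3
##sequence-region chr 1 1000
chr\ttest\tgene\t101\t400\t.\t+\t.\tID=gene1;Name=abcX;category=translation
chr\ttest\tCDS\t101\t400\t.\t+\t.\tID=cds1;Parent=gene1
chr\ttest\tgene\t500\t620\t.\t-\t.\tID=gene2
chr\ttest\tncRNA\t500\t620\t.\t-\t.\tID=rna1;Parent=gene2
chr\ttest\tregion\t1\t1000\t.\t+\t.\tID=skipme
"""


class TestReadGff:
    def test_reads_cds_and_ncrna_with_gene_attributes(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_SMALL)
        fs = cs.read_gff(p, genome_length=1000)
        assert len(fs) == 2
        cds = fs.get("cds1")
        assert cds.kind == "CDS" and cds.strand == "F"
        assert cds.gene_name == "abcX"
        assert cds.functional_category == "translation"
        assert cds.parent_gene == "gene1"
        assert fs.get("rna1").kind == "RNA_gene"
        assert fs.get("rna1").strand == "R"

    def test_feature_beyond_genome_is_error(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text(GFF_SMALL)
        with pytest.raises(CoordinateError):
            cs.read_gff(p, genome_length=550)

    def test_write_read_round_trip_preserves_features(self, tmp_path):
        features = [
            feat("g1_cds", "CDS", "F", 201, 400, parent="g1", category="transport"),
            feat("g2_rna", "RNA_gene", "R", 600, 700, parent="g2"),
        ]
        fs = cs.FeatureSet("chr", 1000, features)
        p = tmp_path / "c.gff3"
        cs.write_gff(fs, p)
        back = cs.read_gff(p, 1000)
        assert {(f.feature_id, f.kind, f.strand, f.start, f.end)
                for f in back.features} == {
            ("g1_cds", "CDS", "F", 201, 400),
            ("g2_rna", "RNA_gene", "R", 600, 700),
        }
        assert back.get("g1_cds").functional_category == "transport"


class TestDeriveUtrs:
    def test_lone_forward_cds_gets_both_flanks(self):
        fs = cs.FeatureSet("g", 1000, [feat("c1", "CDS", "F", 201, 400, parent="g1")])
        out = cs.derive_utrs(fs, 100, 50)
        utrs = {(f.kind, f.start, f.end) for f in out.features if f.kind != "CDS"}
        assert utrs == {("five_prime_UTR", 101, 200), ("three_prime_UTR", 401, 450)}

    def test_reverse_strand_mirrors_flanks(self):
        fs = cs.FeatureSet("g", 1000, [feat("c1", "CDS", "R", 201, 400, parent="g1")])
        out = cs.derive_utrs(fs, 100, 50)
        utrs = {(f.kind, f.start, f.end) for f in out.features if f.kind != "CDS"}
        assert utrs == {("five_prime_UTR", 401, 500), ("three_prime_UTR", 151, 200)}

    def test_colliding_derived_utrs_split_at_midpoint(self):
        fs = cs.FeatureSet(
            "g", 1000,
            [feat("c1", "CDS", "F", 201, 400, parent="g1"),
             feat("c2", "CDS", "F", 451, 700, parent="g2")],
        )
        out = cs.derive_utrs(fs, 100, 50)
        got = {(f.feature_id, f.start, f.end) for f in out.features
               if f.kind == "three_prime_UTR" and f.parent_gene == "g1"}
        assert got == {("g1_3UTR", 401, 425)}
        got5 = {(f.feature_id, f.start, f.end) for f in out.features
                if f.kind == "five_prime_UTR" and f.parent_gene == "g2"}
        assert got5 == {("g2_5UTR", 426, 450)}

    def test_explicit_utr_suppresses_derivation_for_that_side(self):
        fs = cs.FeatureSet(
            "g", 1000,
            [feat("c1", "CDS", "F", 201, 400, parent="g1"),
             feat("u1", "five_prime_UTR", "F", 151, 200, parent="g1")],
        )
        out = cs.derive_utrs(fs, 100, 50)
        five = [f for f in out.features if f.kind == "five_prime_UTR"]
        assert [(f.feature_id, f.start, f.end) for f in five] == [("u1", 151, 200)]
        assert any(f.kind == "three_prime_UTR" for f in out.features)

    def test_derived_utrs_never_overlap_same_strand_features(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            feats = []
            pos = 1
            for i in range(8):
                pos += int(rng.integers(10, 300))
                length = int(rng.integers(50, 400))
                strand = "F" if rng.integers(0, 2) == 0 else "R"
                feats.append(feat(f"c{i}", "CDS", strand, pos, pos + length - 1,
                                  parent=f"g{i}"))
                pos += length
            fs = cs.FeatureSet("g", pos + 500, feats)
            out = cs.derive_utrs(fs, 100, 50)
            derived = [f for f in out.features
                       if f.kind in ("five_prime_UTR", "three_prime_UTR")]
            for d in derived:
                assert 1 <= d.start <= d.end <= out.length
                for other in out.features:
                    if other is d or other.strand != d.strand:
                        continue
                    assert d.end < other.start or d.start > other.end


class TestClassifyPeak:
    FS = cs.FeatureSet(
        "g", 1000,
        [feat("u5", "five_prime_UTR", "F", 81, 100, parent="g1"),
         feat("c1", "CDS", "F", 101, 400, parent="g1")],
    )

    def test_sense_and_antisense_cds(self):
        assert cs.classify_peak(peak(150, 180), self.FS).category == "CDS"
        assert cs.classify_peak(peak(150, 180, strand="R"), self.FS).category == "asCDS"

    def test_majority_overlap_beats_utr(self):
        a = cs.classify_peak(peak(95, 130), self.FS)
        assert a.category == "CDS" and a.overlap_nt == 30

    def test_no_overlap_is_intergenic(self):
        a = cs.classify_peak(peak(600, 650), self.FS)
        assert a.category == "intergenic" and a.assigned_feature is None

    def test_matches_brute_force_oracle_on_random_genomes(self):
        rng = np.random.default_rng(404)
        kinds = ["CDS", "RNA_gene", "five_prime_UTR", "three_prime_UTR"]
        for _ in range(5):
            feats = []
            for i in range(50):
                start = int(rng.integers(1, 4800))
                end = start + int(rng.integers(0, 300))
                feats.append(
                    feat(f"f{i}", kinds[int(rng.integers(0, 4))],
                         "F" if rng.integers(0, 2) == 0 else "R",
                         start, min(end, 5000), parent=f"g{i}")
                )
            fs = cs.FeatureSet("g", 5000, feats)
            tuples = [(f.feature_id, f.kind, f.strand, f.start, f.end)
                      for f in fs.features]
            for j in range(200):
                s = int(rng.integers(1, 4950))
                e = s + int(rng.integers(0, 120))
                strand = "F" if rng.integers(0, 2) == 0 else "R"
                p = peak(s, min(e, 5000), strand=strand, pid=j + 1)
                got = cs.classify_peak(p, fs)
                cat, fid, ov = brute_classify(p.start, p.end, strand, tuples)
                assert (got.category, got.assigned_feature, got.overlap_nt) == \
                    (cat, fid, ov)


class TestPeaksToGenes:
    def test_three_peaks_collapse_to_one_gene(self):
        fs = cs.FeatureSet(
            "g", 1000,
            [feat("u5", "five_prime_UTR", "F", 101, 200, parent="g1"),
             feat("c1", "CDS", "F", 201, 700, parent="g1"),
             feat("u3", "three_prime_UTR", "F", 701, 750, parent="g1")],
        )
        anns = cs.annotate_peaks(
            [peak(110, 150, pid=1), peak(300, 350, pid=2), peak(710, 730, pid=3)],
            fs,
        )
        out = cs.peaks_to_genes(anns, fs)
        assert out.sense == [("g1", [1, 2, 3])]
        assert out.antisense == []
        assert out.n_genes == 1

    def test_antisense_peaks_reported_separately(self):
        fs = cs.FeatureSet("g", 1000, [feat("c1", "CDS", "F", 101, 400, parent="g1")])
        anns = cs.annotate_peaks(
            [peak(150, 200, pid=1), peak(210, 260, strand="R", pid=2)], fs
        )
        out = cs.peaks_to_genes(anns, fs)
        assert out.sense == [("g1", [1])]
        assert out.antisense == [("g1", [2])]

    def test_unique_gene_count_bounded_by_peak_count(self, default_sim):
        _, fs, libs = default_sim
        probes = [peak(r.start, r.end, strand=r.strand, pid=r.truth_id)
                  for r in libs.truth.rows]
        anns = cs.annotate_peaks(probes, fs)
        out = cs.peaks_to_genes(anns, fs)
        assert out.n_genes <= len(probes)

    def test_empty_annotations_give_empty_result(self):
        fs = cs.FeatureSet("g", 100, [])
        out = cs.peaks_to_genes([], fs)
        assert out.sense == [] and out.antisense == []


class TestCategoryDistribution:
    def _ann(self, pid, cat):
        return cs.PeakAnnotation(peak_id=pid, category=cat,
                                 assigned_feature=None, overlap_nt=0)

    def test_fractions(self):
        anns = [self._ann(1, "CDS"), self._ann(2, "CDS"),
                self._ann(3, "asCDS"), self._ann(4, "5UTR")]
        assert cs.category_distribution(anns) == {
            "CDS": 0.5, "5UTR": 0.25, "asCDS": 0.25
        }

    def test_all_intergenic_and_order_invariance(self):
        anns = [self._ann(i, "intergenic") for i in range(3)]
        assert cs.category_distribution(anns) == {"intergenic": 1.0}
        mixed = [self._ann(1, "CDS"), self._ann(2, "RNA"), self._ann(3, "asRNA")]
        assert cs.category_distribution(mixed) == \
            cs.category_distribution(list(reversed(mixed)))

    def test_distribution_is_probability_vector(self, default_sim):
        _, fs, libs = default_sim
        probes = [peak(r.start, r.end, strand=r.strand, pid=r.truth_id)
                  for r in libs.truth.rows]
        dist = cs.category_distribution(cs.annotate_peaks(probes, fs))
        assert all(v > 0 for v in dist.values())
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_list_is_domain_error(self):
        with pytest.raises(CrafdValidationError):
            cs.category_distribution([])
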