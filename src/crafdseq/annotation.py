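"""Genomic-category classification of peaks against an annotation.

Peaks are assigned to one of eight genomic categories — CDS, 5'UTR,
3'UTR, RNA (non-coding RNA gene) and their antisense counterparts
(asCDS, as5UTR, as3UTR, asRNA) — plus ``intergenic`` for peaks that
overlap nothing.  Assignment picks the single feature with the largest
overlap in nucleotides, regardless of strand; the category is
antisense-prefixed when the winning feature lies on the strand opposite
the peak.  Sense and antisense features therefore compete on equal
footing, which matters for baits whose targets are predominantly
antisense RNAs.

Annotations are read from GFF3 (via :mod:`gffutils`).  Where a GFF has
no explicit UTR records, :func:`derive_utrs` adds fixed-width flanking
UTRs clipped against neighbouring same-strand features.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

from .coverage import Strand
from .errors import CoordinateError, CrafdValidationError
from .peaks import Peak

logger = logging.getLogger(__name__)

FeatureKind = str  # "CDS" | "RNA_gene" | "five_prime_UTR" | "three_prime_UTR"

#: output order of peak categories
CATEGORIES = [
    "CDS", "5UTR", "3UTR", "RNA",
    "asCDS", "as5UTR", "as3UTR", "asRNA",
    "intergenic",
]

_KIND_TO_CATEGORY = {
    "CDS": "CDS",
    "RNA_gene": "RNA",
    "five_prime_UTR": "5UTR",
    "three_prime_UTR": "3UTR",
}

# tie-break precedence among equally overlapping feature kinds
_KIND_PRECEDENCE = {
    "five_prime_UTR": 0,
    "three_prime_UTR": 1,
    "RNA_gene": 2,
    "CDS": 3,
}

_GFF_TYPE_TO_KIND = {
    "CDS": "CDS",
    "ncRNA": "RNA_gene",
    "tRNA": "RNA_gene",
    "rRNA": "RNA_gene",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
}


@dataclass(frozen=True)
class Feature:
    """One annotated element: a CDS, an RNA gene, or a UTR.

    ``parent_gene`` links UTRs and CDSs to their gene; 1-based inclusive
    coordinates on forward-strand numbering, ``strand`` in {F, R}.
    """

    feature_id: str
    kind: FeatureKind
    strand: Strand
    start: int
    end: int
    gene_name: str | None = None
    functional_category: str | None = None
    parent_gene: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CrafdValidationError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.kind not in _KIND_PRECEDENCE:
            raise CrafdValidationError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class FeatureSet:
    """All features of one replicon with an interval index."""

    def __init__(self, genome_id: str, length: int, features: Iterable[Feature]):
        self.genome_id = genome_id
        self.length = int(length)
        self.features: list[Feature] = sorted(
            features, key=lambda f: (f.start, f.end, f.feature_id)
        )
        for f in self.features:
            if f.start < 1 or f.end > self.length:
                raise CoordinateError(
                    f"feature {f.feature_id} [{f.start}, {f.end}] outside "
                    f"genome of length {self.length}"
                )
        self._tree = IntervalTree()
        for f in self.features:
            self._tree[f.start : f.end + 1] = f
        self._by_id = {f.feature_id: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def get(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def overlapping(self, start: int, end: int) -> list[Feature]:
        """Features overlapping the 1-based inclusive interval, either strand."""
        return [iv.data for iv in self._tree.overlap(start, end + 1)]

    def genes(self) -> dict[str, list[Feature]]:
        """Group features by parent gene id (features without a parent
        group under their own id)."""
        out: dict[str, list[Feature]] = defaultdict(list)
        for f in self.features:
            out[f.parent_gene or f.feature_id].append(f)
        return dict(out)


@dataclass(frozen=True)
class PeakAnnotation:
    """Category assignment of one peak."""

    peak_id: int
    category: str
    assigned_feature: str | None
    overlap_nt: int
    gene_id: str | None = None


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path, genome_length: int, category_key: str = "category") -> FeatureSet:
    """Read CDS / ncRNA / UTR records from a GFF3 file.

    Gene-level ``Name`` and functional-category attributes are inherited
    by child features through their ``Parent`` links; records of other
    types are skipped with a logged count.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome_id = "genome"
    gene_meta: dict[str, tuple[str | None, str | None]] = {}
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", [None])[0]
        cat = g.attributes.get(category_key, [None])[0]
        gene_meta[g.id] = (name, cat)
        genome_id = g.seqid
    features: list[Feature] = []
    skipped = 0
    for rec in db.all_features():
        if rec.featuretype == "gene":
            continue
        kind = _GFF_TYPE_TO_KIND.get(rec.featuretype)
        if kind is None or rec.strand not in ("+", "-"):
            skipped += 1
            continue
        if rec.start < 1 or rec.end > genome_length:
            raise CoordinateError(
                f"{rec.id or rec.featuretype} [{rec.start}, {rec.end}] outside "
                f"genome of length {genome_length}"
            )
        parent = rec.attributes.get("Parent", [None])[0]
        name, cat = gene_meta.get(parent, (None, None))
        own_cat = rec.attributes.get(category_key, [None])[0]
        features.append(
            Feature(
                feature_id=rec.id or f"{rec.featuretype}:{rec.start}-{rec.end}",
                kind=kind,
                strand="F" if rec.strand == "+" else "R",
                start=rec.start,
                end=rec.end,
                gene_name=rec.attributes.get("Name", [name])[0] or name,
                functional_category=own_cat or cat,
                parent_gene=parent,
            )
        )
        genome_id = rec.seqid
    if skipped:
        logger.info("read_gff: skipped %d records of unhandled type/strand", skipped)
    return FeatureSet(genome_id=genome_id, length=genome_length, features=features)


def write_gff(fs: FeatureSet, path) -> None:
    """Write a FeatureSet as GFF3 with explicit gene parents (deterministic)."""
    kind_to_type = {v: k for k, v in _GFF_TYPE_TO_KIND.items() if v != "RNA_gene"}
    kind_to_type["RNA_gene"] = "ncRNA"
    genes = fs.genes()
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {fs.genome_id} 1 {fs.length}\n")
        for gene_id in sorted(genes, key=lambda g: min(f.start for f in genes[g])):
            members = genes[gene_id]
            g_start = min(f.start for f in members)
            g_end = max(f.end for f in members)
            strand = "+" if members[0].strand == "F" else "-"
            name = next((f.gene_name for f in members if f.gene_name), None)
            cat = next(
                (f.functional_category for f in members if f.functional_category), None
            )
            attrs = [f"ID={gene_id}"]
            if name:
                attrs.append(f"Name={name}")
            if cat:
                attrs.append(f"category={cat}")
            fh.write(
                "\t".join(
                    [fs.genome_id, "crafdseq", "gene", str(g_start), str(g_end),
                     ".", strand, ".", ";".join(attrs)]
                ) + "\n"
            )
            for f in sorted(members, key=lambda f: (f.start, f.feature_id)):
                fh.write(
                    "\t".join(
                        [fs.genome_id, "crafdseq", kind_to_type[f.kind],
                         str(f.start), str(f.end), ".",
                         "+" if f.strand == "F" else "-", ".",
                         f"ID={f.feature_id};Parent={gene_id}"]
                    ) + "\n"
                )


# ---------------------------------------------------------------------------
# UTR derivation
# ---------------------------------------------------------------------------

def derive_utrs(
    fs: FeatureSet, five_prime_flank: int = 100, three_prime_flank: int = 50
) -> FeatureSet:
    """Add fixed-width UTRs to CDSs that lack explicit ones.

    For each CDS whose parent gene has no explicit 5' (3') UTR, a
    flanking interval of ``five_prime_flank`` (``three_prime_flank``) nt
    is added upstream (downstream), strand-aware.  Derived intervals are
    clipped at the genome ends and at the nearest same-strand existing
    feature; two derived intervals that would still collide are truncated
    at the midpoint of their overlap.  Derived UTRs therefore never
    overlap any same-strand feature.
    """
    existing_by_strand: dict[str, list[Feature]] = {"F": [], "R": []}
    for f in fs.features:
        existing_by_strand[f.strand].append(f)

    has_utr: dict[tuple[str, str], bool] = {}
    for f in fs.features:
        if f.kind in ("five_prime_UTR", "three_prime_UTR"):
            has_utr[(f.parent_gene or f.feature_id, f.kind)] = True

    derived: list[Feature] = []
    for cds in fs.features:
        if cds.kind != "CDS":
            continue
        gene = cds.parent_gene or cds.feature_id
        sides = []
        if not has_utr.get((gene, "five_prime_UTR")):
            if cds.strand == "F":
                sides.append(("five_prime_UTR", cds.start - five_prime_flank, cds.start - 1))
            else:
                sides.append(("five_prime_UTR", cds.end + 1, cds.end + five_prime_flank))
        if not has_utr.get((gene, "three_prime_UTR")):
            if cds.strand == "F":
                sides.append(("three_prime_UTR", cds.end + 1, cds.end + three_prime_flank))
            else:
                sides.append(("three_prime_UTR", cds.start - three_prime_flank, cds.start - 1))
        for kind, lo, hi in sides:
            lo = max(lo, 1)
            hi = min(hi, fs.length)
            # clip against nearest same-strand existing features
            for other in existing_by_strand[cds.strand]:
                if other is cds:
                    continue
                if other.start <= hi and other.end >= lo:
                    if other.start > cds.end:  # neighbour downstream of CDS
                        hi = min(hi, other.start - 1)
                    elif other.end < cds.start:  # neighbour upstream
                        lo = max(lo, other.end + 1)
                    else:
                        # overlaps the CDS itself; clip on the flank side
                        if lo > cds.end:
                            lo = max(lo, other.end + 1)
                        else:
                            hi = min(hi, other.start - 1)
            if lo > hi:
                continue
            suffix = "5UTR" if kind == "five_prime_UTR" else "3UTR"
            derived.append(
                Feature(
                    feature_id=f"{gene}_{suffix}",
                    kind=kind,
                    strand=cds.strand,
                    start=lo,
                    end=hi,
                    gene_name=cds.gene_name,
                    functional_category=cds.functional_category,
                    parent_gene=gene,
                )
            )

    derived = _resolve_derived_collisions(derived, fs)
    return FeatureSet(fs.genome_id, fs.length, [*fs.features, *derived])


def _resolve_derived_collisions(
    derived: list[Feature], fs: FeatureSet
) -> list[Feature]:
    """Truncate overlapping derived intervals at the midpoint of their overlap
    (left interval keeps the floor position); drop emptied intervals."""
    gene_start = {
        gid: min(f.start for f in members) for gid, members in fs.genes().items()
    }
    out: list[Feature] = []
    for strand in ("F", "R"):
        group = sorted(
            (f for f in derived if f.strand == strand),
            key=lambda f: (f.start, gene_start.get(f.parent_gene, f.start), f.feature_id),
        )
        resolved: list[Feature] = []
        for f in group:
            while resolved and f is not None:
                prev = resolved[-1]
                if f.start > prev.end:
                    break
                o1, o2 = max(prev.start, f.start), min(prev.end, f.end)
                mid = (o1 + o2) // 2
                prev2 = replace(prev, end=mid) if mid >= prev.start else None
                f2 = replace(f, start=mid + 1) if mid + 1 <= f.end else None
                resolved.pop()
                if prev2 is not None:
                    resolved.append(prev2)
                f = f2
            if f is not None:
                resolved.append(f)
        out.extend(resolved)
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_peak(peak: Peak, fs: FeatureSet) -> PeakAnnotation:
    """Assign one peak to its genomic category.

    Among all features overlapping the peak on either strand, the one
    with maximal overlap in nt wins; ties break by kind precedence
    (5'UTR > 3'UTR > RNA gene > CDS), then smaller feature, then
    lexicographic id.  No overlap at all yields ``intergenic``.
    """
    if peak.start < 1 or peak.end > fs.length:
        raise CoordinateError(
            f"peak {peak.peak_id} [{peak.start}, {peak.end}] outside genome"
        )
    best: tuple | None = None
    for f in fs.overlapping(peak.start, peak.end):
        ov = min(peak.end, f.end) - max(peak.start, f.start) + 1
        key = (-ov, _KIND_PRECEDENCE[f.kind], f.length, f.feature_id)
        if best is None or key < best[0]:
            best = (key, f, ov)
    if best is None:
        return PeakAnnotation(peak.peak_id, "intergenic", None, 0, None)
    _, feat, ov = best
    category = _KIND_TO_CATEGORY[feat.kind]
    if feat.strand != peak.strand:
        category = "as" + category
    return PeakAnnotation(
        peak_id=peak.peak_id,
        category=category,
        assigned_feature=feat.feature_id,
        overlap_nt=ov,
        gene_id=feat.parent_gene or feat.feature_id,
    )


def annotate_peaks(peaks: Sequence[Peak], fs: FeatureSet) -> list[PeakAnnotation]:
    """Classify every peak (see :func:`classify_peak`)."""
    return [classify_peak(p, fs) for p in peaks]


@dataclass
class GeneAssignments:
    """Peaks collapsed to unique target genes, sense and antisense."""

    sense: list[tuple[str, list[int]]]
    antisense: list[tuple[str, list[int]]]

    @property
    def n_genes(self) -> int:
        return len({g for g, _ in self.sense} | {g for g, _ in self.antisense})


def peaks_to_genes(
    annotations: Sequence[PeakAnnotation], fs: FeatureSet
) -> GeneAssignments:
    """Group annotated peaks by target gene.

    Sense-category peaks (CDS/UTR/RNA) map to the parent gene of their
    assigned feature; antisense-category peaks map to the sense gene they
    oppose and are reported in a separate list.  Intergenic peaks are
    dropped.  The unique gene count never exceeds the peak count.
    """
    sense: dict[str, list[int]] = defaultdict(list)
    anti: dict[str, list[int]] = defaultdict(list)
    for a in annotations:
        if a.category == "intergenic" or a.gene_id is None:
            continue
        (anti if a.category.startswith("as") else sense)[a.gene_id].append(a.peak_id)
    return GeneAssignments(
        sense=sorted((g, sorted(ids)) for g, ids in sense.items()),
        antisense=sorted((g, sorted(ids)) for g, ids in anti.items()),
    )


def category_distribution(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Fraction of peaks per category (only categories present; sums to 1)."""
    if len(annotations) == 0:
        raise CrafdValidationError("category_distribution of an empty list")
    counts: dict[str, int] = defaultdict(int)
    for a in annotations:
        counts[a.category] += 1
    n = len(annotations)
    return {c: counts[c] / n for c in CATEGORIES if counts[c] > 0}
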