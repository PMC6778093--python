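"""Synthetic genomes, annotations, and pull-down/control coverage
libraries with known ground truth.

The generator emulates the processed form of an sRNA affinity pull-down
experiment: duplicate pull-down libraries and one unenriched control,
each as strand-specific per-nucleotide coverage.  All libraries share a
flat transcriptome-like background; pull-down libraries additionally
carry *multiplicative* coverage steps over planted intervals (targets
are enriched out of the same lysate, so a pulled-down region scales the
shared profile rather than adding counts on top of it).  Planted "true"
peaks have fold changes comfortably above the enrichment threshold,
planted decoys sit below it so the not-/partially-enriched branches of
the classifier are exercised.  Per-replicate lognormal jitter on the
planted folds and per-library depth factors make replicate agreement and
library-size normalization meaningful.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical seeds give byte-identical GFF3,
grp files, and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from .annotation import Feature, FeatureSet
from .coverage import CoverageTrack, GrpFile, write_grp
from .enrichment import EnrichmentCall
from .errors import CrafdValidationError
from .peaks import Peak

_CATEGORY_NAMES = [
    "translation", "photosynthesis_respiration", "regulatory_functions",
    "energy_metabolism", "carbon_metabolism", "amino_acid_biosynthesis",
    "cell_envelope", "transport_binding", "dna_replication", "hypothetical",
]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Coverage units are normalized-read-depth-like; lengths in nt.
    ``background_mean`` is the expected per-nucleotide control coverage,
    ``true_fold_range`` the multiplicative enrichment of planted target
    peaks, and ``decoy_fold_range`` the sub-threshold folds of planted
    decoys.  ``replicate_jitter_sd`` perturbs each planted fold per
    replicate on the log scale; ``depth_factor_sd`` (log scale) varies
    raw sequencing depth between libraries so that normalization is
    exercised.
    """

    genome_length: int = 70_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (200, 1500)
    min_gene_gap: int = 50
    rna_gene_fraction: float = 0.15
    utr5_flank: int = 100
    utr3_flank: int = 50
    background_mean: float = 25.0
    noise_model: Literal["poisson", "negbin", "none"] = "poisson"
    negbin_dispersion: float = 0.1
    n_true_peaks: int = 30
    true_fold_range: tuple[float, float] = (2.5, 6.0)
    peak_width_range: tuple[int, int] = (30, 150)
    n_decoy_peaks: int = 10
    decoy_fold_range: tuple[float, float] = (1.0, 1.4)
    n_replicates: int = 2
    replicate_jitter_sd: float = 0.1
    depth_factor_sd: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("gene_length_range", "true_fold_range",
                     "peak_width_range", "decoy_fold_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise CrafdValidationError(f"{name} must be positive and ordered")
        if self.genome_length < 1 or self.background_mean <= 0:
            raise CrafdValidationError("genome_length and background_mean must be positive")
        if self.n_replicates < 1:
            raise CrafdValidationError("need at least one replicate")


@dataclass(frozen=True)
class TruthRow:
    truth_id: int
    strand: str
    start: int
    end: int
    true_fold: float
    is_decoy: bool
    overlapped_feature: str | None
    expected_category: str


@dataclass
class TruthTable:
    """Planted-interval ground truth for recovery scoring."""

    rows: list[TruthRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def true_rows(self) -> list[TruthRow]:
        return [r for r in self.rows if not r.is_decoy]

    def decoy_rows(self) -> list[TruthRow]:
        return [r for r in self.rows if r.is_decoy]


def simulate_annotation(cfg: SimulationConfig) -> FeatureSet:
    """Place non-overlapping genes with explicit derived UTRs.

    Genes (CDS or non-coding RNA) are packed left to right with at least
    ``min_gene_gap`` nt between them, the residual slack distributed
    randomly over the gaps; strands and functional categories are random.
    Raises when the requested genes cannot fit.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    if n == 0:
        return FeatureSet(genome_id="synthetic", length=cfg.genome_length, features=[])
    lengths = rng.integers(
        cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n
    )
    needed = int(lengths.sum()) + (n + 1) * cfg.min_gene_gap
    if needed > cfg.genome_length:
        raise CrafdValidationError(
            f"cannot pack {n} genes totalling {int(lengths.sum())} nt plus "
            f"{cfg.min_gene_gap} nt gaps into {cfg.genome_length} nt; "
            "reduce n_genes or enlarge the genome"
        )
    slack = cfg.genome_length - needed
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    strands = rng.integers(0, 2, size=n)  # 0 -> F, 1 -> R
    is_rna = rng.random(n) < cfg.rna_gene_fraction
    categories = rng.integers(0, len(_CATEGORY_NAMES), size=n)

    features: list[Feature] = []
    pos = 1
    for i in range(n):
        pos += cfg.min_gene_gap + int(extra[i])
        start = pos
        end = start + int(lengths[i]) - 1
        pos = end + 1
        gid = f"g{i + 1:04d}"
        features.append(
            Feature(
                feature_id=f"{gid}_{'rna' if is_rna[i] else 'cds'}",
                kind="RNA_gene" if is_rna[i] else "CDS",
                strand="F" if strands[i] == 0 else "R",
                start=start,
                end=end,
                gene_name=gid.upper(),
                functional_category=_CATEGORY_NAMES[categories[i]],
                parent_gene=gid,
            )
        )
    fs = FeatureSet("synthetic", cfg.genome_length, features)
    return ann.derive_utrs(fs, cfg.utr5_flank, cfg.utr3_flank)


@dataclass
class SimulatedLibraries:
    """Raw (un-normalized) tracks of the synthetic experiment plus truth."""

    pulldown: list[dict[str, CoverageTrack]]  # one {"F": ..., "R": ...} per replicate
    control: dict[str, CoverageTrack]
    truth: TruthTable

    def library_total(self, tracks: dict[str, CoverageTrack]) -> float:
        """Library size: summed raw coverage of both strands."""
        return tracks["F"].total() + tracks["R"].total()


def _place_intervals(
    rng: np.random.Generator,
    n: int,
    widths: np.ndarray,
    genome_length: int,
    occupied: dict[str, list[tuple[int, int]]],
    min_gap: int,
) -> list[tuple[str, int, int]]:
    """Place n disjoint intervals (per strand, with a margin) by rejection."""
    placed: list[tuple[str, int, int]] = []
    attempts = 0
    for w in widths:
        w = int(w)
        while True:
            attempts += 1
            if attempts > 10_000 * n:
                raise CrafdValidationError(
                    "could not place planted peaks; genome too crowded"
                )
            strand = "F" if rng.integers(0, 2) == 0 else "R"
            start = int(rng.integers(1, genome_length - w + 2))
            end = start + w - 1
            ok = all(
                end + min_gap < a or start - min_gap > b
                for a, b in occupied[strand]
            )
            if ok:
                occupied[strand].append((start, end))
                placed.append((strand, start, end))
                break
    return placed


def simulate_libraries(
    cfg: SimulationConfig, fs: FeatureSet
) -> SimulatedLibraries:
    """Sample raw pull-down replicate and control coverage with planted peaks.

    The control is pure background noise; each pull-down replicate is
    background times the planted multiplicative fold profile (per-peak
    lognormal replicate jitter) times a per-library depth factor,
    re-sampled under the noise model.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.genome_length

    n_total = cfg.n_true_peaks + cfg.n_decoy_peaks
    widths = rng.integers(
        cfg.peak_width_range[0], cfg.peak_width_range[1] + 1, size=n_total
    )
    # planted intervals stay clear of each other so boundary windows of
    # neighbouring peaks cannot interact
    margin = 50
    occupied: dict[str, list[tuple[int, int]]] = {"F": [], "R": []}
    placed = _place_intervals(rng, n_total, widths, L, occupied, margin)
    true_folds = rng.uniform(*cfg.true_fold_range, size=cfg.n_true_peaks)
    decoy_folds = rng.uniform(*cfg.decoy_fold_range, size=cfg.n_decoy_peaks)
    folds = np.concatenate([true_folds, decoy_folds])

    rows: list[TruthRow] = []
    for t, ((strand, start, end), fold) in enumerate(zip(placed, folds), start=1):
        probe = Peak(peak_id=t, strand=strand, start=start, end=end, mean_coverage=0.0)
        pa = ann.classify_peak(probe, fs)
        rows.append(
            TruthRow(
                truth_id=t,
                strand=strand,
                start=start,
                end=end,
                true_fold=float(fold),
                is_decoy=t > cfg.n_true_peaks,
                overlapped_feature=pa.assigned_feature,
                expected_category=pa.category,
            )
        )
    truth = TruthTable(rows=rows)

    # per-library raw depth factors (replicates first, control last)
    depth = np.exp(rng.normal(0.0, cfg.depth_factor_sd, size=cfg.n_replicates + 1))

    def sample(lam: np.ndarray) -> np.ndarray:
        if cfg.noise_model == "poisson":
            return rng.poisson(lam).astype(float)
        if cfg.noise_model == "negbin":
            # mean lam, variance lam * (1 + dispersion * lam)
            r = 1.0 / cfg.negbin_dispersion
            p = r / (r + lam)
            return rng.negative_binomial(r, p).astype(float)
        return lam.astype(float)  # "none": noiseless expectation

    pulldown: list[dict[str, CoverageTrack]] = []
    for rep in range(cfg.n_replicates):
        profiles = {"F": np.ones(L), "R": np.ones(L)}
        for row in rows:
            jitter = (
                math.exp(rng.normal(0.0, cfg.replicate_jitter_sd))
                if cfg.replicate_jitter_sd > 0
                else 1.0
            )
            profiles[row.strand][row.start - 1 : row.end] = row.true_fold * jitter
        tracks = {}
        for strand in ("F", "R"):
            lam = cfg.background_mean * profiles[strand] * depth[rep]
            tracks[strand] = CoverageTrack(
                genome_id=fs.genome_id,
                strand=strand,  # type: ignore[arg-type]
                values=sample(lam),
                label=f"pulldown_rep{rep + 1}",
            )
        pulldown.append(tracks)

    control = {}
    for strand in ("F", "R"):
        lam = np.full(L, cfg.background_mean * depth[-1])
        control[strand] = CoverageTrack(
            genome_id=fs.genome_id,
            strand=strand,  # type: ignore[arg-type]
            values=sample(lam),
            label="control",
        )
    return SimulatedLibraries(pulldown=pulldown, control=control, truth=truth)


def write_simulation(
    cfg: SimulationConfig, fs: FeatureSet, libs: SimulatedLibraries, outdir
) -> dict[str, str]:
    """Write GFF3, per-strand grp files, and truth.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    gff = outdir / "genome.gff3"
    ann.write_gff(fs, gff)
    paths["gff"] = str(gff)
    for strand in ("F", "R"):
        tracks = [rep[strand] for rep in libs.pulldown] + [libs.control[strand]]
        grp = GrpFile.from_tracks(tracks)
        p = outdir / f"coverage_{'fwd' if strand == 'F' else 'rev'}.grp"
        write_grp(grp, p)
        paths[f"grp_{strand}"] = str(p)
    tt = outdir / "truth.tsv"
    libs.truth.to_frame().to_csv(tt, sep="\t", index=False)
    paths["truth"] = str(tt)
    return paths


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Recall/precision of enriched-peak detection against planted truth."""

    n_true: int
    n_called_enriched: int
    n_matched_true: int
    n_matched_called: int
    recall: float
    precision: float
    no_calls: bool
    boundary_errors: list[int]
    median_boundary_error: float
    q90_boundary_error: float
    decoys_called_enriched: int


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def score_recovery(
    called: Sequence[EnrichmentCall],
    truth: TruthTable,
    tolerance_nt: int = 15,
) -> RecoveryReport:
    """Match enriched calls to planted true peaks by reciprocal overlap >= 50%.

    Recall counts planted (non-decoy) peaks with a matching enriched call
    on the same strand; precision counts enriched calls matching some
    planted true peak.  With no enriched calls precision is reported as
    1.0 by convention, flagged by ``no_calls``.  Boundary errors (|start
    offset| and |end offset| of matched pairs) are summarized by their
    median and 90th percentile; ``tolerance_nt`` is carried in the report
    consumers' assertions, not used for matching.
    """
    enriched = [c for c in called if c.status == "enriched"]
    matched_true: set[int] = set()
    matched_called: set[int] = set()
    boundary_errors: list[int] = []
    for row in truth.true_rows():
        best = None
        for ci, call in enumerate(enriched):
            p = call.peak
            if p.strand != row.strand:
                continue
            ro = _reciprocal_overlap((row.start, row.end), (p.start, p.end))
            if ro >= 0.5:
                matched_called.add(ci)
                if best is None or ro > best[0]:
                    best = (ro, ci)
        if best is not None:
            matched_true.add(row.truth_id)
            p = enriched[best[1]].peak
            boundary_errors.extend(
                [abs(p.start - row.start), abs(p.end - row.end)]
            )
    decoys_hit = 0
    for row in truth.decoy_rows():
        for call in enriched:
            p = call.peak
            if p.strand == row.strand and _reciprocal_overlap(
                (row.start, row.end), (p.start, p.end)
            ) >= 0.5:
                decoys_hit += 1
                break
    n_true = len(truth.true_rows())
    recall = len(matched_true) / n_true if n_true else 1.0
    no_calls = len(enriched) == 0
    precision = 1.0 if no_calls else len(matched_called) / len(enriched)
    be = sorted(boundary_errors)
    return RecoveryReport(
        n_true=n_true,
        n_called_enriched=len(enriched),
        n_matched_true=len(matched_true),
        n_matched_called=len(matched_called),
        recall=recall,
        precision=precision,
        no_calls=no_calls,
        boundary_errors=be,
        median_boundary_error=float(np.median(be)) if be else 0.0,
        q90_boundary_error=float(np.quantile(be, 0.9)) if be else 0.0,
        decoys_called_enriched=decoys_hit,
    )
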