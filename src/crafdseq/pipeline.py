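"""End-to-end orchestration: normalize -> merge -> call peaks -> enrich
-> annotate -> statistics, with a reproducible run manifest.

The pipeline consumes per-strand grp files (one per library), normalizes
each library to its size (summed raw coverage of both strands unless an
explicit total is given), peak-calls the positionwise mean of the
normalized pull-down replicates, scores every peak against the control
in every replicate, annotates peaks against a GFF3, and runs the
category-enrichment and rank-comparison statistics.  Every output is a
deterministic function of the inputs and parameters; the manifest
records the fully resolved configuration so a run can be repeated
byte-identically from it.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    category_distribution,
    annotate_peaks,
    derive_utrs,
    peaks_to_genes,
    read_gff,
)
from .coverage import CoverageTrack, merge_tracks, normalize_to_library_size, read_grp
from .enrichment import EnrichmentCall, EnrichmentParams, classify_peaks
from .errors import CrafdError, CrafdValidationError
from .peaks import Peak, PeakCallParams, call_peaks_stranded
from .stats import category_enrichment, compare_enriched_ranks

logger = logging.getLogger(__name__)


@dataclass
class LibraryInput:
    """One library given as a forward- and a reverse-strand grp file."""

    label: str
    fwd: str
    rev: str
    total_reads: float | None = None  # default: summed raw coverage, both strands


@dataclass
class PipelineConfig:
    pulldown: list[LibraryInput]
    control: LibraryInput
    outdir: str
    genome_length: int | None = None  # inferred from the grp files when None
    gff: str | None = None
    derive_utrs_flag: bool = True
    flank5: int = 100
    flank3: int = 50
    ranks: str | None = None  # TSV with columns peak_id, rank
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    enrich_params: EnrichmentParams = field(default_factory=EnrichmentParams)
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["pulldown"] = [LibraryInput(**e) for e in d["pulldown"]]
        d["control"] = LibraryInput(**d["control"])
        d["peak_params"] = PeakCallParams(**d.get("peak_params", {}))
        d["enrich_params"] = EnrichmentParams(**d.get("enrich_params", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@contextmanager
def _stage(name: str, detail: str = ""):
    t0 = time.perf_counter()
    try:
        yield
    except CrafdError as exc:
        raise type(exc)(
            f"stage {name!r} failed" + (f" on {detail}" if detail else "") + f": {exc}"
        ) from exc
    except OSError as exc:
        raise OSError(
            f"stage {name!r} failed" + (f" on {detail}" if detail else "") + f": {exc}"
        ) from exc
    logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def _load_library(lib: LibraryInput) -> dict[str, CoverageTrack]:
    tracks = {}
    for strand, path in (("F", lib.fwd), ("R", lib.rev)):
        grp = read_grp(path)
        if grp.strand != strand:
            raise CrafdValidationError(
                f"{path}: declares strand {grp.strand}, expected {strand}"
            )
        label = lib.label if lib.label in grp.column_labels else grp.column_labels[0]
        tracks[strand] = grp.track(label)
    return tracks


def _normalize_library(
    tracks: dict[str, CoverageTrack], total: float | None
) -> dict[str, CoverageTrack]:
    if total is None:
        total = tracks["F"].total() + tracks["R"].total()
    return {s: normalize_to_library_size(t, total) for s, t in tracks.items()}


def run_all(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Writes merged coverage, ``peaks.tsv``, ``enrichment.tsv`` and — when
    an annotation is supplied — ``annot.tsv``,
    ``category_distribution.tsv`` and ``category_enrichment.tsv``; with a
    rank table also ``rank_test.tsv``.  ``manifest.json`` holds the
    resolved configuration.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("normalize"):
        if not config.pulldown:
            raise CrafdValidationError("at least one pull-down library required")
        pd_norm = [
            _normalize_library(_load_library(lib), lib.total_reads)
            for lib in config.pulldown
        ]
    with _stage("merge"):
        merged = {
            s: merge_tracks([rep[s] for rep in pd_norm], "mean") for s in ("F", "R")
        }

    with _stage("callpeaks"):
        peaks = call_peaks_stranded(merged["F"], merged["R"], config.peak_params)
        peaks_df = pd.DataFrame(
            [
                {
                    "peak_id": p.peak_id,
                    "strand": p.strand,
                    "start": p.start,
                    "end": p.end,
                    "length": p.length,
                    "mean_coverage": p.mean_coverage,
                }
                for p in peaks
            ],
            columns=["peak_id", "strand", "start", "end", "length", "mean_coverage"],
        )
        peaks_df.to_csv(outdir / "peaks.tsv", sep="\t", index=False)

    with _stage("enrich", detail="control library"):
        if config.control is None:
            raise CrafdValidationError("a control library is required")
        ctrl_norm = _normalize_library(
            _load_library(config.control), config.control.total_reads
        )
        calls: list[EnrichmentCall] = []
        for strand in ("F", "R"):
            strand_peaks = [p for p in peaks if p.strand == strand]
            calls.extend(
                classify_peaks(
                    strand_peaks,
                    [rep[strand] for rep in pd_norm],
                    ctrl_norm[strand],
                    config.enrich_params,
                )
            )
        calls.sort(key=lambda c: c.peak.peak_id)
        n_reps = len(config.pulldown)
        enr_df = pd.DataFrame(
            [
                {
                    "peak_id": c.peak.peak_id,
                    "strand": c.peak.strand,
                    "start": c.peak.start,
                    "end": c.peak.end,
                    **{
                        f"fold_rep{i + 1}": c.replicate_folds[i] for i in range(n_reps)
                    },
                    "status": c.status,
                }
                for c in calls
            ],
            columns=["peak_id", "strand", "start", "end"]
            + [f"fold_rep{i + 1}" for i in range(n_reps)]
            + ["status"],
        )
        enr_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    annotations = None
    fs = None
    if config.gff is not None:
        with _stage("annotate", detail=config.gff):
            genome_length = config.genome_length or merged["F"].length
            fs = read_gff(config.gff, genome_length)
            if config.derive_utrs_flag:
                fs = derive_utrs(fs, config.flank5, config.flank3)
            annotations = annotate_peaks(peaks, fs)
            status_by_id = {c.peak.peak_id: c.status for c in calls}
            ann_df = pd.DataFrame(
                [
                    {
                        "peak_id": a.peak_id,
                        "category": a.category,
                        "feature_id": a.assigned_feature or "",
                        "gene_id": a.gene_id or "",
                        "overlap_nt": a.overlap_nt,
                        "status": status_by_id[a.peak_id],
                    }
                    for a in annotations
                ],
                columns=["peak_id", "category", "feature_id", "gene_id",
                         "overlap_nt", "status"],
            )
            ann_df.to_csv(outdir / "annot.tsv", sep="\t", index=False)

            enriched_ids = {c.peak.peak_id for c in calls if c.status == "enriched"}
            enriched_ann = [a for a in annotations if a.peak_id in enriched_ids]
            if enriched_ann:
                dist = category_distribution(enriched_ann)
            else:
                dist = {}
            pd.DataFrame(
                [{"category": c, "fraction": f} for c, f in dist.items()],
                columns=["category", "fraction"],
            ).to_csv(outdir / "category_distribution.tsv", sep="\t", index=False)

        with _stage("stats-categories"):
            background = {
                gid: {f.functional_category for f in members if f.functional_category}
                for gid, members in fs.genes().items()
            }
            background = {g: c for g, c in background.items() if c}
            assignments = peaks_to_genes(enriched_ann, fs)
            target_genes = {
                g
                for g, _ in assignments.sense + assignments.antisense
                if g in background
            }
            if background and target_genes:
                cat_rows = category_enrichment(target_genes, background, config.alpha)
            else:
                cat_rows = []
            pd.DataFrame(
                [r.__dict__ for r in cat_rows],
                columns=[
                    "category", "n_background", "k_background_in_cat", "n_targets",
                    "k_targets_in_cat", "p_value", "adjusted_p",
                    "significant_raw", "significant_adjusted",
                ],
            ).to_csv(outdir / "category_enrichment.tsv", sep="\t", index=False)

    if config.ranks is not None:
        with _stage("stats-ranks", detail=config.ranks):
            ranks_df = pd.read_csv(config.ranks, sep="\t")
            status_by_id = {c.peak.peak_id: c.status for c in calls}
            table = [
                (int(r.peak_id), status_by_id[int(r.peak_id)], float(r.rank))
                for r in ranks_df.itertuples()
                if int(r.peak_id) in status_by_id
            ]
            rc = compare_enriched_ranks(table)
            pd.DataFrame(
                [
                    {
                        "n_enriched": len(rc.ranks_enriched),
                        "n_not_enriched": len(rc.ranks_non_enriched),
                        "H": rc.H,
                        "p_value": rc.p_value,
                        "method": rc.method,
                        "median_enriched": rc.median_enriched,
                        "median_not_enriched": rc.median_non_enriched,
                        "direction": rc.direction,
                    }
                ]
            ).to_csv(outdir / "rank_test.tsv", sep="\t", index=False)

    with _stage("manifest"):
        manifest = {
            "package": "crafdseq",
            "version": __version__,
            "config": config.to_dict(),
        }
        with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return outdir


def run_from_manifest(manifest_path, outdir: str | None = None) -> Path:
    """Repeat a run from its manifest (byte-identical outputs)."""
    with open(manifest_path, "rt", encoding="utf-8") as fh:
        manifest = json.load(fh)
    cfg = PipelineConfig.from_dict(manifest["config"])
    if outdir is not None:
        cfg.outdir = outdir
    return run_all(cfg)
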