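"""Replicate-consensus enrichment calling of peaks against a control.

Each called peak is scored as the fold change of its mean pull-down
coverage over its mean control coverage, separately for every pull-down
replicate.  A peak is *enriched* when every replicate exceeds the fold
threshold (strictly "more than" the threshold, default 2), *partially
enriched* when some but not all do, and *not enriched* otherwise — the
green / striped / white box semantics of replicate-consensus calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .coverage import CoverageTrack
from .errors import CrafdValidationError, IncompatibleTracksError, StateError
from .peaks import Peak

EnrichmentStatus = Literal["enriched", "partially_enriched", "not_enriched"]


@dataclass(frozen=True)
class EnrichmentParams:
    """Fold threshold (strict ``>``), pseudocount, and consensus rule."""

    fold_threshold: float = 2.0
    pseudocount_eps: float = 0.1
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise CrafdValidationError("fold_threshold must be > 1")
        if self.pseudocount_eps < 0:
            raise CrafdValidationError("pseudocount_eps must be >= 0")


@dataclass
class EnrichmentCall:
    """Per-replicate fold changes and the consensus status for one peak."""

    peak: Peak
    replicate_folds: list[float]
    status: EnrichmentStatus


def _check_pair(pulldown: CoverageTrack, control: CoverageTrack) -> None:
    if not (pulldown.normalized and control.normalized):
        raise StateError("fold changes require normalized tracks")
    if pulldown.strand != control.strand or pulldown.length != control.length:
        raise IncompatibleTracksError(
            "pull-down and control tracks differ in strand or length"
        )


def peak_fold_change(
    peak: Peak,
    pulldown: CoverageTrack,
    control: CoverageTrack,
    eps: float = 0.1,
) -> float:
    """(mean pull-down + eps) / (mean control + eps) over the peak interval."""
    _check_pair(pulldown, control)
    if peak.strand != pulldown.strand:
        raise IncompatibleTracksError(
            f"peak {peak.peak_id} on strand {peak.strand} scored against "
            f"strand-{pulldown.strand} tracks"
        )
    pd = pulldown.region_mean(peak.start, peak.end)
    ct = control.region_mean(peak.start, peak.end)
    return (pd + eps) / (ct + eps)


def classify_peaks(
    peaks: Sequence[Peak],
    pulldown_reps: Sequence[CoverageTrack],
    control: CoverageTrack,
    params: EnrichmentParams | None = None,
) -> list[EnrichmentCall]:
    """Score every peak against the control in every replicate and assign
    the three-way consensus status.

    With ``require_all_replicates`` (default) *enriched* means every
    replicate fold is strictly above the threshold; otherwise a single
    passing replicate suffices and the partial status is never emitted.
    """
    params = params or EnrichmentParams()
    if len(pulldown_reps) == 0:
        raise CrafdValidationError("at least one pull-down replicate required")
    for rep in pulldown_reps:
        _check_pair(rep, control)
    calls = []
    for peak in peaks:
        folds = [
            peak_fold_change(peak, rep, control, params.pseudocount_eps)
            for rep in pulldown_reps
        ]
        n_pass = sum(f > params.fold_threshold for f in folds)
        if params.require_all_replicates:
            if n_pass == len(folds):
                status: EnrichmentStatus = "enriched"
            elif n_pass > 0:
                status = "partially_enriched"
            else:
                status = "not_enriched"
        else:
            status = "enriched" if n_pass > 0 else "not_enriched"
        calls.append(EnrichmentCall(peak=peak, replicate_folds=folds, status=status))
    return calls
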