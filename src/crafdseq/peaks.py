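"""Sliding-window fold-change peak calling on coverage tracks.

The caller detects peak boundaries by comparing the mean coverage of two
``w``-nucleotide windows separated by an ``s``-nucleotide spacer.  A
position ``i`` is a *start* candidate when the downstream window (the
``w`` bases starting at ``i``) exceeds the upstream window (the ``w``
bases ending ``s+1`` bases before ``i``) by at least a fold change ``f``;
*end* candidates are the mirror image.  Runs of consecutive candidate
positions are collapsed to the position of maximal fold (ties to the
leftmost), starts and ends are paired left to right, and intervals whose
mean coverage falls below a fraction ``c`` of the genome-wide average
coverage of the dataset are discarded.

Defaults are w=5, s=10, f=1.5, c=0.2.  A small pseudocount on both
window means keeps folds finite over zero-coverage background; because
both the boundary test and the coverage filter are ratios, peak calls
are invariant under global rescaling of the coverage (with the
pseudocount co-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .coverage import CoverageTrack, Strand
from .errors import CrafdValidationError

BoundaryKind = Literal["start", "end"]


@dataclass(frozen=True)
class PeakCallParams:
    """Tuning parameters of the windowed fold-change peak caller.

    Attributes
    ----------
    window_w : int
        Width in nt of each averaging window (default 5).
    spacer_s : int
        Number of ignored nt between the two windows (default 10).
    boundary_fold_f : float
        Minimum fold change between the window means for a boundary
        (default 1.5, compared with ``>=``).
    min_cov_frac_c : float
        A peak's mean coverage must be at least this fraction of the
        average per-nucleotide coverage of the dataset (default 0.2).
    pseudocount_eps : float
        Added to both window means before taking the ratio (default 0.1
        in normalized coverage units); use 0 on strictly positive tracks.
    min_peak_len : int
        Shorter intervals are discarded (default 1 = keep all).
    circular : bool
        Evaluate windows across the origin of a circular replicon.
    close_open_peaks : bool
        Close a dangling start at the end of the track instead of
        discarding it.
    """

    window_w: int = 5
    spacer_s: int = 10
    boundary_fold_f: float = 1.5
    min_cov_frac_c: float = 0.2
    pseudocount_eps: float = 0.1
    min_peak_len: int = 1
    circular: bool = False
    close_open_peaks: bool = False

    def __post_init__(self) -> None:
        if self.window_w < 1:
            raise CrafdValidationError("window_w must be >= 1")
        if self.spacer_s < 0:
            raise CrafdValidationError("spacer_s must be >= 0")
        if not self.boundary_fold_f > 1:
            raise CrafdValidationError("boundary_fold_f must be > 1")
        if not (0 < self.min_cov_frac_c <= 1):
            raise CrafdValidationError("min_cov_frac_c must be in (0, 1]")
        if self.pseudocount_eps < 0:
            raise CrafdValidationError("pseudocount_eps must be >= 0")
        if self.min_peak_len < 1:
            raise CrafdValidationError("min_peak_len must be >= 1")


@dataclass(frozen=True)
class BoundaryCandidate:
    """A collapsed start or end boundary with its window fold change."""

    position: int  # 1-based
    kind: BoundaryKind
    fold: float


@dataclass
class Peak:
    """A called interval on one strand, 1-based inclusive coordinates."""

    peak_id: int
    strand: Strand
    start: int
    end: int
    mean_coverage: float
    source_label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _window_means(values: np.ndarray, w: int, circular: bool) -> np.ndarray:
    """M[i] = mean of the w values starting at 1-based position i+1.

    Linear tracks return length-(L-w+1) arrays; circular tracks wrap and
    return length-L arrays.
    """
    if circular:
        ext = np.concatenate([values, values[: w - 1]]) if w > 1 else values
    else:
        ext = values
    if ext.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(ext, w)
    # row-wise sequential sum matches a plain left-to-right accumulation
    # for the small w used here, keeping the brute-force oracle bit-equal
    return windows.sum(axis=1) / w


def _collapse_runs(
    positions: np.ndarray, folds: np.ndarray, kind: BoundaryKind
) -> list[BoundaryCandidate]:
    """Collapse maximal runs of consecutive candidate positions to the
    position of maximal fold.

    Ties break leftmost for starts and rightmost for ends, so a clean
    coverage step yields the boundary pair spanning the whole elevated
    region (peaks contain only elevated coverage).
    """
    out: list[BoundaryCandidate] = []
    if positions.size == 0:
        return out
    run_breaks = np.flatnonzero(np.diff(positions) > 1) + 1
    for run in np.split(np.arange(positions.size), run_breaks):
        f = folds[run]
        if kind == "start":
            best = run[int(np.argmax(f))]
        else:
            best = run[len(run) - 1 - int(np.argmax(f[::-1]))]
        out.append(BoundaryCandidate(int(positions[best]), kind, float(folds[best])))
    return out


def scan_boundaries(
    track: CoverageTrack, params: PeakCallParams
) -> list[BoundaryCandidate]:
    """Find collapsed start/end boundary candidates, sorted by position.

    Positions whose upstream or downstream window would extend past the
    track (and the track is not circular) are not evaluated; a track
    shorter than ``2*w + s`` yields no candidates.
    """
    w, s = params.window_w, params.spacer_s
    f, eps = params.boundary_fold_f, params.pseudocount_eps
    L = track.length
    if L < 2 * w + s:
        return []
    v = track.values

    if params.circular:
        M = _window_means(v, w, circular=True)  # M[i] for all L positions (0-based i)
        idx = np.arange(L)
        hi_start = M[idx]
        up_start = M[(idx - s - w) % L]
        hi_end = M[(idx - w + 1) % L]
        low_end = M[(idx + s + 1) % L]
        start_pos = idx + 1
        end_pos = idx + 1
    else:
        M = _window_means(v, w, circular=False)  # M[i] = mean at position i+1
        # start candidate i needs i-s-w >= 1 and i+w-1 <= L
        i = np.arange(s + w + 1, L - w + 2)  # 1-based start positions
        hi_start = M[i - 1]
        up_start = M[i - s - w - 1]
        start_pos = i
        # end candidate j needs j-w+1 >= 1 and j+s+w <= L
        j = np.arange(w, L - s - w + 1)  # 1-based end positions
        hi_end = M[j - w]
        low_end = M[j + s]
        end_pos = j

    start_fold = (hi_start + eps) / (up_start + eps)
    end_fold = (hi_end + eps) / (low_end + eps)
    start_mask = start_fold >= f
    end_mask = end_fold >= f

    candidates = _collapse_runs(start_pos[start_mask], start_fold[start_mask], "start")
    candidates += _collapse_runs(end_pos[end_mask], end_fold[end_mask], "end")
    # at a shared position a start sorts before an end, so a single-base
    # peak can open and close at the same coordinate
    candidates.sort(key=lambda c: (c.position, 0 if c.kind == "start" else 1))
    return candidates


def pair_boundaries(
    candidates: Sequence[BoundaryCandidate],
    track_length: int,
    params: PeakCallParams,
) -> list[tuple[int, int]]:
    """Pair boundary candidates into intervals by a left-to-right scan.

    The first start opens an interval; further starts before an end are
    ignored; the first end at a position >= the opening start closes it.
    Ends with no open interval are ignored.  A still-open interval at the
    end of the scan is closed at ``track_length`` when
    ``close_open_peaks`` is set, else discarded.
    """
    intervals: list[tuple[int, int]] = []
    open_start: int | None = None
    for c in candidates:
        if c.kind == "start":
            if open_start is None:
                open_start = c.position
        else:
            if open_start is not None and c.position >= open_start:
                intervals.append((open_start, c.position))
                open_start = None
    if open_start is not None and params.close_open_peaks:
        intervals.append((open_start, track_length))
    return [
        (a, b) for a, b in intervals if b - a + 1 >= params.min_peak_len
    ]


def dataset_mean_coverage(tracks: Sequence[CoverageTrack]) -> float:
    """Grand mean coverage per nucleotide over all supplied tracks
    (by default both strands of the peak-called library)."""
    if len(tracks) == 0:
        raise CrafdValidationError("dataset_mean_coverage requires >= 1 track")
    lengths = {t.length for t in tracks}
    if len(lengths) != 1:
        raise CrafdValidationError("dataset tracks must share one length")
    total = sum(t.total() for t in tracks)
    return total / (tracks[0].length * len(tracks))


def call_peaks(
    track: CoverageTrack,
    companion_tracks: Sequence[CoverageTrack] = (),
    params: PeakCallParams | None = None,
) -> list[Peak]:
    """Call peaks on one track.

    ``companion_tracks`` supplies the rest of the dataset (normally the
    other strand of the same library) for the genome-average coverage
    used by the minimum-coverage filter; when empty the dataset is the
    track alone.  Returned peaks are disjoint, sorted by start, and
    numbered 1..n.
    """
    params = params or PeakCallParams()
    candidates = scan_boundaries(track, params)
    intervals = pair_boundaries(candidates, track.length, params)
    ds_mean = dataset_mean_coverage([track, *companion_tracks])
    threshold = params.min_cov_frac_c * ds_mean
    peaks = []
    for start, end in intervals:
        mc = track.region_mean(start, end)
        if mc >= threshold:
            peaks.append(
                Peak(
                    peak_id=len(peaks) + 1,
                    strand=track.strand,
                    start=start,
                    end=end,
                    mean_coverage=mc,
                    source_label=track.label,
                )
            )
    return peaks


def call_peaks_stranded(
    forward: CoverageTrack,
    reverse: CoverageTrack,
    params: PeakCallParams | None = None,
) -> list[Peak]:
    """Call peaks on both strands of a library.

    The two strands form one dataset for the coverage filter.  Peak ids
    run in coordinate order within each strand and continue across
    strands, forward first.
    """
    fwd_peaks = call_peaks(forward, [reverse], params)
    rev_peaks = call_peaks(reverse, [forward], params)
    for k, p in enumerate(rev_peaks, start=len(fwd_peaks) + 1):
        p.peak_id = k
    return fwd_peaks + rev_peaks
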