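"""ChIP coverage arithmetic: depth normalization, peak calling, window
maxima, replicate correlation, and PAM fraction by enrichment rank.

Coverage is fragment-pileup depth at single-base resolution.  Relative
coverage is raw coverage divided by (total reads in the run / 100,000), so
tracks from runs of different depth are directly comparable.  The threshold
peak caller here is deliberately minimal plumbing: maximal runs above a
threshold, gap-merged, width-filtered, with a leftmost-argmax center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .offtarget_scan import ScanHit

READS_PER_UNIT = 100_000


@dataclass
class CoverageTrack:
    """Per-base coverage over one contig plus the run's total read count."""

    contig: str
    values: np.ndarray
    total_reads: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage must be nonnegative everywhere")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Peak:
    """A called peak; ``center`` is the (leftmost) coverage maximum."""

    contig: str
    start: int
    end: int
    center: int
    center_coverage: float

    def __post_init__(self) -> None:
        if not (self.start <= self.center < self.end):
            raise ValueError("peak center must lie within [start, end)")


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Divide every value by total_reads / 100,000.

    Invariant under joint scaling of counts and depth; with exactly 100,000
    reads the normalized track equals the raw one.
    """
    if track.total_reads is None or track.total_reads <= 0:
        raise ValueError("normalization requires total_reads > 0")
    factor = track.total_reads / READS_PER_UNIT
    return replace(track, values=track.values / factor, normalized=True)


def call_peaks(
    track: CoverageTrack,
    threshold: float,
    merge_gap: int = 100,
    min_width: int = 1,
) -> list[Peak]:
    """Maximal above-threshold runs, merged across small gaps.

    Runs separated by <= ``merge_gap`` bases are merged; merged intervals
    narrower than ``min_width`` are discarded.  The peak center is the
    leftmost position attaining the interval maximum.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = track.values > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    run_starts = ([0] if above[0] else []) + [int(e) + 1 for e in edges if not above[e]]
    run_ends = [int(e) + 1 for e in edges if above[e]] + ([len(above)] if above[-1] else [])

    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    peaks = []
    for s, e in merged:
        if e - s < min_width:
            continue
        center = s + int(np.argmax(track.values[s:e]))
        peaks.append(
            Peak(
                contig=track.contig,
                start=s,
                end=e,
                center=center,
                center_coverage=float(track.values[center]),
            )
        )
    return peaks


def window_max_track(track: CoverageTrack, window: int = 1000) -> np.ndarray:
    """Maximum coverage in each non-overlapping ``window``-sized tile.

    Tiles the contig left to right; the final tile may be partial.  Returns
    ceil(L / window) maxima (the compact representation used for genome-wide
    plots).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(track.values)
    n_tiles = math.ceil(n / window)
    return np.array(
        [track.values[i * window : (i + 1) * window].max() for i in range(n_tiles)]
    )


def coverage_at(track: CoverageTrack, positions: Sequence[int]) -> np.ndarray:
    return track.values[np.asarray(positions, dtype=int)]


def dataset_r2(
    peaks: Sequence[Peak], track_a: CoverageTrack, track_b: CoverageTrack
) -> float | None:
    """Squared Pearson correlation of coverage at peak centers in two tracks.

    Both tracks should be depth-normalized.  Returns None (undefined) when
    either set of center coverages has zero variance.
    """
    if len(peaks) < 3:
        raise ValueError("dataset_r2 requires >= 3 peaks")
    centers = [p.center for p in peaks]
    a = coverage_at(track_a, centers)
    b = coverage_at(track_b, centers)
    if a.std() == 0 or b.std() == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak annotated with its best-scoring scan hit (or None)."""

    peak: Peak
    hit: "ScanHit | None"

    @property
    def pam(self) -> str | None:
        return None if self.hit is None else self.hit.site.pam

    @property
    def enrichment(self) -> float:
        return self.peak.center_coverage


def associate_peaks(
    peaks: Sequence[Peak], hits: Sequence["ScanHit"], max_dist: int = 250
) -> list[AnnotatedPeak]:
    """Annotate each peak with the best hit within ``max_dist`` of its center.

    Best = most matched (non-flipped) positions, then nearest to the peak
    center, then leftmost.  Peaks with no hit in range get ``hit=None``.
    """
    out = []
    for peak in peaks:
        candidates = []
        for h in hits:
            if h.site.contig != peak.contig:
                continue
            mid = (h.site.start + h.site.end) // 2
            dist = abs(mid - peak.center)
            if dist <= max_dist:
                candidates.append((-h.matched_nonflipped, dist, h.site.start, h))
        candidates.sort(key=lambda t: t[:3])
        out.append(AnnotatedPeak(peak=peak, hit=candidates[0][3] if candidates else None))
    return out


def pam_fraction_by_rank(
    annotated: Sequence[AnnotatedPeak],
    top_fraction: float = 0.2,
    pam: str = "AAG",
) -> tuple[float, float]:
    """Fraction of peaks with the given PAM in the top slice vs the rest.

    Peaks are sorted by enrichment (normalized center coverage) descending,
    ties broken by coordinate; the top ``top_fraction`` (at least one peak)
    is compared with the remainder.
    """
    if not annotated:
        raise ValueError("pam_fraction_by_rank requires a nonempty peak set")
    if any(a.hit is None for a in annotated):
        raise ValueError("every peak must be annotated with a PAM (hit is None)")
    order = sorted(
        annotated, key=lambda a: (-a.enrichment, a.peak.contig, a.peak.start)
    )
    n_top = max(1, int(math.floor(len(order) * top_fraction + 1e-9)))
    top, rest = order[:n_top], order[n_top:]
    frac_top = sum(a.pam == pam for a in top) / len(top)
    frac_rest = sum(a.pam == pam for a in rest) / len(rest) if rest else float("nan")
    return frac_top, frac_rest
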