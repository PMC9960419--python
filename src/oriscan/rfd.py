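"""OK-seq replication fork directionality (RFD) profiles and origin calling.

RFD per 1-kb window is (C - W)/(C + W) for Crick- and Watson-strand read
counts; +1 means purely rightward-moving forks, -1 purely leftward.  An
origin appears as an upshift of the profile from -1 toward +1, so origins
are called at maxima of the slope of a linear model fitted to the RFD in a
sliding 200-kb window, after moving-average smoothing.

Crick counts are rescaled genome-wide so that the Watson and Crick totals
match before RFD is computed, compensating for strand library imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeIndex
from .pma import OriCall, pick_peaks, smooth

log = logging.getLogger(__name__)


@dataclass
class RfdTrack:
    """Per-chromosome stranded read counts and derived profiles."""

    chrom: str
    bin_size: int
    watson: np.ndarray
    crick: np.ndarray
    rfd: np.ndarray | None = None
    slope: np.ndarray | None = None
    slope_smooth: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.watson)

    def bin_center(self, b: int) -> int:
        return b * self.bin_size + self.bin_size // 2


def read_stranded_counts(watson_path, crick_path, index: GenomeIndex,
                         bin_size: int = 1000) -> dict[str, RfdTrack]:
    """Build tracks from two bedGraph files (Watson, Crick counts per window)."""
    tracks = {
        chrom: RfdTrack(chrom, bin_size,
                        np.zeros(-(-length // bin_size)),
                        np.zeros(-(-length // bin_size)))
        for chrom, length in index.chrom_lengths.items()
    }

    def load(path, attr):
        df = pd.read_csv(path, sep="\t", header=None, comment="t",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
        for row in df.itertuples(index=False):
            chrom = index.normalize(row.chrom)
            if chrom is None:
                continue
            b = int(row.start) // bin_size
            if b < tracks[chrom].n_bins:
                getattr(tracks[chrom], attr)[b] += float(row.value)

    load(watson_path, "watson")
    load(crick_path, "crick")
    return tracks


def rescale_crick(tracks: dict[str, RfdTrack]) -> float:
    """Rescale Crick counts in place so that sum(C) == sum(W) genome-wide.

    Returns the factor applied.  Raises if there are no Crick reads.
    """
    total_w = sum(t.watson.sum() for t in tracks.values())
    total_c = sum(t.crick.sum() for t in tracks.values())
    if total_c == 0:
        raise ValueError("no Crick-strand reads; cannot rescale")
    factor = total_w / total_c
    for t in tracks.values():
        t.crick = t.crick * factor
    return factor


def compute_rfd(track: RfdTrack) -> np.ndarray:
    """RFD = (C - W)/(C + W) per window; masked (NaN) where C + W = 0."""
    c, w = track.crick, track.watson
    depth = c + w
    with np.errstate(divide="ignore", invalid="ignore"):
        rfd = (c - w) / depth
    rfd[depth == 0] = np.nan
    track.rfd = rfd
    return rfd


def slope_scan(rfd: np.ndarray, window_bins: int = 200,
               bin_size: int = 1000, min_valid: float = 0.5) -> np.ndarray:
    """OLS slope of RFD vs position in a sliding window, at the window center.

    The fit uses window-center-relative bp coordinates (conditioning).
    Windows with fewer than *min_valid* of their bins unmasked, or fewer
    than 2 points, are masked.
    """
    y = np.asarray(rfd, dtype=float)
    n = len(y)
    valid = np.isfinite(y).astype(float)
    y0 = np.where(np.isfinite(y), y, 0.0)
    x = np.arange(n, dtype=float) * bin_size

    kernel = np.ones(window_bins)

    def rolling_sum(a):
        # centered window [i - (w-1)//2, i + w//2]
        return np.convolve(a, kernel, mode="same")

    m = rolling_sum(valid)            # points per window
    sx = rolling_sum(x * valid)
    sy = rolling_sum(y0)
    sxx = rolling_sum(x * x * valid)
    sxy = rolling_sum(x * y0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / m
        var = sxx - sx * sx / m
        slope = cov / var
    bad = (m < max(2, min_valid * window_bins)) | ~np.isfinite(slope)
    slope[bad] = np.nan
    return slope


def detect_okseq_origins(tracks: dict[str, RfdTrack], window_bins: int = 200,
                         smooth_n: int = 200, neighlim_bins: int = 100,
                         min_score: float = 0.0,
                         rescale: bool = True) -> list[OriCall]:
    """Call origins at smoothed slope maxima of the RFD profile.

    Reuses the moving-average and peak contracts of the mutation-based
    caller; the smoothed slope is reported as the call score (no
    significance filter is applied by default).
    """
    if rescale:
        rescale_crick(tracks)
    calls: list[OriCall] = []
    for chrom, track in tracks.items():
        compute_rfd(track)
        track.slope = slope_scan(track.rfd, window_bins, track.bin_size)
        track.slope_smooth = smooth(track.slope, smooth_n)
        for b in pick_peaks(track.slope_smooth, neighlim_bins, min_score):
            depth = float(track.crick[b] + track.watson[b])
            calls.append(OriCall(chrom, track.bin_center(int(b)),
                                 float(track.slope_smooth[b]),
                                 np.nan, np.nan, int(round(depth))))
    return calls
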