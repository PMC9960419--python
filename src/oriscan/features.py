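"""Distance-binned genomic feature context around replication origins.

Covers the descriptive analyses around an origin set: feature-occurrence
fold-change profiles in 20-kb distance bins, chromatin-loop-anchor
profiles normalized by the number of loops reaching each interior depth,
mean signal (e.g. methylation beta) per distance bin, uniform random
position generation over the gap-excluded genome, and inter-position
spacing comparison between two sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genome import GenomeIndex, GenomicInterval

log = logging.getLogger(__name__)


def _positions_by_chrom(origins) -> dict[str, np.ndarray]:
    """Normalize an origin set to {chrom: sorted positions}."""
    if isinstance(origins, dict):
        return {c: np.sort(np.asarray(v, dtype=float))
                for c, v in origins.items()}
    out: dict[str, list[float]] = {}
    for item in origins:
        if isinstance(item, GenomicInterval):
            out.setdefault(item.chrom, []).append(item.midpoint)
        else:  # (chrom, pos)
            out.setdefault(item[0], []).append(item[1])
    return {c: np.sort(np.asarray(v, dtype=float)) for c, v in out.items()}


def _nearest_offsets(points: dict[str, np.ndarray],
                     origins: dict[str, np.ndarray]) -> np.ndarray:
    """Signed offset of each point from its nearest origin (nearest only)."""
    offsets = []
    for chrom, pts in points.items():
        oris = origins.get(chrom)
        if oris is None or len(oris) == 0:
            continue
        idx = np.searchsorted(oris, pts)
        left = oris[np.clip(idx - 1, 0, len(oris) - 1)]
        right = oris[np.clip(idx, 0, len(oris) - 1)]
        use_right = np.abs(pts - right) < np.abs(pts - left)
        nearest = np.where(use_right, right, left)
        offsets.append(pts - nearest)
    return np.concatenate(offsets) if offsets else np.empty(0)


@dataclass
class EnrichmentProfile:
    """Feature counts and fold changes per signed distance bin."""

    bin_edges: np.ndarray             # signed bp offsets, symmetric around 0
    counts: pd.DataFrame              # rows = features, cols = bin centers
    fold_change: pd.DataFrame

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def enrichment_profile(origins, features: dict[str, list],
                       bin: int = 20_000, span: int = 500_000,
                       use_midpoint: bool = True) -> EnrichmentProfile:
    """Count feature elements per distance bin from the nearest origin.

    Each feature element (interval midpoint by default, every overlapped
    bin with ``use_midpoint=False``) is assigned to its nearest origin
    only, so closely spaced origins do not double-count.  Fold change is
    each row divided by its minimum; rows whose minimum is 0 use 1 with a
    warning, rows with no elements are dropped with a warning.
    """
    ori = _positions_by_chrom(origins)
    edges = np.arange(-span, span + bin, bin, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2
    rows, names = [], []
    for name, elements in features.items():
        pts: dict[str, list[float]] = {}
        for el in elements:
            if isinstance(el, GenomicInterval):
                if use_midpoint:
                    pts.setdefault(el.chrom, []).append(el.midpoint)
                else:
                    for p in range(el.start + bin // 2, el.end, bin):
                        pts.setdefault(el.chrom, []).append(p)
            else:
                pts.setdefault(el[0], []).append(el[1])
        if not pts:
            log.warning("feature %s has no elements; row dropped", name)
            continue
        offs = _nearest_offsets({c: np.asarray(v, dtype=float)
                                 for c, v in pts.items()}, ori)
        counts, _ = np.histogram(offs, bins=edges)
        rows.append(counts)
        names.append(name)
    counts_df = pd.DataFrame(rows, index=names, columns=centers, dtype=float)
    mins = counts_df.min(axis=1)
    zero_rows = mins == 0
    if zero_rows.any():
        log.warning("feature row(s) %s have a zero minimum; using 1",
                    list(counts_df.index[zero_rows]))
        mins = mins.mask(zero_rows, 1.0)
    fold = counts_df.div(mins, axis=0)
    return EnrichmentProfile(edges, counts_df, fold)


@dataclass
class LoopProfile:
    """Origin counts around chromatin-loop anchors, loop-length normalized.

    The axis runs from -span (outside the loop) through 0 (the anchor)
    into the loop interior; interior offsets are measured inward from the
    nearer anchor, capped at the loop midpoint.  Interior bins are
    normalized by the number of loops whose half-length reaches that
    depth, exterior bins by the total loop count.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    normalizer: np.ndarray
    normalized: np.ndarray


def loop_profile(origins, loops: list[tuple[str, int, int]],
                 bin: int = 20_000, span: int = 500_000) -> LoopProfile:
    """Profile origin occurrence around loop anchors.

    *loops* are (chrom, anchor1, anchor2) with both anchors on one
    chromosome.  Every origin is assigned to its nearest anchor; positions
    between the anchors get a positive (interior) offset, positions
    outside a negative one.
    """
    if not loops:
        raise ValueError("no loops supplied")
    ori = _positions_by_chrom(origins)
    anchors: dict[str, list[tuple[int, int, int]]] = {}
    half_lengths = []
    for chrom, a1, a2 in loops:
        a1, a2 = (a1, a2) if a1 <= a2 else (a2, a1)
        anchors.setdefault(chrom, []).append((a1, a2, (a2 - a1) // 2))
        half_lengths.append((a2 - a1) / 2)
    half_lengths = np.asarray(half_lengths, dtype=float)

    edges = np.arange(-span, span + bin, bin, dtype=float)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins)
    for chrom, positions in ori.items():
        loops_here = anchors.get(chrom)
        if not loops_here:
            continue
        anchor_pos = np.sort(np.array([a for s, e, _ in loops_here
                                       for a in (s, e)], dtype=float))
        for pos in positions:
            # nearest anchor over all loops on the chromosome
            i = np.searchsorted(anchor_pos, pos)
            cands = anchor_pos[max(i - 1, 0):i + 1]
            dmin = float(np.min(np.abs(cands - pos)))
            # every loop tied at that distance receives the origin, so
            # co-anchored (e.g. duplicated) loops scale counts with the
            # normalizer
            for s, e, _ in loops_here:
                if min(abs(pos - s), abs(pos - e)) != dmin:
                    continue
                if s <= pos <= e:
                    depth = min(pos - s, e - pos)  # inward from nearer anchor
                    k = int(depth // bin) + n_bins // 2
                elif dmin > span:
                    continue
                elif dmin > 0:
                    k = n_bins // 2 - 1 - int((dmin - 1) // bin)
                else:
                    k = n_bins // 2
                if 0 <= k < n_bins:
                    counts[k] += 1
    normalizer = np.empty(n_bins)
    for k in range(n_bins):
        lo = edges[k]
        if lo < 0:
            normalizer[k] = len(loops)
        else:
            normalizer[k] = np.sum(half_lengths >= lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(normalizer > 0, counts / normalizer, np.nan)
    return LoopProfile(edges, counts, normalizer, normalized)


def signal_profile(origins, signal, bin: int = 20_000,
                   span: int = 500_000) -> tuple[np.ndarray, np.ndarray]:
    """Mean signal value per distance bin from the nearest origin.

    *signal* is a sequence of (chrom, pos, value) probes or scored
    intervals (midpoint used).  Returns (bin_edges, means); empty bins are
    masked.
    """
    ori = _positions_by_chrom(origins)
    pts: dict[str, list[tuple[float, float]]] = {}
    for el in signal:
        if isinstance(el, GenomicInterval):
            pts.setdefault(el.chrom, []).append((el.midpoint, el.score or 0.0))
        else:
            pts.setdefault(el[0], []).append((float(el[1]), float(el[2])))
    edges = np.arange(-span, span + bin, bin, dtype=float)
    sums = np.zeros(len(edges) - 1)
    ns = np.zeros(len(edges) - 1)
    for chrom, pv in pts.items():
        oris = ori.get(chrom)
        if oris is None or len(oris) == 0:
            continue
        arr = np.asarray(pv)
        offs = _nearest_offsets({chrom: arr[:, 0]}, {chrom: oris})
        which = np.digitize(offs, edges) - 1
        ok = (which >= 0) & (which < len(edges) - 1)
        np.add.at(sums, which[ok], arr[ok, 1])
        np.add.at(ns, which[ok], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(ns > 0, sums / ns, np.nan)
    return edges, means


def _allowed_intervals(index: GenomeIndex, exclude_gaps: bool,
                       restrict_to) -> list[tuple[str, int, int]]:
    if restrict_to is not None:
        base = [(iv.chrom, iv.start, iv.end) for iv in restrict_to]
    else:
        base = [(c, 0, l) for c, l in index.chrom_lengths.items()]
    if not exclude_gaps or not index.gap_regions:
        return [iv for iv in base if iv[2] > iv[1]]
    out = []
    for chrom, start, end in base:
        cursor = start
        for gs, ge in sorted(index.gap_regions.get(chrom, [])):
            if ge <= cursor or gs >= end:
                continue
            if gs > cursor:
                out.append((chrom, cursor, min(gs, end)))
            cursor = max(cursor, ge)
        if cursor < end:
            out.append((chrom, cursor, end))
    return out


def random_positions(index: GenomeIndex, n: int, seed=None,
                     exclude_gaps: bool = True,
                     restrict_to=None) -> dict[str, np.ndarray]:
    """*n* distinct positions uniform over the allowed genome space.

    Gap regions are excluded by default; *restrict_to* (intervals)
    confines sampling further.  Reproducible for equal seeds.
    """
    rng = np.random.default_rng(seed)
    allowed = _allowed_intervals(index, exclude_gaps, restrict_to)
    sizes = np.array([e - s for _, s, e in allowed], dtype=np.int64)
    usable = int(sizes.sum())
    if usable <= 0:
        raise ValueError("no usable genome space to sample from")
    if n > usable:
        raise ValueError(f"cannot draw {n} distinct positions from {usable} bp")
    cum = np.concatenate(([0], np.cumsum(sizes)))
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(0, usable, size=n - len(chosen))
        chosen.update(int(v) for v in draw)
    flat = np.sort(np.fromiter(chosen, dtype=np.int64, count=len(chosen)))[:n] \
        if len(chosen) > n else np.sort(np.fromiter(chosen, dtype=np.int64))
    out: dict[str, list[int]] = {}
    idx = np.searchsorted(cum, flat, side="right") - 1
    for v, k in zip(flat, idx):
        chrom, start, _ = allowed[k]
        out.setdefault(chrom, []).append(start + int(v - cum[k]))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


@dataclass
class SpacingStats:
    """Inter-position gap comparison between two sets."""

    median_a: float
    median_b: float
    var_a: float
    var_b: float
    p_value: float
    gaps_a: np.ndarray
    gaps_b: np.ndarray


def _gaps(positions: dict[str, np.ndarray]) -> np.ndarray:
    gs = [np.diff(np.sort(np.asarray(v, dtype=float)))
          for v in positions.values() if len(v) >= 2]
    return np.concatenate(gs) if gs else np.empty(0)


def spacing_stats(set_a, set_b) -> SpacingStats:
    """Compare inter-position spacing distributions of two sets.

    Gaps are successive distances within each chromosome; the two gap
    samples are compared by a two-sided Wilcoxon rank-sum test.
    """
    ga = _gaps(_positions_by_chrom(set_a))
    gb = _gaps(_positions_by_chrom(set_b))
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("need at least 2 positions per set on some chromosome")
    combined = np.concatenate([ga, gb])
    if np.all(combined == combined[0]):
        p = 1.0  # every gap identical: no evidence of any difference
    else:
        p = float(mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
    return SpacingStats(float(np.median(ga)), float(np.median(gb)),
                        float(np.var(ga)), float(np.var(gb)), p, ga, gb)
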