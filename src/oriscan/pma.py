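"""Mutation-asymmetry (PMA) score and two-stage replication-origin calling.

The PMA score at genome position ``n`` contrasts leading- and
lagging-strand-specific mutation counts upstream and downstream of ``n``
within a +/-d window::

    PMA_n = 4/W_n^2 * ( sum_{i=n-d}^{n-1} k_i^lead * sum_{i=n}^{n+d} k_i^lag
                        - sum_{i=n-d}^{n-1} k_i^lag * sum_{i=n}^{n+d} k_i^lead )
    W_n   = sum_{i=n-d}^{n+d} k_i^N

where ``k_i^lead`` / ``k_i^lag`` count scheme mutations per bin summed over
patients and ``k_i^N`` counts all substitutions.  PMA is bounded in [-1, 1];
it reaches +1 at an ideally covered origin (all upstream mutations
lead-type, all downstream lag-type, balanced counts) and -1 at the reverse
pattern expected where two forks meet.

Detection scans the score in 1-kb bins with a 200-kb window, smooths it
(moving average n=100), picks local maxima (strict maximum within
+/-neighlim bins), drops peaks below a score threshold, and filters the
rest with a two-sided Fisher's exact test on the windowed 2x2 lead/lag
count table under Benjamini-Hochberg control.

The two-stage variant first detects origins with the POLE-exo-specific
classes only, profiles the per-class asymmetry at the top-scoring origins,
clusters the 96 mutation types into asymmetric clusters A/B plus a flat
remainder, rebuilds the counting scheme from clusters A and B, and reruns
the detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from . import mutcontext as mc
from .genome import GenomeIndex
from .mutcontext import LeadLagScheme, MutationRecord

log = logging.getLogger(__name__)


@dataclass
class PmaConfig:
    """Tunable parameters of the mORI detection (defaults = standard run)."""

    bin_size: int = 1000              # bp per bin
    window: int = 100_000             # half-window d, bp
    smooth_n: int = 100               # moving-average width, bins
    neighlim: int = 100               # peak isolation radius, bins
    min_score: float = 0.1            # smoothed-PMA peak threshold
    use_median_min_score: bool = False  # replace min_score by observed median
    alpha: float = 0.01               # BH significance level
    top_k: int = 1000                 # origins used for the class profile
    cluster_k: int = 3                # class clusters (A, B, flat)
    min_fraction: float = 0.2         # POLE-exo-specific sample cutoff
    min_coverage: float = 0.1         # min fraction of nominal window in-chromosome

    @property
    def d_bins(self) -> int:
        return self.window // self.bin_size


@dataclass
class PmaTrack:
    """Per-chromosome 1-kb-binned lead/lag/total counts and PMA profiles."""

    chrom: str
    bin_size: int
    lead: np.ndarray
    lag: np.ndarray
    total: np.ndarray
    pma_raw: np.ndarray | None = None
    pma_smooth: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.total)

    def bin_center(self, b: int) -> int:
        return b * self.bin_size + self.bin_size // 2


@dataclass
class OriCall:
    """One called origin; position is the center of the peak bin."""

    chrom: str
    position: int
    pma: float
    p_value: float
    q_value: float
    n_support: int


def bin_counts(records: list[MutationRecord], scheme: LeadLagScheme,
               index: GenomeIndex, bin_size: int = 1000,
               samples=None) -> dict[str, PmaTrack]:
    """Accumulate per-bin (k_lead, k_lag, k_total) over the selected samples.

    ``k_total`` counts every substitution regardless of class; the lead/lag
    channels count scheme classes only.  Records on chromosomes absent from
    the index are dropped with a warning.
    """
    sample_set = set(samples) if samples is not None else None
    tracks = {
        chrom: PmaTrack(chrom, bin_size,
                        np.zeros(-(-length // bin_size), dtype=np.int64),
                        np.zeros(-(-length // bin_size), dtype=np.int64),
                        np.zeros(-(-length // bin_size), dtype=np.int64))
        for chrom, length in index.chrom_lengths.items()
    }
    n_dropped = 0
    for rec in records:
        if sample_set is not None and rec.sample not in sample_set:
            continue
        chrom = index.normalize(rec.chrom)
        if chrom is None:
            n_dropped += 1
            continue
        track = tracks[chrom]
        b = rec.pos // bin_size
        if b >= track.n_bins:
            n_dropped += 1
            continue
        track.total[b] += 1
        side = scheme.side(rec.observed())
        if side == "lead":
            track.lead[b] += 1
        elif side == "lag":
            track.lag[b] += 1
    if n_dropped:
        log.warning("bin_counts: dropped %d record(s) outside the genome index",
                    n_dropped)
    return tracks


def pma_profile(track: PmaTrack, d_bins: int,
                min_coverage: float = 0.1) -> np.ndarray:
    """PMA at every bin of a track (prefix-sum implementation).

    Upstream sums run over bins [n-d, n-1], downstream over [n, n+d]; the
    center bin belongs to the downstream sum.  Windows truncate at
    chromosome ends; positions with W_n = 0 or with less than
    *min_coverage* of the nominal window inside the chromosome are masked
    (NaN) rather than forced to 0.
    """
    n = track.n_bins
    cl = np.concatenate(([0], np.cumsum(track.lead)))
    cg = np.concatenate(([0], np.cumsum(track.lag)))
    ct = np.concatenate(([0], np.cumsum(track.total)))
    pos = np.arange(n)
    lo = np.clip(pos - d_bins, 0, n)
    hi = np.clip(pos + d_bins + 1, 0, n)
    up_lead = cl[pos] - cl[lo]
    up_lag = cg[pos] - cg[lo]
    down_lead = cl[hi] - cl[pos]
    down_lag = cg[hi] - cg[pos]
    w = (ct[hi] - ct[lo]).astype(float)
    coverage = (hi - lo) / (2 * d_bins + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pma = 4.0 / w**2 * (up_lead * down_lag - up_lag * down_lead)
    pma[(w == 0) | (coverage < min_coverage)] = np.nan
    return pma


def pma_score(track: PmaTrack, position: int, d_bins: int,
              min_coverage: float = 0.1) -> float:
    """PMA at a single bin index (NaN where undefined)."""
    return float(pma_profile(track, d_bins, min_coverage)[position])


def pma_at_positions(records: list[MutationRecord], scheme: LeadLagScheme,
                     centers: list[tuple[str, int]],
                     window: int = 100_000,
                     return_w: bool = False):
    """PMA evaluated at exact bp positions, without binning.

    Window sums run over [c - window, c) upstream and [c, c + window)
    downstream in base-pair coordinates; W counts every record in the full
    window.  Free of the 1-kb discretization of the track-based scan, so
    an ideally asymmetric pattern scores exactly +/-1.
    """
    by_side: dict[str, dict[str, list[int]]] = {"lead": {}, "lag": {}, "all": {}}
    for rec in records:
        by_side["all"].setdefault(rec.chrom, []).append(rec.pos)
        side = scheme.side(rec.observed())
        if side:
            by_side[side].setdefault(rec.chrom, []).append(rec.pos)
    arrs = {k: {c: np.sort(np.asarray(v)) for c, v in d.items()}
            for k, d in by_side.items()}

    def count(kind, chrom, lo, hi):
        arr = arrs[kind].get(chrom)
        if arr is None:
            return 0
        return int(np.searchsorted(arr, hi, side="left")
                   - np.searchsorted(arr, lo, side="left"))

    out = np.full(len(centers), np.nan)
    ws = np.zeros(len(centers))
    for k, (chrom, c) in enumerate(centers):
        ul = count("lead", chrom, c - window, c)
        ug = count("lag", chrom, c - window, c)
        dl = count("lead", chrom, c, c + window)
        dg = count("lag", chrom, c, c + window)
        w = count("all", chrom, c - window, c + window)
        ws[k] = w
        if w > 0:
            out[k] = 4.0 / w**2 * (ul * dg - ug * dl)
    return (out, ws) if return_w else out


def smooth(values: np.ndarray, n: int = 100) -> np.ndarray:
    """Centered moving average over *n* bins.

    Truncates at the edges and excludes masked (NaN) bins from each
    average; all-masked windows stay masked.
    """
    if n < 1:
        raise ValueError("smoothing window must be >= 1")
    return (pd.Series(np.asarray(values, dtype=float))
            .rolling(n, center=True, min_periods=1).mean().to_numpy())


def pick_peaks(values: np.ndarray, neighlim_bins: int = 100,
               min_score: float = 0.1) -> np.ndarray:
    """Local maxima: strict maximum within +/-neighlim bins, above min_score.

    An exactly tied plateau yields its leftmost bin (strictly above the
    left window, at least as high as the right window).  Candidates closer
    than neighlim are merged keeping the higher score (greedy, highest
    first), so returned positions are >= neighlim apart.
    """
    v = np.asarray(values, dtype=float)
    s = pd.Series(np.where(np.isnan(v), -np.inf, v))
    left = s.rolling(neighlim_bins, min_periods=1).max().shift(1).to_numpy()
    right = s[::-1].rolling(neighlim_bins, min_periods=1).max().shift(1).to_numpy()[::-1]
    left = np.where(np.isnan(left), -np.inf, left)
    right = np.where(np.isnan(right), -np.inf, right)
    cand = np.flatnonzero(np.isfinite(v) & (v > left) & (v >= right)
                          & (v >= min_score))
    if len(cand) == 0:
        return cand
    order = cand[np.argsort(v[cand])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= neighlim_bins for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def _peak_table(track: PmaTrack, peak: int, d_bins: int) -> tuple[int, int, int, int, int]:
    lo = max(peak - d_bins, 0)
    hi = min(peak + d_bins + 1, track.n_bins)
    up = slice(lo, peak)
    down = slice(peak, hi)
    return (int(track.lead[up].sum()), int(track.lag[up].sum()),
            int(track.lead[down].sum()), int(track.lag[down].sum()),
            int(track.total[lo:hi].sum()))


def fisher_filter(peaks: list[tuple[str, int]], tracks: dict[str, PmaTrack],
                  d_bins: int, alpha: float = 0.01) -> list[OriCall]:
    """Filter peaks by a two-sided Fisher's exact test with BH correction.

    Per peak the 2x2 table is [[up_lead, up_lag], [down_lead, down_lag]]
    over the +/-d window — the contrast whose reversal the PMA score
    measures, with power limited by the mutation count, which is what the
    filter is for.  q-values are computed across all supplied peaks (call
    genome-wide); peaks with q < alpha are kept.
    """
    if not peaks:
        return []
    rows = []
    for chrom, b in peaks:
        track = tracks[chrom]
        ul, ug, dl, dg, tot = _peak_table(track, b, d_bins)
        p = fisher_exact([[ul, ug], [dl, dg]], alternative="two-sided")[1]
        score = float(track.pma_smooth[b]) if track.pma_smooth is not None \
            else float(track.pma_raw[b])
        rows.append((chrom, b, p, score, tot))
    pvals = np.array([r[2] for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    calls = [
        OriCall(chrom, tracks[chrom].bin_center(b), score, float(p), float(q), tot)
        for (chrom, b, p, score, tot), q in zip(rows, qvals)
        if q < alpha
    ]
    calls.sort(key=lambda c: (list(tracks).index(c.chrom), c.position))
    return calls


def refine_peak(track: PmaTrack, b: int, radius: int) -> int:
    """Sharpen a smoothed-track peak to the raw-score maximum nearby.

    Smoothing stabilizes detection but lets the maximum wander by up to
    half the smoothing window; the raw PMA profile localizes the origin
    much more sharply, so the reported bin is the raw argmax within
    +/-radius of the smoothed peak.
    """
    lo = max(b - radius, 0)
    hi = min(b + radius + 1, track.n_bins)
    seg = track.pma_raw[lo:hi]
    if np.all(np.isnan(seg)):
        return b
    return lo + int(np.nanargmax(seg))


def detect_from_scheme(records: list[MutationRecord], scheme: LeadLagScheme,
                       index: GenomeIndex, cfg: PmaConfig | None = None,
                       samples=None) -> tuple[list[OriCall], dict[str, PmaTrack]]:
    """One full scan/smooth/pick/filter pass with a fixed lead/lag scheme."""
    cfg = cfg or PmaConfig()
    tracks = bin_counts(records, scheme, index, cfg.bin_size, samples)
    raw_candidates: list[tuple[str, int]] = []
    for chrom, track in tracks.items():
        track.pma_raw = pma_profile(track, cfg.d_bins, cfg.min_coverage)
        track.pma_smooth = smooth(track.pma_raw, cfg.smooth_n)
        for b in pick_peaks(track.pma_smooth, cfg.neighlim, -np.inf):
            raw_candidates.append((chrom, int(b)))
    min_score = cfg.min_score
    if cfg.use_median_min_score and raw_candidates:
        min_score = float(np.median([tracks[c].pma_smooth[b]
                                     for c, b in raw_candidates]))
    peaks = [(c, refine_peak(tracks[c], b, cfg.smooth_n // 2))
             for c, b in raw_candidates
             if tracks[c].pma_smooth[b] >= min_score]
    return fisher_filter(peaks, tracks, cfg.d_bins, cfg.alpha), tracks


@dataclass
class ClassPmaProfile:
    """Per-sample, per-mutation-type PMA evaluated at a set of origins.

    Columns are the 96 mutation types labeled by their C/A-reference
    observation; the column PMA uses that observation as the lead form and
    the type's own mutations as W, so entries lie in [-1, 1] and a positive
    value means the C/A form is leading-strand-specific.
    """

    values: pd.DataFrame  # rows = samples, columns = types (C/A labels)
    ori_positions: list[tuple[str, int]] = field(default_factory=list)


def class_pma_profile(records: list[MutationRecord],
                      ori_positions: list[tuple[str, int]],
                      window: int = 100_000, top_k: int = 1000,
                      ori_scores=None) -> ClassPmaProfile:
    """Profile every mutation type's asymmetry at the top-scoring origins.

    *ori_positions* are (chrom, bp) origin centers; when *ori_scores* is
    given the *top_k* highest-scoring origins are used, otherwise the first
    *top_k* (with a warning if fewer are available).  Cells of types with
    no mutations in a sample are masked.
    """
    oris = list(ori_positions)
    if ori_scores is not None and len(oris) > top_k:
        order = np.argsort(np.asarray(ori_scores))[::-1][:top_k]
        oris = [oris[i] for i in order]
    elif len(oris) > top_k:
        oris = oris[:top_k]
    if len(oris) < top_k:
        log.warning("class_pma_profile: only %d origin(s) available (top_k=%d)",
                    len(oris), top_k)

    # per sample, per observed class: sorted position arrays per chromosome
    by_sample: dict[str, dict[str, dict[str, list[int]]]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample, {}) \
            .setdefault(rec.observed(), {}) \
            .setdefault(rec.chrom, []).append(rec.pos)
    for sample in by_sample:
        for obs in by_sample[sample]:
            for chrom in by_sample[sample][obs]:
                by_sample[sample][obs][chrom] = np.sort(
                    np.asarray(by_sample[sample][obs][chrom]))

    def window_counts(positions_by_chrom, chrom, center):
        arr = positions_by_chrom.get(chrom)
        if arr is None:
            return 0, 0
        lo = np.searchsorted(arr, center - window, side="left")
        mid = np.searchsorted(arr, center, side="left")
        hi = np.searchsorted(arr, center + window, side="right")
        return int(mid - lo), int(hi - mid)  # upstream, downstream

    types = mc.canonical_classes()
    labels = [mc.ca_representative(t) for t in types]
    samples = sorted(by_sample)
    mat = np.full((len(samples), len(labels)), np.nan)
    empty: dict[str, list[int]] = {}
    for si, sample in enumerate(samples):
        classes = by_sample[sample]
        for ci, lead_obs in enumerate(labels):
            lag_obs = mc.revcomp_class(lead_obs)
            lead_pos = classes.get(lead_obs, empty)
            lag_pos = classes.get(lag_obs, empty)
            if not lead_pos and not lag_pos:
                continue
            vals = []
            for chrom, center in oris:
                ul, dl = window_counts(lead_pos, chrom, center)
                ug, dg = window_counts(lag_pos, chrom, center)
                w = ul + dl + ug + dg
                if w == 0:
                    continue
                vals.append(4.0 / w**2 * (ul * dg - ug * dl))
            if vals:
                mat[si, ci] = float(np.mean(vals))
    return ClassPmaProfile(pd.DataFrame(mat, index=samples, columns=labels),
                           oris)


def cluster_classes(profile: ClassPmaProfile | pd.DataFrame,
                    k: int = 3) -> dict[str, list[str]]:
    """Cluster mutation-type columns into groups A (most positive mean
    asymmetry), B (most negative) and "other".

    Agglomerative clustering, Euclidean distance, complete linkage —
    deterministic.  Masked cells are treated as 0 (no asymmetry evidence).
    """
    from sklearn.cluster import AgglomerativeClustering

    df = profile.values if isinstance(profile, ClassPmaProfile) else profile
    df = df.dropna(axis=1, how="all")
    if df.shape[1] < 2:
        raise ValueError("need at least 2 informative mutation-type columns")
    k = min(k, df.shape[1])
    x = df.fillna(0.0).to_numpy().T  # rows = types, features = samples
    labels = AgglomerativeClustering(n_clusters=k, metric="euclidean",
                                     linkage="complete").fit_predict(x)
    means = np.array([x[labels == g].mean() for g in range(k)])
    g_a, g_b = int(np.argmax(means)), int(np.argmin(means))
    if g_a == g_b:
        raise ValueError("degenerate profile: a single cluster only")
    out: dict[str, list[str]] = {"A": [], "B": [], "other": []}
    for col, g in zip(df.columns, labels):
        out["A" if g == g_a else "B" if g == g_b else "other"].append(col)
    return out


@dataclass
class MoriResult:
    """Everything the two-stage detection produced."""

    stage1: list[OriCall]
    stage2: list[OriCall]
    scheme1: LeadLagScheme
    scheme2: LeadLagScheme | None
    profile: ClassPmaProfile | None
    clusters: dict[str, list[str]] | None
    selected_samples: list[str]
    fractions: dict[str, float]
    tracks1: dict[str, PmaTrack] | None = None
    tracks2: dict[str, PmaTrack] | None = None

    @property
    def calls(self) -> list[OriCall]:
        return self.stage2 if self.stage2 else self.stage1


def detect_mori(records: list[MutationRecord], index: GenomeIndex,
                cfg: PmaConfig | None = None,
                keep_tracks: bool = False) -> MoriResult:
    """Two-stage origin detection from classified mutation records.

    Stage 1 scans with the POLE-exo-specific scheme over samples passing
    the >= min_fraction selection; stage 2 profiles all 96 mutation types
    at the top-scoring stage-1 origins, clusters them, rebuilds the scheme
    from the asymmetric clusters A and B, and rescans.
    """
    cfg = cfg or PmaConfig()
    if not records:
        raise ValueError("no mutation records supplied")
    fractions = mc.pole_exo_fraction(records)
    selected = mc.select_samples(fractions, cfg.min_fraction)
    if not selected:
        raise ValueError("no samples pass the POLE-exo-specific fraction cutoff")
    recs = [r for r in records if r.sample in set(selected)]

    scheme1 = mc.stage1_scheme()
    stage1, tracks1 = detect_from_scheme(recs, scheme1, index, cfg)
    if not stage1:
        log.warning("stage 1 produced no origin calls; skipping stage 2")
        return MoriResult(stage1, [], scheme1, None, None, None, selected,
                          fractions, tracks1 if keep_tracks else None, None)

    profile = class_pma_profile(
        recs, [(c.chrom, c.position) for c in stage1],
        window=cfg.window, top_k=cfg.top_k,
        ori_scores=[c.pma for c in stage1])
    try:
        clusters = cluster_classes(profile, cfg.cluster_k)
        scheme2 = mc.stage2_scheme(clusters["A"], clusters["B"])
    except ValueError as exc:
        log.warning("stage 2 aborted (%s); returning stage-1 calls", exc)
        return MoriResult(stage1, [], scheme1, None, profile, None, selected,
                          fractions, tracks1 if keep_tracks else None, None)
    stage2, tracks2 = detect_from_scheme(recs, scheme2, index, cfg)
    return MoriResult(stage1, stage2, scheme1, scheme2, profile, clusters,
                      selected, fractions,
                      tracks1 if keep_tracks else None,
                      tracks2 if keep_tracks else None)
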