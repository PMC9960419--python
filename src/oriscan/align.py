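"""Numeric vector alignment (NVA) and its progressive multiple extension (MNVA).

Two sets of genomic positions (sorted coordinate vectors A and B, one per
chromosome) are compared by a Needleman-Wunsch-style dynamic program in
which the pairing cost is the absolute coordinate distance and each
unpaired element costs a flat gap penalty d::

    S[i,j] = min( S[i-1,j-1] + |A_i - B_j|,  S[i,j-1] + d,  S[i-1,j] + d )

with S[0,0] = 0 and all-gap borders.  The scoring is minimized (the
reverse of the classical sequence-alignment maximization): a low score
means similar position sets.  The alignment score is the terminal cell;
the consensus is the per-column average of paired elements with unpaired
elements carried through.

MNVA generalizes this to n sets: (1) all pairwise NVA scores, (2) a
neighbor-joining guide tree on the score matrix, (3) progressive alignment
in tree order, each vector aligned against the running consensus, and
(4) a final pass re-aligning every source vector to the final consensus
without introducing new consensus columns, yielding an n x m gapped
position matrix with per-column detection fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_GAP_PENALTY = 1_000_000  # bp-equivalents per unpaired element

_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass
class PositionVector:
    """Sorted, duplicate-free positions of one source on one chromosome."""

    chrom: str
    positions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class NvaAlignment:
    """Optimal pairing of two position vectors.

    ``pairs`` holds (i, j) index pairs, monotone in both coordinates;
    ``gaps_a``/``gaps_b`` the unpaired indices.  ``columns`` lists the
    alignment columns in order as (i, j) with -1 marking a gap.  ``score``
    equals the DP terminal cell: sum of |A_i - B_j| over pairs plus
    gap_penalty per unpaired element.  ``consensus`` averages paired
    elements and carries unpaired ones through, sorted.
    """

    pairs: list[tuple[int, int]]
    gaps_a: list[int]
    gaps_b: list[int]
    columns: list[tuple[int, int]]
    score: float
    consensus: np.ndarray
    gap_penalty: float


def _dp_matrix(a: np.ndarray, b: np.ndarray, d: float) -> tuple[np.ndarray, np.ndarray]:
    """Fill the score and move matrices (tie-break: diagonal > up > left)."""
    n, m = len(a), len(b)
    s = np.empty((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)
    s[0, :] = np.arange(m + 1) * d
    s[:, 0] = np.arange(n + 1) * d
    move[0, 1:] = _LEFT
    move[1:, 0] = _UP
    dist = np.abs(a[:, None] - b[None, :])
    for i in range(1, n + 1):
        row = s[i]
        prev = s[i - 1]
        di = dist[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + di[j - 1]
            up = prev[j] + d
            left = row[j - 1] + d
            # minimization; on ties prefer diagonal, then up, then left
            if diag <= up and diag <= left:
                row[j], move[i, j] = diag, _DIAG
            elif up <= left:
                row[j], move[i, j] = up, _UP
            else:
                row[j], move[i, j] = left, _LEFT
    return s, move


def nva(a, b, d: float = DEFAULT_GAP_PENALTY) -> NvaAlignment:
    """Align two position vectors (same chromosome) with gap penalty *d*.

    Accepts :class:`PositionVector` or plain arrays.  Empty vectors are
    allowed and produce all-gap alignments.
    """
    if d <= 0:
        raise ValueError("gap penalty must be positive")
    if isinstance(a, PositionVector) and isinstance(b, PositionVector):
        if a.chrom != b.chrom:
            raise ValueError(f"chromosome mismatch: {a.chrom} vs {b.chrom}")
    av = a.positions if isinstance(a, PositionVector) else np.asarray(a, dtype=float)
    bv = b.positions if isinstance(b, PositionVector) else np.asarray(b, dtype=float)
    s, move = _dp_matrix(av, bv, float(d))
    pairs: list[tuple[int, int]] = []
    gaps_a: list[int] = []
    gaps_b: list[int] = []
    columns: list[tuple[int, int]] = []
    i, j = len(av), len(bv)
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == _DIAG:
            pairs.append((i - 1, j - 1))
            columns.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == _UP:
            gaps_a.append(i - 1)
            columns.append((i - 1, -1))
            i -= 1
        else:
            gaps_b.append(j - 1)
            columns.append((-1, j - 1))
            j -= 1
    pairs.reverse()
    gaps_a.reverse()
    gaps_b.reverse()
    columns.reverse()
    consensus = np.sort(np.concatenate([
        np.array([(av[i] + bv[j]) / 2.0 for i, j in pairs]),
        av[gaps_a], bv[gaps_b],
    ])) if (pairs or gaps_a or gaps_b) else np.empty(0)
    return NvaAlignment(pairs, gaps_a, gaps_b, columns, float(s[-1, -1]),
                        consensus, float(d))


@dataclass
class GenomeNva:
    """Per-chromosome NVA alignments plus the genome-wide total score."""

    per_chrom: dict[str, NvaAlignment]
    total_score: float


def _as_chrom_dict(positions) -> dict[str, np.ndarray]:
    """Normalize a position set to {chrom: sorted array}."""
    if isinstance(positions, dict):
        return {c: np.asarray(v.positions if isinstance(v, PositionVector) else v,
                              dtype=float)
                for c, v in positions.items()}
    out: dict[str, np.ndarray] = {}
    for pv in positions:
        out[pv.chrom] = np.asarray(pv.positions, dtype=float)
    return out


def nva_genome(set_a, set_b, d: float = DEFAULT_GAP_PENALTY) -> GenomeNva:
    """Chromosome-by-chromosome NVA of two genome-wide position sets.

    Chromosomes present in only one set contribute all-gap alignments
    (every element penalized).
    """
    a, b = _as_chrom_dict(set_a), _as_chrom_dict(set_b)
    per_chrom = {}
    total = 0.0
    for chrom in sorted(set(a) | set(b)):
        aln = nva(a.get(chrom, np.empty(0)), b.get(chrom, np.empty(0)), d)
        per_chrom[chrom] = aln
        total += aln.score
    return GenomeNva(per_chrom, total)


def pairwise_similarity(sets: list, d: float = DEFAULT_GAP_PENALTY,
                        labels: list[str] | None = None) -> pd.DataFrame:
    """Symmetric dissimilarity matrix of position sets.

    Entry (r, s) is the genome-wide NVA score normalized by the combined
    element count |r| + |s| (mean per-element cost); lower means more
    similar, 0 on the diagonal.
    """
    n = len(sets)
    if n < 2:
        raise ValueError("need at least 2 sets")
    dicts = [_as_chrom_dict(s) for s in sets]
    sizes = [sum(len(v) for v in s.values()) for s in dicts]
    labels = labels or [f"set{i}" for i in range(n)]
    mat = np.zeros((n, n))
    for r in range(n):
        for s_ in range(r + 1, n):
            score = nva_genome(dicts[r], dicts[s_], d).total_score
            denom = sizes[r] + sizes[s_]
            mat[r, s_] = mat[s_, r] = score / denom if denom else 0.0
    return pd.DataFrame(mat, index=labels, columns=labels)


def _guide_order(score_matrix: np.ndarray, labels: list[str]) -> list[int]:
    """Leaf visiting order for progressive alignment.

    A neighbor-joining tree is built on the pairwise score matrix; the
    traversal starts at the closest leaf pair (patristic distance) and
    accretes the unplaced leaf closest to the placed set, ClustalW-style.
    Ties break toward the lower input index.
    """
    n = len(labels)
    if n == 2:
        return [0, 1]
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = [str(i) for i in range(n)]
    sym = (score_matrix + score_matrix.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    tree = nj(DistanceMatrix(sym, ids))
    td = tree.tip_tip_distances(ids).data  # patristic distances, input order
    # NJ can produce tiny negative branch lengths; clamp for ordering only
    td = np.maximum(td, 0.0)
    big = td.max() + 1.0
    masked = td + np.eye(n) * big
    i, j = np.unravel_index(np.argmin(masked), masked.shape)
    order = [min(i, j), max(i, j)]
    placed = set(order)
    while len(order) < n:
        best, best_d = None, np.inf
        for cand in range(n):
            if cand in placed:
                continue
            dmin = min(td[cand, p] for p in placed)
            if dmin < best_d:
                best, best_d = cand, dmin
        order.append(best)
        placed.add(best)
    return order


@dataclass
class MnvaMatrix:
    """n x m gapped position matrix from a multiple alignment.

    ``matrix`` has NaN for gaps; stripping the NaNs from row r reproduces
    source r's positions exactly and in order.  ``column_fraction`` is the
    per-column fraction of sources detecting the position;
    ``column_consensus`` the per-column mean of non-gap entries.
    """

    labels: list[str]
    chroms: list[str]                 # chromosome of each column
    matrix: np.ndarray                # n_sources x m, NaN = gap
    column_fraction: np.ndarray = field(init=False)
    column_consensus: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        present = ~np.isnan(self.matrix)
        with np.errstate(invalid="ignore"):
            self.column_fraction = present.mean(axis=0)
            self.column_consensus = np.where(
                present.any(axis=0),
                np.nansum(self.matrix, axis=0) / np.maximum(present.sum(axis=0), 1),
                np.nan)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_dataframe(self, gap: str = "-") -> pd.DataFrame:
        """Readable frame: rows = sources, gap marker for missing entries."""
        cells = np.where(np.isnan(self.matrix), None, self.matrix)
        df = pd.DataFrame(cells, index=self.labels)
        df = df.map(lambda v: gap if v is None else f"{v:.0f}")
        df.columns = [f"{c}:{i}" for i, c in enumerate(self.chroms)]
        return df


def _progressive_columns(vectors: list[np.ndarray], order: list[int],
                         d: float) -> list[list[float]]:
    """Step 3: align vectors in guide order against the running consensus.

    Columns hold the member values contributed so far; the consensus used
    for the next alignment is the per-column running mean.
    """
    columns: list[list[float]] = [[v] for v in vectors[order[0]]]
    for idx in order[1:]:
        v = vectors[idx]
        consensus = np.array([float(np.mean(c)) for c in columns])
        aln = nva(consensus, v, d)
        new_cols: list[list[float]] = []
        for i, j in aln.columns:
            if i >= 0 and j >= 0:       # paired: v joins the column
                new_cols.append(columns[i] + [float(v[j])])
            elif i >= 0:                # consensus column unmatched
                new_cols.append(list(columns[i]))
            else:                       # new column from v
                new_cols.append([float(v[j])])
        columns = new_cols
    return columns


def _assign_to_consensus(v: np.ndarray, consensus: np.ndarray) -> list[int]:
    """Step 4: monotone injection of v into consensus columns, min total |.|.

    Consensus columns are fixed (no new gaps); every element of v must be
    assigned to a distinct column in order.
    """
    n, m = len(v), len(consensus)
    if n == 0:
        return []
    if n > m:
        raise ValueError("source vector longer than consensus; cannot re-align")
    inf = np.inf
    s = np.full((n + 1, m + 1), inf)
    s[0, :] = 0.0
    choice = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = paired here
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            skip = s[i, j - 1]
            pair = s[i - 1, j - 1] + abs(v[i - 1] - consensus[j - 1])
            if pair <= skip:
                s[i, j], choice[i, j] = pair, 1
            else:
                s[i, j], choice[i, j] = skip, 0
    cols = []
    i, j = n, m
    while i > 0:
        if choice[i, j] == 1:
            cols.append(j - 1)
            i, j = i - 1, j - 1
        else:
            j -= 1
    cols.reverse()
    return cols


def mnva(sets: list, d: float = DEFAULT_GAP_PENALTY,
         labels: list[str] | None = None) -> MnvaMatrix:
    """Multiple numeric vector alignment of >= 2 genome-wide position sets.

    The guide tree is built once from genome-wide pairwise NVA scores and
    the same leaf order is used on every chromosome; per-chromosome
    matrices are concatenated in sorted chromosome order.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    dicts = [_as_chrom_dict(s) for s in sets]
    n = len(dicts)
    labels = labels or [f"set{i}" for i in range(n)]

    scores = np.zeros((n, n))
    for r in range(n):
        for s_ in range(r + 1, n):
            scores[r, s_] = scores[s_, r] = nva_genome(dicts[r], dicts[s_],
                                                       d).total_score
    order = _guide_order(scores, labels)

    chroms = sorted(set().union(*[set(s) for s in dicts]))
    all_chrom_cols: list[str] = []
    all_cols: list[np.ndarray] = []
    for chrom in chroms:
        vectors = [s.get(chrom, np.empty(0)) for s in dicts]
        chrom_order = [i for i in order]
        columns = _progressive_columns(vectors, chrom_order, d)
        if not columns:
            continue
        consensus = np.array([float(np.mean(c)) for c in columns])
        m = len(consensus)
        mat = np.full((n, m), np.nan)
        for r in range(n):
            for vi, cj in enumerate(_assign_to_consensus(vectors[r], consensus)):
                mat[r, cj] = vectors[r][vi]
        keep = ~np.isnan(mat).all(axis=0)
        mat = mat[:, keep]
        all_cols.append(mat)
        all_chrom_cols.extend([chrom] * mat.shape[1])
    matrix = np.concatenate(all_cols, axis=1) if all_cols else np.empty((n, 0))
    return MnvaMatrix(labels, all_chrom_cols, matrix)


def select_by_agreement(matrix: MnvaMatrix, min_fraction: float,
                        strict: bool = False) -> list[tuple[str, float, float]]:
    """Columns detected by enough sources, as consensus positions.

    Returns (chrom, consensus position, fraction) for columns whose
    detection fraction is >= min_fraction (or > with *strict*).
    """
    out = []
    for k in range(matrix.n_columns):
        frac = float(matrix.column_fraction[k])
        ok = frac > min_fraction if strict else frac >= min_fraction
        if ok:
            out.append((matrix.chroms[k], float(matrix.column_consensus[k]), frac))
    return out
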