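"""Synthetic cohorts with the statistical structure the detectors assume.

The generator plants replication origins on a toy genome and emits

* per-sample somatic mutations whose strand-resolved trinucleotide classes
  are asymmetric around the origins: an oriented class is observed in its
  leading-strand form upstream of the nearest origin and as its reverse
  complement downstream, with probability ``orientation_fidelity`` (and
  flipped otherwise), mimicking the POLE-exonuclease mutator pattern;
* stranded OK-seq read counts whose expected fork directionality is a
  sawtooth: +1 immediately downstream of every origin, decaying linearly
  to -1 at the next origin, with binomial read sampling per window;
* feature tracks (origin-coupled, uniform background, loop anchors) for
  the enrichment analyses.

With fidelity f the expected asymmetry score at a planted origin is
2f - 1 when every mutation is oriented (substituting expected counts into
the score); the generator is the test bed for that law.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import GenomeIndex, GenomicInterval, write_bed
from .mutcontext import MutationRecord, observed_class, revcomp_class

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 20-Mb toy genome with 25 planted origins at least
    500 kb apart, 20 POLE-exo-like samples and 50,000 oriented mutations
    placed with orientation fidelity 0.9 — a desk-scale stand-in for a
    POLE-exo hypermutator cohort.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000})
    origins: dict[str, list[int]] | None = None  # explicit positions, or:
    n_origins: int = 25
    min_spacing: int = 500_000
    n_samples: int = 20
    n_mutations: int = 50_000        # total over all samples
    # oriented mutation types, named by their leading-strand observation,
    # with mixture weights; reverse complements are emitted downstream.
    # TCT>TAT and TCG>TTG dominate (the POLE-exo-specific pair); TCC>TAC is
    # a further C/A-led type and TTT>TGT a type led by its G/T-reference
    # form, so both asymmetric cluster directions are represented.
    oriented_mix: dict[str, float] = field(
        default_factory=lambda: {"TCT>TAT": 0.50, "TCG>TTG": 0.20,
                                 "TCC>TAC": 0.10, "TTT>TGT": 0.10})
    # strand-symmetric noise types (emitted in either orientation)
    symmetric_mix: dict[str, float] = field(
        default_factory=lambda: {"ACA>AGA": 0.10})
    orientation_fidelity: float = 0.9
    okseq_depth: int = 200           # reads per 1-kb window
    bin_size: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.orientation_fidelity <= 1.0:
            raise ValueError("orientation_fidelity must be in [0, 1]")
        for w in list(self.oriented_mix.values()) + list(self.symmetric_mix.values()):
            if w < 0:
                raise ValueError("mixture weights must be non-negative")

    def index(self) -> GenomeIndex:
        return GenomeIndex(dict(self.chrom_lengths))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def plant_origins(config: SimulationConfig,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Planted origin positions honouring the minimum spacing.

    Explicit positions in the config win; otherwise origins are placed on
    a jittered grid so neighbours stay >= min_spacing apart.
    """
    if config.origins is not None:
        out = {}
        for chrom, pos in config.origins.items():
            arr = np.sort(np.asarray(pos, dtype=np.int64))
            if len(arr) > 1 and np.min(np.diff(arr)) < config.min_spacing:
                log.warning("explicit origins on %s violate min_spacing", chrom)
            out[chrom] = arr
        return out
    out = {}
    n_left = config.n_origins
    total = sum(config.chrom_lengths.values())
    for chrom, length in config.chrom_lengths.items():
        k = max(1, round(config.n_origins * length / total)) if n_left else 0
        k = min(k, n_left)
        n_left -= k
        if k == 0:
            continue
        cell = length / k
        jitter_room = max((cell - config.min_spacing) / 2, 0)
        centers = (np.arange(k) + 0.5) * cell
        jitter = rng.uniform(-jitter_room, jitter_room, size=k)
        out[chrom] = np.sort((centers + jitter).astype(np.int64))
    return out


def _replicon_bounds(origins: np.ndarray, length: int) -> np.ndarray:
    """Replicon boundaries: chromosome ends and midpoints between origins."""
    mids = (origins[:-1] + origins[1:]) // 2
    return np.concatenate(([0], mids, [length]))


@dataclass
class MutationSim:
    records: list[MutationRecord]
    origins: dict[str, np.ndarray]
    config: SimulationConfig


def simulate_mutations(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> MutationSim:
    """Draw the cohort's mutations around planted origins."""
    rng = rng or np.random.default_rng(config.seed)
    origins = plant_origins(config, rng)
    if not any(len(v) for v in origins.values()):
        raise ValueError("no origins planted")

    classes = list(config.oriented_mix) + list(config.symmetric_mix)
    weights = np.array(list(config.oriented_mix.values())
                       + list(config.symmetric_mix.values()), dtype=float)
    if weights.sum() <= 0:
        raise ValueError("empty class mixture")
    weights = weights / weights.sum()
    n_oriented_types = len(config.oriented_mix)

    # mutation density is uniform per bp, so an origin's replicon draws
    # mutations in proportion to its length
    chroms = [c for c in origins if len(origins[c])]
    bounds = {c: _replicon_bounds(origins[c], config.chrom_lengths[c])
              for c in chroms}
    chrom_w = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    replicon_w = {c: np.diff(bounds[c]) / np.diff(bounds[c]).sum()
                  for c in chroms}

    f = config.orientation_fidelity
    records: list[MutationRecord] = []
    chrom_pick = rng.choice(len(chroms), size=config.n_mutations, p=chrom_w)
    class_pick = rng.choice(len(classes), size=config.n_mutations, p=weights)
    sample_pick = rng.integers(0, config.n_samples, size=config.n_mutations)
    u_pos = rng.random(config.n_mutations)
    u_flip = rng.random(config.n_mutations)
    ori_pick = rng.random(config.n_mutations)
    strand_pick = rng.random(config.n_mutations)
    cum_repl = {c: np.cumsum(replicon_w[c]) for c in chroms}
    for k in range(config.n_mutations):
        chrom = chroms[chrom_pick[k]]
        oris = origins[chrom]
        oi = int(np.searchsorted(cum_repl[chrom], ori_pick[k]))
        oi = min(oi, len(oris) - 1)
        lo, hi = bounds[chrom][oi], bounds[chrom][oi + 1]
        pos = int(lo + u_pos[k] * (hi - lo))
        cls = classes[class_pick[k]]
        if class_pick[k] < n_oriented_types:
            upstream = pos < oris[oi]
            as_lead = (u_flip[k] < f) if upstream else (u_flip[k] >= f)
            obs = cls if as_lead else revcomp_class(cls)
        else:
            obs = cls if strand_pick[k] < 0.5 else revcomp_class(cls)
        ctx, mut = obs.split(">")
        records.append(MutationRecord(chrom, pos, ctx[1], mut[1],
                                      f"S{sample_pick[k]:02d}", ctx))
    return MutationSim(records, origins, config)


def write_mutation_table(records: list[MutationRecord], path: str | Path) -> None:
    """TSV with 1-based positions and precomputed contexts."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsample\tcontext\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.ref}\t{r.alt}\t{r.sample}\t"
                     f"{r.context or ''}\n")


def write_truth_bed(origins: dict[str, np.ndarray], path: str | Path) -> None:
    write_bed([GenomicInterval(c, int(p), int(p) + 1)
               for c, arr in origins.items() for p in arr], path)


def write_reference_fasta(records: list[MutationRecord],
                          config: SimulationConfig, path: str | Path,
                          rng: np.random.Generator | None = None,
                          line_width: int = 70) -> list[MutationRecord]:
    """Write a synthetic reference consistent with the records' contexts.

    Random sequence everywhere except at mutation sites, where each
    record's 3-mer context is stamped in (later stamps win).  Records
    whose context survives the stamping are returned; overlapping,
    contradictory records are dropped with a warning.  Intended for small
    test genomes.
    """
    rng = rng or np.random.default_rng(config.seed)
    arrays = {c: rng.integers(0, 4, size=l).astype(np.uint8)
              for c, l in config.chrom_lengths.items()}
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    code = {ord(b): i for i, b in enumerate("ACGT")}
    for r in records:
        if r.context is None or not (1 <= r.pos < len(arrays[r.chrom]) - 1):
            continue
        arrays[r.chrom][r.pos - 1:r.pos + 2] = [code[ord(b)] for b in r.context]
    kept = []
    n_dropped = 0
    for r in records:
        seq = arrays[r.chrom][r.pos - 1:r.pos + 2]
        ctx = bytes(lut[seq]).decode()
        if r.context == ctx:
            kept.append(r)
        else:
            n_dropped += 1
    if n_dropped:
        log.warning("%d record(s) dropped: context overwritten by an "
                    "overlapping neighbour", n_dropped)
    with open(path, "w") as fh:
        for chrom, arr in arrays.items():
            fh.write(f">{chrom}\n")
            seq = bytes(lut[arr]).decode()
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
    return kept


@dataclass
class OkseqSim:
    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]
    expected_rfd: dict[str, np.ndarray]
    origins: dict[str, np.ndarray]
    config: SimulationConfig


def sawtooth_rfd(origins: np.ndarray, length: int, bin_size: int) -> np.ndarray:
    """Expected fork directionality: +1 after each origin, linear decay to
    -1 at the next.

    The simulated chromosome stands for an interior genomic window, not a
    telomere-to-telomere chromosome: virtual flanking origins are placed
    one neighbour-spacing outside each end, so every planted origin sits
    between two decay segments like a real interior origin.
    """
    n_bins = -(-length // bin_size)
    x = (np.arange(n_bins) + 0.5) * bin_size
    rfd = np.empty(n_bins)
    s_first = origins[1] - origins[0] if len(origins) > 1 else length
    s_last = origins[-1] - origins[-2] if len(origins) > 1 else length
    knots = np.concatenate(([origins[0] - s_first], origins,
                            [origins[-1] + s_last]))
    for o1, o2 in zip(knots[:-1], knots[1:]):
        sel = (x >= o1) & (x < o2)
        rfd[sel] = 1.0 - 2.0 * (x[sel] - o1) / (o2 - o1)
    return np.clip(rfd, -1.0, 1.0)


def simulate_okseq(config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   deterministic: bool = False,
                   origins: dict[str, np.ndarray] | None = None) -> OkseqSim:
    """Stranded per-window read counts with an RFD step at each origin.

    Crick reads per window are Binomial(depth, (1 + RFD)/2); with
    *deterministic* the expectation is emitted instead (fractional
    counts), so the empirical RFD equals the sawtooth exactly.  Pass
    *origins* to reuse positions already planted (e.g. by a mutation
    simulation of the same cohort).
    """
    rng = rng or np.random.default_rng(config.seed)
    if origins is None:
        origins = plant_origins(config, rng)
    watson, crick, expected = {}, {}, {}
    for chrom, length in config.chrom_lengths.items():
        oris = origins.get(chrom, np.empty(0, dtype=np.int64))
        if len(oris) == 0:
            rfd = np.full(-(-length // config.bin_size), -1.0)
        else:
            rfd = sawtooth_rfd(oris, length, config.bin_size)
        p_crick = (1.0 + rfd) / 2.0
        depth = config.okseq_depth
        if deterministic:
            c = depth * p_crick
        else:
            c = rng.binomial(depth, p_crick).astype(float)
        watson[chrom] = depth - c
        crick[chrom] = c
        expected[chrom] = rfd
    return OkseqSim(watson, crick, expected, origins, config)


def write_bedgraph(values: dict[str, np.ndarray], path: str | Path,
                   bin_size: int = 1000) -> None:
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            for b, v in enumerate(arr):
                fh.write(f"{chrom}\t{b * bin_size}\t{(b + 1) * bin_size}\t{v:g}\n")


def simulate_feature_tracks(origins: dict[str, np.ndarray],
                            index: GenomeIndex,
                            rng: np.random.Generator,
                            coupled_offset: float = 0.0,
                            coupled_sd: float = 5_000.0,
                            n_background: int = 500,
                            loop_fraction: float = 0.5,
                            loop_length: int = 300_000,
                            feature_width: int = 200) -> dict[str, list]:
    """Feature BED sets for the enrichment analyses.

    Returns origin-coupled features (one per origin at offset +/- noise),
    a uniform background set, and loop anchors tied to a random subset of
    origins (second anchor displaced by loop_length).
    """
    coupled, background, loops = [], [], []
    for chrom, oris in origins.items():
        length = index.length(chrom)
        for o in oris:
            p = int(np.clip(o + coupled_offset + rng.normal(0, coupled_sd)
                            if coupled_sd > 0 else o + coupled_offset,
                            0, length - feature_width - 1))
            coupled.append(GenomicInterval(chrom, p, p + feature_width))
            if rng.random() < loop_fraction:
                a2 = int(min(o + loop_length, length - 1))
                loops.append((chrom, int(o), a2))
    total = sum(index.chrom_lengths.values())
    for _ in range(n_background):
        r = rng.integers(0, total - feature_width)
        for chrom, length in index.chrom_lengths.items():
            if r < length:
                start = int(min(r, length - feature_width - 1))
                background.append(GenomicInterval(chrom, start,
                                                  start + feature_width))
                break
            r -= length
    return {"coupled": coupled, "background": background, "loops": loops}
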