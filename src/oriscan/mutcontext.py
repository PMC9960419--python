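"""Strand-resolved trinucleotide mutation classes and lead/lag schemes.

DNA polymerase epsilon synthesizes the leading strand; a damaged POLE
exonuclease (proofreading) domain therefore deposits its characteristic
errors — above all C>A in a TxT context — asymmetrically around replication
origins.  On the reference plus strand this is seen as TCT>TAT upstream of
an origin and as the reverse complement AGA>ATA downstream.  This module
classifies substitutions into the 96 canonical pyrimidine-centered
trinucleotide classes while keeping track of which strand the observation
fell on, selects hypermutator samples by their POLE-exo-specific mutation
fraction, and builds the leading/lagging class sets the asymmetry score
counts.

Observed (strand-resolved) classes are written as ``"TCT>TAT"`` — the
reference-strand 3-mer and its mutated form.  Canonical classes use the
pyrimidine-centered SBS96 notation ``"T[C>A]T"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path

log = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def observed_class(context: str, alt: str) -> str:
    """Reference-strand observation string, e.g. ('TCT','A') -> 'TCT>TAT'."""
    return f"{context}>{context[0]}{alt}{context[2]}"


def revcomp_class(obs: str) -> str:
    """Reverse-complement observation: 'TCT>TAT' -> 'AGA>ATA'."""
    a, b = obs.split(">")
    return f"{revcomp(a)}>{revcomp(b)}"


def class_ref(obs: str) -> str:
    """Reference allele of an observed class ('AGA>ATA' -> 'G')."""
    return obs[1]


@dataclass
class MutationRecord:
    """One somatic substitution; ``pos`` is internal 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    context: str | None = None

    def observed(self) -> str:
        if self.context is None:
            raise ValueError("context not annotated")
        return observed_class(self.context, self.alt)


@dataclass(frozen=True)
class StrandedClass:
    """A canonical pyrimidine-centered class plus the observation strand."""

    canonical: str  # e.g. "T[C>A]T"
    orientation: str  # "forward" | "revcomp"


def classify(record: MutationRecord) -> StrandedClass:
    """Collapse an observed substitution onto its canonical class.

    If the reference base is a pyrimidine the observation is the canonical
    form itself (orientation "forward"); otherwise the reverse complement
    is taken (orientation "revcomp").  Total on all 192 context/ref/alt
    triples, 2-to-1 onto the 96 canonical classes.
    """
    ctx, ref, alt = record.context, record.ref, record.alt
    if ctx is None:
        raise ValueError("context not annotated")
    if len(ctx) != 3 or any(b not in BASES for b in ctx):
        raise ValueError(f"invalid context {ctx!r}")
    if ctx[1] != ref:
        raise ValueError(f"context {ctx} center does not match ref {ref}")
    if ref == alt:
        raise ValueError("ref equals alt")
    if ref in PYRIMIDINES:
        return StrandedClass(f"{ctx[0]}[{ref}>{alt}]{ctx[2]}", "forward")
    rc = revcomp(ctx)
    return StrandedClass(f"{rc[0]}[{rc[1]}>{revcomp(alt)}]{rc[2]}", "revcomp")


def canonical_classes() -> list[str]:
    """The 96 canonical classes (6 substitutions x 16 flanking contexts)."""
    out = []
    for ref in "CT":
        for alt in BASES:
            if alt == ref:
                continue
            for five, three in product(BASES, BASES):
                out.append(f"{five}[{ref}>{alt}]{three}")
    return out


def class_pair(canonical: str) -> tuple[str, str]:
    """Forward and reverse-complement observed forms of a canonical class."""
    five, ref, alt, three = canonical[0], canonical[2], canonical[4], canonical[6]
    fwd = observed_class(five + ref + three, alt)
    return fwd, revcomp_class(fwd)


def ca_representative(canonical: str) -> str:
    """The observed form whose reference allele is C or A.

    Every revcomp pair has exactly one member with a C/A reference allele;
    this fixed representative anchors the sign convention of the per-class
    asymmetry profile and the cluster combination rule.
    """
    fwd, rev = class_pair(canonical)
    return fwd if class_ref(fwd) in "CA" else rev


def canonical_of(obs: str) -> str:
    """Canonical class of an observed form."""
    a, b = obs.split(">")
    if a[1] in PYRIMIDINES:
        return f"{a[0]}[{a[1]}>{b[1]}]{a[2]}"
    ra, rb = revcomp(a), revcomp(b)
    return f"{ra[0]}[{ra[1]}>{rb[1]}]{ra[2]}"


# The two substitutions dominating POLE-exonuclease mutator genomes
# (signatures SBS10a/b): TCT>TAT and TCG>TTG, counted on either strand.
POLE_EXO_LEAD: tuple[str, str] = ("TCT>TAT", "TCG>TTG")
POLE_EXO_CANONICAL = frozenset(canonical_of(c) for c in POLE_EXO_LEAD)


def annotate_context(records: list[MutationRecord], reference) -> tuple[
        list[MutationRecord], list[MutationRecord]]:
    """Fill reference plus-strand 3-mer contexts from an indexed FASTA.

    *reference* is a path or a ``pyfaidx.Fasta``.  Returns (annotated,
    excluded): records at chromosome edges, with ambiguous (N) contexts, or
    whose ref allele mismatches the reference center base are excluded with
    a warning and never enter any count.
    """
    import pyfaidx

    fasta = reference if isinstance(reference, pyfaidx.Fasta) else \
        pyfaidx.Fasta(str(reference))
    annotated, excluded = [], []
    for rec in records:
        if rec.chrom not in fasta:
            log.warning("%s not in reference, record at %s:%d excluded",
                        rec.chrom, rec.chrom, rec.pos)
            excluded.append(rec)
            continue
        seq = fasta[rec.chrom]
        if rec.pos < 1 or rec.pos + 1 >= len(seq):
            log.warning("context undefined at chromosome edge %s:%d, excluded",
                        rec.chrom, rec.pos)
            excluded.append(rec)
            continue
        ctx = seq[rec.pos - 1:rec.pos + 2].seq.upper()
        if any(b not in BASES for b in ctx):
            excluded.append(rec)
            continue
        if ctx[1] != rec.ref:
            log.warning("ref mismatch at %s:%d: record %s vs reference %s, excluded",
                        rec.chrom, rec.pos, rec.ref, ctx[1])
            excluded.append(rec)
            continue
        rec.context = ctx
        annotated.append(rec)
    return annotated, excluded


def pole_exo_fraction(records: list[MutationRecord]) -> dict[str, float]:
    """Per-sample fraction of POLE-exo-specific substitutions.

    TCT>TAT and TCG>TTG observations are counted strand-symmetrically
    (i.e. AGA>ATA and CGA>CAA observations count too).  Samples with zero
    mutations do not appear in the result.
    """
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for rec in records:
        totals[rec.sample] = totals.get(rec.sample, 0) + 1
        if classify(rec).canonical in POLE_EXO_CANONICAL:
            hits[rec.sample] = hits.get(rec.sample, 0) + 1
    return {s: hits.get(s, 0) / n for s, n in totals.items()}


def select_samples(fractions: dict[str, float], min_fraction: float = 0.2) -> list[str]:
    """Samples whose POLE-exo-specific fraction is >= *min_fraction*."""
    return sorted(s for s, f in fractions.items() if f >= min_fraction)


@dataclass(frozen=True)
class LeadLagScheme:
    """Observed classes counted as leading- vs lagging-strand-specific.

    The lagging set is the element-wise reverse complement of the leading
    set, so the same mutational process seen from the other strand is
    counted on the opposite side of an origin.
    """

    lead: frozenset
    lag: frozenset

    def __post_init__(self) -> None:
        if self.lead & self.lag:
            raise ValueError("lead and lag class sets overlap")

    @classmethod
    def from_lead(cls, lead_classes) -> "LeadLagScheme":
        lead = frozenset(lead_classes)
        return cls(lead, frozenset(revcomp_class(c) for c in lead))

    def side(self, obs: str) -> str | None:
        if obs in self.lead:
            return "lead"
        if obs in self.lag:
            return "lag"
        return None

    def is_consistent(self) -> bool:
        return self.lag == frozenset(revcomp_class(c) for c in self.lead)


def stage1_scheme() -> LeadLagScheme:
    """The POLE-exo-specific scheme used in detection stage 1."""
    return LeadLagScheme.from_lead(POLE_EXO_LEAD)


def stage2_scheme(cluster_a, cluster_b) -> LeadLagScheme:
    """Combine the two asymmetric mutation-type clusters into one scheme.

    Clusters are sets of mutation types (each type identifies a
    reverse-complement pair of observations; any orientation may be used to
    name it).  For a type from cluster A the observation with a C/A
    reference allele is leading-strand-specific; for a type from cluster B
    the G/T-reference observation is.  The lagging set is the reverse
    complement of the leading set by construction, and a violation check is
    still performed and reported.
    """
    types_a = {canonical_of(c) for c in cluster_a}
    types_b = {canonical_of(c) for c in cluster_b}
    if types_a & types_b:
        raise ValueError(f"clusters overlap on type(s) {sorted(types_a & types_b)}")
    if not types_a and not types_b:
        return LeadLagScheme(frozenset(), frozenset())
    lead = {ca_representative(t) for t in types_a} | \
           {revcomp_class(ca_representative(t)) for t in types_b}
    scheme = LeadLagScheme(frozenset(lead),
                           frozenset(revcomp_class(c) for c in lead))
    if not scheme.is_consistent():  # pragma: no cover - holds by construction
        log.warning("stage-2 scheme lag set is not revcomp(lead)")
    return scheme


def read_class_list(path: str | Path) -> list[str]:
    """Read a plain-text class list (one observed or canonical class per line)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip().split(":")[0]
        if line and not line.startswith("#"):
            out.append(line)
    return out
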