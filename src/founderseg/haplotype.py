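"""Founder-haplotype (shared segment) detection under zygosity constraints.

The cohort carries a recessive index allele either homozygously or as one
allele of a compound heterozygote.  If the index allele descends from a single
ancestor, the carriers share a chromosomal segment around it (identity by
descent).  Homozygous carriers are autozygous over that segment, so every
marker inside it must be homozygous in them; heterozygous carriers hold the
founder haplotype on one chromosome, so a marker allele carried by the founder
must appear in them at least heterozygously.  Because the cohort is unphased,
a heterozygous genotype in a heterozygous carrier is *assumed* to sit on the
founder allele — the detected segment is therefore an upper bound on the true
IBD segment.

A site's genotype pattern is classified as:

* ``BREAKER`` — incompatible with continued sharing: a heterozygous genotype
  in a homozygous carrier, two homozygous carriers homozygous for different
  alleles, or a haplotype-defining allele confidently absent (HOM_REF) from a
  heterozygous carrier;
* ``CONSISTENT`` — haplotype-defining (at least one homozygous carrier is
  HOM_ALT) and every callable genotype is compatible with sharing;
* ``UNINFORMATIVE`` — everything else (reference-homozygous in the homozygous
  carriers, or not callable in the deciding samples).

The shared segment is the maximal run of CONSISTENT sites around the index,
extended through UNINFORMATIVE sites and truncated by the first BREAKER on
each side (or the window edge).  Endpoints are the outermost CONSISTENT
sites, not the breaker positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .variants import (
    CarrierClass,
    CohortGenotypeTable,
    SampleRole,
    Zygosity,
)

__all__ = [
    "SiteCall",
    "BreakerReason",
    "BreakerEvidence",
    "SiteStatus",
    "Breaker",
    "SharedSegment",
    "NarrowingStep",
    "NarrowingResult",
    "classify_site",
    "detect_segment",
    "narrow_incrementally",
    "segment_length",
]


class SiteCall(enum.Enum):
    CONSISTENT = "CONSISTENT"
    BREAKER = "BREAKER"
    UNINFORMATIVE = "UNINFORMATIVE"


class BreakerReason(str, enum.Enum):
    HET_IN_HOMOZYGOUS_CARRIER = "HET_IN_HOMOZYGOUS_CARRIER"
    ABSENT_IN_HETEROZYGOUS_CARRIER = "ABSENT_IN_HETEROZYGOUS_CARRIER"
    HOMOZYGOUS_CONFLICT = "HOMOZYGOUS_CONFLICT"


@dataclass(frozen=True)
class BreakerEvidence:
    sample_id: str
    reason: BreakerReason


@dataclass(frozen=True)
class SiteStatus:
    """Classification of one site; breaker evidence present iff BREAKER."""

    call: SiteCall
    evidence: Optional[BreakerEvidence] = None

    def __post_init__(self) -> None:
        if (self.call is SiteCall.BREAKER) != (self.evidence is not None):
            raise ValueError("breaker evidence present iff call is BREAKER")


@dataclass(frozen=True)
class Breaker:
    position: int
    evidence: BreakerEvidence


@dataclass(frozen=True)
class SharedSegment:
    """The detected founder segment, closed 1-based interval [start, end]."""

    chrom: str
    start: int
    end: int
    length_bp: int
    p_breaker: Optional[Breaker]
    q_breaker: Optional[Breaker]
    supporting_sites: tuple
    window: tuple

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.length_bp != self.end - self.start + 1:
            raise ValueError("length_bp must equal end - start + 1")
        if self.p_breaker is not None and self.p_breaker.position >= self.start:
            raise ValueError("p-side breaker must lie strictly before start")
        if self.q_breaker is not None and self.q_breaker.position <= self.end:
            raise ValueError("q-side breaker must lie strictly after end")
        for p in self.supporting_sites:
            if not (self.start <= p <= self.end):
                raise ValueError(f"supporting site {p} outside [start, end]")


def segment_length(start: int, end: int) -> int:
    """Closed-interval length in bp: ``end - start + 1``."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


# genotype codes (match Zygosity)
_HOM_REF, _HET, _HOM_ALT = 0, 1, 2
_CODE_UNINF, _CODE_CONS, _CODE_BRK = 0, 1, 2


def _classify_matrix(
    G: np.ndarray, hom_cols: Sequence[int], het_cols: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized site classification.

    Returns ``(codes, reasons, offender)`` over the rows of ``G``:
    codes in {UNINFORMATIVE, CONSISTENT, BREAKER}; for breakers, ``reasons``
    holds the rule index (0=het-in-hom, 1=hom-conflict, 2=absent-in-het) and
    ``offender`` the column index of the offending sample.
    """
    n = G.shape[0]
    hom = G[:, list(hom_cols)] if len(hom_cols) else np.empty((n, 0), np.int8)
    het = G[:, list(het_cols)] if len(het_cols) else np.empty((n, 0), np.int8)

    hom_het = hom == _HET
    brk_a = hom_het.any(axis=1)
    hom_alt_any = (hom == _HOM_ALT).any(axis=1)
    hom_ref = hom == _HOM_REF
    brk_b = ~brk_a & hom_alt_any & hom_ref.any(axis=1)
    defining = hom_alt_any & ~brk_a & ~brk_b
    het_ref = het == _HOM_REF
    brk_c = defining & het_ref.any(axis=1)

    codes = np.zeros(n, dtype=np.int8)
    reasons = np.full(n, -1, dtype=np.int8)
    offender = np.full(n, -1, dtype=np.int64)

    codes[defining & ~brk_c] = _CODE_CONS
    for mask, reason, local, cols in (
        (brk_a, 0, hom_het, hom_cols),
        (brk_b, 1, hom_ref, hom_cols),
        (brk_c, 2, het_ref, het_cols),
    ):
        if not mask.any():
            continue
        codes[mask] = _CODE_BRK
        reasons[mask] = reason
        rows = np.nonzero(mask)[0]
        first = np.argmax(local[rows], axis=1)
        offender[rows] = np.asarray(list(cols))[first]
    return codes, reasons, offender


_REASONS = (
    BreakerReason.HET_IN_HOMOZYGOUS_CARRIER,
    BreakerReason.HOMOZYGOUS_CONFLICT,
    BreakerReason.ABSENT_IN_HETEROZYGOUS_CARRIER,
)


def classify_site(
    genotypes: Union[Mapping[str, Zygosity], Sequence[Zygosity]],
    roles: Sequence[SampleRole],
) -> SiteStatus:
    """Classify one site's genotype pattern against the sharing rules.

    ``genotypes`` maps sample id -> Zygosity (or is a sequence aligned with
    ``roles``); every sample in ``roles`` must have a genotype (MISSING is a
    genotype).  Rules, in order: (a) HET in a homozygous carrier breaks;
    (b) two homozygous carriers callably homozygous for different alleles
    break; (c) a haplotype-defining allele (some homozygous carrier HOM_ALT)
    confidently absent from a heterozygous carrier breaks; (d) a
    haplotype-defining site with all callable genotypes compatible is
    CONSISTENT; (e) anything else is UNINFORMATIVE.
    """
    if not roles:
        raise ValueError("roles must be non-empty")
    if isinstance(genotypes, Mapping):
        try:
            row = [genotypes[r.sample_id] for r in roles]
        except KeyError as e:
            raise ValueError(f"no genotype for sample {e.args[0]!r}")
    else:
        if len(genotypes) != len(roles):
            raise ValueError("genotypes and roles length mismatch")
        row = list(genotypes)
    G = np.array([[int(z) for z in row]], dtype=np.int8)
    hom_cols = [i for i, r in enumerate(roles)
                if r.carrier_class is CarrierClass.HOMOZYGOUS_CARRIER]
    het_cols = [i for i, r in enumerate(roles)
                if r.carrier_class is CarrierClass.HETEROZYGOUS_CARRIER]
    codes, reasons, offender = _classify_matrix(G, hom_cols, het_cols)
    if codes[0] == _CODE_BRK:
        ev = BreakerEvidence(roles[int(offender[0])].sample_id,
                             _REASONS[int(reasons[0])])
        return SiteStatus(SiteCall.BREAKER, ev)
    if codes[0] == _CODE_CONS:
        return SiteStatus(SiteCall.CONSISTENT)
    return SiteStatus(SiteCall.UNINFORMATIVE)


def _site_groups(table: CohortGenotypeTable, roles: Sequence[SampleRole]):
    """Per-position classification, breaker-wins within a position group.

    Returns (positions sorted unique, codes, evidence list) where evidence is
    a Breaker-ready ``BreakerEvidence`` or None per position.
    """
    sub = table if [r.sample_id for r in roles] == table.sample_ids \
        else table.subset_samples([r.sample_id for r in roles])
    hom_cols = [i for i, r in enumerate(roles)
                if r.carrier_class is CarrierClass.HOMOZYGOUS_CARRIER]
    het_cols = [i for i, r in enumerate(roles)
                if r.carrier_class is CarrierClass.HETEROZYGOUS_CARRIER]
    codes, reasons, offender = _classify_matrix(sub.genotypes, hom_cols, het_cols)

    positions = sub.positions
    uniq, starts = np.unique(positions, return_index=True)
    grp_codes = np.empty(len(uniq), dtype=np.int8)
    grp_ev: list[Optional[BreakerEvidence]] = [None] * len(uniq)
    bounds = list(starts) + [len(positions)]
    for k in range(len(uniq)):
        rows = slice(bounds[k], bounds[k + 1])
        c = codes[rows]
        if (c == _CODE_BRK).any():
            j = rows.start + int(np.argmax(c == _CODE_BRK))
            grp_codes[k] = _CODE_BRK
            grp_ev[k] = BreakerEvidence(
                roles[int(offender[j])].sample_id, _REASONS[int(reasons[j])]
            )
        elif (c == _CODE_CONS).any():
            grp_codes[k] = _CODE_CONS
        else:
            grp_codes[k] = _CODE_UNINF
    return uniq, grp_codes, grp_ev


def detect_segment(
    table: CohortGenotypeTable,
    roles: Optional[Sequence[SampleRole]] = None,
    *,
    max_uninformative_gap_bp: Optional[int] = None,
) -> SharedSegment:
    """Detect the maximal shared segment around the index variant.

    Sites are scanned outward from the index in position order on each side;
    UNINFORMATIVE sites are skipped, extension stops at the first BREAKER per
    side (recorded) or at the window edge.  ``max_uninformative_gap_bp``, if
    given, stops extension once the next site lies more than that many bp
    beyond the current endpoint (no breaker recorded; default unlimited —
    exome data has long uninformative gaps by construction).

    The index site itself must classify CONSISTENT, otherwise the cohort is
    malformed and ``ValueError`` is raised.
    """
    if roles is None:
        roles = table.samples
    if not roles:
        raise ValueError("roles must be non-empty")
    uniq, codes, ev = _site_groups(table, roles)
    idx_pos = table.index_variant.pos
    k0 = int(np.searchsorted(uniq, idx_pos))
    if k0 >= len(uniq) or uniq[k0] != idx_pos:
        raise ValueError("index variant position absent from table")
    if codes[k0] != _CODE_CONS:
        what = "a BREAKER" if codes[k0] == _CODE_BRK else "UNINFORMATIVE"
        raise ValueError(
            f"index site at {idx_pos} classifies as {what}; malformed cohort"
        )

    def scan(direction: int):
        endpoint = idx_pos
        breaker = None
        k = k0 + direction
        while 0 <= k < len(uniq):
            pos = int(uniq[k])
            if (
                max_uninformative_gap_bp is not None
                and abs(pos - endpoint) > max_uninformative_gap_bp
            ):
                break
            if codes[k] == _CODE_BRK:
                breaker = Breaker(pos, ev[k])
                break
            if codes[k] == _CODE_CONS:
                endpoint = pos
            k += direction
        return endpoint, breaker

    start, p_breaker = scan(-1)
    end, q_breaker = scan(+1)
    in_seg = (uniq >= start) & (uniq <= end)
    support = tuple(int(p) for p in uniq[in_seg & (codes == _CODE_CONS)])
    assert not (in_seg & (codes == _CODE_BRK)).any(), \
        "breaker inside reported segment"
    return SharedSegment(
        chrom=table.chrom,
        start=int(start),
        end=int(end),
        length_bp=segment_length(int(start), int(end)),
        p_breaker=p_breaker,
        q_breaker=q_breaker,
        supporting_sites=support,
        window=(int(uniq[0]), int(uniq[-1])),
    )


@dataclass(frozen=True)
class NarrowingStep:
    sample_ids: tuple
    segment: Optional[SharedSegment]


@dataclass(frozen=True)
class NarrowingResult:
    steps: tuple
    final: SharedSegment


def narrow_incrementally(
    table: CohortGenotypeTable,
    order: Optional[Sequence[str]] = None,
    *,
    max_uninformative_gap_bp: Optional[int] = None,
) -> NarrowingResult:
    """Narrow the putative shared segment by adding samples one at a time.

    Runs :func:`detect_segment` on growing prefixes of ``order`` (default:
    homozygous carriers in table order, then heterozygous carriers — the
    homozygosity run is found first, then narrowed by the heterozygous
    carriers).  Intermediate segments are exposed for inspection; a prefix in
    which the index site is not yet CONSISTENT (e.g. no homozygous carrier
    present) records ``None``.  The final step uses every sample and equals
    joint detection.
    """
    if order is None:
        homs = [s.sample_id for s in table.samples
                if s.carrier_class is CarrierClass.HOMOZYGOUS_CARRIER]
        hets = [s.sample_id for s in table.samples
                if s.carrier_class is CarrierClass.HETEROZYGOUS_CARRIER]
        order = homs + hets
    order = list(order)
    if sorted(order) != sorted(table.sample_ids):
        raise ValueError("order must be a permutation of the table's samples")
    by_id = {s.sample_id: s for s in table.samples}
    steps = []
    segment = None
    for k in range(1, len(order) + 1):
        prefix = order[:k]
        roles = [by_id[s] for s in prefix]
        try:
            segment = detect_segment(
                table, roles, max_uninformative_gap_bp=max_uninformative_gap_bp
            )
        except ValueError:
            if k == len(order):
                raise
            segment = None
        steps.append(NarrowingStep(tuple(prefix), segment))
    assert segment is not None
    return NarrowingResult(tuple(steps), segment)
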