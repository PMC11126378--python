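"""Splice-donor disruption reasoning for variants hitting the invariant GT.

When a variant destroys the near-invariant GT dinucleotide of a 5' splice
site (donor), the spliceosome may either activate a nearby cryptic donor or
skip the upstream exon.  This module enumerates candidate cryptic donors
(every GT within a search window of the authentic donor), scores them with an
injected donor-strength scorer, and classifies the predicted transcript
outcome: cryptic activation when some candidate scores close enough to the
authentic donor, otherwise exon skipping — frameshifting iff the skipped exon
length is not a multiple of 3.

The scorer is a contract, not an implementation: any callable mapping a
9-mer donor window (3 exonic + 6 intronic bases, the convention of
maximum-entropy 5'ss models) to a real score, higher = stronger donor.  A
lookup-table scorer backed by a two-column file is provided; the packaged
fixture table maps synthetic donor contexts to published scores so the
classification logic is testable offline.  All outcomes are predictions; no
transcript-level validation is implied.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

__all__ = [
    "DonorContext",
    "DonorScorer",
    "TableDonorScorer",
    "SpliceOutcomeKind",
    "CandidateDonor",
    "SpliceCall",
    "enumerate_candidate_donors",
    "classify_outcome",
    "load_donor_contexts",
]

_BASES = frozenset("ACGT")
DONOR_EXONIC = 3   # exonic bases in the donor 9-mer
DONOR_INTRONIC = 6  # intronic bases in the donor 9-mer

DonorScorer = Callable[[str], float]


@dataclass(frozen=True)
class DonorContext:
    """Reference sequence around an authentic 5' splice donor.

    ``authentic_offset`` is the 0-based index within ``sequence`` of the
    first intronic base (the G of the authentic GT).  ``sequence`` is given
    on the coding strand (a minus-strand gene is reverse-complemented before
    construction; ``strand`` records the genomic orientation).
    ``exon_length_bp`` is the length of the exon upstream of this donor.
    """

    name: str
    sequence: str
    authentic_offset: int
    exon_length_bp: int
    strand: str = "+"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or not _BASES.issuperset(seq):
            raise ValueError(f"{self.name}: sequence must be non-empty A/C/G/T")
        if not (0 <= self.authentic_offset <= len(seq) - 2):
            raise ValueError(f"{self.name}: authentic_offset out of range")
        if seq[self.authentic_offset : self.authentic_offset + 2] != "GT":
            raise ValueError(
                f"{self.name}: reference bases at the authentic donor must be GT"
            )
        if self.exon_length_bp < 1:
            raise ValueError(f"{self.name}: exon_length_bp must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-'")

    def ninemer(self, offset: int = 0) -> str:
        """Donor 9-mer (3 exonic + 6 intronic) at signed ``offset`` from the
        authentic donor."""
        p = self.authentic_offset + offset
        if p - DONOR_EXONIC < 0 or p + DONOR_INTRONIC > len(self.sequence):
            raise ValueError(f"{self.name}: 9-mer at offset {offset:+d} out of range")
        return self.sequence[p - DONOR_EXONIC : p + DONOR_INTRONIC]


@dataclass(frozen=True)
class CandidateDonor:
    offset: int       # signed, relative to the authentic donor G
    ninemer: str
    score: Optional[float] = None


class SpliceOutcomeKind(str, enum.Enum):
    CRYPTIC_ACTIVATION = "CRYPTIC_ACTIVATION"
    EXON_SKIP_FRAMESHIFT = "EXON_SKIP_FRAMESHIFT"
    EXON_SKIP_INFRAME = "EXON_SKIP_INFRAME"


@dataclass(frozen=True)
class SpliceCall:
    """Predicted transcript outcome with its score evidence."""

    context: str
    outcome: SpliceOutcomeKind
    authentic_score: float
    best_candidate: Optional[CandidateDonor]
    margin: float
    floor: float
    exon_length_bp: int

    def __post_init__(self) -> None:
        skip = (
            SpliceOutcomeKind.EXON_SKIP_FRAMESHIFT
            if self.exon_length_bp % 3
            else SpliceOutcomeKind.EXON_SKIP_INFRAME
        )
        if self.outcome is not SpliceOutcomeKind.CRYPTIC_ACTIVATION \
                and self.outcome is not skip:
            raise ValueError(
                "frameshift classification must follow exon_length_bp mod 3"
            )


class TableDonorScorer:
    """Lookup-table donor scorer: 9-mer -> score.

    ``default`` (if given) is returned for 9-mers absent from the table;
    otherwise unknown 9-mers raise ``KeyError``.
    """

    def __init__(self, table: dict, default: Optional[float] = None):
        self._table = {k.upper(): float(v) for k, v in table.items()}
        for k in self._table:
            if len(k) != 9 or not _BASES.issuperset(k):
                raise ValueError(f"invalid donor 9-mer {k!r}")
        self._default = default

    @classmethod
    def from_tsv(cls, path, default: Optional[float] = None) -> "TableDonorScorer":
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                ninemer, score = line.split("\t")
                table[ninemer] = float(score)
        return cls(table, default=default)

    def __call__(self, ninemer: str) -> float:
        ninemer = ninemer.upper()
        if ninemer in self._table:
            return self._table[ninemer]
        if self._default is not None:
            return self._default
        raise KeyError(f"no score for donor 9-mer {ninemer!r}")


def enumerate_candidate_donors(
    ctx: DonorContext, window_bp: int = 35
) -> list[CandidateDonor]:
    """All GT dinucleotides within ±``window_bp`` of the authentic donor.

    The disrupted authentic site itself is excluded.  Offsets are signed
    relative to the authentic donor G; each candidate carries its 9-mer donor
    window.  Raises ``ValueError`` when the window (including the 9-mer
    extent of its outermost candidates) does not fit inside the sequence.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    a, seq = ctx.authentic_offset, ctx.sequence
    if a - window_bp < DONOR_EXONIC or a + window_bp + DONOR_INTRONIC > len(seq):
        raise ValueError(
            f"{ctx.name}: ±{window_bp} bp window exceeds the context sequence"
        )
    out = []
    for offset in range(-window_bp, window_bp + 1):
        if offset == 0:
            continue
        p = a + offset
        if seq[p : p + 2] == "GT":
            out.append(CandidateDonor(offset, ctx.ninemer(offset)))
    return out


def classify_outcome(
    ctx: DonorContext,
    candidates: Sequence[CandidateDonor],
    scorer: Optional[DonorScorer] = None,
    *,
    authentic_score: Optional[float] = None,
    margin: float = 3.0,
    floor: float = 0.0,
) -> SpliceCall:
    """Classify the predicted outcome of a disrupted authentic donor.

    A candidate activates cryptically when its score reaches
    ``max(floor, authentic_score - margin)``; the defaults demand a candidate
    within 3 score units of the authentic donor and no weaker than 0.
    Otherwise the upstream exon is predicted skipped — frameshifting iff its
    length is not a multiple of 3.  Candidate scores are taken from the
    records or computed with ``scorer``; the authentic score likewise.
    """
    if authentic_score is None:
        if scorer is None:
            raise ValueError("need a scorer or an explicit authentic_score")
        authentic_score = float(scorer(ctx.ninemer(0)))
    scored = []
    for c in candidates:
        score = c.score
        if score is None:
            if scorer is None:
                raise ValueError(f"candidate at {c.offset:+d} has no score")
            score = float(scorer(c.ninemer))
        scored.append(CandidateDonor(c.offset, c.ninemer, float(score)))
    best = max(scored, key=lambda c: c.score) if scored else None
    threshold = max(floor, authentic_score - margin)
    if best is not None and best.score >= threshold:
        outcome = SpliceOutcomeKind.CRYPTIC_ACTIVATION
    elif ctx.exon_length_bp % 3:
        outcome = SpliceOutcomeKind.EXON_SKIP_FRAMESHIFT
    else:
        outcome = SpliceOutcomeKind.EXON_SKIP_INFRAME
    return SpliceCall(
        context=ctx.name,
        outcome=outcome,
        authentic_score=float(authentic_score),
        best_candidate=best,
        margin=float(margin),
        floor=float(floor),
        exon_length_bp=ctx.exon_length_bp,
    )


def load_donor_contexts(fasta_path) -> list[DonorContext]:
    """Read donor contexts from FASTA.

    Record descriptions carry ``key=value`` pairs: ``authentic_offset``
    (0-based index of the authentic G), ``exon_length_bp``, optional
    ``strand``.
    """
    from Bio import SeqIO

    contexts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        meta = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        try:
            contexts.append(
                DonorContext(
                    name=rec.id,
                    sequence=str(rec.seq),
                    authentic_offset=int(meta["authentic_offset"]),
                    exon_length_bp=int(meta["exon_length_bp"]),
                    strand=meta.get("strand", "+"),
                )
            )
        except KeyError as e:
            raise ValueError(
                f"FASTA record {rec.id}: missing {e.args[0]} in description"
            )
    if not contexts:
        raise ValueError(f"no donor contexts in {fasta_path}")
    return contexts
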