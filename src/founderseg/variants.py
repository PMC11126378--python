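"""Domain types and genotype semantics shared by all pipeline stages.

The pipeline reasons about small variants (SNVs and short indels) on 1-based
GRCh38 coordinates, about per-sample zygosity at those variants, and about the
role each sample plays relative to an *index variant* — the pathogenic allele
around which haplotype sharing is assessed.  Samples that are homozygous for
the index allele are expected to be autozygous across the shared founder
segment; samples that are compound-heterozygous carry the founder haplotype on
one chromosome only.

Coordinates are 1-based and intervals are fully closed throughout, so a
segment from ``start`` to ``end`` spans ``end - start + 1`` bp.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Zygosity",
    "CarrierClass",
    "CoverageClass",
    "GenomicVariant",
    "SampleRole",
    "CohortGenotypeTable",
    "canonical_chrom",
    "normalize_variant",
    "derive_roles",
]

_BASES = frozenset("ACGT")


class Zygosity(enum.IntEnum):
    """Per-sample genotype at a biallelic site.

    MISSING is *not* HOM_REF: it means the position was not callable for the
    sample (e.g. outside exome capture), whereas HOM_REF is a confident
    reference call.  Nothing in the pipeline may silently coerce one into the
    other.
    """

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class CarrierClass(str, enum.Enum):
    """Zygosity class of a sample at the index variant."""

    HOMOZYGOUS_CARRIER = "HOMOZYGOUS_CARRIER"
    HETEROZYGOUS_CARRIER = "HETEROZYGOUS_CARRIER"


class CoverageClass(str, enum.Enum):
    """Sequencing breadth of a sample: whole genome, or exome capture."""

    GENOME = "GENOME"
    EXOME = "EXOME"


def canonical_chrom(name: str) -> str:
    """Canonicalize a chromosome name: accept ``chr1`` or ``1``, return ``1``."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise ValueError("empty chromosome name")
    return name


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """One normalized biallelic small variant on a 1-based coordinate.

    ``ref`` and ``alt`` are non-empty ACGT strings; indels carry a left
    anchor base and are expected to be left-aligned (see
    :func:`normalize_variant`).  Exactly one alt allele per record —
    multi-allelic input is split upstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vid: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", canonical_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _BASES.issuperset(allele):
                raise ValueError(
                    f"{name} allele {allele!r} at {self.chrom}:{self.pos} is not a "
                    "non-empty A/C/G/T string"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SampleRole:
    """A cohort sample: its carrier class at the index variant and coverage."""

    sample_id: str
    carrier_class: CarrierClass
    coverage_class: CoverageClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "carrier_class", CarrierClass(self.carrier_class))
        object.__setattr__(self, "coverage_class", CoverageClass(self.coverage_class))


Reference = Union[str, Callable[[int], str]]


def _ref_base(reference: Reference, pos: int, reference_start: int) -> Optional[str]:
    """Reference base at 1-based ``pos``, or None when out of range."""
    if callable(reference):
        try:
            base = reference(pos)
        except (IndexError, KeyError):
            return None
        return base.upper() if base else None
    i = pos - reference_start
    if 0 <= i < len(reference):
        return reference[i].upper()
    return None


def _normalize_one(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    vid: Optional[str],
    reference: Optional[Reference],
    reference_start: int,
) -> GenomicVariant:
    # Parsimony-trim and left-align, VCF-style (anchor base retained for
    # indels).  Left-shifting across the reference is only possible when a
    # reference context is supplied.
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (
            ref[-1] == alt[-1]
            and len(ref) != len(alt)
            and reference is not None
            and pos > 1
        ):
            prev = _ref_base(reference, pos - 1, reference_start)
            if prev is None:
                break
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return GenomicVariant(chrom, pos, ref, alt, vid)


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    *,
    vid: Optional[str] = None,
    reference: Optional[Reference] = None,
    reference_start: int = 1,
) -> list[GenomicVariant]:
    """Split a possibly multi-allelic record into normalized biallelic variants.

    Each alt allele yields one :class:`GenomicVariant`; order is preserved.
    Indels are parsimony-trimmed and, when ``reference`` is given (a string
    whose first base sits at 1-based ``reference_start``, or a callable
    ``pos -> base``), left-aligned to the leftmost admissible anchor.

    Raises ``ValueError`` (naming the record) for malformed non-ACGT alleles.
    """
    if not alts:
        raise ValueError(f"record {chrom}:{pos} has no alt alleles")
    ident = vid or f"{chrom}:{pos}"
    ref = str(ref).upper()
    if not ref or not _BASES.issuperset(ref):
        raise ValueError(f"record {ident}: malformed ref allele {ref!r}")
    out = []
    for alt in alts:
        alt = str(alt).upper()
        if not alt or not _BASES.issuperset(alt):
            raise ValueError(f"record {ident}: malformed alt allele {alt!r}")
        if alt == ref:
            raise ValueError(f"record {ident}: alt equals ref ({ref!r})")
        out.append(_normalize_one(chrom, pos, ref, alt, vid, reference, reference_start))
    return out


@dataclass(eq=False)
class CohortGenotypeTable:
    """Variants x samples zygosity matrix with explicit missingness.

    ``genotypes`` is an int8 matrix of :class:`Zygosity` codes with shape
    ``(len(variants), len(samples))``.  All variants lie on the index
    variant's chromosome; ordering is strict on ``(pos, ref, alt)`` — split
    multi-allelic records may share a position.  Every sample must be a
    carrier at the index variant (HET or HOM_ALT) and its declared carrier
    class must match its observed zygosity there.
    """

    samples: list[SampleRole]
    variants: list[GenomicVariant]
    genotypes: np.ndarray
    index_variant: GenomicVariant

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.variants = list(self.variants)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_var, n_smp = len(self.variants), len(self.samples)
        if self.genotypes.shape != (n_var, n_smp):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n_var} variants x {n_smp} samples"
            )
        valid = {int(z) for z in Zygosity}
        if not set(np.unique(self.genotypes)).issubset(valid):
            raise ValueError("genotype matrix contains codes outside Zygosity")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        chrom = self.index_variant.chrom
        keys = []
        for v in self.variants:
            if v.chrom != chrom:
                raise ValueError(
                    f"variant {v} is not on the index chromosome {chrom!r}"
                )
            keys.append((v.pos, v.ref, v.alt))
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("variants must be strictly increasing by (pos, ref, alt)")
        try:
            self._index_idx = next(
                i for i, v in enumerate(self.variants)
                if v.key == self.index_variant.key
            )
        except StopIteration:
            raise ValueError(f"index variant {self.index_variant} absent from table")
        idx_row = self.genotypes[self._index_idx]
        for role, g in zip(self.samples, idx_row):
            z = Zygosity(int(g))
            if z in (Zygosity.MISSING, Zygosity.HOM_REF):
                raise ValueError(
                    f"sample {role.sample_id} is {z.name} at the index variant "
                    "and is not a carrier"
                )
            expected = (
                CarrierClass.HOMOZYGOUS_CARRIER
                if z is Zygosity.HOM_ALT
                else CarrierClass.HETEROZYGOUS_CARRIER
            )
            if role.carrier_class is not expected:
                raise ValueError(
                    f"sample {role.sample_id}: declared {role.carrier_class.value} "
                    f"but observed {z.name} at the index variant"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.index_variant.chrom

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def index_idx(self) -> int:
        return self._index_idx

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}")

    def zygosity(self, variant: GenomicVariant, sample_id: str) -> Zygosity:
        for i, v in enumerate(self.variants):
            if v.key == variant.key:
                return Zygosity(int(self.genotypes[i, self.sample_index(sample_id)]))
        raise KeyError(f"variant {variant} absent from table")

    def subset_samples(self, sample_ids: Iterable[str]) -> "CohortGenotypeTable":
        """Restrict to the given samples (order as given)."""
        cols = [self.sample_index(s) for s in sample_ids]
        return CohortGenotypeTable(
            samples=[self.samples[c] for c in cols],
            variants=list(self.variants),
            genotypes=self.genotypes[:, cols].copy(),
            index_variant=self.index_variant,
        )

    def to_frame(self):
        """Zygosity names as a pandas DataFrame (variants x samples)."""
        import pandas as pd

        return pd.DataFrame(
            [[Zygosity(int(g)).name for g in row] for row in self.genotypes],
            index=[str(v) for v in self.variants],
            columns=self.sample_ids,
        )

    def equals(self, other: "CohortGenotypeTable") -> bool:
        return (
            self.samples == other.samples
            and [v.key for v in self.variants] == [v.key for v in other.variants]
            and self.index_variant.key == other.index_variant.key
            and np.array_equal(self.genotypes, other.genotypes)
        )


def derive_roles(
    table: CohortGenotypeTable,
    coverage: Optional[Mapping[str, CoverageClass]] = None,
) -> list[SampleRole]:
    """Assign carrier classes from observed zygosity at the index variant.

    HOM_ALT at the index → HOMOZYGOUS_CARRIER; HET → HETEROZYGOUS_CARRIER.
    Coverage classes pass through from the table (or from ``coverage`` when
    given).  A sample that is HOM_REF or MISSING at the index is not a
    carrier and raises ``ValueError`` naming it.
    """
    idx_row = table.genotypes[table.index_idx]
    roles = []
    for role, g in zip(table.samples, idx_row):
        z = Zygosity(int(g))
        if z is Zygosity.HOM_ALT:
            cc = CarrierClass.HOMOZYGOUS_CARRIER
        elif z is Zygosity.HET:
            cc = CarrierClass.HETEROZYGOUS_CARRIER
        else:
            raise ValueError(
                f"sample {role.sample_id} is {z.name} at the index variant "
                "and is not a carrier"
            )
        cov = coverage[role.sample_id] if coverage else role.coverage_class
        roles.append(SampleRole(role.sample_id, cc, CoverageClass(cov)))
    return roles
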