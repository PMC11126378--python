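"""Catalog and cohort statistics: score summaries, allele frequencies from
counts, and protein-domain localization.

Pathogenicity scores (InMeRF, CADD-normalized, DANN) are consumed as input
columns on the probability scale: 1.000 most pathogenic, 0.000 least.  Allele
frequencies are computed from allele counts (``ac/an``) and reported to a
fixed number of significant figures, matching the scientific-notation style
minor-allele frequencies are usually printed in.  Protein domains are closed
codon intervals on the protein coordinate of a stated isoform.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AlleleCount",
    "DomainMap",
    "allele_frequency",
    "score_summary",
    "locate_in_domain",
    "count_missense_in_domain",
    "catalog_counts",
]


@dataclass(frozen=True)
class AlleleCount:
    """Alternate-allele count over total allele number."""

    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ValueError(f"an must be > 0, got {self.an}")
        if not (0 <= self.ac <= self.an):
            raise ValueError(f"require 0 <= ac <= an, got ac={self.ac}, an={self.an}")

    @property
    def exact(self) -> Fraction:
        """The exact rational frequency ac/an."""
        return Fraction(self.ac, self.an)


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures (not decimal places)."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0:
        return 0.0
    return float(f"{x:.{sig_figs - 1}e}")


def allele_frequency(count: AlleleCount, sig_figs: int = 2) -> float:
    """Allele frequency ``ac/an`` rounded to significant figures.

    Scale-free: ``(k*ac, k*an)`` yields the same frequency.  The exact
    rational is available as ``count.exact``.
    """
    return round_sig(count.ac / count.an, sig_figs)


def score_summary(scores: Sequence[float], decimals: int = 3) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of scores.

    The n-1 (sample) denominator is used deliberately: summaries of small
    catalogs of variant scores are estimates over a notional population of
    pathogenic variants, and the population-SD (n) alternative is rejected.
    Both values are rounded to ``decimals`` decimals.  Requires n >= 2.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 scores, got {arr.size}")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return (
        float(np.round(arr.mean(), decimals)),
        float(np.round(arr.std(ddof=1), decimals)),
    )


class DomainMap:
    """Closed, non-overlapping codon intervals labelling protein domains."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        entries = []
        for label, start, end in intervals:
            start, end = int(start), int(end)
            if start < 1 or start > end:
                raise ValueError(
                    f"domain {label!r}: require 1 <= codon_start <= codon_end, "
                    f"got [{start}, {end}]"
                )
            entries.append((str(label), start, end))
        entries.sort(key=lambda e: e[1])
        for (la, sa, ea), (lb, sb, eb) in zip(entries, entries[1:]):
            if sb <= ea:
                raise ValueError(
                    f"domains {la!r} [{sa},{ea}] and {lb!r} [{sb},{eb}] overlap"
                )
        self._entries = entries

    @classmethod
    def from_tsv(cls, path) -> "DomainMap":
        """Read ``label<TAB>codon_start<TAB>codon_end`` lines (``#`` comments)."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                label, start, end = line.split("\t")
                entries.append((label, int(start), int(end)))
        return cls(entries)

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self._entries]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def locate(self, codon: int) -> Optional[str]:
        """Label of the unique closed interval containing ``codon``, else None."""
        if codon < 1:
            raise ValueError(f"codon must be >= 1, got {codon}")
        for label, start, end in self._entries:
            if start <= codon <= end:
                return label
        return None


def locate_in_domain(codon: int, domain_map: DomainMap) -> Optional[str]:
    """Functional alias for :meth:`DomainMap.locate`."""
    return domain_map.locate(codon)


def count_missense_in_domain(
    catalog: Sequence, disease, domain_map: DomainMap, domain_label: str
) -> int:
    """Missense records of ``disease`` whose codon falls inside the domain.

    Variants annotated at domain interfaces fall outside every pure domain's
    codon range and are therefore not counted in either flanking domain.
    """
    from .io import Consequence, Disease

    if domain_label not in domain_map.labels:
        raise ValueError(f"unknown domain label {domain_label!r}")
    disease = Disease(disease)
    n = 0
    for rec in catalog:
        if (
            rec.disease is disease
            and rec.consequence is Consequence.MISSENSE
            and rec.codon is not None
            and domain_map.locate(rec.codon) == domain_label
        ):
            n += 1
    return n


def catalog_counts(catalog: Sequence) -> dict:
    """Distinct-variant count per disease label.

    Records are deduplicated on (disease, coordinate, coding HGVS) so that
    per-patient tables listing the same variant in several carriers count it
    once.
    """
    seen = {}
    for rec in catalog:
        key = (rec.disease, rec.coordinate_grch38, rec.hgvs_c)
        seen.setdefault(rec.disease.value, set()).add(key)
    return {disease: len(keys) for disease, keys in seen.items()}
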