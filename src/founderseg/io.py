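"""Readers and writers for the formats the pipeline touches.

Multi-sample VCF (v4.2, GT field) in and out via pysam; tab-separated variant
catalogs transcribed from the published tables; per-sample role/coverage
sidecars; gene panels; per-sample callable-region BEDs; and the segment
report (machine TSV plus a human-readable text summary).

Genotype semantics on read: ``./.`` maps to MISSING by default, which keeps
read→write→read a fixed point on the genotype matrix and never coerces
MISSING to HOM_REF.  An optional coverage-aware mode reflects the asymmetry
between genome and exome samples: an uncalled genotype in a genome-sequenced
sample is confident HOM_REF, while in an exome sample it is HOM_REF only
inside that sample's callable capture intervals and MISSING elsewhere.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .haplotype import Breaker, BreakerEvidence, BreakerReason, SharedSegment
from .variants import (
    CarrierClass,
    CohortGenotypeTable,
    CoverageClass,
    GenomicVariant,
    SampleRole,
    Zygosity,
    canonical_chrom,
    derive_roles,
    normalize_variant,
)

__all__ = [
    "Disease",
    "Consequence",
    "CatalogRecord",
    "read_catalog",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_roles",
    "read_gene_panel",
    "filter_by_panel",
    "write_segment_report",
    "read_segment_report",
]


class Disease(str, enum.Enum):
    SJS = "SJS"    # Schwartz-Jampel syndrome
    DDSH = "DDSH"  # dyssegmental dysplasia, Silverman-Handmaker type
    DDRD = "DDRD"  # dyssegmental dysplasia, Rolland-Desbuquois type


class Consequence(str, enum.Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICING = "SPLICING"
    INFRAME = "INFRAME"
    OTHER = "OTHER"


@dataclass(frozen=True)
class CatalogRecord:
    """One row of the variant catalog (published-table transcription).

    Scores, when present, lie on [0, 1] (1.000 most pathogenic).  Missense
    records must carry a codon.  ``patient`` and ``zygosity_label`` are
    filled for per-patient cohort tables and empty for literature catalogs.
    """

    disease: Disease
    coordinate_grch38: str
    hgvs_c: str
    consequence: Consequence
    hgvs_p: str = ""
    codon: Optional[int] = None
    domain_label: str = ""
    inmerf: Optional[float] = None
    cadd: Optional[float] = None
    dann: Optional[float] = None
    dbsnp: str = ""
    patient: str = ""
    zygosity_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease", Disease(self.disease))
        object.__setattr__(self, "consequence", Consequence(self.consequence))
        for name in ("inmerf", "cadd", "dann"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"{self.hgvs_c}: {name} score {v} outside [0, 1]"
                )
        if self.consequence is Consequence.MISSENSE and self.codon is None:
            raise ValueError(f"{self.hgvs_c}: missense record requires a codon")
        if self.codon is not None and self.codon < 1:
            raise ValueError(f"{self.hgvs_c}: codon must be >= 1")


_CATALOG_REQUIRED = ["disease", "coordinate_grch38", "hgvs_c", "consequence"]
_CATALOG_OPTIONAL = [
    "hgvs_p", "codon", "domain_label", "inmerf", "cadd", "dann",
    "dbsnp", "patient", "zygosity_label",
]


def read_catalog(path) -> list[CatalogRecord]:
    """Read a variant-catalog TSV into validated records.

    The header must contain ``disease, coordinate_grch38, hgvs_c,
    consequence``; the remaining documented columns are optional.  Empty
    cells mean "not available".  Unknown disease labels and scores outside
    [0, 1] raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        kw = {}
        for col in _CATALOG_REQUIRED + _CATALOG_OPTIONAL:
            if col not in df.columns:
                continue
            val = getattr(row, col).strip()
            if col == "codon":
                kw[col] = int(val) if val else None
            elif col in ("inmerf", "cadd", "dann"):
                kw[col] = float(val) if val else None
            else:
                kw[col] = val
        try:
            kw["disease"] = Disease(kw["disease"])
        except ValueError:
            raise ValueError(
                f"catalog {path}: unknown disease label {kw['disease']!r}"
            )
        records.append(CatalogRecord(**kw))
    return records


# ---------------------------------------------------------------------------
# roles / panels
# ---------------------------------------------------------------------------

def read_roles(path) -> dict[str, CoverageClass]:
    """Read the sample sidecar: ``sample_id<TAB>coverage_class`` per line."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "coverage_class" not in df.columns:
        raise ValueError(
            f"roles file {path}: need columns sample_id, coverage_class"
        )
    out = {}
    for row in df.itertuples(index=False):
        out[row.sample_id.strip()] = CoverageClass(row.coverage_class.strip())
    if not out:
        raise ValueError(f"roles file {path} is empty")
    return out


def read_gene_panel(path) -> set[str]:
    """Read a gene panel: one symbol per line, ``#`` comments allowed."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line)
    if not symbols:
        raise ValueError(f"gene panel {path} is empty")
    return symbols


def filter_by_panel(
    annotated: Iterable[tuple[str, GenomicVariant]], panel: Iterable[str]
) -> list[tuple[str, GenomicVariant]]:
    """Keep (gene, variant) pairs whose gene is in the panel; order preserved."""
    panel = set(panel)
    return [(gene, v) for gene, v in annotated if gene in panel]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_bed_intervals(path) -> list[tuple[int, int]]:
    """BED (0-based, half-open) intervals, merged and sorted."""
    ivals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            ivals.append((int(fields[1]), int(fields[2])))
    ivals.sort()
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _in_intervals(ivals: Sequence[tuple[int, int]], pos0: int) -> bool:
    i = bisect_right(ivals, (pos0, float("inf"))) - 1
    return i >= 0 and ivals[i][0] <= pos0 < ivals[i][1]


def _zygosity_of(gt, alt_index: int) -> Optional[Zygosity]:
    """Map a GT tuple to the zygosity of the alt at 1-based ``alt_index``.

    Returns None for fully or partially uncalled genotypes (resolved by the
    caller's uncalled policy).
    """
    if gt is None or any(a is None for a in gt):
        return None
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt >= 2:
        return Zygosity.HOM_ALT
    if n_alt == 1:
        return Zygosity.HET
    return Zygosity.HOM_REF


def read_cohort_vcf(
    path,
    index_variant: GenomicVariant,
    sample_meta: Union[Mapping[str, CoverageClass], str, Path],
    *,
    window_bp: int = 5_000_000,
    window: Optional[tuple[int, int]] = None,
    uncalled: str = "missing",
    callable_regions: Optional[Mapping[str, Union[str, Path, Sequence]]] = None,
) -> CohortGenotypeTable:
    """Read a multi-sample VCF into a cohort genotype table.

    Variants are restricted to the index chromosome within ``window`` (closed
    1-based interval; default ``window_bp`` on both sides of the index).
    Multi-allelic records are split and normalized; positions must be sorted.

    ``sample_meta`` declares each analyzed sample's coverage class (mapping
    or sidecar TSV path); samples declared but absent from the VCF header
    raise ``ValueError``.  ``uncalled`` resolves ``./.`` genotypes:
    ``"missing"`` (default) maps them to MISSING; ``"infer"`` maps them to
    HOM_REF for GENOME samples, and for EXOME samples to HOM_REF inside the
    sample's ``callable_regions`` (BED path or (start0, end0) pairs) and
    MISSING elsewhere.
    """
    if uncalled not in ("missing", "infer"):
        raise ValueError("uncalled must be 'missing' or 'infer'")
    coverage = (
        dict(sample_meta)
        if isinstance(sample_meta, Mapping)
        else read_roles(sample_meta)
    )
    regions = {}
    if callable_regions:
        for sid, spec in callable_regions.items():
            if isinstance(spec, (str, Path)):
                regions[sid] = _read_bed_intervals(spec)
            else:
                regions[sid] = sorted((int(s), int(e)) for s, e in spec)

    chrom = index_variant.chrom
    if window is None:
        window = (max(1, index_variant.pos - window_bp), index_variant.pos + window_bp)
    lo, hi = window

    vf = pysam.VariantFile(str(path))
    header_samples = list(vf.header.samples)
    sample_ids = list(coverage)
    absent = [s for s in sample_ids if s not in header_samples]
    if absent:
        raise ValueError(f"samples {absent} declared in sidecar but absent from VCF")

    def resolve_uncalled(sid: str, pos: int) -> Zygosity:
        if uncalled == "missing":
            return Zygosity.MISSING
        if coverage[sid] is CoverageClass.GENOME:
            return Zygosity.HOM_REF
        ivals = regions.get(sid)
        if ivals is not None and _in_intervals(ivals, pos - 1):
            return Zygosity.HOM_REF
        return Zygosity.MISSING

    entries = []  # (variant, genotype row)
    last_pos = None
    for rec in vf:
        if canonical_chrom(rec.chrom) != chrom:
            continue
        if last_pos is not None and rec.pos < last_pos:
            raise ValueError(f"VCF {path} is not position-sorted at {rec.pos}")
        last_pos = rec.pos
        if not (lo <= rec.pos <= hi):
            continue
        alts = rec.alts or ()
        split = normalize_variant(
            rec.chrom, rec.pos, rec.ref, list(alts), vid=rec.id
        )
        for k, var in enumerate(split):
            row = np.empty(len(sample_ids), dtype=np.int8)
            for j, sid in enumerate(sample_ids):
                z = _zygosity_of(rec.samples[sid].get("GT"), k + 1)
                row[j] = int(z) if z is not None else int(resolve_uncalled(sid, rec.pos))
            entries.append((var, row))
    vf.close()
    entries.sort(key=lambda e: (e[0].pos, e[0].ref, e[0].alt))
    if not entries:
        raise ValueError(f"no variants on chromosome {chrom} within {window}")

    variants = [v for v, _ in entries]
    genotypes = np.vstack([row for _, row in entries])
    keys = [v.key for v in variants]
    if index_variant.key not in keys:
        raise ValueError(f"index variant {index_variant} absent from VCF window")
    idx_row = genotypes[keys.index(index_variant.key)]
    roles = []
    for sid, g in zip(sample_ids, idx_row):
        z = Zygosity(int(g))
        if z is Zygosity.HOM_ALT:
            cc = CarrierClass.HOMOZYGOUS_CARRIER
        elif z is Zygosity.HET:
            cc = CarrierClass.HETEROZYGOUS_CARRIER
        else:
            raise ValueError(
                f"sample {sid} is {z.name} at the index variant and is not a carrier"
            )
        roles.append(SampleRole(sid, cc, coverage[sid]))
    return CohortGenotypeTable(roles, variants, genotypes, index_variant)


_GT_OF = {
    Zygosity.HOM_REF: (0, 0),
    Zygosity.HET: (0, 1),
    Zygosity.HOM_ALT: (1, 1),
    Zygosity.MISSING: (None, None),
}


def write_cohort_vcf(table: CohortGenotypeTable, path) -> None:
    """Write the genotype table as an uncompressed multi-sample VCF v4.2.

    MISSING is written as ``./.`` and survives a round trip with the default
    reader policy; output is byte-deterministic for a given table.
    """
    header = pysam.VariantHeader()
    contig_len = int(max(v.pos + len(v.ref) for v in table.variants)) + 10_000
    header.add_line(f"##contig=<ID={table.chrom},length={contig_len}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in table.sample_ids:
        header.add_sample(sid)
    out = pysam.VariantFile(str(path), "w", header=header)
    for i, v in enumerate(table.variants):
        rec = out.new_record(
            contig=table.chrom,
            start=v.pos - 1,
            alleles=(v.ref, v.alt),
            id=v.vid,
        )
        for j, sid in enumerate(table.sample_ids):
            rec.samples[sid]["GT"] = _GT_OF[Zygosity(int(table.genotypes[i, j]))]
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# segment report
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "chrom", "start", "end", "length_bp",
    "p_breaker_pos", "p_breaker_sample", "p_breaker_reason",
    "q_breaker_pos", "q_breaker_sample", "q_breaker_reason",
    "window_start", "window_end", "n_supporting", "supporting_sites",
]


def write_segment_report(
    segment: SharedSegment, path, text_path=None
) -> None:
    """Write the segment as a one-row TSV plus a human-readable text summary.

    Reading the TSV back with :func:`read_segment_report` reproduces
    endpoints, length and breaker positions bit-exactly.  Integers are
    written without thousands separators.  ``text_path`` defaults to the TSV
    path with a ``.txt`` suffix appended.
    """
    path = Path(path)

    def brk(b: Optional[Breaker]):
        if b is None:
            return (".", ".", ".")
        return (str(b.position), b.evidence.sample_id, b.evidence.reason.value)

    row = [
        segment.chrom, str(segment.start), str(segment.end), str(segment.length_bp),
        *brk(segment.p_breaker), *brk(segment.q_breaker),
        str(segment.window[0]), str(segment.window[1]),
        str(len(segment.supporting_sites)),
        ",".join(str(p) for p in segment.supporting_sites) or ".",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        fh.write("\t".join(row) + "\n")

    text_path = Path(text_path) if text_path else path.with_name(path.name + ".txt")
    lines = [
        "Shared founder segment",
        f"  chromosome      : {segment.chrom}",
        f"  segment         : {segment.start}-{segment.end} "
        f"({segment.length_bp} bp, closed interval)",
        f"  supporting sites: {len(segment.supporting_sites)}",
    ]
    for side, b in (("p-side", segment.p_breaker), ("q-side", segment.q_breaker)):
        if b is None:
            lines.append(f"  {side} breaker  : none (window edge reached)")
        else:
            lines.append(
                f"  {side} breaker  : {b.position} "
                f"({b.evidence.reason.value} in {b.evidence.sample_id})"
            )
    lines.append(
        f"  analysis window : {segment.window[0]}-{segment.window[1]}"
    )
    with open(text_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_segment_report(path) -> SharedSegment:
    """Read a segment-report TSV back into a :class:`SharedSegment`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _REPORT_COLUMNS or len(df) != 1:
        raise ValueError(f"{path} is not a segment report")
    r = df.iloc[0]

    def brk(prefix: str) -> Optional[Breaker]:
        if r[f"{prefix}_pos"] == ".":
            return None
        return Breaker(
            int(r[f"{prefix}_pos"]),
            BreakerEvidence(
                r[f"{prefix}_sample"], BreakerReason(r[f"{prefix}_reason"])
            ),
        )

    support = (
        tuple(int(p) for p in r["supporting_sites"].split(","))
        if r["supporting_sites"] != "."
        else ()
    )
    return SharedSegment(
        chrom=r["chrom"],
        start=int(r["start"]),
        end=int(r["end"]),
        length_bp=int(r["length_bp"]),
        p_breaker=brk("p_breaker"),
        q_breaker=brk("q_breaker"),
        supporting_sites=support,
        window=(int(r["window_start"]), int(r["window_end"])),
    )
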