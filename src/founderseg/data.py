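"""Accessors for the packaged fixtures.

* ``hspg2_catalog_sjs_ddsh.tsv`` — transcription of the published catalog of
  pathogenic HSPG2 variants in Schwartz–Jampel syndrome (44) and
  dyssegmental dysplasia Silverman–Handmaker type (8).
* ``hspg2_cohort_ddrd.tsv`` — the five-patient DDRD cohort table (four
  distinct pathogenic variants across five carriers).
* ``founder_cohort.vcf`` + ``founder_roles.tsv`` — the reference five-sample
  cohort around the index variant chr1:21,839,005 G>A, with the genotype
  patterns that delimit the reported 85,973-bp founder segment.
* ``perlecan_domains.tsv`` — perlecan domain codon ranges (domain IV,
  codons 1695–3655 of NM_001291860.2; user-extensible).
* ``skeletal_panel_illustrative.txt`` — HSPG2 plus 61 illustrative
  skeletal-dysplasia genes (the full published panel is not public).
* ``donor_contexts_synthetic.fa`` + ``donor_scores_synthetic.tsv`` —
  synthetic splice-donor context sequences and a lookup scorer reproducing
  the published MaxEnt-style 5'ss scores for the two disrupted donors.
"""

from __future__ import annotations

from importlib import resources

__all__ = [
    "catalog_path",
    "cohort_catalog_path",
    "founder_cohort_vcf_path",
    "founder_roles_path",
    "domain_map_path",
    "panel_path",
    "donor_contexts_path",
    "donor_scores_path",
    "load_catalog",
    "load_cohort_catalog",
    "load_founder_cohort",
    "load_domain_map",
    "load_panel",
    "load_donor_contexts_fixture",
    "load_donor_scorer",
]

_ROOT = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def _path(name: str):
    p = _ROOT / name
    if not p.is_file():
        raise FileNotFoundError(f"packaged fixture {name} not found")
    return p


def catalog_path():
    return _path("hspg2_catalog_sjs_ddsh.tsv")


def cohort_catalog_path():
    return _path("hspg2_cohort_ddrd.tsv")


def founder_cohort_vcf_path():
    return _path("founder_cohort.vcf")


def founder_roles_path():
    return _path("founder_roles.tsv")


def domain_map_path():
    return _path("perlecan_domains.tsv")


def panel_path():
    return _path("skeletal_panel_illustrative.txt")


def donor_contexts_path():
    return _path("donor_contexts_synthetic.fa")


def donor_scores_path():
    return _path("donor_scores_synthetic.tsv")


INDEX_VARIANT_SPEC = "1:21839005:G:A"


def load_catalog():
    from .io import read_catalog

    return read_catalog(catalog_path())


def load_cohort_catalog():
    from .io import read_catalog

    return read_catalog(cohort_catalog_path())


def load_founder_cohort(**kwargs):
    """The reference cohort as a :class:`CohortGenotypeTable`."""
    from .io import read_cohort_vcf
    from .pipeline import parse_index_spec

    return read_cohort_vcf(
        founder_cohort_vcf_path(),
        parse_index_spec(INDEX_VARIANT_SPEC),
        founder_roles_path(),
        **kwargs,
    )


def load_domain_map():
    from .annotation import DomainMap

    return DomainMap.from_tsv(domain_map_path())


def load_panel():
    from .io import read_gene_panel

    return read_gene_panel(panel_path())


def load_donor_contexts_fixture():
    from .splice import load_donor_contexts

    return load_donor_contexts(donor_contexts_path())


def load_donor_scorer():
    from .splice import TableDonorScorer

    return TableDonorScorer.from_tsv(donor_scores_path())
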