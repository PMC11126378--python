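"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by the most naive route
available (rule-by-rule classification, exhaustive window enumeration,
brute-force representation search) so they stay independent of the library
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from founderseg import data as pkgdata
from founderseg.variants import (
    CarrierClass,
    CohortGenotypeTable,
    CoverageClass,
    GenomicVariant,
    SampleRole,
    Zygosity,
)

# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def founder_table():
    return pkgdata.load_founder_cohort()


@pytest.fixture(scope="session")
def catalog():
    return pkgdata.load_catalog()


@pytest.fixture(scope="session")
def cohort_catalog():
    return pkgdata.load_cohort_catalog()


@pytest.fixture(scope="session")
def domain_map():
    return pkgdata.load_domain_map()


@pytest.fixture(scope="session")
def donor_contexts():
    return {c.name: c for c in pkgdata.load_donor_contexts_fixture()}


@pytest.fixture(scope="session")
def donor_scorer():
    return pkgdata.load_donor_scorer()


# ---------------------------------------------------------------------------
# random cohorts
# ---------------------------------------------------------------------------


def make_random_table(rng: np.random.Generator, max_markers: int = 300):
    """A random cohort genotype table with a valid carrier index site."""
    n = int(rng.integers(20, max_markers + 1))
    positions = np.sort(
        rng.choice(np.arange(1, 1_000_001), size=n, replace=False)
    )
    n_hom = int(rng.integers(1, 3))
    n_het = int(rng.integers(0, 4))
    m = n_hom + n_het
    G = rng.choice(
        np.array([-1, 0, 1, 2], dtype=np.int8),
        size=(n, m),
        p=[0.2, 0.35, 0.2, 0.25],
    )
    idx = n // 2
    G[idx, :n_hom] = int(Zygosity.HOM_ALT)
    G[idx, n_hom:] = int(Zygosity.HET)
    variants = [GenomicVariant("1", int(p), "A", "G") for p in positions]
    roles = [
        SampleRole(
            f"S{i:02d}",
            CarrierClass.HOMOZYGOUS_CARRIER if i < n_hom
            else CarrierClass.HETEROZYGOUS_CARRIER,
            CoverageClass.GENOME if i == 0 else CoverageClass.EXOME,
        )
        for i in range(m)
    ]
    return CohortGenotypeTable(roles, variants, G, variants[idx])


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

CONS, BRK, UNINF = "CONSISTENT", "BREAKER", "UNINFORMATIVE"


def naive_site_status(row, roles) -> str:
    """Rule-by-rule site classification, written independently of the
    vectorized implementation."""
    hom = [Zygosity(int(g)) for g, r in zip(row, roles)
           if r.carrier_class is CarrierClass.HOMOZYGOUS_CARRIER]
    het = [Zygosity(int(g)) for g, r in zip(row, roles)
           if r.carrier_class is CarrierClass.HETEROZYGOUS_CARRIER]
    if any(g is Zygosity.HET for g in hom):
        return BRK
    if any(g is Zygosity.HOM_ALT for g in hom) and any(
        g is Zygosity.HOM_REF for g in hom
    ):
        return BRK
    defining = any(g is Zygosity.HOM_ALT for g in hom)
    if defining and any(g is Zygosity.HOM_REF for g in het):
        return BRK
    if defining:
        return CONS
    return UNINF


def oracle_segment(table: CohortGenotypeTable):
    """Exhaustive contiguous-window enumeration.

    Tests every contiguous site window for: contains the index site, every
    interior site CONSISTENT-or-UNINFORMATIVE, flanked by a BREAKER or the
    window edge on both sides.  Exactly one such window exists; its
    outermost CONSISTENT sites are the segment endpoints.  Returns
    (start, end, supporting positions, p-breaker pos, q-breaker pos).
    """
    roles = table.samples
    statuses = [naive_site_status(row, roles) for row in table.genotypes]
    positions = [v.pos for v in table.variants]
    k0 = table.index_idx
    assert statuses[k0] == CONS
    is_brk = np.array([s == BRK for s in statuses])
    brk_cum = np.concatenate([[0], np.cumsum(is_brk)])
    n = len(positions)
    found = []
    for i in range(n):
        for j in range(i, n):
            if not (i <= k0 <= j):
                continue
            if brk_cum[j + 1] - brk_cum[i] > 0:
                continue
            if i > 0 and statuses[i - 1] != BRK:
                continue
            if j < n - 1 and statuses[j + 1] != BRK:
                continue
            found.append((i, j))
    assert len(found) == 1, f"expected a unique flanked window, got {found}"
    i, j = found[0]
    cons = [positions[k] for k in range(i, j + 1) if statuses[k] == CONS]
    return (
        min(cons),
        max(cons),
        tuple(p for p in cons),
        positions[i - 1] if i > 0 else None,
        positions[j + 1] if j < n - 1 else None,
    )
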