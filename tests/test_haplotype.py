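"""Shared-segment detection: classification rules, scanning, narrowing."""

import numpy as np
import pytest

from conftest import make_random_table, naive_site_status, oracle_segment

from founderseg.haplotype import (
    BreakerReason,
    SiteCall,
    SiteStatus,
    classify_site,
    detect_segment,
    narrow_incrementally,
    segment_length,
)
from founderseg.simulate import SimulationConfig, simulate_cohort
from founderseg.variants import (
    CarrierClass,
    CohortGenotypeTable,
    CoverageClass,
    GenomicVariant,
    SampleRole,
    Zygosity,
)

HOM, HET = CarrierClass.HOMOZYGOUS_CARRIER, CarrierClass.HETEROZYGOUS_CARRIER
GEN, EXO = CoverageClass.GENOME, CoverageClass.EXOME

ROLES5 = [
    SampleRole("P02", HOM, GEN),
    SampleRole("P03", HOM, EXO),
    SampleRole("P04", HET, EXO),
    SampleRole("P06", HET, EXO),
    SampleRole("P07", HET, EXO),
]

M, R, H, A = (int(Zygosity.MISSING), int(Zygosity.HOM_REF),
              int(Zygosity.HET), int(Zygosity.HOM_ALT))


class TestClassifySite:
    @pytest.mark.parametrize(
        "genotypes,call,reason,sample",
        [
            # the shared-haplotype pattern of the reference cohort
            ([A, A, H, H, H], SiteCall.CONSISTENT, None, None),
            # p-side margin: heterozygous SNV in a homozygous carrier
            ([H, R, R, R, R], SiteCall.BREAKER,
             BreakerReason.HET_IN_HOMOZYGOUS_CARRIER, "P02"),
            # q-side margin: defining allele absent from one het carrier
            ([A, A, H, R, H], SiteCall.BREAKER,
             BreakerReason.ABSENT_IN_HETEROZYGOUS_CARRIER, "P06"),
            # homozygous carriers fixed for different alleles
            ([A, R, H, H, H], SiteCall.BREAKER,
             BreakerReason.HOMOZYGOUS_CONFLICT, "P03"),
            # one HOM_ALT homozygous carrier suffices when the other is na
            ([A, M, M, M, M], SiteCall.CONSISTENT, None, None),
            # hom carriers callably reference: cannot delimit sharing
            ([R, R, H, R, R], SiteCall.UNINFORMATIVE, None, None),
            # nothing callable in the deciding class
            ([M, M, H, H, A], SiteCall.UNINFORMATIVE, None, None),
            # het carrier may be HOM_ALT on a defining site
            ([A, A, A, H, H], SiteCall.CONSISTENT, None, None),
            # het-in-hom wins even when a het carrier is also HOM_REF
            ([H, A, R, H, H], SiteCall.BREAKER,
             BreakerReason.HET_IN_HOMOZYGOUS_CARRIER, "P02"),
        ],
    )
    def test_rule_table(self, genotypes, call, reason, sample):
        status = classify_site(genotypes, ROLES5)
        assert status.call is call
        if reason is None:
            assert status.evidence is None
        else:
            assert status.evidence.reason is reason
            assert status.evidence.sample_id == sample

    def test_mapping_input_and_empty_roles(self):
        status = classify_site(
            {"P02": Zygosity.HOM_ALT, "P03": Zygosity.HOM_ALT,
             "P04": Zygosity.HET, "P06": Zygosity.HET, "P07": Zygosity.HET},
            ROLES5,
        )
        assert status.call is SiteCall.CONSISTENT
        with pytest.raises(ValueError):
            classify_site([A], [])

    def test_evidence_invariant_enforced(self):
        from founderseg.haplotype import BreakerEvidence

        with pytest.raises(ValueError):
            SiteStatus(SiteCall.BREAKER, evidence=None)
        with pytest.raises(ValueError):
            SiteStatus(
                SiteCall.CONSISTENT,
                evidence=BreakerEvidence(
                    "P02", BreakerReason.HET_IN_HOMOZYGOUS_CARRIER
                ),
            )

    def test_matches_naive_rule_oracle_on_random_patterns(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            row = rng.choice([M, R, H, A], size=5)
            assert classify_site(list(row), ROLES5).call.value == \
                naive_site_status(row, ROLES5)


def build_table(sites, roles=ROLES5, index_pos=None):
    """sites: list of (pos, [genotypes]) on chromosome 1."""
    variants = [GenomicVariant("1", p, "G", "A") for p, _ in sites]
    G = np.array([g for _, g in sites], dtype=np.int8)
    positions = [p for p, _ in sites]
    idx = positions.index(index_pos if index_pos is not None
                          else positions[len(positions) // 2])
    return CohortGenotypeTable(list(roles), variants, G, variants[idx])


class TestDetectSegment:
    def test_reference_cohort_segment(self, founder_table):
        seg = detect_segment(founder_table)
        assert (seg.start, seg.end, seg.length_bp) == (21_775_527, 21_861_499, 85_973)
        assert seg.p_breaker.position == 21_773_254
        assert seg.p_breaker.evidence.sample_id == "DDRD_P02"
        assert seg.p_breaker.evidence.reason is \
            BreakerReason.HET_IN_HOMOZYGOUS_CARRIER
        assert seg.q_breaker.position == 21_862_954
        assert seg.q_breaker.evidence.sample_id == "DDRD_P06"
        assert seg.q_breaker.evidence.reason is \
            BreakerReason.ABSENT_IN_HETEROZYGOUS_CARRIER
        assert seg.supporting_sites == (
            21_775_527, 21_780_000, 21_800_000, 21_820_000,
            21_839_005, 21_850_000, 21_861_499,
        )

    def test_single_site_segment(self):
        table = build_table(
            [(90, [H, R, R, R, R]), (100, [A, A, H, H, H]), (110, [A, A, H, R, H])],
            index_pos=100,
        )
        seg = detect_segment(table)
        assert (seg.start, seg.end, seg.length_bp) == (100, 100, 1)
        assert seg.p_breaker.position == 90 and seg.q_breaker.position == 110

    def test_window_edges_leave_no_breakers(self):
        table = build_table([(100, [A, A, H, H, H])])
        seg = detect_segment(table)
        assert seg.p_breaker is None and seg.q_breaker is None

    def test_breaker_wins_at_duplicate_position(self):
        # a split multi-allelic: consistent record and breaker record at one pos
        v1 = GenomicVariant("1", 90, "G", "A")
        v2 = GenomicVariant("1", 90, "G", "C")
        v3 = GenomicVariant("1", 100, "G", "A")
        G = np.array([[A, A, H, H, H], [H, R, R, R, R], [A, A, H, H, H]],
                     dtype=np.int8)
        table = CohortGenotypeTable(ROLES5, [v1, v2, v3], G, v3)
        seg = detect_segment(table)
        assert seg.start == 100 and seg.p_breaker.position == 90

    def test_index_must_classify_consistent(self):
        # index HOM_REF in a declared het carrier is rejected at table
        # construction; an uninformative index arises with all-het cohorts
        roles = [SampleRole("S0", HET, GEN), SampleRole("S1", HET, EXO)]
        v = GenomicVariant("1", 100, "G", "A")
        table = CohortGenotypeTable(
            roles, [v], np.array([[H, H]], dtype=np.int8), v
        )
        with pytest.raises(ValueError, match="UNINFORMATIVE"):
            detect_segment(table)

    def test_max_uninformative_gap_stops_extension(self):
        table = build_table(
            [(100, [A, A, H, H, H]), (150, [R, R, R, R, R]),
             (5000, [A, A, H, H, H])],
            index_pos=100,
        )
        assert detect_segment(table).end == 5000
        seg = detect_segment(table, max_uninformative_gap_bp=1000)
        assert seg.end == 100 and seg.q_breaker is None

    def test_roh_reduction_single_homozygous_carrier(self):
        # with one homozygous carrier the rules reduce to a run-of-
        # homozygosity scan: extend through HOM_REF/MISSING, stop at HET
        rng = np.random.default_rng(42)
        roles = [SampleRole("S0", HOM, GEN)]
        for _ in range(50):
            n = int(rng.integers(11, 80))
            pos = np.sort(rng.choice(np.arange(1, 10_000), n, replace=False))
            g = rng.choice([M, R, H, A], size=n)
            k0 = n // 2
            g[k0] = A
            variants = [GenomicVariant("1", int(p), "G", "A") for p in pos]
            table = CohortGenotypeTable(
                roles, variants, g[:, None].astype(np.int8), variants[k0]
            )
            # independent ROH computation
            lo = hi = k0
            k = k0 - 1
            while k >= 0 and g[k] != H:
                if g[k] == A:
                    lo = k
                k -= 1
            k = k0 + 1
            while k < n and g[k] != H:
                if g[k] == A:
                    hi = k
                k += 1
            seg = detect_segment(table)
            assert (seg.start, seg.end) == (int(pos[lo]), int(pos[hi]))

    def test_equals_exhaustive_window_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(30):
            table = make_random_table(rng, max_markers=150)
            start, end, support, p_pos, q_pos = oracle_segment(table)
            seg = detect_segment(table)
            assert (seg.start, seg.end) == (start, end)
            assert seg.supporting_sites == support
            assert (seg.p_breaker.position if seg.p_breaker else None) == p_pos
            assert (seg.q_breaker.position if seg.q_breaker else None) == q_pos

    def test_no_breaker_classifies_inside_reported_segment(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            table = make_random_table(rng, max_markers=120)
            seg = detect_segment(table)
            for i, v in enumerate(table.variants):
                if seg.start <= v.pos <= seg.end:
                    assert naive_site_status(table.genotypes[i], table.samples) \
                        != "BREAKER"


class TestNarrowing:
    def test_study_order_narrows_to_joint_segment(self, founder_table):
        res = narrow_incrementally(founder_table)
        joint = detect_segment(founder_table)
        assert res.final == joint
        # homozygous carriers first, then heterozygous carriers
        assert res.steps[0].sample_ids == ("DDRD_P02",)
        assert res.steps[1].sample_ids == ("DDRD_P02", "DDRD_P03")
        lengths = [s.segment.length_bp for s in res.steps]
        assert lengths == sorted(lengths, reverse=True)

    def test_every_permutation_reaches_joint_segment(self, founder_table):
        import itertools

        joint = detect_segment(founder_table)
        for order in itertools.permutations(founder_table.sample_ids):
            res = narrow_incrementally(founder_table, order=list(order))
            assert res.final == joint

    def test_monotone_narrowing_on_simulated_cohorts(self):
        # genome-sequenced homozygous carrier scanned first (study design):
        # each added sample can only shrink the segment
        for rep in range(25):
            cfg = SimulationConfig(
                seed=3000 + rep, window_bp=1_000_001, generations_to_founder=60,
            )
            table, _ = simulate_cohort(cfg)
            res = narrow_incrementally(table)
            prev = None
            for step in res.steps:
                assert step.segment is not None
                if prev is not None:
                    assert prev.start <= step.segment.start
                    assert step.segment.end <= prev.end
                prev = step.segment

    def test_order_must_be_permutation(self, founder_table):
        with pytest.raises(ValueError):
            narrow_incrementally(founder_table, order=["DDRD_P02"])


class TestSegmentLength:
    def test_reported_segment_arithmetic(self):
        assert segment_length(21_775_527, 21_861_499) == 85_973

    def test_degenerate_and_error(self):
        assert segment_length(7, 7) == 1
        with pytest.raises(ValueError):
            segment_length(8, 7)

    def test_matches_position_enumeration_on_small_intervals(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = int(rng.integers(1, 500))
            b = a + int(rng.integers(0, 500))
            assert segment_length(a, b) == len(range(a, b + 1))
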