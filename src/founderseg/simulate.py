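"""Synthetic founder-cohort simulator with ground truth.

Generates download-free cohorts with the statistical structure the detection
algorithm assumes: a founder allele descending to N carriers, each founder
chromosome retaining an ancestral segment around the index variant that is
truncated on both sides by recombination, background polymorphism on
non-founder chromosomes, optional genotype error, and exome-capture
missingness.  Homozygous carriers inherit two founder copies (autozygosity),
heterozygous carriers one.

Model sketch.  Markers sit on a regular grid at ``1/marker_density_per_bp``
spacing across a window centered on the index variant.  Each founder copy
retains the ancestral haplotype over ``[index - L, index + R]`` with
``L, R ~ Exponential(rate = generations x recomb_rate_per_bp_per_meiosis)``
independently per side (Haldane-style, no interference).  The ancestral
haplotype carries the alternate allele at a fixed fraction of markers,
independent of the background allele-frequency draw: markers are modelled as
ascertained sites where carriers differ from the reference, so tying the
ancestral allele to the population frequency would bias founder markers
toward common alleles.  Everything outside retained intervals — and every
non-founder chromosome — draws alleles per marker from a Beta-distributed
background allele frequency, so apparent sharing extends past the true
segment by chance exactly as identity-by-state does in real cohorts.

The true shared interval (intersection of every founder copy's retained
interval) is returned alongside the cohort for parameter-recovery studies.
All randomness flows from one master seed through independent named
counter-based streams, so changing the number of samples does not perturb
earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .haplotype import detect_segment
from .variants import (
    CarrierClass,
    CohortGenotypeTable,
    CoverageClass,
    GenomicVariant,
    SampleRole,
    Zygosity,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_cohort", "recovery_study"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic founder cohort.

    Defaults mirror the analysis conditions the detector targets: a window of
    5,000,000 bp on both sides of the index variant, two homozygous and three
    heterozygous carriers, the first homozygous carrier genome-sequenced and
    the rest exome samples.
    """

    window_bp: int = 10_000_001
    chrom: str = "1"
    index_pos: int = 21_839_005
    index_ref: str = "G"
    index_alt: str = "A"
    n_hom_carriers: int = 2
    n_het_carriers: int = 3
    generations_to_founder: Union[int, Sequence[int]] = 20
    recomb_rate_per_bp_per_meiosis: float = 1e-8
    marker_density_per_bp: float = 1e-3
    background_af_alpha: float = 0.2
    background_af_beta: float = 2.0
    ancestral_alt_fraction: float = 0.8
    exome_fraction: float = 1.0
    genotype_error_rate: float = 0.0
    n_genome_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hom_carriers + self.n_het_carriers < 1:
            raise ValueError("need at least one carrier")
        if self.n_hom_carriers < 0 or self.n_het_carriers < 0:
            raise ValueError("carrier counts must be >= 0")
        if self.window_bp < 3:
            raise ValueError("window_bp too small")
        if self.recomb_rate_per_bp_per_meiosis < 0:
            raise ValueError("recomb rate must be >= 0")
        if self.marker_density_per_bp <= 0:
            raise ValueError("marker density must be > 0")
        for name in ("ancestral_alt_fraction", "exome_fraction", "genotype_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        gens = self.generations_to_founder
        gens_list = [gens] * self.n_samples if np.isscalar(gens) else list(gens)
        if len(gens_list) != self.n_samples:
            raise ValueError(
                "generations_to_founder must be scalar or one per sample"
            )
        if any(g < 1 for g in gens_list):
            raise ValueError("generations_to_founder must be >= 1")
        object.__setattr__(self, "_gens", tuple(int(g) for g in gens_list))

    @property
    def n_samples(self) -> int:
        return self.n_hom_carriers + self.n_het_carriers

    @property
    def generations(self) -> tuple:
        return self._gens

    @property
    def window(self) -> tuple[int, int]:
        half = (self.window_bp - 1) // 2
        return (max(1, self.index_pos - half), self.index_pos + half)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated cohort.

    ``retained`` maps (sample_id, copy) to the closed interval over which
    that founder copy kept the ancestral haplotype; ``shared_interval`` is
    their intersection; ``ancestral_alt`` flags the markers where the
    ancestral haplotype carries the alternate allele.
    """

    marker_positions: np.ndarray
    ancestral_alt: np.ndarray
    retained: dict
    shared_interval: tuple

    def __post_init__(self) -> None:
        lo, hi = self.shared_interval
        if lo > hi:
            raise ValueError("true shared interval is empty")
        for key, (a, b) in self.retained.items():
            if a > b:
                raise ValueError(f"retained interval for {key} is empty")

    @property
    def informative_positions(self) -> np.ndarray:
        """Haplotype-informative (ancestral-alt) marker positions inside the
        true shared interval."""
        lo, hi = self.shared_interval
        pos = self.marker_positions
        return pos[self.ancestral_alt & (pos >= lo) & (pos <= hi)]

    def to_json(self, path) -> None:
        payload = {
            "shared_interval": [int(x) for x in self.shared_interval],
            "retained": {
                f"{sid}:{copy}": [int(a), int(b)]
                for (sid, copy), (a, b) in sorted(self.retained.items())
            },
            "ancestral_alt_positions": [
                int(p) for p in self.marker_positions[self.ancestral_alt]
            ],
            "n_markers": int(len(self.marker_positions)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=key))
    )


_BASE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "C")]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortGenotypeTable, SyntheticTruth]:
    """Simulate one cohort; fully reproducible from ``config.seed``.

    Sample ids are ``SIM_P01..`` with homozygous carriers first; the first
    ``n_genome_samples`` are GENOME coverage, the rest EXOME.  Index-site
    genotypes are exempt from genotype error and capture masking — they are
    the ascertainment condition defining the cohort.
    """
    lo, hi = config.window
    spacing = max(1, round(1.0 / config.marker_density_per_bp))
    positions = np.arange(lo + spacing // 2, hi + 1, spacing, dtype=np.int64)
    positions = positions[positions != config.index_pos]
    if positions.size == 0:
        raise ValueError("zero markers in window besides the index variant")
    positions = np.sort(np.append(positions, config.index_pos))
    n = positions.size
    idx = int(np.searchsorted(positions, config.index_pos))

    # marker-level draws (stream 1): background AF, ancestral alleles, bases
    rng_m = _rng(config.seed, 1)
    af = rng_m.beta(config.background_af_alpha, config.background_af_beta, size=n)
    anc_alt = rng_m.random(n) < config.ancestral_alt_fraction
    base_pick = rng_m.integers(0, len(_BASE_PAIRS), size=n)
    anc_alt[idx] = True  # the index allele is ancestral by construction

    sample_ids = [f"SIM_P{i + 1:02d}" for i in range(config.n_samples)]
    is_hom = [i < config.n_hom_carriers for i in range(config.n_samples)]
    copies = []  # (sample index, copy number)
    for i in range(config.n_samples):
        copies.extend((i, c) for c in range(2 if is_hom[i] else 1))

    # per-copy recombination truncation (stream 2, keyed by copy)
    retained = {}
    for k, (i, c) in enumerate(copies):
        rate = config.generations[i] * config.recomb_rate_per_bp_per_meiosis
        rng_c = _rng(config.seed, 2, k)
        if rate > 0:
            left, right = rng_c.exponential(1.0 / rate, size=2)
            a = max(lo, int(np.floor(config.index_pos - left)))
            b = min(hi, int(np.ceil(config.index_pos + right)))
        else:
            a, b = lo, hi  # no recombination: the whole window is retained
        retained[(sample_ids[i], c)] = (a, b)
    shared = (
        max(a for a, _ in retained.values()),
        min(b for _, b in retained.values()),
    )

    # per-sample chromosomes (stream 3, keyed by sample)
    G = np.zeros((n, config.n_samples), dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        rng_s = _rng(config.seed, 3, i)
        chroms = (rng_s.random((n, 2)) < af[:, None])  # background draws
        chroms[idx, :] = False  # ascertainment: background copies are ref here
        n_founder = 2 if is_hom[i] else 1
        for c in range(n_founder):
            a, b = retained[(sid, c)]
            inside = (positions >= a) & (positions <= b)
            chroms[inside, c] = anc_alt[inside]
        G[:, i] = chroms.sum(axis=1)

    # genotype error (stream 4): resample to a uniformly different state
    if config.genotype_error_rate > 0:
        rng_e = _rng(config.seed, 4)
        err = rng_e.random((n, config.n_samples)) < config.genotype_error_rate
        shift = rng_e.integers(1, 3, size=(n, config.n_samples), dtype=np.int8)
        err[idx, :] = False
        G = np.where(err, (G + shift) % 3, G).astype(np.int8)

    # exome-capture mask (stream 5): one capture design shared by EXOME samples
    captured = _rng(config.seed, 5).random(n) < config.exome_fraction
    captured[idx] = True
    for i in range(config.n_samples):
        if i >= config.n_genome_samples:
            G[~captured, i] = int(Zygosity.MISSING)

    variants = []
    for j, p in enumerate(positions):
        if j == idx:
            variants.append(
                GenomicVariant(config.chrom, int(p), config.index_ref,
                               config.index_alt, vid="index")
            )
        else:
            ref, alt = _BASE_PAIRS[base_pick[j]]
            variants.append(GenomicVariant(config.chrom, int(p), ref, alt))

    roles = [
        SampleRole(
            sample_ids[i],
            CarrierClass.HOMOZYGOUS_CARRIER if is_hom[i]
            else CarrierClass.HETEROZYGOUS_CARRIER,
            CoverageClass.GENOME if i < config.n_genome_samples
            else CoverageClass.EXOME,
        )
        for i in range(config.n_samples)
    ]
    table = CohortGenotypeTable(roles, variants, G, variants[idx])
    truth = SyntheticTruth(
        marker_positions=positions,
        ancestral_alt=anc_alt,
        retained=retained,
        shared_interval=shared,
    )
    return table, truth


def recovery_study(
    configs: Union[SimulationConfig, Iterable[SimulationConfig]],
    n_reps: int,
    *,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Simulate + detect + compare over a config grid.

    Per replicate the cohort is simulated with seed ``config.seed +
    seed_offset + rep``, the segment detected, and compared with the truth:

    * ``true_length`` / ``detected_length`` — closed-interval lengths in bp;
    * ``boundary_error_bp`` — mean absolute distance between detected and
      true boundaries over the two sides;
    * ``overshoot_p_bp`` / ``overshoot_q_bp`` — how far the detected segment
      extends past the truth per side (0 when inside); chance
      identity-by-state sharing makes small overshoots expected;
    * ``containment_violation`` — True when the detected segment fails to
      contain the haplotype-informative core of the true shared interval;
      at genotype error 0 with full coverage this never happens.
    """
    if isinstance(configs, SimulationConfig):
        configs = [configs]
    rows = []
    for cfg_id, cfg in enumerate(configs):
        for rep in range(n_reps):
            c = replace(cfg, seed=cfg.seed + seed_offset + rep)
            table, truth = simulate_cohort(c)
            seg = detect_segment(table)
            t_lo, t_hi = truth.shared_interval
            core = truth.informative_positions
            violation = bool(
                core.size and (seg.start > core.min() or seg.end < core.max())
            )
            rows.append(
                {
                    "config": cfg_id,
                    "rep": rep,
                    "seed": c.seed,
                    "true_length": t_hi - t_lo + 1,
                    "detected_length": seg.length_bp,
                    "boundary_error_bp": 0.5
                    * (abs(seg.start - t_lo) + abs(seg.end - t_hi)),
                    "overshoot_p_bp": max(0, t_lo - seg.start),
                    "overshoot_q_bp": max(0, seg.end - t_hi),
                    "containment_violation": violation,
                }
            )
    return pd.DataFrame(rows)
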