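"""End-to-end orchestration: simulate/load → detect → annotate → splice → report.

A :class:`PipelineConfig` captures one run in a single artifact (YAML or
constructor arguments); :func:`run_pipeline` executes the stages, writes a
deterministic report bundle (segment TSV + text, annotation summary TSV,
splice outcome TSV, truth/cohort files in simulate mode) and a run log with
versions, a config hash and per-stage counts.  Stage failures propagate as
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, data as pkgdata
from .annotation import DomainMap, count_missense_in_domain, score_summary
from .haplotype import detect_segment
from .io import (
    Consequence,
    Disease,
    read_catalog,
    read_cohort_vcf,
    read_roles,
    write_cohort_vcf,
    write_segment_report,
)
from .simulate import SimulationConfig, simulate_cohort
from .splice import (
    TableDonorScorer,
    classify_outcome,
    enumerate_candidate_donors,
    load_donor_contexts,
)
from .variants import GenomicVariant

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "parse_index_spec"]

log = logging.getLogger("founderseg")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def parse_index_spec(spec: str) -> GenomicVariant:
    """Parse ``chrom:pos:ref:alt`` (e.g. ``chr1:21839005:G:A``)."""
    parts = spec.split(":")
    if len(parts) != 4:
        raise ValueError(f"index spec {spec!r} is not chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return GenomicVariant(chrom, int(pos), ref, alt)


@dataclass
class PipelineConfig:
    """One reproducible pipeline run.

    Paths default to the packaged fixtures, so a bare config reproduces the
    reference analysis end to end.  ``simulate`` switches the cohort source
    from files to the synthetic generator (seeded).
    """

    out_dir: str = "founderseg_out"
    vcf: Optional[str] = None
    roles: Optional[str] = None
    index: str = "1:21839005:G:A"
    window_bp: int = 5_000_000
    catalog: Optional[str] = None
    cohort_catalog: Optional[str] = None
    domain_map: Optional[str] = None
    domain_label: str = "domain IV"
    splice_fasta: Optional[str] = None
    splice_scores: Optional[str] = None
    splice_window_bp: int = 35
    splice_margin: float = 3.0
    splice_floor: float = 0.0
    simulate: bool = False
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        defaults = {
            "vcf": pkgdata.founder_cohort_vcf_path(),
            "roles": pkgdata.founder_roles_path(),
            "catalog": pkgdata.catalog_path(),
            "cohort_catalog": pkgdata.cohort_catalog_path(),
            "domain_map": pkgdata.domain_map_path(),
            "splice_fasta": pkgdata.donor_contexts_path(),
            "splice_scores": pkgdata.donor_scores_path(),
        }
        for key, value in defaults.items():
            if d[key] is None:
                d[key] = str(value)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return a machine-readable summary (also written as
    ``summary.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.resolved()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {"version": __version__, "config_hash": config.config_hash()}
    t0 = time.perf_counter()
    try:
        log.info("founderseg %s, config hash %s", __version__, summary["config_hash"])

        # -- cohort -------------------------------------------------------
        stage = "cohort"
        try:
            index = parse_index_spec(cfg["index"])
            if config.simulate:
                sim_cfg = SimulationConfig(seed=config.seed, **config.sim_overrides)
                table, truth = simulate_cohort(sim_cfg)
                write_cohort_vcf(table, out / "cohort.vcf")
                truth.to_json(out / "truth.json")
                with open(out / "roles.tsv", "w") as fh:
                    fh.write("sample_id\tcoverage_class\n")
                    for s in table.samples:
                        fh.write(f"{s.sample_id}\t{s.coverage_class.value}\n")
                log.info("simulated cohort: %d samples, %d markers, seed %d",
                         len(table.samples), len(table.variants), config.seed)
            else:
                for key in ("vcf", "roles"):
                    if not Path(cfg[key]).exists():
                        raise FileNotFoundError(f"{key} file not found: {cfg[key]}")
                table = read_cohort_vcf(
                    cfg["vcf"], index, cfg["roles"], window_bp=config.window_bp
                )
                log.info("loaded cohort: %d samples, %d variants in window",
                         len(table.samples), len(table.variants))
        except Exception as e:
            raise PipelineError(stage, e)

        # -- detect -------------------------------------------------------
        stage = "detect"
        try:
            segment = detect_segment(table)
            write_segment_report(segment, out / "segment.tsv")
            summary["segment"] = {
                "chrom": segment.chrom,
                "start": segment.start,
                "end": segment.end,
                "length_bp": segment.length_bp,
                "n_supporting": len(segment.supporting_sites),
            }
            log.info("detected segment %d-%d (%d bp, %d supporting sites)",
                     segment.start, segment.end, segment.length_bp,
                     len(segment.supporting_sites))
        except Exception as e:
            raise PipelineError(stage, e)

        # -- annotate -----------------------------------------------------
        stage = "annotate"
        try:
            catalog = read_catalog(cfg["catalog"])
            cohort_catalog = read_catalog(cfg["cohort_catalog"])
            dmap = DomainMap.from_tsv(cfg["domain_map"])
            rows = []
            for disease in Disease:
                recs = [r for r in catalog + cohort_catalog if r.disease is disease]
                if not recs:
                    continue
                # per-patient tables list a variant once per carrier; dedupe
                recs = list(
                    {(r.coordinate_grch38, r.hgvs_c): r for r in recs}.values()
                )
                distinct = {(r.coordinate_grch38, r.hgvs_c) for r in recs}
                missense = [r for r in recs if r.consequence is Consequence.MISSENSE]
                distinct_missense = {(r.coordinate_grch38, r.hgvs_c): r.inmerf
                                     for r in missense}
                scores = [s for s in distinct_missense.values() if s is not None]
                mean_sd = score_summary(scores) if len(scores) >= 2 else (None, None)
                rows.append(
                    {
                        "disease": disease.value,
                        "n_variants": len(distinct),
                        "n_missense": len(distinct_missense),
                        "inmerf_mean": mean_sd[0],
                        "inmerf_sd": mean_sd[1],
                        f"n_missense_{config.domain_label.replace(' ', '_')}":
                            count_missense_in_domain(
                                recs, disease, dmap, config.domain_label
                            ),
                    }
                )
            ann = pd.DataFrame(rows)
            ann.to_csv(out / "annotation_summary.tsv", sep="\t", index=False,
                       float_format="%.3f")
            summary["annotation"] = rows
            log.info("annotation summary over %d diseases", len(rows))
        except Exception as e:
            raise PipelineError(stage, e)

        # -- splice -------------------------------------------------------
        stage = "splice"
        try:
            contexts = load_donor_contexts(cfg["splice_fasta"])
            scorer = TableDonorScorer.from_tsv(cfg["splice_scores"])
            rows = []
            for ctx in contexts:
                cands = enumerate_candidate_donors(ctx, config.splice_window_bp)
                call = classify_outcome(
                    ctx, cands, scorer,
                    margin=config.splice_margin, floor=config.splice_floor,
                )
                best = call.best_candidate
                rows.append(
                    {
                        "context": ctx.name,
                        "predicted_outcome": call.outcome.value,
                        "authentic_score": f"{call.authentic_score:.2f}",
                        "best_candidate_offset":
                            f"{best.offset:+d}" if best else ".",
                        "best_candidate_score":
                            f"{best.score:.2f}" if best else ".",
                        "exon_length_bp": ctx.exon_length_bp,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "splice_outcomes.tsv", sep="\t",
                                      index=False)
            summary["splice"] = rows
            log.info("splice outcomes for %d donor contexts", len(rows))
        except Exception as e:
            raise PipelineError(stage, e)

        summary["elapsed_s"] = round(time.perf_counter() - t0, 3)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.info("pipeline complete in %.3f s", summary["elapsed_s"])
        return summary
    except PipelineError as e:
        log.error("%s", e)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
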