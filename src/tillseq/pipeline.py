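"""End-to-end orchestration: simulate -> (demux -> map) -> call -> evaluate.

A :class:`RunConfig` fixes every knob of a run; all randomness flows
from its single top-level seed (stage seeds are spawned from it), so an
identical config yields byte-identical non-timestamp outputs.  Each run
writes a self-contained output directory: the pooling scheme, the
references, the planted truth, one count table per technical replicate,
the candidate list (TSV and VCF) and an evaluation report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__ as _version
from .caller import (
    CallerConfig,
    call_candidates,
    detect_outlier_pools,
    filter_homopolymer_indels,
    frequency_table,
    write_candidates,
)
from .demux import QualityFilters, align_to_amplicons, demultiplex, iter_fastq, pileup, trim_read
from .dilution import Zygosity
from .pooling import build_scheme, write_scheme
from .reference import barcode_table_for_scheme, read_reference, write_reference
from .simulate import (
    CoverageModel,
    ErrorModel,
    SAMPLED,
    evaluate_calls,
    plant_mutations,
    plant_singletons,
    simulate_counts,
    simulate_reads,
    synthetic_refs,
)
from .tables import read_counts, write_counts

logger = logging.getLogger("tillseq")

__all__ = ["RunConfig", "ConfigError", "PipelineError", "run_end_to_end"]


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 42
    # pooling scheme
    n_plates: int = 8
    n_rows: int = 8
    n_cols: int = 12
    # references: real files, or synthetic when left unset
    refs_fasta: Optional[str] = None
    primer_table: Optional[str] = None
    n_amplicons: int = 4
    amplicon_length: int = 200
    # simulation
    mode: str = "counts"  # "counts" or "reads"
    n_replicates: int = 2
    planting: str = "singletons"  # "singletons" or "density"
    density: float = 1.0 / 300_000
    zygosity: str = "HET"
    coverage: CoverageModel = field(default_factory=CoverageModel)
    error: ErrorModel = field(default_factory=ErrorModel)
    caller: CallerConfig = field(default_factory=CallerConfig)
    barcode_length: int = 10
    barcode_min_hamming: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("coverage", CoverageModel), ("error", ErrorModel), ("caller", CallerConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub_raw = raw[key]
                if key == "error" and "dispersion" in sub_raw:
                    sub_raw["dispersion"] = tuple(sub_raw["dispersion"])
                raw[key] = sub(**sub_raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigError("config is missing required field 'outdir'")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full simulated screen and return paths plus the evaluation.

    Stages: simulate (counts directly, or reads -> demux -> trim -> map
    -> pileup), frequency tables, homopolymer filtering, pool-outlier
    detection per replicate, replicate-union candidate calling with
    deconvolution, and evaluation against the planted truth.
    """
    if config.mode not in ("counts", "reads"):
        raise ConfigError(f"mode must be 'counts' or 'reads', got {config.mode!r}")
    if config.planting not in ("singletons", "density"):
        raise ConfigError(f"planting must be 'singletons' or 'density', got {config.planting!r}")
    for fieldname in ("refs_fasta", "primer_table"):
        p = getattr(config, fieldname)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"config field {fieldname!r} points to missing path {p}")
    if (config.refs_fasta is None) != (config.primer_table is None):
        raise ConfigError("refs_fasta and primer_table must be given together")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3 + config.n_replicates)
    seed_of = lambda i: int(children[i].generate_state(1)[0] % (2**31))

    scheme = build_scheme(config.n_plates, config.n_rows, config.n_cols)
    write_scheme(scheme, outdir / "scheme.tsv")
    logger.info("scheme: %d pools over %d individuals", len(scheme.pools()), scheme.population_size)

    if config.refs_fasta is not None:
        refs = _stage("load-references")(read_reference, config.refs_fasta, config.primer_table)
    else:
        refs = synthetic_refs(config.n_amplicons, config.amplicon_length, seed=seed_of(0))
    write_reference(refs, outdir / "refs.fasta", outdir / "primers.tsv")

    if config.planting == "singletons":
        truth = plant_singletons(
            scheme, refs, zygosity=Zygosity(config.zygosity), seed=seed_of(1)
        )
    else:
        truth = plant_mutations(scheme, refs, config.density, seed=seed_of(1))
    truth.write(outdir / "truth.tsv")
    logger.info("planted %d mutations across %d amplicons", len(truth.mutations), len(refs))

    pool_labels = [p.label for p in scheme.pools()]
    meta = {"tillseq_version": _version, "seed": config.seed, "mode": config.mode}
    flags_frames = []
    count_paths = []
    for rep in range(config.n_replicates):
        rep_seed = seed_of(3 + rep)
        if config.mode == "counts":
            counts = _stage("simulate-counts")(
                simulate_counts, scheme, truth, refs, config.coverage, config.error,
                SAMPLED, rep_seed,
            )
        else:
            counts = _run_read_replicate(config, scheme, truth, refs, rep, rep_seed, outdir)
        path = outdir / f"counts_rep{rep + 1}.tsv"
        write_counts(counts, path, {**meta, "replicate": rep + 1, "replicate_seed": rep_seed})
        count_paths.append(path)
        freq = frequency_table(counts, config.caller)
        freq = filter_homopolymer_indels(freq, refs, config.caller)
        flags = detect_outlier_pools(freq, pool_labels, config.caller)
        logger.info("replicate %d: %d variant rows, %d flagged pools", rep + 1, len(freq), len(flags))
        flags_frames.append(flags)

    candidates = _stage("call")(call_candidates, flags_frames, scheme, config.caller)
    write_candidates(candidates, outdir / "candidates.tsv", "tsv")
    write_candidates(candidates, outdir / "candidates.vcf", "vcf", refs=refs)
    report = evaluate_calls(truth, candidates)
    logger.info(
        "candidates: %d (tier99 %d) | recall %.2f, individual accuracy %.2f",
        len(candidates),
        sum(c.tier == 99 for c in candidates),
        report.recall,
        report.individual_accuracy,
    )
    evaluation = {
        "seed": config.seed,
        "version": _version,
        "n_candidates": len(candidates),
        "n_tier99": sum(c.tier == 99 for c in candidates),
        **report.to_dict(),
    }
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return {
        "outdir": str(outdir),
        "counts": [str(p) for p in count_paths],
        "candidates_tsv": str(outdir / "candidates.tsv"),
        "candidates_vcf": str(outdir / "candidates.vcf"),
        "evaluation": evaluation,
        "n_candidates": len(candidates),
    }


def _run_read_replicate(config, scheme, truth, refs, rep, rep_seed, outdir):
    barcodes = barcode_table_for_scheme(
        scheme, config.barcode_length, config.barcode_min_hamming, seed=config.seed
    )
    barcodes.write(outdir / "barcodes.tsv")
    fastq = outdir / f"reads_rep{rep + 1}.fastq"
    summary = _stage("simulate-reads")(
        simulate_reads, scheme, truth, refs, barcodes, config.coverage, config.error,
        rep_seed, fastq,
    )
    logger.info("replicate %d: %d reads (%d junk)", rep + 1, summary["n_reads"], summary["n_junk"])
    demux_result = _stage("demux")(demultiplex, iter_fastq(fastq), barcodes)
    rng = np.random.default_rng(rep_seed + 1)
    records = []
    n_trim_rejected = 0
    n_align_rejected = 0
    for pool_label, reads in demux_result.assigned.items():
        for read in reads:
            trimmed, reason = trim_read(read, refs, pool=pool_label)
            if trimmed is None:
                n_trim_rejected += 1
                continue
            rec = align_to_amplicons(trimmed, refs, rng=rng)
            if rec is None:
                n_align_rejected += 1
                continue
            records.append(rec)
    logger.info(
        "replicate %d: %d unassigned, %d trim-rejected, %d align-rejected, %d mapped",
        rep + 1, len(demux_result.unassigned), n_trim_rejected, n_align_rejected, len(records),
    )
    pool_labels = [p.label for p in scheme.pools()]
    return _stage("pileup")(pileup, records, refs, QualityFilters(), pool_labels)
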