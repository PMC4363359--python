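"""Rare-variant calling over pooled allele-count tables.

The caller turns count tables into per-pool substitution frequencies,
drops homopolymer indel artifacts, finds pools whose frequency is an
outlier for a given substitution at a given position (z-score across all
pools, within a lower/upper SD band), and deconvolves each group of
flagged pools to candidate source individuals with an ordinal confidence
tier:

* **99** — pools from all three dimensions intersect in one individual,
* **85** — a two-dimension intersection (or an ambiguous triple): a
  small subset to re-test individually,
* **75** — a single flagged pool (retained when ``min_pools`` is 1).

Frequencies are always compared across pools *within* one substitution
type; different substitution types have different background error rates
and are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pooling import DeconvolutionResult, PoolId, PoolingScheme, Resolution, deconvolve
from .reference import AmpliconRef, homopolymer_mask
from .tables import BASES

__all__ = [
    "CallerConfig",
    "PoolObservation",
    "VariantCandidate",
    "InsufficientDataError",
    "frequency_table",
    "filter_homopolymer_indels",
    "detect_outlier_pools",
    "call_candidates",
    "write_candidates",
    "read_candidates",
]

FLAG_COLUMNS = ["amplicon", "position", "ref", "alt", "pool", "frequency", "coverage", "zscore"]


class InsufficientDataError(ValueError):
    """Too few pools to compute across-pool statistics."""


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for variant calling and pool-outlier detection.

    The call-level gates (coverage 100, frequency 0.1%) decide which
    substitutions enter the frequency table at all; the candidate-level
    gates (coverage 500, frequency 0.5%) decide which pools may be
    flagged as carrying a putative mutation.  A pool is flagged when its
    z-score across all pools lies within [lower_sd_cutoff,
    upper_sd_cutoff]; values above the upper cutoff are treated as
    systematic artifacts (e.g. mismapping), not mutations.
    """

    min_coverage_call: int = 100
    min_frequency_call: float = 0.001
    min_coverage_candidate: int = 500
    min_frequency_candidate: float = 0.005
    max_alleles: int = 4
    lower_sd_cutoff: float = 2.0
    upper_sd_cutoff: float = 10.0
    min_pools: int = 1
    homopolymer_min_run: int = 3
    loo: bool = False  # leave the tested pool out of mu/sigma

    def __post_init__(self) -> None:
        if self.min_coverage_candidate < self.min_coverage_call:
            raise ValueError("candidate coverage threshold below call threshold")
        if self.min_frequency_candidate < self.min_frequency_call:
            raise ValueError("candidate frequency threshold below call threshold")
        if self.lower_sd_cutoff >= self.upper_sd_cutoff:
            raise ValueError("lower_sd_cutoff must be < upper_sd_cutoff")
        if self.max_alleles < 2:
            raise ValueError("max_alleles must be >= 2")


def frequency_table(counts: pd.DataFrame, cfg: Optional[CallerConfig] = None) -> pd.DataFrame:
    """Per-pool variant frequencies from an allele-count table.

    Emits, for every position with base coverage >= ``min_coverage_call``,
    each non-reference substitution (and insertion/deletion observation)
    with frequency >= ``min_frequency_call``, keeping at most
    ``max_alleles`` alleles per position (the reference plus the
    highest-frequency alternates).  The denominator is the total base
    coverage at the position; indel observations are excluded from it.
    """
    cfg = cfg or CallerConfig()
    base = counts[["pool", "amplicon", "position", "ref"]].copy()
    base["coverage"] = counts[BASES].sum(axis=1)
    parts = []
    for alt in BASES + ["ins", "del"]:
        sub = base.copy()
        sub["alt"] = alt
        sub["count"] = counts[alt].to_numpy()
        if alt in BASES:
            sub = sub[sub["ref"] != alt]
        parts.append(sub)
    df = pd.concat(parts, ignore_index=True)
    df = df[df["coverage"] >= cfg.min_coverage_call]
    df = df[df["count"] > 0]
    df["frequency"] = df["count"] / df["coverage"]
    df = df[df["frequency"] >= cfg.min_frequency_call]
    df = (
        df.sort_values("frequency", ascending=False)
        .groupby(["pool", "amplicon", "position"], sort=False)
        .head(cfg.max_alleles - 1)
    )
    return df.sort_values(["amplicon", "position", "pool", "alt"]).reset_index(drop=True)[
        ["pool", "amplicon", "position", "ref", "alt", "count", "coverage", "frequency"]
    ]


def filter_homopolymer_indels(
    freq: pd.DataFrame, refs: Sequence[AmpliconRef], cfg: Optional[CallerConfig] = None
) -> pd.DataFrame:
    """Drop indel variants inside or adjacent to homopolymer runs.

    Spurious insertions/deletions in homopolymer tracts are the dominant
    artifact of the sequencing chemistry; substitutions are never removed
    by this filter.
    """
    cfg = cfg or CallerConfig()
    masks = {
        r.id: homopolymer_mask(r.sequence, cfg.homopolymer_min_run, pad=1) for r in refs
    }
    def in_run(row) -> bool:
        mask = masks.get(row["amplicon"])
        if mask is None:
            return False
        return bool(mask[int(row["position"]) - 1])
    is_indel = freq["alt"].isin(["ins", "del"])
    if not is_indel.any():
        return freq.reset_index(drop=True)
    drop = is_indel & freq.apply(in_run, axis=1)
    return freq[~drop].reset_index(drop=True)


def detect_outlier_pools(
    freq: pd.DataFrame, pools: Sequence[str], cfg: Optional[CallerConfig] = None
) -> pd.DataFrame:
    """Flag pools whose frequency is an SD-band outlier for a substitution.

    For each (amplicon, position, substitution), the mean and population
    standard deviation of the frequency are computed across *all* pools
    of the scheme (pools with no table entry count as frequency 0).  A
    pool is flagged when its coverage and frequency clear the candidate
    gates and its z-score lies within the configured band.  When sigma is
    zero (all pools identical) any pool above the candidate frequency is
    flagged with z reported as +inf.  With ``loo`` the tested pool is
    left out of mu/sigma.
    """
    cfg = cfg or CallerConfig()
    pools = list(pools)
    n = len(pools)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pools for outlier detection, got {n}")
    if freq.empty:
        return pd.DataFrame(columns=FLAG_COLUMNS)
    key = ["amplicon", "position", "ref", "alt"]
    fpiv = (
        freq.pivot_table(index=key, columns="pool", values="frequency", fill_value=0.0)
        .reindex(columns=pools, fill_value=0.0)
    )
    cpiv = (
        freq.pivot_table(index=key, columns="pool", values="coverage", fill_value=0)
        .reindex(columns=pools, fill_value=0)
    )
    x = fpiv.to_numpy(dtype=float)
    cov = cpiv.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sigma = x.std(axis=1, ddof=0, keepdims=True)
    eps = 1e-12  # frequencies are <= 1; below this sigma is numerically zero
    if cfg.loo:
        mu_i = (n * mu - x) / (n - 1)
        ex2 = (x**2).mean(axis=1, keepdims=True)
        var_i = np.maximum((n * ex2 - x**2) / (n - 1) - mu_i**2, 0.0)
        sig_i = np.sqrt(var_i)
        degenerate = sig_i < eps
        z = np.where(degenerate, np.inf, (x - mu_i) / np.where(degenerate, 1.0, sig_i))
    else:
        degenerate = np.broadcast_to(sigma < eps, x.shape)
        z = np.where(degenerate, np.inf, (x - mu) / np.where(degenerate, 1.0, sigma))
    passes_gates = (cov >= cfg.min_coverage_candidate) & (x >= cfg.min_frequency_candidate)
    in_band = (z >= cfg.lower_sd_cutoff) & (z <= cfg.upper_sd_cutoff)
    flagged = passes_gates & (in_band | degenerate)
    rows = []
    idx = fpiv.index
    for i, j in zip(*np.nonzero(flagged)):
        amp, pos, ref, alt = idx[i]
        rows.append(
            (amp, int(pos), ref, alt, pools[j], x[i, j], int(cov[i, j]), float(z[i, j]))
        )
    return pd.DataFrame(rows, columns=FLAG_COLUMNS)


# -- candidates -------------------------------------------------------------

@dataclass(frozen=True)
class PoolObservation:
    frequency: float
    coverage: int
    zscore: float


@dataclass(frozen=True)
class VariantCandidate:
    amplicon_id: str
    position: int
    ref: str
    alt: str
    pools: dict  # pool label -> PoolObservation
    wells: frozenset
    resolution: Resolution
    tier: int
    ems_consistent: bool

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def max_frequency(self) -> float:
        return max(o.frequency for o in self.pools.values()) if self.pools else 0.0

    @property
    def ambiguous(self) -> bool:
        return len(self.wells) > 1


_TIER_BY_RESOLUTION = {
    Resolution.INDIVIDUAL: 99,
    Resolution.SUBSET: 85,
    Resolution.NONE: 75,
}


def call_candidates(
    flags: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    scheme: PoolingScheme,
    cfg: Optional[CallerConfig] = None,
) -> list:
    """Deconvolve flagged pools into confidence-tiered variant candidates.

    ``flags`` may be a single flag table or several (replicate runs);
    replicate flags are unioned per substitution before deconvolution, so
    complementary intersecting pools found in different runs still
    combine into a three-dimensional intersection.  Groups with fewer
    than ``min_pools`` flagged pools are dropped.  Output is sorted by
    tier, then maximum pool frequency, descending.
    """
    cfg = cfg or CallerConfig()
    if isinstance(flags, pd.DataFrame):
        frames = [flags]
    else:
        frames = list(flags)
    frames = [f for f in frames if not f.empty]
    candidates = []
    if not frames:
        return candidates
    merged = pd.concat(frames, ignore_index=True)
    # keep, per substitution and pool, the strongest replicate observation
    merged = (
        merged.sort_values("frequency", ascending=False)
        .drop_duplicates(["amplicon", "position", "ref", "alt", "pool"])
    )
    for (amp, pos, ref, alt), grp in merged.groupby(
        ["amplicon", "position", "ref", "alt"], sort=True
    ):
        pool_obs = {
            r.pool: PoolObservation(float(r.frequency), int(r.coverage), float(r.zscore))
            for r in grp.itertuples()
        }
        if len(pool_obs) < cfg.min_pools:
            continue
        result = deconvolve(scheme, [PoolId.parse(lbl) for lbl in pool_obs])
        tier = _TIER_BY_RESOLUTION[result.resolution]
        candidates.append(
            VariantCandidate(
                amplicon_id=amp,
                position=int(pos),
                ref=ref,
                alt=alt,
                pools=pool_obs,
                wells=result.candidates,
                resolution=result.resolution,
                tier=tier,
                ems_consistent=f"{ref}>{alt}" in ("G>A", "C>T"),
            )
        )
    candidates.sort(key=lambda c: (-c.tier, -c.max_frequency, c.amplicon_id, c.position))
    return candidates


# -- serialization ----------------------------------------------------------

CANDIDATE_COLUMNS = [
    "amplicon",
    "position",
    "ref",
    "alt",
    "tier",
    "resolution",
    "ems_consistent",
    "ambiguous",
    "n_pools",
    "pools",
    "frequencies",
    "coverages",
    "zscores",
    "wells",
]


def candidates_to_frame(candidates: Sequence[VariantCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        labels = sorted(c.pools)
        rows.append(
            (
                c.amplicon_id,
                c.position,
                c.ref,
                c.alt,
                c.tier,
                c.resolution.value,
                c.ems_consistent,
                c.ambiguous,
                len(c.pools),
                ",".join(labels),
                ",".join(repr(c.pools[l].frequency) for l in labels),
                ",".join(str(c.pools[l].coverage) for l in labels),
                ",".join(repr(c.pools[l].zscore) for l in labels),
                ",".join(w.label for w in sorted(c.wells)),
            )
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates(
    candidates: Sequence[VariantCandidate],
    path,
    format: str = "tsv",
    refs: Optional[Sequence[AmpliconRef]] = None,
) -> None:
    """Write candidates as TSV (Table-style columns) or VCF 4.2."""
    if format == "tsv":
        candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        _write_vcf(candidates, path, refs)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")


def _write_vcf(candidates, path, refs) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tillseq\n")
        for ref in refs or []:
            fh.write(f"##contig=<ID={ref.id},length={len(ref.sequence)}>\n")
        fh.write('##INFO=<ID=TIER,Number=1,Type=Integer,Description="Confidence tier (75/85/99)">\n')
        fh.write('##INFO=<ID=RES,Number=1,Type=String,Description="Deconvolution resolution">\n')
        fh.write('##INFO=<ID=POOLS,Number=.,Type=String,Description="Flagged pools">\n')
        fh.write('##INFO=<ID=FREQS,Number=.,Type=Float,Description="Pool variant frequencies">\n')
        fh.write('##INFO=<ID=WELLS,Number=.,Type=String,Description="Candidate source wells">\n')
        fh.write('##INFO=<ID=EMS,Number=0,Type=Flag,Description="EMS-consistent substitution">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in candidates:
            alt = c.alt if c.alt in BASES else f"<{c.alt.upper()}>"
            labels = sorted(c.pools)
            info = [
                f"TIER={c.tier}",
                f"RES={c.resolution.value}",
                "POOLS=" + ",".join(labels),
                "FREQS=" + ",".join(f"{c.pools[l].frequency:.6g}" for l in labels),
            ]
            if c.wells:
                info.append("WELLS=" + ",".join(w.label for w in sorted(c.wells)))
            if c.ems_consistent:
                info.append("EMS")
            fh.write(
                f"{c.amplicon_id}\t{c.position}\t.\t{c.ref}\t{alt}\t.\tPASS\t"
                + ";".join(info)
                + "\n"
            )


def read_candidates(path) -> list:
    """Read back a candidate TSV written by :func:`write_candidates`."""
    import re

    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    out = []
    well_re = re.compile(r"P(\d+)R(\d+)C(\d+)")
    from .pooling import WellAddress  # local import to avoid cycles at module load

    for r in df.itertuples():
        labels = str(r.pools).split(",") if r.pools else []
        freqs = [float(v) for v in str(r.frequencies).split(",")] if labels else []
        covs = [int(v) for v in str(r.coverages).split(",")] if labels else []
        zs = [float(v) for v in str(r.zscores).split(",")] if labels else []
        pool_obs = {
            l: PoolObservation(f, cv, z) for l, f, cv, z in zip(labels, freqs, covs, zs)
        }
        wells = frozenset(
            WellAddress(int(m.group(1)), int(m.group(2)), int(m.group(3)))
            for m in well_re.finditer(str(r.wells))
        )
        out.append(
            VariantCandidate(
                amplicon_id=str(r.amplicon),
                position=int(r.position),
                ref=str(r.ref),
                alt=str(r.alt),
                pools=pool_obs,
                wells=wells,
                resolution=Resolution(r.resolution),
                tier=int(r.tier),
                ems_consistent=bool(r.ems_consistent),
            )
        )
    return out
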