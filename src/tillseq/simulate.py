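"""Synthetic pooled-amplicon mutation screens.

This module plants EMS-style mutations in a pooled population and
generates the data every downstream stage consumes — either per-pool
allele-count tables directly (``simulate_counts``) or barcoded FASTQ
reads that must first be demultiplexed, trimmed, aligned and piled up
(``simulate_reads``).

The error structure emulates an Ion-Torrent-like amplicon run:

* a mean substitution error around 0.1% per base, with G>A and T>C
  transitions elevated relative to the other ten substitution types;
* run-to-run jitter of each substitution type's rate, drawn with a
  standard deviation of 26-56% of its mean;
* insertion/deletion artifacts concentrated in homopolymer runs;
* pool-to-pool coverage variability (lognormal), a mild 3' coverage
  drop-off, and (in read mode) a population of ~50 bp primer-dimer
  "junk" reads that carry no usable insert.

EMS chemistry biases planted mutations heavily toward G/C -> A/T
transitions; the default mutation density of 1 per 300 kb per individual
matches classic EMS screen estimates.  Among M2 carriers a third of
mutations are homozygous (1:2 HOM:HET segregation after selfing of the
mutagenized M1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dilution import Zygosity
from .pooling import PoolingScheme, WellAddress
from .reference import AmpliconRef, BarcodeTable, homopolymer_mask, revcomp
from .tables import BASES, COUNT_COLUMNS

__all__ = [
    "SUBSTITUTIONS",
    "ErrorModel",
    "CoverageModel",
    "PlantedMutation",
    "SimTruth",
    "EvaluationReport",
    "plant_mutations",
    "plant_singletons",
    "simulate_counts",
    "simulate_reads",
    "evaluate_calls",
    "synthetic_refs",
    "SAMPLED",
    "EXPECTED",
]

SAMPLED = "sampled"
EXPECTED = "expected"

SUBSTITUTIONS = [f"{a}>{b}" for a in BASES for b in BASES if a != b]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _default_multipliers() -> dict:
    # G>A and T>C transitions run hotter on this chemistry; the remaining
    # ten types are scaled so the 12-type mean equals mean_substitution_rate.
    mult = {s: 0.7 for s in SUBSTITUTIONS}
    mult["G>A"] = 2.5
    mult["T>C"] = 2.5
    return mult


@dataclass(frozen=True)
class ErrorModel:
    """Per-substitution sequencing error rates and their run-to-run jitter."""

    mean_substitution_rate: float = 0.001
    multipliers: dict = field(default_factory=_default_multipliers)
    dispersion: tuple = (0.26, 0.56)  # SD as a fraction of the mean, drawn per run
    homopolymer_indel_multiplier: float = 5.0  # x mean rate, inside runs >= min_run
    background_indel_rate: float = 2e-4
    homopolymer_min_run: int = 3
    max_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.mean_substitution_rate <= self.max_rate:
            raise ValueError("mean_substitution_rate outside [0, max_rate]")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("substitution multipliers must be positive")

    def mean_rates(self) -> dict:
        return {
            s: min(self.mean_substitution_rate * self.multipliers.get(s, 1.0), self.max_rate)
            for s in SUBSTITUTIONS
        }

    def draw_rates(self, rng: np.random.Generator) -> dict:
        """One run's realized rates: N(mean, d*mean) per type, d ~ U(dispersion)."""
        rates = {}
        for s, m in self.mean_rates().items():
            d = rng.uniform(*self.dispersion)
            rates[s] = float(np.clip(rng.normal(m, d * m), 0.0, self.max_rate))
        return rates


@dataclass(frozen=True)
class CoverageModel:
    """Per-pool read depth and its variability."""

    mean_coverage_per_pool: float = 3000.0
    pool_cv: float = 0.5
    end_dropoff_fraction: float = 0.1  # 3' tail with linearly decaying coverage
    junk_read_fraction: float = 0.2  # FASTQ mode only

    def __post_init__(self) -> None:
        if self.mean_coverage_per_pool < 0 or self.pool_cv < 0:
            raise ValueError("coverage parameters must be >= 0")
        if not 0 <= self.end_dropoff_fraction <= 1 or not 0 <= self.junk_read_fraction <= 1:
            raise ValueError("fractions must be within [0, 1]")

    def draw_pool_coverage(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Lognormal coverage draws with the configured mean and CV."""
        if self.pool_cv == 0:
            return np.full(n, self.mean_coverage_per_pool)
        sigma2 = np.log1p(self.pool_cv**2)
        mu = np.log(self.mean_coverage_per_pool) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)

    def position_profile(self, length: int) -> np.ndarray:
        """Relative coverage along the amplicon: flat, decaying to 0.5 at the 3' end."""
        profile = np.ones(length)
        k = int(round(self.end_dropoff_fraction * length))
        if k > 0:
            profile[length - k :] = np.linspace(1.0, 0.5, k + 1)[1:]
        return profile


@dataclass(frozen=True)
class PlantedMutation:
    well: WellAddress
    amplicon_id: str
    position: int  # 1-based on the amplicon target
    ref_base: str
    alt_base: str
    zygosity: Zygosity

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"

    @property
    def is_ems_type(self) -> bool:
        return self.substitution in ("G>A", "C>T")


@dataclass(frozen=True)
class SimTruth:
    """Planted mutations plus everything needed to reproduce the run."""

    mutations: tuple
    seed: int
    n_plates: int
    n_rows: int
    n_cols: int
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    m.well.plate,
                    m.well.row,
                    m.well.column,
                    m.amplicon_id,
                    m.position,
                    m.ref_base,
                    m.alt_base,
                    m.zygosity.value,
                )
                for m in self.mutations
            ],
            columns=["plate", "row", "column", "amplicon", "position", "ref", "alt", "zygosity"],
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            fh.write(f"# scheme={self.n_plates}x{self.n_rows}x{self.n_cols}\n")
            for k, v in self.params.items():
                fh.write(f"# {k}={v}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SimTruth":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
        df = pd.read_csv(path, sep="\t", comment="#")
        muts = tuple(
            PlantedMutation(
                WellAddress(int(r.plate), int(r.row), int(r.column)),
                str(r.amplicon),
                int(r.position),
                str(r.ref),
                str(r.alt),
                Zygosity(r.zygosity),
            )
            for r in df.itertuples()
        )
        dims = [int(x) for x in meta.get("scheme", "0x0x0").split("x")]
        return cls(muts, int(meta.get("seed", 0)), *dims)


def _validate_mutation(m: PlantedMutation, refs_by_id: dict, scheme: PoolingScheme) -> None:
    if m.amplicon_id not in refs_by_id:
        raise ValueError(f"mutation references unknown amplicon {m.amplicon_id!r}")
    seq = refs_by_id[m.amplicon_id].sequence
    if not 1 <= m.position <= len(seq):
        raise ValueError(f"position {m.position} outside amplicon {m.amplicon_id}")
    if seq[m.position - 1] != m.ref_base:
        raise ValueError(
            f"reference base mismatch at {m.amplicon_id}:{m.position}: "
            f"amplicon has {seq[m.position - 1]}, mutation says {m.ref_base}"
        )
    if m.alt_base == m.ref_base:
        raise ValueError("alt base must differ from reference base")
    scheme.pools_of(m.well)  # raises if the well is out of range / unoccupied


def plant_mutations(
    scheme: PoolingScheme,
    refs: Sequence[AmpliconRef],
    density: float = 1.0 / 300_000,
    *,
    mutations: Optional[Iterable[PlantedMutation]] = None,
    ems_fraction: float = 0.99,
    hom_fraction: float = 1.0 / 3.0,
    seed: int = 0,
) -> SimTruth:
    """Plant EMS-screen mutations across the population.

    In density mode the number of mutations per (individual x amplicon)
    is Poisson with mean ``density * amplicon_length``.  Each mutation is
    a G/C -> A/T transition at a G/C site with probability
    ``ems_fraction``, otherwise a random non-EMS substitution; it is
    homozygous with probability ``hom_fraction``.  Alternatively an
    explicit mutation list can be supplied (validated against the
    references).  Deterministic given the seed.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    refs_by_id = {r.id: r for r in refs}
    params = dict(
        density=density, ems_fraction=ems_fraction, hom_fraction=hom_fraction
    )
    if mutations is not None:
        muts = tuple(mutations)
        for m in muts:
            _validate_mutation(m, refs_by_id, scheme)
        return SimTruth(
            muts, seed, scheme.n_plates, scheme.n_rows, scheme.n_cols, {"mode": "explicit"}
        )
    for name, frac in (("ems_fraction", ems_fraction), ("hom_fraction", hom_fraction)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be within [0, 1]")
    rng = np.random.default_rng(seed)
    wells = scheme.wells()
    gc_sites = {r.id: [i for i, b in enumerate(r.sequence) if b in "GC"] for r in refs}
    muts = []
    for well in wells:
        for ref in refs:
            k = rng.poisson(density * len(ref.sequence))
            for _ in range(k):
                seq = ref.sequence
                if rng.random() < ems_fraction and gc_sites[ref.id]:
                    pos0 = int(rng.choice(gc_sites[ref.id]))
                    ref_b = seq[pos0]
                    alt_b = "A" if ref_b == "G" else "T"
                else:
                    pos0 = int(rng.integers(len(seq)))
                    ref_b = seq[pos0]
                    choices = [
                        b
                        for b in BASES
                        if b != ref_b and f"{ref_b}>{b}" not in ("G>A", "C>T")
                    ]
                    alt_b = str(rng.choice(choices))
                zyg = Zygosity.HOM if rng.random() < hom_fraction else Zygosity.HET
                muts.append(PlantedMutation(well, ref.id, pos0 + 1, ref_b, alt_b, zyg))
    return SimTruth(tuple(muts), seed, scheme.n_plates, scheme.n_rows, scheme.n_cols, params)


def plant_singletons(
    scheme: PoolingScheme,
    refs: Sequence[AmpliconRef],
    *,
    zygosity: Zygosity = Zygosity.HET,
    seed: int = 0,
) -> SimTruth:
    """One EMS-type mutation per amplicon, each in a random single individual."""
    rng = np.random.default_rng(seed)
    wells = scheme.wells()
    muts = []
    for ref in refs:
        gc_sites = [i for i, b in enumerate(ref.sequence) if b in "GC"]
        if not gc_sites:
            raise ValueError(f"amplicon {ref.id} has no G/C site to mutate")
        well = wells[int(rng.integers(len(wells)))]
        pos0 = int(rng.choice(gc_sites))
        ref_b = ref.sequence[pos0]
        alt_b = "A" if ref_b == "G" else "T"
        muts.append(PlantedMutation(well, ref.id, pos0 + 1, ref_b, alt_b, Zygosity(zygosity)))
    return SimTruth(
        tuple(muts), seed, scheme.n_plates, scheme.n_rows, scheme.n_cols, {"mode": "singletons"}
    )


# -- count-table simulation -------------------------------------------------

def simulate_counts(
    scheme: PoolingScheme,
    truth: SimTruth,
    refs: Sequence[AmpliconRef],
    cov: Optional[CoverageModel] = None,
    err: Optional[ErrorModel] = None,
    mode: str = SAMPLED,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-pool allele-count tables directly (no reads).

    In ``SAMPLED`` mode coverage is lognormal per pool, substitution
    rates are jittered per run, and observed alternate counts are
    Binomial(coverage, carrier fraction + error rate).  In ``EXPECTED``
    mode every stochastic draw is replaced by its (rounded) expectation,
    so the output is deterministic and matches closed-form allele
    fractions — the oracle the sampled path is tested against.  A
    carrier's contribution to its pool is ``allele_dose / (2 * pool
    members)``.  Counts at every position sum exactly to coverage.
    """
    cov = cov or CoverageModel()
    err = err or ErrorModel()
    if mode not in (SAMPLED, EXPECTED):
        raise ValueError(f"mode must be {SAMPLED!r} or {EXPECTED!r}")
    sampled = mode == SAMPLED
    rng = np.random.default_rng(seed)
    pools = scheme.pools()
    labels = [p.label for p in pools]
    n_pools = len(pools)
    member_count = np.array([len(scheme.members(p)) for p in pools], dtype=float)
    pool_index = {p: i for i, p in enumerate(pools)}
    refs_by_id = {r.id: r for r in refs}
    for m in truth.mutations:
        _validate_mutation(m, refs_by_id, scheme)
    rates = err.draw_rates(rng) if sampled else err.mean_rates()
    frames = []
    for ref in refs:
        seq = ref.sequence
        length = len(seq)
        ref_idx = np.array([_BASE_INDEX[b] for b in seq])
        profile = cov.position_profile(length)
        if sampled:
            pool_cov = cov.draw_pool_coverage(rng, n_pools)
        else:
            pool_cov = np.full(n_pools, cov.mean_coverage_per_pool)
        covm = np.maximum(np.rint(pool_cov[:, None] * profile[None, :]), 0).astype(np.int64)

        # per-(pool, position, alt) success probability: error + carrier dose
        p_alt = np.zeros((n_pools, length, 4))
        for j, alt in enumerate(BASES):
            for b in BASES:
                if b == alt:
                    continue
                p_alt[:, ref_idx == _BASE_INDEX[b], j] = rates[f"{b}>{alt}"]
        for m in truth.mutations:
            if m.amplicon_id != ref.id:
                continue
            for pool in scheme.pools_of(m.well):
                i = pool_index[pool]
                p_alt[i, m.position - 1, _BASE_INDEX[m.alt_base]] += (
                    m.zygosity.allele_dose / (2.0 * member_count[i])
                )

        hp = homopolymer_mask(seq, err.homopolymer_min_run)
        p_ind = np.where(
            hp,
            err.homopolymer_indel_multiplier * err.mean_substitution_rate,
            err.background_indel_rate,
        )
        if sampled:
            ins = rng.binomial(covm, p_ind[None, :])
            dele = rng.binomial(covm - ins, p_ind[None, :])
        else:
            ins = np.rint(covm * p_ind[None, :]).astype(np.int64)
            dele = np.rint((covm - ins) * p_ind[None, :]).astype(np.int64)
        bases_tot = covm - ins - dele

        alt_counts = np.zeros((n_pools, length, 4), dtype=np.int64)
        for j in range(4):
            pj = p_alt[:, :, j]
            if sampled:
                alt_counts[:, :, j] = rng.binomial(bases_tot, pj)
            else:
                alt_counts[:, :, j] = np.rint(bases_tot * pj).astype(np.int64)
        ref_count = bases_tot - alt_counts.sum(axis=2)
        # Independent binomials can (rarely) overshoot; shave the excess
        # off the largest alternate counts to preserve conservation.
        for i, l in zip(*np.nonzero(ref_count < 0)):
            excess = -ref_count[i, l]
            order = np.argsort(alt_counts[i, l])[::-1]
            for j in order:
                take = min(excess, alt_counts[i, l, j])
                alt_counts[i, l, j] -= take
                excess -= take
                if excess == 0:
                    break
            ref_count[i, l] = bases_tot[i, l] - alt_counts[i, l].sum()
        counts = alt_counts.copy()
        counts[:, np.arange(length), ref_idx] = ref_count

        frame = pd.DataFrame(
            {
                "pool": np.repeat(labels, length),
                "amplicon": ref.id,
                "position": np.tile(np.arange(1, length + 1), n_pools),
                "ref": np.tile(list(seq), n_pools),
                "A": counts[:, :, 0].ravel(),
                "C": counts[:, :, 1].ravel(),
                "G": counts[:, :, 2].ravel(),
                "T": counts[:, :, 3].ravel(),
                "ins": ins.ravel(),
                "del": dele.ravel(),
            }
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]


# -- read simulation --------------------------------------------------------

def simulate_reads(
    scheme: PoolingScheme,
    truth: SimTruth,
    refs: Sequence[AmpliconRef],
    barcodes: BarcodeTable,
    cov: Optional[CoverageModel] = None,
    err: Optional[ErrorModel] = None,
    seed: int = 0,
    out_path="reads.fastq",
) -> dict:
    """Write barcoded FASTQ reads for the whole screen.

    Read layout: barcode + universal tag + forward primer + target +
    revcomp(reverse primer) + trP1, possibly 3'-truncated.  A
    ``junk_read_fraction`` of reads are ~50 bp primer-dimer artifacts
    that lack the pool barcode (failed second-step priming) and carry no
    target insert.  Deterministic per seed.
    """
    cov = cov or CoverageModel()
    err = err or ErrorModel()
    rng = np.random.default_rng(seed)
    pools = scheme.pools()
    refs_by_id = {r.id: r for r in refs}
    for m in truth.mutations:
        _validate_mutation(m, refs_by_id, scheme)
    for pool in pools:
        if pool.label not in barcodes.barcodes:
            raise ValueError(f"no barcode for pool {pool.label}")
    rates = err.draw_rates(rng)
    n_real = 0
    n_junk = 0
    n_intended_total = 0
    counter = 0
    with open(out_path, "w") as fh:
        for ref in refs:
            seq = ref.sequence
            length = len(seq)
            hp = homopolymer_mask(seq, err.homopolymer_min_run)
            p_ind = np.where(
                hp,
                err.homopolymer_indel_multiplier * err.mean_substitution_rate,
                err.background_indel_rate,
            )
            # cumulative per-position substitution thresholds (3 alts each)
            alt_table = []
            thr = np.zeros((length, 3))
            for pos0, b in enumerate(seq):
                alts = [a for a in BASES if a != b]
                alt_table.append(alts)
                thr[pos0] = np.cumsum([rates[f"{b}>{a}"] for a in alts])
            suffix = revcomp(ref.reverse_primer) + ref.trp1_adapter
            for pool in pools:
                members = scheme.members(pool)
                n2 = 2.0 * len(members)
                prefix = barcodes[pool.label] + ref.universal_tag + ref.forward_primer
                n_intended = int(rng.poisson(cov.draw_pool_coverage(rng, 1)[0]))
                n_reads = 0 if cov.junk_read_fraction >= 1.0 else n_intended
                n_intended_total += n_intended
                muts = [
                    (m.position - 1, m.alt_base, m.zygosity.allele_dose / n2)
                    for m in truth.mutations
                    if m.amplicon_id == ref.id and m.well in members
                ]
                carrier = {
                    pos0: (alt_b, rng.random(n_reads) < p)
                    for pos0, alt_b, p in muts
                }
                u_err = rng.random((n_reads, length)) if n_reads else None
                u_ind = rng.random((n_reads, length)) if n_reads else None
                trunc = rng.random(n_reads) < cov.end_dropoff_fraction
                for r in range(n_reads):
                    target = list(seq)
                    for pos0, (alt_b, flags) in carrier.items():
                        if flags[r]:
                            target[pos0] = alt_b
                    # substitution errors
                    err_pos = np.nonzero(u_err[r] < thr[:, 2])[0]
                    for pos0 in err_pos:
                        k = int(np.searchsorted(thr[pos0], u_err[r, pos0], side="right"))
                        target[pos0] = alt_table[pos0][min(k, 2)]
                    # homopolymer indel artifacts
                    ind_pos = np.nonzero(u_ind[r] < p_ind)[0]
                    for pos0 in ind_pos[::-1]:
                        if rng.random() < 0.5:
                            target.insert(pos0, seq[pos0])
                        else:
                            del target[pos0]
                    read = prefix + "".join(target) + suffix
                    if trunc[r]:
                        cut = int(rng.integers(int(len(read) * 0.7), len(read)))
                        read = read[:cut]
                    quals = np.clip(
                        np.rint(rng.normal(32, 3, len(read))), 2, 40
                    ).astype(int)
                    counter += 1
                    fh.write(
                        f"@r{counter:08d}\n{read}\n+\n"
                        + "".join(chr(q + 33) for q in quals)
                        + "\n"
                    )
                n_real += n_reads
        # primer-dimer junk: no barcode, no insert
        jf = cov.junk_read_fraction
        if jf > 0:
            if jf >= 1.0:
                n_junk = n_intended_total
            else:
                n_junk = int(round(n_real * jf / (1.0 - jf)))
            for _ in range(n_junk):
                ref = refs[int(rng.integers(len(refs)))]
                dimer = (
                    ref.universal_tag
                    + ref.forward_primer
                    + revcomp(ref.reverse_primer)
                    + ref.trp1_adapter
                )
                cut = int(rng.integers(45, min(66, len(dimer) + 1)))
                read = dimer[:cut]
                quals = np.clip(np.rint(rng.normal(28, 4, len(read))), 2, 40).astype(int)
                counter += 1
                fh.write(
                    f"@r{counter:08d}\n{read}\n+\n"
                    + "".join(chr(q + 33) for q in quals)
                    + "\n"
                )
    return {"path": str(out_path), "n_reads": n_real + n_junk, "n_real": n_real, "n_junk": n_junk}


# -- evaluation -------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    individual_accuracy: float

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "recall": self.recall,
            "precision": self.precision,
            "individual_accuracy": self.individual_accuracy,
        }


def evaluate_calls(truth: SimTruth, candidates: Sequence) -> EvaluationReport:
    """Score candidate calls against the planted truth.

    A candidate is a true positive when its (amplicon, position,
    substitution) matches a planted mutation and its deconvolved well set
    contains the true carrier; ``individual_accuracy`` is the fraction of
    true positives resolved to exactly the correct single well.  The same
    mutation present in two individuals (two carriers of one
    substitution) is matched per carrier.
    """
    truth_wells: dict = {}
    for m in truth.mutations:
        truth_wells.setdefault(
            (m.amplicon_id, m.position, m.ref_base, m.alt_base), set()
        ).add(m.well)
    tp = 0
    fp = 0
    exact = 0
    recovered: dict = {}
    for c in candidates:
        key = (c.amplicon_id, c.position, c.ref, c.alt)
        hit_wells = truth_wells.get(key, set()) & set(c.wells)
        if hit_wells:
            tp += 1
            recovered.setdefault(key, set()).update(hit_wells)
            if len(c.wells) == 1:
                exact += 1
        else:
            fp += 1
    fn = sum(
        len(wells - recovered.get(key, set())) for key, wells in truth_wells.items()
    )
    accuracy = exact / tp if tp else 0.0
    return EvaluationReport(tp, fp, fn, accuracy)


# -- synthetic references ---------------------------------------------------

def synthetic_refs(
    n: int = 4, length: int = 200, gc: float = 0.5, seed: int = 0
) -> list:
    """Synthetic amplicon references (random target + random 20-mer primers).

    These stand in for real gene amplicons in demos and tests; they make
    no attempt to satisfy primer QC rules.
    """
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    refs = []
    for i in range(n):
        seq = "".join(np.array(BASES)[rng.choice(4, size=length, p=probs)])
        fwd = "".join(np.array(BASES)[rng.choice(4, size=20, p=probs)])
        rev = "".join(np.array(BASES)[rng.choice(4, size=20, p=probs)])
        refs.append(AmpliconRef(id=f"amp{i + 1}", sequence=seq, forward_primer=fwd, reverse_primer=rev))
    return refs
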