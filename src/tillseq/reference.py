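"""Amplicon reference sequences, primer/barcode metadata and primer QC.

Each screened gene region is represented by an :class:`AmpliconRef`: the
target sequence lying *between* the two gene-specific primers, plus the
fixed sequences the two-step PCR adds around it (a universal tag on the
forward side and the trP1 adapter on the reverse side).  Pool barcodes
are prepended during the second PCR step and are modelled by
:class:`BarcodeTable`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

__all__ = [
    "UNIVERSAL_TAG",
    "TRP1_ADAPTER",
    "AmpliconRef",
    "BarcodeTable",
    "PrimerQCReport",
    "InputFormatError",
    "CapacityError",
    "read_reference",
    "write_reference",
    "primer_qc",
    "gc_content",
    "max_homopolymer",
    "homopolymer_mask",
    "build_barcode_set",
    "revcomp",
]

# Universal primer tag (Travis Glenn tag 6) and Ion Torrent trP1 adapter.
UNIVERSAL_TAG = "CAGTCGGGCGTCATCA"
TRP1_ADAPTER = "CCTCTCTATGGGCAGTCGGTGAT"

_DNA = set("ACGT")


class InputFormatError(ValueError):
    """Malformed reference/primer/barcode input."""


class CapacityError(ValueError):
    """A barcode set of the requested size/distance cannot be built."""


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def max_homopolymer(seq: str) -> int:
    """Length of the longest run of identical bases."""
    return max(len(list(g)) for _, g in itertools.groupby(seq)) if seq else 0


def homopolymer_mask(seq: str, min_run: int = 3, pad: int = 0) -> np.ndarray:
    """Boolean array marking positions inside homopolymer runs >= ``min_run``.

    With ``pad`` > 0 the mask is widened by that many positions on each
    side of every run ("immediately adjacent" positions).
    """
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[max(0, i - pad) : min(n, j + pad)] = True
        i = j
    return mask


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases; invariant under complementation."""
    sequence = _check_dna(sequence, "sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


@dataclass(frozen=True)
class AmpliconRef:
    """One amplicon: target region plus its primers and fixed adapters."""

    id: str
    sequence: str
    forward_primer: str
    reverse_primer: str
    universal_tag: str = UNIVERSAL_TAG
    trp1_adapter: str = TRP1_ADAPTER

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, "sequence"))
        object.__setattr__(
            self, "forward_primer", _check_dna(self.forward_primer, "forward_primer")
        )
        object.__setattr__(
            self, "reverse_primer", _check_dna(self.reverse_primer, "reverse_primer")
        )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def read_layout(self, barcode: str = "") -> str:
        """The full sequenced construct: barcode+tag+primer+target+rc(rev)+trP1."""
        return (
            barcode
            + self.universal_tag
            + self.forward_primer
            + self.sequence
            + revcomp(self.reverse_primer)
            + self.trp1_adapter
        )


def read_reference(fasta_path, primer_table_path) -> list:
    """Load amplicon references from a FASTA and a primer TSV (id, forward, reverse).

    One :class:`AmpliconRef` per FASTA record; every record must have a
    primer row and vice versa.
    """
    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except Exception as exc:  # pragma: no cover - SeqIO raises assorted types
        raise InputFormatError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    primers = pd.read_csv(primer_table_path, sep="\t", comment="#")
    needed = {"id", "forward", "reverse"}
    if not needed <= set(primers.columns):
        raise InputFormatError(
            f"primer table must have columns {sorted(needed)}, got {list(primers.columns)}"
        )
    by_id = {str(r["id"]): r for _, r in primers.iterrows()}
    fasta_ids = [rec.id for rec in records]
    unknown = set(by_id) - set(fasta_ids)
    if unknown:
        raise InputFormatError(f"primer rows reference unknown amplicon ids: {sorted(unknown)}")
    missing = set(fasta_ids) - set(by_id)
    if missing:
        raise InputFormatError(f"no primer row for amplicon ids: {sorted(missing)}")
    refs = []
    for rec in records:
        row = by_id[rec.id]
        refs.append(
            AmpliconRef(
                id=rec.id,
                sequence=str(rec.seq),
                forward_primer=str(row["forward"]),
                reverse_primer=str(row["reverse"]),
            )
        )
    return refs


def write_reference(refs: Sequence[AmpliconRef], fasta_path, primer_table_path) -> None:
    with open(fasta_path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.id}\n{ref.sequence}\n")
    pd.DataFrame(
        [(r.id, r.forward_primer, r.reverse_primer) for r in refs],
        columns=["id", "forward", "reverse"],
    ).to_csv(primer_table_path, sep="\t", index=False)


# -- primer QC --------------------------------------------------------------

@dataclass(frozen=True)
class PrimerQCReport:
    length_ok: bool
    tm_ok: bool
    gc_clamp_ok: bool
    homopolymer_ok: bool
    tm: float
    max_homopolymer: int
    messages: tuple

    @property
    def all_ok(self) -> bool:
        return self.length_ok and self.tm_ok and self.gc_clamp_ok and self.homopolymer_ok


def primer_qc(
    primer: str,
    *,
    min_length: int = 19,
    max_length: int = 21,
    tm_range: tuple = (59.0, 61.0),
    gc_clamp_min: int = 2,
    max_run: int = 3,
) -> PrimerQCReport:
    """Check a primer against the amplicon-design rules.

    Length 19-21 nt, melting temperature within 59-61 C (nearest-neighbour
    thermodynamics at standard conditions; advisory, since different Tm
    models disagree by a degree or two), at least two G/C among the five
    3'-terminal bases, and no homopolymer run longer than three.
    """
    primer = _check_dna(primer, "primer")
    messages = []
    length_ok = min_length <= len(primer) <= max_length
    if not length_ok:
        messages.append(f"length {len(primer)} outside [{min_length}, {max_length}]")
    tm = float(MeltingTemp.Tm_NN(Seq(primer)))
    tm_ok = tm_range[0] <= tm <= tm_range[1]
    if not tm_ok:
        messages.append(f"Tm {tm:.1f} C outside [{tm_range[0]}, {tm_range[1]}]")
    tail = primer[-5:]
    clamp = sum(b in "GC" for b in tail)
    gc_clamp_ok = clamp >= gc_clamp_min
    if not gc_clamp_ok:
        messages.append(f"only {clamp} G/C in 3'-terminal five bases (need >= {gc_clamp_min})")
    run = max_homopolymer(primer)
    homopolymer_ok = run <= max_run
    if not homopolymer_ok:
        messages.append(f"homopolymer run {run} exceeds {max_run}")
    return PrimerQCReport(
        length_ok, tm_ok, gc_clamp_ok, homopolymer_ok, tm, run, tuple(messages)
    )


# -- barcodes ---------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeTable:
    """Pool label -> barcode sequence; all barcodes same length, unique."""

    barcodes: dict
    min_hamming: int = 1

    def __post_init__(self) -> None:
        seqs = list(self.barcodes.values())
        if not seqs:
            raise ValueError("barcode table must not be empty")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("barcodes must all have the same length")
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcodes must be unique")
        arr = _seq_matrix(seqs)
        n = len(seqs)
        for i in range(n):
            d = (arr[i + 1 :] != arr[i]).sum(axis=1)
            if len(d) and d.min() < self.min_hamming:
                raise ValueError(
                    f"barcode pair closer than Hamming distance {self.min_hamming}"
                )

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    def __getitem__(self, pool_label: str) -> str:
        return self.barcodes[pool_label]

    def __len__(self) -> int:
        return len(self.barcodes)

    def items(self):
        return self.barcodes.items()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.barcodes.items()), columns=["pool", "barcode"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, min_hamming: int = 1) -> "BarcodeTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"pool", "barcode"} <= set(df.columns):
            raise InputFormatError("barcode table needs columns: pool, barcode")
        return cls(dict(zip(df["pool"].astype(str), df["barcode"].astype(str))), min_hamming)


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def build_barcode_set(
    n: int,
    length: int = 10,
    min_hamming: int = 3,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
) -> BarcodeTable:
    """Greedy randomized construction of ``n`` barcodes of the given length.

    Every barcode has homopolymer runs <= 3 and pairwise Hamming distance
    >= ``min_hamming``; deterministic for a seed.  Raises
    :class:`CapacityError` when the request is infeasible (outright, or
    after a bounded random search).
    """
    if n < 1 or length < 1 or min_hamming < 1:
        raise ValueError("n, length and min_hamming must be positive")
    if min_hamming > length or 4**length < n:
        raise CapacityError(
            f"{n} barcodes of length {length} at Hamming >= {min_hamming} are infeasible"
        )
    if labels is not None and len(labels) != n:
        raise ValueError("labels must match n")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list = []
    acc: Optional[np.ndarray] = None
    attempts = 0
    max_attempts = 2000 * n
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"could not build {n} barcodes of length {length} at Hamming "
                f">= {min_hamming} within {max_attempts} attempts"
            )
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        if max_homopolymer(cand) > 3:
            continue
        if acc is not None:
            carr = np.frombuffer(cand.encode(), dtype="S1")
            if ((acc != carr).sum(axis=1) < min_hamming).any():
                continue
        accepted.append(cand)
        acc = _seq_matrix(accepted)
    keys = list(labels) if labels is not None else [f"BC{i + 1}" for i in range(n)]
    return BarcodeTable(dict(zip(keys, accepted)), min_hamming)


def barcode_table_for_scheme(scheme, length: int = 10, min_hamming: int = 3, seed: int = 0) -> BarcodeTable:
    """A barcode per pool of a pooling scheme (labels A1.., B1.., C1..)."""
    labels = [p.label for p in scheme.pools()]
    return build_barcode_set(len(labels), length, min_hamming, seed, labels=labels)
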