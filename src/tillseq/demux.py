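"""Demultiplex, trim, align and pile up barcoded amplicon reads.

The read layout produced by the two-step PCR is

    barcode + universal tag + forward primer + target + rc(reverse primer) + trP1

``demultiplex`` assigns reads to pools by their barcode prefix and strips
it; ``trim_read`` strips the tag/primer scaffold and recovers the target
insert; ``align_to_amplicons`` places the insert on the best-matching
amplicon reference with cost-minimizing semi-global alignment; and
``pileup`` accumulates quality-filtered per-position allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import AmpliconRef, BarcodeTable, revcomp
from .tables import BASES, COUNT_COLUMNS

__all__ = [
    "FastqRead",
    "DemuxResult",
    "TrimmedRead",
    "AlignCosts",
    "AlignmentRecord",
    "QualityFilters",
    "iter_fastq",
    "demultiplex",
    "trim_read",
    "align_to_amplicons",
    "pileup",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str  # Sanger-scaled ASCII

    @property
    def qual_array(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode(), dtype=np.uint8).astype(int) - 33


def iter_fastq(path) -> Iterable[FastqRead]:
    with open(path) as fh:
        for name, seq, qual in FastqGeneralIterator(fh):
            yield FastqRead(name.split()[0], seq.upper(), qual)


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


@dataclass
class DemuxResult:
    assigned: dict  # pool label -> list of barcode-stripped FastqRead
    unassigned: list
    counts: dict  # pool label (or "unassigned") -> read count

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def demultiplex(
    reads: Iterable[FastqRead], barcodes: BarcodeTable, max_mismatch: int = 0
) -> DemuxResult:
    """Assign reads to pools by barcode prefix; ambiguous reads are unassigned.

    A read is assigned when its prefix matches exactly one barcode within
    ``max_mismatch`` substitutions; the barcode is stripped from the
    assigned read.  Conservation holds: assigned + unassigned equals the
    input count.
    """
    if len(barcodes) == 0:
        raise ValueError("barcode table must not be empty")
    k = barcodes.barcode_length
    items = list(barcodes.items())
    exact = {bc: label for label, bc in items}
    assigned: dict = {label: [] for label, _ in items}
    unassigned: list = []
    for read in reads:
        prefix = read.sequence[:k]
        label = None
        if len(prefix) == k:
            if max_mismatch == 0:
                label = exact.get(prefix)
            else:
                hits = [
                    lab for lab, bc in items if _mismatches(prefix, bc, max_mismatch) <= max_mismatch
                ]
                label = hits[0] if len(hits) == 1 else None
        if label is None:
            unassigned.append(read)
        else:
            assigned[label].append(
                FastqRead(read.name, read.sequence[k:], read.quality[k:])
            )
    counts = {label: len(lst) for label, lst in assigned.items()}
    counts["unassigned"] = len(unassigned)
    return DemuxResult(assigned, unassigned, counts)


@dataclass
class TrimmedRead:
    insert: str
    qualities: np.ndarray
    original_length: int
    pool: Optional[str] = None


def trim_read(
    read: FastqRead,
    refs: Sequence[AmpliconRef],
    *,
    pool: Optional[str] = None,
    max_mismatch: int = 1,
    min_insert: int = 30,
):
    """Strip the PCR scaffold from a demultiplexed read.

    Locates the universal tag at the read start, then one of the forward
    primers (each within ``max_mismatch`` substitutions), and removes any
    trailing reverse-primer/trP1 suffix (including 3'-truncated
    suffixes).  Returns ``(TrimmedRead, "ok")`` or ``(None, reason)``;
    rejection is a reported outcome, not an error.  Primer-dimer
    artifacts (~50 bp, no target between the primers) fail the
    ``min_insert`` floor.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    tag = refs[0].universal_tag
    seq = read.sequence
    if len(seq) < len(tag) + min_insert:
        return None, "too_short"
    if _mismatches(seq[: len(tag)], tag, max_mismatch) > max_mismatch:
        return None, "no_tag"
    rest = seq[len(tag) :]
    matched_ref = None
    for ref in refs:
        fp = ref.forward_primer
        if len(rest) >= len(fp) and _mismatches(rest[: len(fp)], fp, max_mismatch) <= max_mismatch:
            matched_ref = ref
            break
    if matched_ref is None:
        return None, "no_primer"
    offset = len(tag) + len(matched_ref.forward_primer)
    insert = seq[offset:]
    suffix_full = revcomp(matched_ref.reverse_primer) + matched_ref.trp1_adapter
    probe = suffix_full[:10]
    cut = insert.find(probe)
    if cut < 0:
        # 3'-truncated adapter: longest suffix of the insert that is a
        # prefix of the expected adapter sequence
        for klen in range(min(len(suffix_full), len(insert)) , 4, -1):
            if insert.endswith(suffix_full[:klen]):
                cut = len(insert) - klen
                break
    if cut >= 0:
        insert = insert[:cut]
    if len(insert) < min_insert:
        return None, "short_insert"
    quals = read.qual_array[offset : offset + len(insert)]
    return TrimmedRead(insert, quals, len(seq), pool), "ok"


# -- alignment --------------------------------------------------------------

@dataclass(frozen=True)
class AlignCosts:
    """Per-event alignment costs (cost-minimizing, linear gaps)."""

    mismatch: float = 2.0
    insertion: float = 3.0
    deletion: float = 3.0


def _make_aligner(costs: AlignCosts) -> Align.PairwiseAligner:
    # Cost minimization expressed as score maximization: unit match
    # reward, penalties in the stated 2:3 mismatch:gap ratio, free end
    # gaps on both sequences (read semi-global against a local stretch
    # of the reference).
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -costs.mismatch
    aligner.open_gap_score = -max(costs.insertion, costs.deletion)
    aligner.extend_gap_score = -max(costs.insertion, costs.deletion)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@dataclass
class AlignmentRecord:
    amplicon_id: str
    start: int  # 1-based inclusive reference coords of the aligned span
    end: int
    ref_pos: np.ndarray  # 0-based reference positions of aligned columns
    read_pos: np.ndarray  # matching 0-based read positions
    mismatch_read_pos: np.ndarray
    insertions: list  # (0-based ref position of left flank, 0-based read position)
    deletions: list  # (0-based ref position, 0-based read position of left flank)
    similarity: float
    aligned_fraction: float
    read: TrimmedRead


def _alignment_stats(aln, ref_seq: str, query: str):
    blocks_t, blocks_q = aln.aligned
    identities = 0
    mismatch_read = []
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        for i in range(te - ts):
            if ref_seq[ts + i] == query[qs + i]:
                identities += 1
            else:
                mismatch_read.append(qs + i)
    internal_gaps = 0
    insertions = []
    deletions = []
    for k in range(1, len(blocks_t)):
        tgap = int(blocks_t[k][0] - blocks_t[k - 1][1])
        qgap = int(blocks_q[k][0] - blocks_q[k - 1][1])
        internal_gaps += tgap + qgap
        if qgap > 0:  # read bases absent from the reference
            left = int(blocks_t[k - 1][1]) - 1
            for qp in range(int(blocks_q[k - 1][1]), int(blocks_q[k][0])):
                insertions.append((max(left, 0), qp))
        if tgap > 0:  # reference bases absent from the read
            flank = max(int(blocks_q[k - 1][1]) - 1, 0)
            for tp in range(int(blocks_t[k - 1][1]), int(blocks_t[k][0])):
                deletions.append((tp, flank))
    aligned_cols = sum(int(te - ts) for (ts, te) in blocks_t) + internal_gaps
    similarity = identities / aligned_cols if aligned_cols else 0.0
    span_q = int(blocks_q[-1][1] - blocks_q[0][0]) if len(blocks_q) else 0
    aligned_fraction = span_q / len(query) if query else 0.0
    ref_pos = np.concatenate(
        [np.arange(ts, te) for (ts, te) in blocks_t]
    ) if len(blocks_t) else np.array([], dtype=int)
    read_pos = np.concatenate(
        [np.arange(qs, qe) for (qs, qe) in blocks_q]
    ) if len(blocks_q) else np.array([], dtype=int)
    return (
        ref_pos,
        read_pos,
        np.array(mismatch_read, dtype=int),
        insertions,
        deletions,
        similarity,
        aligned_fraction,
        int(blocks_t[0][0]) + 1 if len(blocks_t) else 0,
        int(blocks_t[-1][1]) if len(blocks_t) else 0,
    )


def align_to_amplicons(
    tread: TrimmedRead,
    refs: Sequence[AmpliconRef],
    costs: Optional[AlignCosts] = None,
    min_length_fraction: float = 0.8,
    min_similarity: float = 0.8,
    rng: Optional[np.random.Generator] = None,
):
    """Align a trimmed insert against all amplicon references.

    The best-scoring reference wins; exact score ties are broken by a
    seeded uniform choice (non-specific matches map randomly).  The
    alignment is accepted only when at least ``min_length_fraction`` of
    the read aligns and the identity over aligned columns is at least
    ``min_similarity``; reverse-complement alignment is attempted as a
    fallback when the forward orientation fails.  Returns an
    :class:`AlignmentRecord` or ``None``.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    costs = costs or AlignCosts()
    rng = rng or np.random.default_rng()
    aligner = _make_aligner(costs)

    def attempt(query: str, quals: np.ndarray):
        scores = np.array([aligner.score(ref.sequence, query) for ref in refs])
        best = np.nonzero(scores == scores.max())[0]
        idx = int(best[0]) if len(best) == 1 else int(rng.choice(best))
        ref = refs[idx]
        aln = aligner.align(ref.sequence, query)[0]
        (
            ref_pos,
            read_pos,
            mm,
            ins,
            dels,
            similarity,
            aligned_fraction,
            start,
            end,
        ) = _alignment_stats(aln, ref.sequence, query)
        if aligned_fraction < min_length_fraction or similarity < min_similarity:
            return None
        trimmed = TrimmedRead(query, quals, tread.original_length, tread.pool)
        return AlignmentRecord(
            ref.id, start, end, ref_pos, read_pos, mm, ins, dels,
            similarity, aligned_fraction, trimmed,
        )

    record = attempt(tread.insert, tread.qualities)
    if record is None:
        record = attempt(revcomp(tread.insert), tread.qualities[::-1])
    return record


# -- pileup -----------------------------------------------------------------

@dataclass(frozen=True)
class QualityFilters:
    central_q: int = 20
    neighborhood_q: int = 15
    radius: int = 5
    max_gap_mismatch: int = 5


def _window_sums(values: np.ndarray, radius: int) -> np.ndarray:
    """Sum of ``values`` over a +-radius window truncated at the read ends."""
    n = len(values)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - radius, 0)
    hi = np.minimum(np.arange(n) + radius + 1, n)
    return cs[hi] - cs[lo]


def pileup(
    records: Iterable[AlignmentRecord],
    refs: Sequence[AmpliconRef],
    filters: Optional[QualityFilters] = None,
    pools: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Accumulate quality-filtered allele counts from accepted alignments.

    An aligned base contributes to its reference position only when its
    own quality reaches ``central_q``, the mean quality within
    ``+-radius`` on the read reaches ``neighborhood_q``, and the read has
    at most ``max_gap_mismatch`` combined gaps and mismatches within that
    window.  Insertions and deletions are tallied at their left-flanking
    reference position, gated on the flanking read base.  ``pools``
    optionally forces zero-count rows for pools with no accepted reads.
    """
    filters = filters or QualityFilters()
    by_id = {r.id: r for r in refs}
    arrays: dict = {}

    def ensure(pool: str, amplicon: str) -> np.ndarray:
        key = (pool, amplicon)
        if key not in arrays:
            arrays[key] = np.zeros((len(by_id[amplicon].sequence), 6), dtype=np.int64)
        return arrays[key]

    for rec in records:
        if rec.amplicon_id not in by_id:
            raise ValueError(f"alignment references unknown amplicon {rec.amplicon_id!r}")
        pool = rec.read.pool or "pool"
        arr = ensure(pool, rec.amplicon_id)
        q = rec.read.qualities
        n = len(q)
        bad = np.zeros(n)
        if len(rec.mismatch_read_pos):
            np.add.at(bad, rec.mismatch_read_pos, 1.0)
        for _, qp in rec.insertions:
            bad[min(qp, n - 1)] += 1.0
        for _, flank in rec.deletions:
            bad[min(flank, n - 1)] += 1.0
        counts_in_window = np.minimum(np.arange(n) + filters.radius + 1, n) - np.maximum(
            np.arange(n) - filters.radius, 0
        )
        wmean = _window_sums(q.astype(float), filters.radius) / counts_in_window
        wbad = _window_sums(bad, filters.radius)
        gate = (
            (q >= filters.central_q)
            & (wmean >= filters.neighborhood_q)
            & (wbad <= filters.max_gap_mismatch)
        )
        read_bases = np.frombuffer(rec.read.insert.encode(), dtype="S1")
        keep = gate[rec.read_pos]
        tpos = rec.ref_pos[keep]
        bidx = np.array(
            [_BASE_INDEX.get(b.decode(), -1) for b in read_bases[rec.read_pos[keep]]]
        )
        ok = bidx >= 0
        np.add.at(arr, (tpos[ok], bidx[ok]), 1)
        for ref_left, qp in rec.insertions:
            if gate[min(qp, n - 1)]:
                arr[ref_left, 4] += 1
        for ref_p, flank in rec.deletions:
            if gate[min(flank, n - 1)]:
                arr[max(ref_p - 1, 0), 5] += 1  # left-flanking reference position

    if pools is not None:
        for pool in pools:
            for amp in by_id:
                ensure(pool, amp)
    frames = []
    for (pool, amp), arr in sorted(arrays.items()):
        seq = by_id[amp].sequence
        frames.append(
            pd.DataFrame(
                {
                    "pool": pool,
                    "amplicon": amp,
                    "position": np.arange(1, len(seq) + 1),
                    "ref": list(seq),
                    "A": arr[:, 0],
                    "C": arr[:, 1],
                    "G": arr[:, 2],
                    "T": arr[:, 3],
                    "ins": arr[:, 4],
                    "del": arr[:, 5],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]
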