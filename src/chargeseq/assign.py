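"""Read preprocessing, 3'-anchored alignment and isodecoder assignment.

Because the ligation chemistry defines the tRNA 3' end (the CCA-adaptor
junction), every sequenced insert shares its 3' terminus with its source
reference sequence.  Alignment is therefore a deterministic, ungapped
3'-anchored comparison against each mature reference sequence, permitting
5' truncation of the read and a configurable mismatch allowance (default
one, absorbing reverse-transcriptase misincorporation at methylated
adenines).  This replaces a general-purpose short-read aligner with an
exactly testable matcher; a SAM export preserves interoperability.

Multimapping policy: tied best hits confined to one isodecoder count for
that isodecoder; ties spanning two or more isodecoders are tallied as
ambiguous and excluded from isodecoder counts (conservative, keeps counts
integral).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .chemistry import ADAPTOR_3P, ADAPTOR_RT
from .reference import ChargeRefIndex, reverse_complement, sequence_hash

MIN_READ_LEN = 20
MIN_ADAPTOR_MATCH = 8
MIN_MERGE_OVERLAP = 15
MAX_MERGE_MISMATCHES = 2

UNIQUE_GENE = "unique_gene"
MULTI_WITHIN = "multi_within_isodecoder"
MULTI_ACROSS = "multi_across_isodecoders"
SPIKE_IN = "spike_in"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    sequence: str
    source: str  # "merged" or "mate1_only"


@dataclass(frozen=True)
class GeneHit:
    gene_id: str
    mismatches: int
    aligned_length: int


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: str
    isodecoder: str | None
    gene_hits: tuple[GeneHit, ...]


@dataclass
class AssignmentCounts:
    """Per-sample tallies; statuses always sum to library_size."""

    sample_id: str
    isodecoder_counts: dict[str, int] = field(default_factory=dict)
    spike_in: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    library_size: int = 0

    def check_conservation(self) -> None:
        total = sum(self.isodecoder_counts.values()) + self.spike_in
        total += self.unassigned + self.ambiguous
        if total != self.library_size:
            raise AssertionError(
                f"{self.sample_id}: status tallies {total} != library_size {self.library_size}"
            )


# ---------------------------------------------------------------------------
# Preprocessing: adaptor trimming and mate merging
# ---------------------------------------------------------------------------

def _find_adaptor(seq: str, adaptor: str) -> int:
    """Earliest start of a 3' adaptor occurrence, or -1.

    An occurrence is a match of the adaptor prefix running to the read end
    (or the full adaptor), at least MIN_ADAPTOR_MATCH nt long, with at most
    one mismatch in the matched span.  Because at most one mismatch is
    tolerated, any occurrence must contain an exact copy of either the
    first or the second 4-mer of the adaptor, which serve as seeds.
    """
    limit = len(seq) - MIN_ADAPTOR_MATCH
    if limit < 0:
        return -1
    candidates: set[int] = set()
    for seed, offset in ((adaptor[:4], 0), (adaptor[4:8], 4)):
        pos = seq.find(seed)
        while pos != -1:
            if 0 <= pos - offset <= limit:
                candidates.add(pos - offset)
            pos = seq.find(seed, pos + 1)
    for start in sorted(candidates):
        span = min(len(adaptor), len(seq) - start)
        mism = 0
        for i in range(span):
            if seq[start + i] != adaptor[i]:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return start
    return -1


def trim_adaptor(seq: str, qual: str, adaptor: str) -> tuple[str, str]:
    pos = _find_adaptor(seq, adaptor)
    if pos == -1:
        return seq, qual
    return seq[:pos], qual[:pos]


def _overlap_mismatches(a: str, b: str, cap: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > cap:
                return m
    return m


def _merge(
    s1: str, q1: str, s2rc: str, q2rc: str
) -> tuple[str, str] | None:
    """Merge mate 1 with the reverse-complemented mate 2.

    Returns ``(merged sequence, shift)`` on success.  The shift ``t`` is the
    offset of the mate-2 start within mate 1; bases of mate 1 extending
    past the mate-2 end (adaptor read-through) and bases of mate 2 left of
    the mate-1 start are discarded.  Disagreements inside the overlap are
    resolved toward the higher-quality base call.
    """
    n1, n2 = len(s1), len(s2rc)
    candidates: list[int] = []
    seed = s2rc[:MIN_MERGE_OVERLAP]
    pos = s1.find(seed)
    while pos != -1:
        candidates.append(pos)
        pos = s1.find(seed, pos + 1)
    seed1 = s1[:MIN_MERGE_OVERLAP]
    pos = s2rc.find(seed1)
    while pos != -1:
        candidates.append(-pos)
        pos = s2rc.find(seed1, pos + 1)
    # fall back to an exhaustive scan if the exact seeds found nothing
    if not candidates:
        candidates = list(range(-(n2 - MIN_MERGE_OVERLAP), n1 - MIN_MERGE_OVERLAP + 1))

    best: tuple[int, int, int] | None = None  # (overlap, -mismatches, t)
    for t in candidates:
        if t >= 0:
            o = min(n1 - t, n2)
            if o < MIN_MERGE_OVERLAP:
                continue
            m = _overlap_mismatches(s1[t:t + o], s2rc[:o], MAX_MERGE_MISMATCHES)
        else:
            o = min(n2 + t, n1)
            if o < MIN_MERGE_OVERLAP:
                continue
            m = _overlap_mismatches(s1[:o], s2rc[-t:-t + o], MAX_MERGE_MISMATCHES)
        if m > MAX_MERGE_MISMATCHES:
            continue
        cand = (o, -m, t)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    o, neg_m, t = best

    def consensus(a: str, qa: str, b: str, qb: str) -> str:
        if a == b:
            return a
        return "".join(
            x if x == y or qx >= qy else y for x, y, qx, qy in zip(a, b, qa, qb)
        )

    if t >= 0:
        mid = consensus(s1[t:t + o], q1[t:t + o], s2rc[:o], q2rc[:o])
        tail = s2rc[o:] if n2 > o else ""
        merged = s1[:t] + mid + tail
    else:
        # negative shift: mate 2 sticks out 5' of mate 1, which can only be
        # adaptor remnants; likewise any mate-1 bases past the mate-2 end
        mid = consensus(s1[:o], q1[:o], s2rc[-t:-t + o], q2rc[-t:-t + o])
        tail = s2rc[-t + o:] if (n2 + t) > n1 else ""
        merged = mid + tail
    return merged, t


def preprocess_read_pair(
    read_id: str,
    mate1: tuple[str, str],
    mate2: tuple[str, str],
    adaptor_3p: str = ADAPTOR_3P,
    adaptor_rt: str = ADAPTOR_RT,
) -> tuple[ProcessedRead | None, str | None]:
    """Adaptor-trim and merge one read pair.

    Returns ``(processed, None)`` or ``(None, reason)`` when the pair is
    discarded (currently only ``"too_short"``).  Mates that do not overlap
    by MIN_MERGE_OVERLAP nt with at most MAX_MERGE_MISMATCHES disagreements
    fall back to mate 1 alone.
    """
    s1, q1 = trim_adaptor(mate1[0].upper(), mate1[1], adaptor_3p)
    s2, q2 = trim_adaptor(mate2[0].upper(), mate2[1], adaptor_rt)
    if len(s1) < MIN_READ_LEN:
        return None, "too_short"
    merged = None
    if len(s2) >= MIN_MERGE_OVERLAP:
        merged = _merge(s1, q1, reverse_complement(s2), q2[::-1])
    if merged is None:
        return ProcessedRead(read_id, s1, "mate1_only"), None
    return ProcessedRead(read_id, merged[0], "merged"), None


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

MIN_ALIGN_OVERLAP = 20


class _RefMatrix:
    """Mature reference sequences packed 3'-aligned into a byte matrix."""

    def __init__(self, ref: ChargeRefIndex) -> None:
        seqs = sorted(ref.mature_sequences) + [ref.spike_mature]
        self.seqs = seqs
        self.lengths = np.array([len(s) for s in seqs])
        width = int(self.lengths.max())
        mat = np.zeros((len(seqs), width), dtype=np.uint8)
        for i, s in enumerate(seqs):
            mat[i, width - len(s):] = np.frombuffer(s.encode(), dtype=np.uint8)
        self.matrix = mat
        self.width = width
        self.gene_sets: list[tuple[str, ...]] = [
            tuple(sorted(ref.mature_sequences[s])) for s in seqs[:-1]
        ] + [(ref.spike_in.gene_id,)]


def _align_encoded(
    rm: _RefMatrix, seq: str, max_mismatches: int
) -> list[tuple[int, int, int]]:
    """(ref index, mismatches, overlap) for every retained 3'-anchored hit."""
    L = len(seq)
    if L > rm.width:
        seq = seq[-rm.width:]
        L = rm.width
    read = np.frombuffer(seq.encode(), dtype=np.uint8)
    block = rm.matrix[:, rm.width - L:]
    overlaps = np.minimum(rm.lengths, L)
    diffs = block != read
    # positions of the read hanging 5' of a shorter reference do not align;
    # exclude them from the mismatch count but also from the overlap
    mism = np.empty(len(rm.seqs), dtype=int)
    full = diffs.sum(axis=1)
    short = np.nonzero(rm.lengths < L)[0]
    mism[:] = full
    for i in short:
        skip = L - int(rm.lengths[i])
        mism[i] = int(diffs[i, skip:].sum())
    keep = (mism <= max_mismatches) & (overlaps >= MIN_ALIGN_OVERLAP)
    hits = [(int(i), int(mism[i]), int(overlaps[i])) for i in np.nonzero(keep)[0]]
    hits.sort(key=lambda h: (h[1], -h[2]))
    return hits


def align_read(
    seq: str, ref: ChargeRefIndex, max_mismatches: int = 1
) -> list[GeneHit]:
    """Align one read 3'-anchored against every mature reference sequence.

    The read's 3' end is pinned to each reference 3' end (CCA), the two are
    compared ungapped over their overlap (5' truncation of the read is
    allowed), and hits with at most ``max_mismatches`` mismatches over an
    overlap of at least 20 nt are returned best-first (fewest mismatches,
    then longest overlap).  N bases count as mismatches.  No hit returns an
    empty list.
    """
    rm = _RefMatrix(ref)
    out: list[GeneHit] = []
    for i, mm, ov in _align_encoded(rm, seq, max_mismatches):
        for gene_id in rm.gene_sets[i]:
            out.append(GeneHit(gene_id, mm, ov))
    return out


# ---------------------------------------------------------------------------
# Assignment and counting
# ---------------------------------------------------------------------------

def _classify(
    rm: _RefMatrix,
    ref: ChargeRefIndex,
    seq: str,
    max_mismatches: int,
) -> tuple[str, str | None, tuple[GeneHit, ...]]:
    hits = _align_encoded(rm, seq, max_mismatches)
    if not hits:
        return UNASSIGNED, None, ()
    best_mm, best_ov = hits[0][1], hits[0][2]
    tied = [h for h in hits if h[1] == best_mm and h[2] == best_ov]
    gene_hits = tuple(
        GeneHit(g, mm, ov) for i, mm, ov in hits for g in rm.gene_sets[i]
    )
    spike_id = ref.spike_in.gene_id
    tied_genes = {g for i, _, _ in tied for g in rm.gene_sets[i]}
    if spike_id in tied_genes:
        return SPIKE_IN, None, gene_hits
    isodecoders = {ref.isodecoder_of(g) for g in tied_genes}
    if len(isodecoders) > 1:
        return MULTI_ACROSS, None, gene_hits
    key = isodecoders.pop()
    status = UNIQUE_GENE if len(tied_genes) == 1 else MULTI_WITHIN
    return status, key, gene_hits


def assign_and_count(
    reads: Iterable[ProcessedRead | None],
    ref: ChargeRefIndex,
    max_mismatches: int = 1,
    sample_id: str = "sample",
    *,
    keep_assignments: bool = True,
) -> tuple[list[Assignment], AssignmentCounts]:
    """Assign processed reads to isodecoders and tally counts.

    ``None`` entries (reads discarded during preprocessing) are tallied as
    unassigned so the conservation invariant holds over the whole library.
    Identical read sequences are classified once and the result reused.
    """
    rm = _RefMatrix(ref)
    counts = AssignmentCounts(sample_id=sample_id)
    counts.isodecoder_counts = {k: 0 for k in ref.isodecoders}
    assignments: list[Assignment] = []
    cache: dict[str, tuple[str, str | None, tuple[GeneHit, ...]]] = {}
    for read in reads:
        counts.library_size += 1
        if read is None:
            counts.unassigned += 1
            if keep_assignments:
                assignments.append(Assignment("", UNASSIGNED, None, ()))
            continue
        res = cache.get(read.sequence)
        if res is None:
            res = _classify(rm, ref, read.sequence, max_mismatches)
            cache[read.sequence] = res
        status, key, gene_hits = res
        if status == SPIKE_IN:
            counts.spike_in += 1
        elif status == UNASSIGNED:
            counts.unassigned += 1
        elif status == MULTI_ACROSS:
            counts.ambiguous += 1
        else:
            counts.isodecoder_counts[key] += 1
        if keep_assignments:
            assignments.append(Assignment(read.read_id, status, key, gene_hits))
    counts.check_conservation()
    return assignments, counts


# ---------------------------------------------------------------------------
# FASTQ-level driver and outputs
# ---------------------------------------------------------------------------

def _fastq_records(path: str) -> Iterator[tuple[str, str, str]]:
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:].strip().split()[0], seq, qual


def process_library(
    r1_path: str,
    r2_path: str,
    ref: ChargeRefIndex,
    max_mismatches: int = 1,
    sample_id: str = "sample",
    *,
    keep_assignments: bool = False,
) -> tuple[list[Assignment], AssignmentCounts]:
    """Preprocess and assign a whole paired FASTQ library."""

    def processed() -> Iterator[ProcessedRead | None]:
        for (rid1, s1, q1), (_, s2, q2) in zip(
            _fastq_records(r1_path), _fastq_records(r2_path)
        ):
            rid = rid1[:-2] if rid1.endswith("/1") else rid1
            read, _reason = preprocess_read_pair(rid, (s1, q1), (s2, q2))
            yield read

    return assign_and_count(
        processed(), ref, max_mismatches, sample_id, keep_assignments=keep_assignments
    )


def counts_to_frame(counts: AssignmentCounts):
    import pandas as pd

    rows = [
        {
            "sample": counts.sample_id,
            "isodecoder": key,
            "count": n,
            "spike_in": counts.spike_in,
            "unassigned": counts.unassigned,
            "ambiguous": counts.ambiguous,
            "library_size": counts.library_size,
        }
        for key, n in sorted(counts.isodecoder_counts.items())
    ]
    return pd.DataFrame(rows)


def counts_from_frame(frame) -> AssignmentCounts:
    first = frame.iloc[0]
    counts = AssignmentCounts(
        sample_id=str(first["sample"]),
        spike_in=int(first["spike_in"]),
        unassigned=int(first["unassigned"]),
        ambiguous=int(first["ambiguous"]),
        library_size=int(first["library_size"]),
    )
    counts.isodecoder_counts = {
        str(k): int(n) for k, n in zip(frame["isodecoder"], frame["count"])
    }
    return counts


def write_sam(
    assignments: list[Assignment],
    reads: dict[str, str],
    ref: ChargeRefIndex,
    path: str,
) -> None:
    """Export best-hit alignments as SAM (reference names = sequence hashes)."""
    mature = sorted(ref.mature_sequences) + [ref.spike_mature]
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for seq in mature:
            fh.write(f"@SQ\tSN:{sequence_hash(seq)}\tLN:{len(seq)}\n")
        name_of = {}
        for seq in mature:
            for g in ref.mature_sequences.get(seq, ()):  # spike handled below
                name_of[g] = sequence_hash(seq)
        name_of[ref.spike_in.gene_id] = sequence_hash(ref.spike_mature)
        len_of = {sequence_hash(s): len(s) for s in mature}
        for a in assignments:
            seq = reads.get(a.read_id, "*")
            if not a.gene_hits:
                fh.write(f"{a.read_id or '*'}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            best = a.gene_hits[0]
            rname = name_of[best.gene_id]
            pos = len_of[rname] - best.aligned_length + 1  # 1-based
            cigar = f"{best.aligned_length}M" if seq == "*" else f"{len(seq)}M"
            fh.write(
                f"{a.read_id}\t0\t{rname}\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\t"
                f"NM:i:{best.mismatches}\n"
            )
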