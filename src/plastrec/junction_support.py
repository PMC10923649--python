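"""Junction reference construction and spanning-read counting.

Each candidate conformer has a diagnostic breakpoint; a short reference is
built around it (the diagnostic core plus flanking sequence) and reads are
scored: a read supports the junction when it, or its reverse complement,
aligns ungapped to a window containing the full core plus at least
``min_overhang`` bases on each side, with at most ``max_mismatch``
substitutions.  Matching is by exact k-mer anchor plus ungapped extension; no
external aligner is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .genome_model import Interval, PlastomeStructure, reverse_complement
from .recombinator import Conformer, SegmentPartition

ANCHOR_K = 15

JUNCTION_LABELS = ("G-type", "B-inversion", "A-type", "reciprocal", "C-deletion")


@dataclass(frozen=True)
class JunctionRef:
    """A junction reference: diagnostic core plus flanks.

    ``core`` is an interval within ``sequence``; for a pure deletion
    breakpoint the core has zero length and the diagnostic signal is the
    novel adjacency itself.
    """

    label: str
    sequence: str
    core: Interval
    flank_len: int
    truncated: bool = False
    recommended_overhang: int = 20

    def __post_init__(self):
        if self.core.end > len(self.sequence):
            raise ValueError("core outside the junction sequence")

    @property
    def core_seq(self) -> str:
        return self.sequence[self.core.start:self.core.end]


@dataclass(frozen=True)
class SupportCount:
    junction: str
    n_spanning: int
    n_partial: int
    min_overhang: int
    max_mismatch: int
    n_reads: int
    spanning_read_ids: tuple = ()
    cross_match: bool = False


def build_junction_refs(
    parent: PlastomeStructure,
    partition: SegmentPartition,
    conformers: Optional[Sequence[Conformer]] = None,
    flank_len: int = 300,
) -> list[JunctionRef]:
    """Build the diagnostic junction references for a partitioned parent.

    Emitted junctions: the parent A|B|C junction (supports the G-type), the
    inversion junction A|revcomp(B)|C, the A-type junction (B flanked on both
    sides by area-A context, per the A-B-A structure), the reciprocal
    junction (B flanked by area-C context), and the bare area-C deletion
    junction joining the sequences adjacent to area C.  Flanks are truncated
    to the available region sequence and flagged.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be positive")
    seq = parent.sequence.residues
    n = len(seq)
    a, b, c = partition.area_a, partition.area_b, partition.area_c
    core = seq[b.start:b.end]
    arm_len = partition.repeat.arm_len

    fa = min(flank_len, len(a))     # flank drawn from area A (its tail)
    fc = min(flank_len, len(c))     # flank drawn from area C (its head)
    a_tail = seq[b.start - fa:b.start]
    c_head = seq[b.end:b.end + fc]
    trunc_a = fa < flank_len
    trunc_c = fc < flank_len

    refs = [
        JunctionRef("G-type", a_tail + core + c_head,
                    Interval(fa, fa + len(core)), flank_len,
                    truncated=trunc_a or trunc_c),
        JunctionRef("B-inversion",
                    a_tail + reverse_complement(core) + c_head,
                    Interval(fa, fa + len(core)), flank_len,
                    truncated=trunc_a or trunc_c,
                    recommended_overhang=arm_len),
        JunctionRef("A-type",
                    a_tail + core + reverse_complement(a_tail),
                    Interval(fa, fa + len(core)), flank_len,
                    truncated=trunc_a),
        JunctionRef("reciprocal",
                    reverse_complement(c_head) + core + c_head,
                    Interval(fc, fc + len(core)), flank_len,
                    truncated=trunc_c),
    ]

    # deletion junction: parent sequence adjacent to area C on both sides,
    # joined; flanks are parent-contiguous (upstream may run from B into A)
    fl = min(flank_len, c.start)
    fr = min(flank_len, n - c.end)
    refs.append(JunctionRef(
        "C-deletion",
        seq[c.start - fl:c.start] + seq[c.end:c.end + fr],
        Interval(fl, fl), flank_len,
        truncated=fl < flank_len or fr < flank_len,
    ))

    if conformers is not None:
        by_label = {c_.label: c_ for c_ in conformers}
        checks = {"B-inversion": "B-inversion", "A-type": "A-type",
                  "reciprocal": "reciprocal"}
        for ref in refs:
            conf = by_label.get(checks.get(ref.label, ""))
            if conf is not None and not junction_in_conformer(ref, conf):
                raise AssertionError(
                    f"junction {ref.label!r} absent from its conformer sequence"
                )
    return refs


def junction_in_conformer(ref: JunctionRef, conformer: Conformer) -> bool:
    doubled = conformer.sequence.residues * 2
    return ref.sequence in doubled or reverse_complement(ref.sequence) in doubled


# ---------------------------------------------------------------------------
# spanning-read counting


def _read_sequences(reads) -> list[str]:
    if hasattr(reads, "sequences"):
        return list(reads.sequences())
    return [str(r).upper() for r in reads]


def _anchor_offsets(read: str, index: dict, k: int) -> list[int]:
    offsets = set()
    positions = list(range(0, max(1, len(read) - k + 1), k))
    tail = len(read) - k
    if tail > 0 and tail not in positions:
        positions.append(tail)
    for q in positions:
        for rp in index.get(read[q:q + k], ()):
            offsets.add(rp - q)
    return sorted(offsets)


def _mismatches(read: str, ref: str, offset: int, limit: int) -> tuple[int, int, int]:
    """Ungapped comparison at ``offset``; bases hanging off the reference are
    soft-clipped.  Returns (mismatches, overlap_start, overlap_end) in
    reference coordinates; mismatches stop counting once past ``limit``."""
    lo = max(0, offset)
    hi = min(len(ref), offset + len(read))
    mism = 0
    for t in range(lo, hi):
        if read[t - offset] != ref[t]:
            mism += 1
            if mism > limit:
                break
    return mism, lo, hi


def count_spanning_reads(
    ref: JunctionRef,
    reads,
    min_overhang: int = 20,
    max_mismatch: int = 0,
    read_ids: Optional[Sequence[str]] = None,
) -> SupportCount:
    """Count reads spanning the junction core with ``min_overhang`` bases of
    flank on each side.  Reads are scored on both strands and each read is
    counted at most once.  Reads that align over part of the core without
    spanning it are tallied as ``n_partial``."""
    span_lo = ref.core.start - min_overhang
    span_hi = ref.core.end + min_overhang
    if span_lo < 0 or span_hi > len(ref.sequence):
        raise ValueError(
            f"min_overhang {min_overhang} exceeds the available flank of "
            f"junction {ref.label!r}"
        )
    refseq = ref.sequence
    index: dict[str, list[int]] = {}
    for i in range(len(refseq) - ANCHOR_K + 1):
        index.setdefault(refseq[i:i + ANCHOR_K], []).append(i)

    seqs = _read_sequences(reads)
    if read_ids is None:
        read_ids = [str(i) for i in range(len(seqs))]

    n_span = n_partial = 0
    spanning_ids = []
    empty_core = len(ref.core) == 0
    for rid, read in zip(read_ids, seqs):
        spanning = partial = False
        for r in (read, reverse_complement(read)):
            for off in _anchor_offsets(r, index, ANCHOR_K):
                mism, lo, hi = _mismatches(r, refseq, off, max_mismatch)
                if mism > max_mismatch:
                    continue
                if lo <= span_lo and hi >= span_hi:
                    spanning = True
                    break
                if empty_core:
                    touches = lo < ref.core.start < hi
                else:
                    touches = lo < ref.core.end and hi > ref.core.start
                if touches:
                    partial = True
            if spanning:
                break
        if spanning:
            n_span += 1
            spanning_ids.append(rid)
        elif partial:
            n_partial += 1

    return SupportCount(
        junction=ref.label,
        n_spanning=n_span,
        n_partial=n_partial,
        min_overhang=min_overhang,
        max_mismatch=max_mismatch,
        n_reads=len(seqs),
        spanning_read_ids=tuple(spanning_ids),
    )


def support_table(
    refs: Sequence[JunctionRef],
    reads,
    min_overhang: Optional[int] = None,
    max_mismatch: int = 0,
) -> list[SupportCount]:
    """Score every junction; a junction whose spanning reads also span
    another junction is flagged as a cross match.  When ``min_overhang`` is
    None each junction's recommended overhang is used (11 bp for the
    inversion test, 20 bp otherwise)."""
    seqs = _read_sequences(reads)
    counts = [
        count_spanning_reads(
            ref, seqs,
            min_overhang=ref.recommended_overhang if min_overhang is None else min_overhang,
            max_mismatch=max_mismatch,
        )
        for ref in refs
    ]
    out = []
    for i, sc in enumerate(counts):
        mine = set(sc.spanning_read_ids)
        cross = any(
            mine & set(other.spanning_read_ids)
            for j, other in enumerate(counts) if j != i
        )
        out.append(SupportCount(
            junction=sc.junction, n_spanning=sc.n_spanning,
            n_partial=sc.n_partial, min_overhang=sc.min_overhang,
            max_mismatch=sc.max_mismatch, n_reads=sc.n_reads,
            spanning_read_ids=sc.spanning_read_ids, cross_match=cross,
        ))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path) -> tuple[list[str], list[str]]:
    """Read sequences (and ids) from a FASTQ file; qualities are ignored."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ids, seqs


def read_fastq_pair(path1, path2=None) -> tuple[list[str], list[str]]:
    """Read one or two FASTQ files; mates are scored independently."""
    ids, seqs = read_fastq(path1)
    if path2 is not None:
        ids2, seqs2 = read_fastq(path2)
        ids += ids2
        seqs += seqs2
    return ids, seqs


def write_junction_fasta(refs: Iterable[JunctionRef], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.label} core={ref.core.start + 1}-{ref.core.end} "
                     f"flank={ref.flank_len} truncated={ref.truncated}\n")
            for i in range(0, len(ref.sequence), width):
                fh.write(ref.sequence[i:i + width] + "\n")


def write_support_tsv(counts: Iterable[SupportCount], path) -> None:
    lines = ["junction\tn_spanning\tn_partial\tmin_overhang\tmax_mismatch"
             "\tn_reads\tcross_match"]
    for sc in counts:
        lines.append(f"{sc.junction}\t{sc.n_spanning}\t{sc.n_partial}"
                     f"\t{sc.min_overhang}\t{sc.max_mismatch}\t{sc.n_reads}"
                     f"\t{str(sc.cross_match).lower()}")
    Path(path).write_text("\n".join(lines) + "\n")
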