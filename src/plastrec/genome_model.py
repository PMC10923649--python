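"""Circular plastome model and quadripartite (LSC/IRb/SSC/IRa) structure detection.

Coordinates are 0-based half-open on the canonical linearization; conversion
to 1-based inclusive happens only in report writers.  The canonical rotation
starts at LSC position 0 with region order LSC -> IRb -> SSC -> IRa; among the
two flip-flop isomers the one whose SSC forward strand is lexicographically
smaller is canonical.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BAD_CHAR = re.compile(r"[^ACGTN]")

#: seed length for inverted-repeat detection (shared k-mers between strands)
DEFAULT_SEED_K = 21


class SequenceAlphabetError(ValueError):
    """A residue outside {A,C,G,T,N} was found."""

    def __init__(self, char: str, position: int):
        super().__init__(
            f"invalid residue {char!r} at position {position} "
            "(expected one of A, C, G, T, N)"
        )
        self.char = char
        self.position = position


class NoQuadripartiteError(ValueError):
    """No inverted repeat of the required length partitions the circle."""


class AmbiguousStructureError(ValueError):
    """More than one non-nested maximal inverted repeat candidate."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "ambiguous quadripartite structure; maximal candidates: "
            + ", ".join(f"(arms at {u} and {v}, len {L})" for u, v, L in self.candidates)
        )


def _check_alphabet(seq: str) -> None:
    m = _BAD_CHAR.search(seq)
    if m:
        raise SequenceAlphabetError(m.group(0), m.start())


def complement(seq: str) -> str:
    """Watson-Crick complement, not reversed (N maps to N)."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; rejects other characters."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that ``offset`` becomes position 0."""
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    s2 = s + s
    n2 = len(s2)
    f = [-1] * n2
    k = 0
    for j in range(1, n2):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_circular(seq: str) -> str:
    """Canonical form of a circular sequence: the lexicographically smallest
    rotation over both strands.  Rotations and global strand flips of the same
    molecule map to the same canonical string; flip-flop isomers do not.
    """
    a = rotate(seq, _least_rotation(seq))
    rc = reverse_complement(seq)
    b = rotate(rc, _least_rotation(rc))
    return min(a, b)


@dataclass(frozen=True)
class CircularSequence:
    """A named circular DNA sequence over {A,C,G,T,N}."""

    name: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError("circular sequence must be non-empty")
        _check_alphabet(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def rotated(self, offset: int) -> "CircularSequence":
        return CircularSequence(self.name, rotate(self.residues, offset))

    def fetch(self, start: int, end: int) -> str:
        """Circular slice; ``end`` may exceed the length (wraps around)."""
        n = self.length
        span = end - start
        if span < 0 or span > n:
            raise ValueError("slice must be within one full turn of the circle")
        start %= n
        return (self.residues + self.residues)[start:start + span]

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(self.name, reverse_complement(self.residues))


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval; ``wraps`` marks origin-crossing intervals."""

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative interval start {self.start}")
        if not self.wraps and self.end < self.start:
            raise ValueError(f"inverted interval [{self.start}, {self.end})")

    def length(self, genome_length: Optional[int] = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if genome_length is None:
            raise ValueError("wrapping interval length requires the genome length")
        return self.end + genome_length - self.start

    def __len__(self) -> int:  # non-wrapping convenience
        if self.wraps:
            raise TypeError("len() undefined for wrapping intervals")
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


REGION_ORDER = ("lsc", "irb", "ssc", "ira")


@dataclass(frozen=True)
class PlastomeStructure:
    """A circular plastome in canonical rotation with its four regions."""

    sequence: CircularSequence
    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    canonical_offset: int = 0
    ssc_flipped: bool = False
    lsc_by_hint: bool = False

    def region(self, name: str) -> Interval:
        return getattr(self, name)

    def region_seq(self, name: str) -> str:
        iv = self.region(name)
        return self.sequence.residues[iv.start:iv.end]

    def regions(self):
        return {name: self.region(name) for name in REGION_ORDER}

    def validate(self, exact_ir: bool = True) -> None:
        n = self.sequence.length
        ivs = [self.region(r) for r in REGION_ORDER]
        if ivs[0].start != 0 or ivs[-1].end != n:
            raise ValueError("regions must tile the canonical linearization")
        for a, b in zip(ivs, ivs[1:]):
            if a.end != b.start:
                raise ValueError("regions must be contiguous and non-overlapping")
        if len(self.irb) != len(self.ira):
            raise ValueError("IR copies differ in length")
        if exact_ir and self.region_seq("ira") != reverse_complement(self.region_seq("irb")):
            raise ValueError("IRa is not the exact reverse complement of IRb")
        if len(self.lsc) + len(self.ssc) + 2 * len(self.irb) != n:
            raise ValueError("region sizes do not sum to the genome size")


@dataclass(frozen=True)
class StructureMetrics:
    genome_size: int
    lsc_size: int
    ssc_size: int
    ir_size: int
    gc_total: Optional[float]
    gc_lsc: Optional[float]
    gc_ssc: Optional[float]
    gc_ir: Optional[float]


def _extend_diagonal(sd: str, comp_sd: str, d: int, p0: int, p1: int,
                     budget: int) -> tuple[int, int]:
    """Maximal run of matches on anti-diagonal ``d`` (position p pairs with
    d - p) containing [p0, p1], optionally stepping over ``budget`` mismatches
    (trailing mismatches are never included)."""
    n2 = len(sd)
    lo_bound = max(0, d - n2 + 1)
    hi_bound = min(n2 - 1, d)

    def match(p: int) -> bool:
        return sd[p] == comp_sd[d - p]

    def run_down(p: int) -> int:
        while p - 1 >= lo_bound and match(p - 1):
            p -= 1
        return p

    def run_up(p: int) -> int:
        while p + 1 <= hi_bound and match(p + 1):
            p += 1
        return p

    p0 = run_down(p0)
    p1 = run_up(p1)
    remaining = budget
    while remaining > 0 and p0 - 2 >= lo_bound and match(p0 - 2):
        p0 = run_down(p0 - 2)
        remaining -= 1
    while remaining > 0 and p1 + 2 <= hi_bound and match(p1 + 2):
        p1 = run_up(p1 + 2)
        remaining -= 1
    return p0, p1


def detect_quadripartite(
    seq: Union[str, CircularSequence],
    min_ir_len: int = 1000,
    allow_mismatch: int = 0,
    lsc_hint: Optional[str] = None,
    name: str = "genome",
) -> PlastomeStructure:
    """Detect the quadripartite structure of a circular plastome.

    Finds the maximal-arm inverted repeat that partitions the circle into two
    single-copy regions.  The longer single-copy region is labelled LSC unless
    ``lsc_hint`` is given, in which case the single-copy region whose sequence
    equals the hint (on either strand) is labelled LSC regardless of length —
    the homology-based override used for rearranged conformers.

    Raises :class:`NoQuadripartiteError` when no inverted repeat of at least
    ``min_ir_len`` exists, and :class:`AmbiguousStructureError` when several
    non-nested maximal candidates tie.
    """
    cs = seq if isinstance(seq, CircularSequence) else CircularSequence(name, seq)
    if min_ir_len < 50:
        raise ValueError("min_ir_len must be >= 50")
    n = cs.length
    if n <= 2 * min_ir_len:
        raise ValueError("genome shorter than twice min_ir_len")

    s = cs.residues
    sd = s + s
    comp_sd = sd.translate(_COMPLEMENT)
    rc_sd = comp_sd[::-1]
    n2 = len(sd)
    k = min(DEFAULT_SEED_K, min_ir_len)

    index: dict[str, list[int]] = {}
    for i in range(n2 - k + 1):
        index.setdefault(sd[i:i + k], []).append(i)

    covered: dict[int, list[tuple[int, int]]] = {}
    candidates: dict[tuple[int, int, int], int] = {}
    for i in range(n):
        key = rc_sd[n2 - i - k:n2 - i]  # reverse complement of sd[i:i+k]
        hits = index.get(key)
        if not hits:
            continue
        for j in hits:
            if j <= i:
                continue
            d = i + j + k - 1
            runs = covered.setdefault(d, [])
            if any(lo <= i <= hi for lo, hi in runs):
                continue
            p0, p1 = _extend_diagonal(sd, comp_sd, d, i, i + k - 1, allow_mismatch)
            runs.append((p0, p1))
            # clamp so both single-copy gaps exist on the circle
            if d - 2 * p1 - 1 < 1:          # gap between left arm end and right arm
                p1 = (d - 2) // 2
            if 2 * p0 + n - d - 1 < 1:      # wrap-around gap
                p0 = -(-(d + 2 - n) // 2)
            arm = p1 - p0 + 1
            if p1 < p0 or arm < min_ir_len or arm > n // 2:
                continue
            u = p0 % n
            v = (d - p1) % n
            key2 = (min(u, v), max(u, v), arm)
            candidates[key2] = arm

    if not candidates:
        raise NoQuadripartiteError(
            f"no inverted repeat of >= {min_ir_len} bp found in {cs.name!r}"
        )
    best = max(arm for _, _, arm in candidates)
    top = sorted(key2 for key2 in candidates if key2[2] == best)
    if len(top) > 1:
        raise AmbiguousStructureError(top)
    u, v, arm = top[0]

    gap_uv_start = (u + arm) % n
    gap_uv_len = (v - u - arm) % n
    gap_vu_start = (v + arm) % n
    gap_vu_len = (u - v - arm) % n

    def gap_seq(start: int, length: int) -> str:
        return (s + s)[start:start + length]

    lsc_by_hint = False
    lsc_is_uv = gap_uv_len >= gap_vu_len
    if lsc_hint is not None:
        hint_rc = reverse_complement(lsc_hint)
        uv = gap_seq(gap_uv_start, gap_uv_len)
        vu = gap_seq(gap_vu_start, gap_vu_len)
        uv_match = uv == lsc_hint or uv == hint_rc
        vu_match = vu == lsc_hint or vu == hint_rc
        if uv_match != vu_match:
            lsc_is_uv = uv_match
            lsc_by_hint = True

    if lsc_is_uv:
        offset = gap_uv_start
        lsc_len, ssc_len = gap_uv_len, gap_vu_len
    else:
        offset = gap_vu_start
        lsc_len, ssc_len = gap_vu_len, gap_uv_len

    canon = rotate(s, offset)
    lsc = Interval(0, lsc_len)
    irb = Interval(lsc_len, lsc_len + arm)
    ssc = Interval(irb.end, irb.end + ssc_len)
    ira = Interval(ssc.end, n)

    ssc_flipped = False
    ssc_seq = canon[ssc.start:ssc.end]
    ssc_rc = reverse_complement(ssc_seq)
    if ssc_rc < ssc_seq:
        canon = canon[:ssc.start] + ssc_rc + canon[ssc.end:]
        ssc_flipped = True

    structure = PlastomeStructure(
        sequence=CircularSequence(cs.name, canon),
        lsc=lsc, irb=irb, ssc=ssc, ira=ira,
        canonical_offset=offset, ssc_flipped=ssc_flipped, lsc_by_hint=lsc_by_hint,
    )
    structure.validate(exact_ir=(allow_mismatch == 0))
    return structure


def gc_fraction(seq: str) -> Optional[float]:
    """GC fraction with Ns excluded from numerator and denominator;
    ``None`` when no unambiguous base remains."""
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        return None
    return gc / acgt


def compute_metrics(structure: PlastomeStructure) -> StructureMetrics:
    """Region sizes and per-region GC content of a detected structure."""
    return StructureMetrics(
        genome_size=structure.sequence.length,
        lsc_size=len(structure.lsc),
        ssc_size=len(structure.ssc),
        ir_size=len(structure.irb),
        gc_total=gc_fraction(structure.sequence.residues),
        gc_lsc=gc_fraction(structure.region_seq("lsc")),
        gc_ssc=gc_fraction(structure.region_seq("ssc")),
        gc_ir=gc_fraction(structure.region_seq("irb")),
    )


# ---------------------------------------------------------------------------
# FASTA and report I/O


def read_fasta(path) -> list[CircularSequence]:
    from Bio import SeqIO

    records = [
        CircularSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[CircularSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")


def structure_report(structure: PlastomeStructure,
                     metrics: Optional[StructureMetrics] = None) -> dict:
    """JSON-serializable structure report (1-based inclusive coordinates)."""
    metrics = metrics or compute_metrics(structure)
    gc = {"lsc": metrics.gc_lsc, "irb": metrics.gc_ir,
          "ssc": metrics.gc_ssc, "ira": metrics.gc_ir}
    report = {
        "name": structure.sequence.name,
        "genome_size": metrics.genome_size,
        "gc_total": metrics.gc_total,
        "canonical_offset": structure.canonical_offset,
        "ssc_flipped": structure.ssc_flipped,
        "lsc_by_hint": structure.lsc_by_hint,
        "regions": [
            {
                "region": name.upper(),
                "start_1based": structure.region(name).start + 1,
                "end_1based": structure.region(name).end,
                "length": len(structure.region(name)),
                "gc": gc[name],
            }
            for name in REGION_ORDER
        ],
    }
    return report


def write_structure_json(structure: PlastomeStructure, path,
                         metrics: Optional[StructureMetrics] = None) -> None:
    Path(path).write_text(json.dumps(structure_report(structure, metrics), indent=2) + "\n")


def write_structure_bed(structure: PlastomeStructure, path) -> None:
    lines = [
        "\t".join([structure.sequence.name,
                   str(structure.region(name).start),
                   str(structure.region(name).end),
                   name.upper()])
        for name in REGION_ORDER
    ]
    Path(path).write_text("\n".join(lines) + "\n")
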