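"""Ground-truth engine: toy quadripartite plastomes with a planted short
inverted repeat, independently spliced conformers, and simulated reads from
conformer mixtures.

The toy generator rejection-samples until (i) the planted repeat pair is the
only inverted pair of at least its arm length in the scanned spacer range of
the LSC, (ii) the planted arms are exactly maximal (no accidental single-base
extension), and (iii) the large IR recovers exactly under structure
detection.  Conformers are constructed here by direct region-string splicing,
independently of the event-driven assembly, so each implementation checks the
other.

Mixture proportions are molecule (copy-number) proportions: the expected
read count of each conformer is proportional to proportion x genome length,
so region-depth arithmetic on the parent reference recovers the requested
proportion directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_model import (
    CircularSequence,
    Interval,
    PlastomeStructure,
    canonical_circular,
    detect_quadripartite,
    reverse_complement,
)
from .recombinator import Gene, SegmentPartition, partition_lsc
from .repeat_finder import INVERTED, RepeatPair, find_repeat_pairs

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy quadripartite plastome with a planted inverted
    repeat pair partitioning the LSC into areas A, B, C (arms included in A
    and C)."""

    len_a: int = 111
    len_b: int = 20
    len_c: int = 69
    arm_len: int = 11
    len_ssc: int = 150
    len_ir: int = 200
    gc: float = 0.375
    seed: int = 0
    genes: tuple = ()  # (name, area, gtype) with area in A/B/C/SSC/IR
    arm_seq: Optional[str] = None
    uniqueness_spacer: Optional[tuple] = None  # spacer range scanned for strays
    name: str = "toy"

    def __post_init__(self):
        if self.arm_len < 4:
            raise ValueError("arm_len must be >= 4")
        if self.len_a < self.arm_len or self.len_c < self.arm_len:
            raise ValueError("arms must fit inside areas A and C")
        if self.len_b < 0:
            raise ValueError("negative area B length")
        if self.len_ssc < 2:
            raise ValueError("SSC must be at least 2 bp")
        if self.len_ir < 50:
            raise ValueError("large IR must be at least 50 bp")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be a fraction in (0, 1)")
        if self.arm_seq is not None and len(self.arm_seq) != self.arm_len:
            raise ValueError("arm_seq length differs from arm_len")

    @property
    def len_lsc(self) -> int:
        return self.len_a + self.len_b + self.len_c

    @property
    def genome_size(self) -> int:
        return self.len_lsc + 2 * self.len_ir + self.len_ssc

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class ToyPlastome:
    spec: ToySpec
    structure: PlastomeStructure
    partition: SegmentPartition
    repeat: RepeatPair
    annotation: tuple


class ToySpecError(ValueError):
    """Rejection sampling failed: the spec is too repetitive."""


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    if length == 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _comp(ch: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}[ch]


def make_toy_plastome(spec: ToySpec, max_attempts: int = 200,
                      verify: bool = True) -> ToyPlastome:
    """Generate a toy plastome from the recipe; see the module docstring for
    the rejection-sampling guarantees."""
    rng = np.random.default_rng(spec.seed)
    m = spec.arm_len
    scan_lo, scan_hi = spec.uniqueness_spacer or (0, spec.len_lsc)

    for _ in range(max_attempts):
        arm = spec.arm_seq or _random_dna(rng, m, spec.gc)
        area_a = _random_dna(rng, spec.len_a - m, spec.gc) + arm
        area_b = _random_dna(rng, spec.len_b, spec.gc)
        area_c = reverse_complement(arm) + _random_dna(rng, spec.len_c - m, spec.gc)
        big_ir = _random_dna(rng, spec.len_ir, spec.gc)
        ssc = _random_dna(rng, spec.len_ssc, spec.gc)
        if reverse_complement(ssc) < ssc:  # pre-canonicalize the flip-flop isomer
            ssc = reverse_complement(ssc)

        lsc_seq = area_a + area_b + area_c
        genome = lsc_seq + big_ir + ssc + reverse_complement(big_ir)

        # planted short arms must be exactly maximal
        if genome[(spec.len_a - m - 1) % len(genome)] == _comp(
                genome[spec.len_a + spec.len_b + m]):
            continue  # outward extension possible
        if spec.len_b >= 2 and area_b[0] == _comp(area_b[-1]):
            continue  # inward extension possible
        # large IR must be exactly maximal
        if area_c[-1] == _comp(area_a[0]):
            continue
        if ssc[0] == _comp(ssc[-1]):
            continue

        # the planted pair must be the only inverted pair >= arm_len in the
        # scanned spacer range of the LSC
        found = find_repeat_pairs(
            lsc_seq, min_arm=m, max_arm=len(lsc_seq),
            min_spacer=scan_lo, max_spacer=scan_hi, orientation=INVERTED,
        )
        planted = RepeatPair(
            arm_len=m,
            left_arm=Interval(spec.len_a - m, spec.len_a),
            right_arm=Interval(spec.len_a + spec.len_b, spec.len_a + spec.len_b + m),
            orientation=INVERTED,
            spacer_len=spec.len_b,
            left_seq=arm,
            right_seq=reverse_complement(arm),
        )
        if len(found) != 1 or found[0].key() != planted.key():
            continue

        structure = PlastomeStructure(
            sequence=CircularSequence(spec.name, genome),
            lsc=Interval(0, spec.len_lsc),
            irb=Interval(spec.len_lsc, spec.len_lsc + spec.len_ir),
            ssc=Interval(spec.len_lsc + spec.len_ir,
                         spec.len_lsc + spec.len_ir + spec.len_ssc),
            ira=Interval(spec.len_lsc + spec.len_ir + spec.len_ssc,
                         spec.genome_size),
        )
        structure.validate()
        if verify:
            # hint pins the LSC label to the constructed LSC even when it is
            # shorter than the SSC (homology-style labeling)
            det = detect_quadripartite(genome, min_ir_len=max(50, min(spec.len_ir, 1000)),
                                       lsc_hint=lsc_seq, name=spec.name)
            if (len(det.lsc), len(det.irb), len(det.ssc)) != (
                    spec.len_lsc, spec.len_ir, spec.len_ssc):
                continue
            if det.sequence.residues != genome:
                continue

        partition = partition_lsc(structure, planted)
        annotation = _place_genes(spec, structure)
        return ToyPlastome(spec, structure, partition, planted, annotation)

    raise ToySpecError(
        f"could not realize toy spec after {max_attempts} attempts "
        "(spec too repetitive or constraints unsatisfiable)"
    )


def _place_genes(spec: ToySpec, structure: PlastomeStructure) -> tuple:
    areas = {
        "A": Interval(0, spec.len_a),
        "B": Interval(spec.len_a, spec.len_a + spec.len_b),
        "C": Interval(spec.len_a + spec.len_b, spec.len_lsc),
        "SSC": structure.ssc,
        "IR": structure.irb,
    }
    by_area: dict[str, list] = {}
    for name, area, gtype in spec.genes:
        by_area.setdefault(area, []).append((name, gtype))
    genes = []
    for area, members in by_area.items():
        iv = areas[area]
        k = len(members)
        slot = len(iv) // k
        if slot < 3:
            raise ToySpecError(f"area {area} too small for {k} genes")
        glen = max(1, slot // 3)
        for idx, (name, gtype) in enumerate(members):
            start = iv.start + idx * slot + slot // 3
            genes.append(Gene(name, gtype, start, start + glen))
            if area == "IR":  # mirrored copy in IRa
                off = start - structure.irb.start
                mstart = structure.ira.start + (len(structure.irb) - off - glen)
                genes.append(Gene(name, gtype, mstart, mstart + glen, strand="-"))
    return tuple(sorted(genes, key=lambda g: (g.start, g.name)))


# ---------------------------------------------------------------------------
# independent conformer splicing (formula construction; the cross-oracle for
# the event-driven assembly in the recombination module)


def splice_conformer(parent: str, partition: SegmentPartition, label: str,
                     ir_len: Optional[int] = None) -> str:
    """Build a conformer by direct region-string cut-and-paste, returned in
    canonical circular form.  ``ir_len`` may be given explicitly; by default
    the large-IR length is inferred from the reverse-complement symmetry of
    the sequence following the LSC (exact for generated toys)."""
    m = partition.repeat.arm_len
    a = parent[partition.area_a.start:partition.area_a.end]
    b = parent[partition.area_b.start:partition.area_b.end]
    c = parent[partition.area_c.start:partition.area_c.end]
    rest = parent[partition.lsc.end:]  # IRb + SSC + IRa
    L = ir_len if ir_len is not None else _ir_len_of(rest)
    ir = rest[:L]
    s = rest[L:len(rest) - L]
    irp = rest[len(rest) - L:]

    if label == "flipflop-isomer":
        seq = a + b + c + ir + reverse_complement(s) + irp
    elif label == "B-inversion":
        seq = a + reverse_complement(b) + c + ir + s + irp
    elif label == "intermediate-dimer":
        arm = a[-m:]
        seq = (arm + b + c + ir + s + irp + a[:-m]
               + arm + reverse_complement(b) + reverse_complement(a)
               + ir + reverse_complement(s) + irp + reverse_complement(c[m:]))
    elif label == "A-type":
        seq = b + reverse_complement(a) + ir + s + irp + a
    elif label == "reciprocal":
        seq = b + c + ir + s + irp + reverse_complement(c)
    else:
        raise ValueError(f"unknown conformer label {label!r}")
    return canonical_circular(seq)


def _ir_len_of(rest: str) -> int:
    """Length of the IR copies in IRb+SSC+IRa, found by maximal symmetric
    reverse-complement agreement of the two ends."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    max_ir = len(rest) // 2
    L = 0
    while L < max_ir and rest[L] == comp[rest[len(rest) - 1 - L]]:
        L += 1
    return L


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    mate: int           # 1 or 2
    sequence: str
    origin: str         # conformer label
    start_1based: int   # fragment start on the conformer forward strand
    strand: str


@dataclass(frozen=True)
class SimulatedReadSet:
    reads: tuple
    read_len: int
    depth: float
    error_rate: float
    mixture: dict
    seed: int

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]

    def read_ids(self) -> list[str]:
        return [f"{r.read_id}/{r.mate}" for r in self.reads]

    def origin_counts(self) -> dict:
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.origin] = out.get(r.origin, 0) + 1
        return out


def simulate_reads(
    conformers: dict,
    mixture: dict,
    read_len: int = 150,
    depth: float = 50.0,
    error_rate: float = 0.0,
    insert_mean: int = 350,
    insert_sd: int = 35,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate paired-end reads from a mixture of circular conformers.

    ``conformers`` maps label -> sequence; ``mixture`` maps label ->
    molecule proportion (must sum to 1).  Fragment starts are uniform on each
    circle (origin-crossing fragments use circular indexing), fragments are
    assigned to conformers multinomially with probability proportional to
    proportion x length, and substitution errors are i.i.d. per base.
    Fully reproducible from the seed.
    """
    labels = list(conformers)
    if set(mixture) - set(labels):
        raise ValueError("mixture contains labels without sequences")
    props = np.array([float(mixture.get(l, 0.0)) for l in labels])
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("mixture proportions must be non-negative and sum to 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    seqs = {l: str(conformers[l]).upper() for l in labels}
    for l, s in seqs.items():
        if props[labels.index(l)] > 0 and read_len > len(s):
            raise ValueError(f"read_len {read_len} exceeds conformer {l!r} length")

    rng = np.random.default_rng(seed)
    lens = np.array([len(seqs[l]) for l in labels], dtype=float)
    weights = props * lens
    total_fragments = int(round(depth * float(weights.sum()) / (2 * read_len)))
    total_fragments = max(total_fragments, 1)
    counts = rng.multinomial(total_fragments, weights / weights.sum())

    reads = []
    frag_no = 0
    for label, cnt in zip(labels, counts):
        if cnt == 0:
            continue
        s = seqs[label]
        L = len(s)
        doubled = s + s
        starts = rng.integers(0, L, size=cnt)
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=cnt)).astype(int),
            read_len, L,
        )
        strands = rng.integers(0, 2, size=cnt)
        for start, ins, flip in zip(starts, inserts, strands):
            frag = doubled[start:start + ins]
            strand = "+"
            if flip:
                frag = reverse_complement(frag)
                strand = "-"
            frag_no += 1
            rid = f"sim{frag_no}"
            for mate, r in ((1, frag[:read_len]),
                            (2, reverse_complement(frag[-read_len:]))):
                if error_rate > 0:
                    r = _mutate(rng, r, error_rate)
                reads.append(ReadRecord(rid, mate, r, label, int(start) + 1, strand))
    return SimulatedReadSet(
        reads=tuple(reads), read_len=read_len, depth=depth,
        error_rate=error_rate, mixture=dict(mixture), seed=seed,
    )


_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _mutate(rng: np.random.Generator, read: str, rate: float) -> str:
    mask = rng.random(len(read)) < rate
    if not mask.any():
        return read
    chars = list(read)
    for pos in np.flatnonzero(mask):
        base = chars[pos]
        if base in _OTHER:
            chars[pos] = _OTHER[base][rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# I/O


def write_fastq_pair(read_set: SimulatedReadSet, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in read_set.reads:
            fh = f1 if r.mate == 1 else f2
            fh.write(f"@{r.read_id}/{r.mate}\n{r.sequence}\n+\n"
                     + "I" * len(r.sequence) + "\n")


def write_truth_tsv(read_set: SimulatedReadSet, path) -> None:
    lines = ["read_id\torigin\tstart_1based\tstrand"]
    for r in read_set.reads:
        lines.append(f"{r.read_id}/{r.mate}\t{r.origin}\t{r.start_1based}\t{r.strand}")
    Path(path).write_text("\n".join(lines) + "\n")
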