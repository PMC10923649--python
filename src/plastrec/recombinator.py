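"""Enumeration of repeat-mediated recombination conformers.

Given a quadripartite parent and a short inverted repeat pair inside its LSC,
the LSC is partitioned into areas A (start through the left arm), B (the
spacer) and C (right arm through the LSC end).  Five conformers are built by
event-driven crossovers and returned with explicitly spliced sequences:

* ``B-inversion`` — intramolecular crossover at the short repeat, area B
  reverse-complemented in place;
* ``intermediate-dimer`` — head-to-head fusion of two parent molecules
  through the short repeat (size doubles);
* ``A-type`` — resolution product with area A duplicated into both large-IR
  copies, area C deleted, and area B left as the residual single-copy LSC;
* ``reciprocal`` — the mass-conserving counterpart (area C duplicated, area A
  deleted); reported even though it may be selectively eliminated in vivo;
* ``flipflop-isomer`` — intramolecular crossover at the large IR (SSC
  inverted).

Crossovers are placed at the left edge of each arm, so one arm copy survives
in every product and |A| + |B| + |C| = LSC holds with the arms counted inside
areas A and C.  Conformer sequences are reported in canonical circular form
(rotation/strand normalised), so an independent splicing construction of the
same product compares byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .genome_model import (
    AmbiguousStructureError,
    CircularSequence,
    Interval,
    NoQuadripartiteError,
    PlastomeStructure,
    StructureMetrics,
    canonical_circular,
    compute_metrics,
    detect_quadripartite,
    reverse_complement,
    rotate,
)
from .repeat_finder import INVERTED, RepeatPair

CONFORMER_LABELS = (
    "flipflop-isomer",
    "B-inversion",
    "intermediate-dimer",
    "A-type",
    "reciprocal",
)

GENE_TYPES = ("protein", "tRNA", "rRNA")


@dataclass(frozen=True)
class Gene:
    name: str
    gtype: str
    start: int  # 0-based, parent canonical linearization
    end: int    # half-open
    strand: str = "+"

    def __post_init__(self):
        if self.gtype not in GENE_TYPES:
            raise ValueError(f"unknown gene type {self.gtype!r}")
        if self.end <= self.start:
            raise ValueError(f"empty gene interval for {self.name!r}")

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)


@dataclass(frozen=True)
class SegmentPartition:
    """The A/B/C decomposition of the LSC around an inverted repeat pair."""

    area_a: Interval
    area_b: Interval
    area_c: Interval
    repeat: RepeatPair
    lsc: Interval

    @property
    def len_a(self) -> int:
        return len(self.area_a)

    @property
    def len_b(self) -> int:
        return len(self.area_b)

    @property
    def len_c(self) -> int:
        return len(self.area_c)


@dataclass(frozen=True)
class RecombinationEvent:
    mechanism: str          # "intramolecular" | "intermolecular"
    repeat_used: str        # "short-repeat" | "large-IR"
    crossover: str = "left-edge"
    description: str = ""


@dataclass(frozen=True)
class Conformer:
    label: str
    events: tuple[RecombinationEvent, ...]
    sequence: CircularSequence
    predicted_metrics: Optional[StructureMetrics]
    parent_name: str
    degenerate: bool = False
    metrics_note: str = ""


@dataclass(frozen=True)
class GeneChangeReport:
    label: str
    deleted: tuple[Gene, ...]
    duplicated: tuple[Gene, ...]
    disrupted: tuple[Gene, ...]
    unchanged_count: int
    unique_before: dict
    unique_after: dict


# ---------------------------------------------------------------------------
# partition


def partition_lsc(structure: PlastomeStructure, repeat: RepeatPair) -> SegmentPartition:
    """Partition the LSC into areas A, B, C around an inverted repeat pair.

    Both arms must lie wholly inside the LSC (coordinates on the canonical
    linearization, where the LSC starts at 0) and the pair must be inverted.
    """
    if repeat.orientation != INVERTED:
        raise ValueError("partition requires an inverted repeat pair")
    lsc = structure.lsc
    for arm in (repeat.left_arm, repeat.right_arm):
        if not lsc.contains(arm):
            raise ValueError(
                f"repeat arm [{arm.start}, {arm.end}) not inside the LSC "
                f"[{lsc.start}, {lsc.end})"
            )
    area_a = Interval(lsc.start, repeat.left_arm.end)
    area_b = Interval(repeat.left_arm.end, repeat.right_arm.start)
    area_c = Interval(repeat.right_arm.start, lsc.end)
    part = SegmentPartition(area_a, area_b, area_c, repeat, lsc)
    assert part.len_a + part.len_b + part.len_c == len(lsc)
    return part


# ---------------------------------------------------------------------------
# event primitives (coordinate-level crossover operations)


def invert_between(seq: str, left_arm: Interval, right_arm: Interval) -> str:
    """Intramolecular crossover between two inverted arm copies with the
    breakpoint at each arm's left edge: the segment from the left arm start
    through the right arm end is reverse-complemented in place.  Because the
    arms are reverse complements of each other, both survive unchanged."""
    l, r = left_arm.start, right_arm.end
    return seq[:l] + reverse_complement(seq[l:r]) + seq[r:]


def fuse_through(seq1: str, left_arm: Interval, seq2: str, right_arm: Interval) -> str:
    """Intermolecular crossover between the left arm of molecule 1 and the
    (inverted) right arm of molecule 2; returns the fused circular dimer."""
    half1 = rotate(seq1, left_arm.start)
    rc2 = reverse_complement(seq2)
    half2 = rotate(rc2, len(seq2) - right_arm.end)
    return half1 + half2


def resolve_at(dimer: str, copy1_start: int, copy2_start: int) -> tuple[str, str]:
    """Intramolecular crossover between two *direct-orientation* repeat copies
    of a circular dimer, excising it into two circles; each product retains
    one copy."""
    if not 0 <= copy1_start < copy2_start < len(dimer):
        raise ValueError("repeat copies must be distinct positions in the dimer")
    return dimer[copy1_start:copy2_start], dimer[copy2_start:] + dimer[:copy1_start]


# ---------------------------------------------------------------------------
# closed-form size predictions


def predicted_sizes(label: str, len_a: int, len_b: int, len_c: int,
                    ir: int, ssc: int) -> dict:
    """Closed-form predicted sizes (bp) for a conformer label given the
    parent's partition and region lengths."""
    parent = len_a + len_b + len_c + 2 * ir + ssc
    if label == "A-type":
        return {"genome": parent + len_a - len_c, "ir": ir + len_a,
                "lsc": len_b, "ssc": ssc}
    if label == "reciprocal":
        return {"genome": parent + len_c - len_a, "ir": ir + len_c,
                "lsc": len_b, "ssc": ssc}
    if label == "intermediate-dimer":
        return {"genome": 2 * parent, "ir": None, "lsc": None, "ssc": None}
    if label in ("B-inversion", "flipflop-isomer"):
        return {"genome": parent, "ir": ir, "lsc": len_a + len_b + len_c, "ssc": ssc}
    raise ValueError(f"unknown conformer label {label!r}")


def percent_size_increase(parent_size: int, conformer_size: int) -> int:
    """Relative size change rounded to the nearest integer percent."""
    return round(100 * (conformer_size - parent_size) / parent_size)


# ---------------------------------------------------------------------------
# conformer enumeration


def _metrics_for(label: str, seq: str, structure: PlastomeStructure,
                 hint: Optional[str]) -> tuple[Optional[StructureMetrics], str]:
    min_ir = max(50, len(structure.irb))
    try:
        sub = detect_quadripartite(seq, min_ir_len=min_ir, lsc_hint=hint,
                                   name=label)
    except (NoQuadripartiteError, AmbiguousStructureError, ValueError) as exc:
        return None, f"structure not re-detected: {exc}"
    return compute_metrics(sub), ""


def enumerate_conformers(
    structure: PlastomeStructure,
    partition: SegmentPartition,
    with_metrics: bool = True,
) -> list[Conformer]:
    """Enumerate the five recombination conformers of a partitioned parent.

    Degenerate partitions (an area reduced to the bare arm, or an empty
    spacer) are emitted flagged rather than suppressed.  Each conformer's
    metrics are recomputed from its spliced sequence by structure detection
    with the homology-based LSC label override; for the dimer, detection is
    genuinely ambiguous (four large-IR copies) and metrics degrade to size
    only.
    """
    parent = structure.sequence.residues
    n = len(parent)
    rep = partition.repeat
    m = rep.arm_len
    a, b, c = partition.len_a, partition.len_b, partition.len_c
    ir, ssc = len(structure.irb), len(structure.ssc)
    area_b_seq = parent[partition.area_b.start:partition.area_b.end]
    lsc_seq = structure.region_seq("lsc")
    degenerate = a == m or c == m or b == 0

    short_intra = RecombinationEvent("intramolecular", "short-repeat",
                                     description="invert spacer between arms")
    fuse_ev = RecombinationEvent("intermolecular", "short-repeat",
                                 description="head-to-head fusion of two parents")
    resolve_ev = RecombinationEvent("intramolecular", "large-IR",
                                    description="excision of the dimer at direct large-IR copies")
    flip_ev = RecombinationEvent("intramolecular", "large-IR",
                                 description="flip-flop inversion of the SSC")

    flip_seq = invert_between(parent, structure.irb, structure.ira)
    binv_seq = invert_between(parent, rep.left_arm, rep.right_arm)
    dimer_seq = fuse_through(parent, rep.left_arm, parent, rep.right_arm)
    # direct-orientation large-IR copies in the dimer: the IRa copy of each
    # fused half (bookkeeping from the fusion layout)
    copy1 = structure.ira.start - rep.left_arm.start
    copy2 = n + m + b + a + ir + ssc
    p1_seq, p2_seq = resolve_at(dimer_seq, copy1, copy2)

    exp = {label: predicted_sizes(label, a, b, c, ir, ssc)["genome"]
           for label in CONFORMER_LABELS}
    built = {
        "flipflop-isomer": (flip_seq, (flip_ev,), lsc_seq),
        "B-inversion": (binv_seq, (short_intra,),
                        parent[:partition.area_b.start] + reverse_complement(area_b_seq)
                        + parent[partition.area_b.end:partition.lsc.end]),
        "intermediate-dimer": (dimer_seq, (fuse_ev,), None),
        "A-type": (p1_seq, (fuse_ev, resolve_ev), area_b_seq or None),
        "reciprocal": (p2_seq, (fuse_ev, resolve_ev), area_b_seq or None),
    }

    out = []
    for label in CONFORMER_LABELS:
        seq, events, hint = built[label]
        if len(seq) != exp[label]:
            raise AssertionError(
                f"{label}: spliced length {len(seq)} != closed form {exp[label]}"
            )
        canon = canonical_circular(seq)
        metrics, note = (None, "metrics skipped")
        if with_metrics:
            metrics, note = _metrics_for(label, canon, structure, hint)
        out.append(Conformer(
            label=label,
            events=events,
            sequence=CircularSequence(f"{structure.sequence.name}|{label}", canon),
            predicted_metrics=metrics,
            parent_name=structure.sequence.name,
            degenerate=degenerate and label in ("A-type", "reciprocal", "B-inversion"),
            metrics_note=note,
        ))
    return out


# ---------------------------------------------------------------------------
# gene gain/loss


def _unique_counts(genes: Iterable[Gene]) -> dict:
    names: dict[str, set] = {t: set() for t in GENE_TYPES}
    for g in genes:
        names[g.gtype].add(g.name)
    return {t: len(names[t]) for t in GENE_TYPES}


def predict_gene_changes(
    partition: SegmentPartition,
    conformer_label: str,
    annotation: Sequence[Gene],
    genome_length: Optional[int] = None,
) -> GeneChangeReport:
    """Classify parent genes as deleted / duplicated / disrupted / unchanged
    for a conformer.

    For ``A-type``: any overlap (>= 1 bp) with area C deletes a gene; genes
    wholly inside area A are duplicated (they enter both large-IR copies);
    genes spanning the A/B or B/C boundary without touching the lost area are
    reported as disrupted.  ``reciprocal`` mirrors this with areas swapped.
    """
    if conformer_label not in CONFORMER_LABELS:
        raise ValueError(f"unknown conformer label {conformer_label!r}")
    if genome_length is not None:
        for g in annotation:
            if g.end > genome_length:
                raise ValueError(
                    f"gene {g.name!r} interval [{g.start}, {g.end}) outside "
                    f"the genome of length {genome_length}"
                )

    if conformer_label in ("A-type", "reciprocal"):
        lost = partition.area_c if conformer_label == "A-type" else partition.area_a
        gained = partition.area_a if conformer_label == "A-type" else partition.area_c
        deleted, duplicated, disrupted, unchanged = [], [], [], []
        for g in annotation:
            iv = g.interval
            if iv.overlaps(lost):
                deleted.append(g)
            elif iv.overlaps(partition.area_b) and not partition.area_b.contains(iv):
                disrupted.append(g)
            elif gained.contains(iv):
                duplicated.append(g)
            else:
                unchanged.append(g)
    elif conformer_label == "intermediate-dimer":
        deleted, disrupted, unchanged = [], [], []
        duplicated = list(annotation)
    else:  # B-inversion, flipflop-isomer: content preserved
        inverted_span = (partition.area_b if conformer_label == "B-inversion"
                         else None)
        deleted, duplicated, disrupted, unchanged = [], [], [], []
        for g in annotation:
            if (inverted_span is not None and g.interval.overlaps(inverted_span)
                    and not inverted_span.contains(g.interval)):
                disrupted.append(g)
            else:
                unchanged.append(g)

    before = _unique_counts(annotation)
    deleted_names = {t: {g.name for g in deleted if g.gtype == t} for t in GENE_TYPES}
    after = {t: before[t] - len(deleted_names[t]) for t in GENE_TYPES}
    return GeneChangeReport(
        label=conformer_label,
        deleted=tuple(deleted),
        duplicated=tuple(duplicated),
        disrupted=tuple(disrupted),
        unchanged_count=len(unchanged),
        unique_before=before,
        unique_after=after,
    )


# ---------------------------------------------------------------------------
# annotation input


def _classify(name: str, feature_type: str) -> str:
    if feature_type == "tRNA" or name.lower().startswith("trn"):
        return "tRNA"
    if feature_type == "rRNA" or name.lower().startswith("rrn"):
        return "rRNA"
    return "protein"


def read_genbank_genes(path) -> list[Gene]:
    """Gene annotation from a GenBank flat file (gene/CDS/tRNA/rRNA features)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "genbank"))
    genes = []
    for feat in record.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        genes.append(Gene(
            name=name,
            gtype=_classify(name, feat.type),
            start=int(feat.location.start),
            end=int(feat.location.end),
            strand="-" if feat.location.strand == -1 else "+",
        ))
    seen = set()
    out = []
    for g in sorted(genes, key=lambda g: (g.start, g.end, g.name)):
        key = (g.name, g.start, g.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(g)
    return out


def read_gff3_genes(path) -> list[Gene]:
    """Gene annotation from GFF3 (gene/tRNA/rRNA/CDS features)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for ftype in ("gene", "tRNA", "rRNA", "CDS"):
        for feat in db.features_of_type(ftype):
            name = (feat.attributes.get("Name")
                    or feat.attributes.get("gene")
                    or feat.attributes.get("ID") or ["?"])[0]
            genes.append(Gene(
                name=name,
                gtype=_classify(name, ftype),
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or "+",
            ))
    seen = set()
    out = []
    for g in sorted(genes, key=lambda g: (g.start, g.end, g.name)):
        key = (g.name, g.start, g.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(g)
    return out


def read_annotation(path) -> list[Gene]:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".gbf", ".genbank"):
        return read_genbank_genes(path)
    return read_gff3_genes(path)


# ---------------------------------------------------------------------------
# reports


def write_conformer_fasta(conformers: Iterable[Conformer], path, width: int = 70) -> None:
    from .genome_model import write_fasta

    write_fasta((c.sequence for c in conformers), path, width=width)


def conformer_to_dict(c: Conformer) -> dict:
    d = {
        "label": c.label,
        "parent": c.parent_name,
        "size": c.sequence.length,
        "degenerate": c.degenerate,
        "events": [
            {"mechanism": e.mechanism, "repeat": e.repeat_used,
             "crossover": e.crossover, "description": e.description}
            for e in c.events
        ],
    }
    if c.predicted_metrics is not None:
        pm = c.predicted_metrics
        d["predicted_metrics"] = {
            "genome_size": pm.genome_size, "lsc_size": pm.lsc_size,
            "ssc_size": pm.ssc_size, "ir_size": pm.ir_size,
            "gc_total": pm.gc_total,
        }
    else:
        d["predicted_metrics"] = None
        d["metrics_note"] = c.metrics_note
    return d


def write_event_log(conformers: Iterable[Conformer], path) -> None:
    Path(path).write_text(
        json.dumps([conformer_to_dict(c) for c in conformers], indent=2) + "\n"
    )


def write_gene_change_tsv(reports: Iterable[GeneChangeReport], path) -> None:
    lines = ["conformer\tcategory\tgene\ttype\tstart_1based\tend"]
    for rep in reports:
        for cat, genes in (("deleted", rep.deleted), ("duplicated", rep.duplicated),
                           ("disrupted", rep.disrupted)):
            for g in genes:
                lines.append(f"{rep.label}\t{cat}\t{g.name}\t{g.gtype}"
                             f"\t{g.start + 1}\t{g.end}")
        for t in GENE_TYPES:
            lines.append(f"{rep.label}\tunique_{t}\t-\t-"
                         f"\t{rep.unique_before[t]}\t{rep.unique_after[t]}")
    Path(path).write_text("\n".join(lines) + "\n")
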