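"""Short direct/inverted repeat pair discovery inside a linear region.

These short repeat pairs are the recombination substrates; matching is exact
and pairs are *maximal*: the coupled arm extension (outward, or inward into
the spacer) cannot proceed while preserving the orientation relation.
Overlapping arms (negative spacer) are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

from .genome_model import Interval, _check_alphabet, _COMPLEMENT, reverse_complement

INVERTED = "inverted"
DIRECT = "direct"

#: below this arm length nearly every sequence position pairs by chance
MIN_SUPPORTED_ARM = 4

_SEED_CAP = 21


@dataclass(frozen=True)
class RepeatPair:
    """Two equal-length arms; for inverted pairs the right arm is the exact
    reverse complement of the left arm, for direct pairs its exact copy."""

    arm_len: int
    left_arm: Interval
    right_arm: Interval
    orientation: str
    spacer_len: int
    left_seq: str
    right_seq: str
    n_equivalent_placements: int = 1

    def __post_init__(self):
        if self.arm_len != len(self.left_arm) or self.arm_len != len(self.right_arm):
            raise ValueError("arm_len inconsistent with arm intervals")
        if self.left_arm.end > self.right_arm.start:
            raise ValueError("left arm must strictly precede the right arm")
        if self.spacer_len != self.right_arm.start - self.left_arm.end:
            raise ValueError("spacer_len inconsistent with arm intervals")
        if self.orientation == INVERTED:
            if self.right_seq != reverse_complement(self.left_seq):
                raise ValueError("inverted pair arms are not reverse complements")
        elif self.orientation == DIRECT:
            if self.right_seq != self.left_seq:
                raise ValueError("direct pair arms differ")
        else:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def key(self) -> tuple:
        return (self.orientation, self.left_arm.start, self.right_arm.start, self.arm_len)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


def _inverted_run(seq: str, comp: str, d: int, p: int) -> tuple[int, int]:
    """Maximal run around ``p`` on anti-diagonal ``d`` of the inverted-match
    relation seq[p] == complement(seq[d-p])."""
    n = len(seq)
    lo_bound = max(0, d - n + 1)
    hi_bound = min(n - 1, d)
    p0 = p1 = p
    while p0 - 1 >= lo_bound and seq[p0 - 1] == comp[d - p0 + 1]:
        p0 -= 1
    while p1 + 1 <= hi_bound and seq[p1 + 1] == comp[d - p1 - 1]:
        p1 += 1
    return p0, p1


def _direct_run(seq: str, c: int, p: int) -> tuple[int, int]:
    """Maximal run around ``p`` of the direct-match relation
    seq[p] == seq[p + c]."""
    hi_bound = len(seq) - c - 1
    p0 = p1 = p
    while p0 - 1 >= 0 and seq[p0 - 1] == seq[p0 - 1 + c]:
        p0 -= 1
    while p1 + 1 <= hi_bound and seq[p1 + 1] == seq[p1 + 1 + c]:
        p1 += 1
    return p0, p1


def _covered(runs: Optional[list[tuple[int, int]]], p: int) -> bool:
    return bool(runs) and any(lo <= p <= hi for lo, hi in runs)


def _make_pair(seq: str, orientation: str, i: int, j: int, arm: int,
               spacer: int) -> RepeatPair:
    return RepeatPair(
        arm_len=arm,
        left_arm=Interval(i, i + arm),
        right_arm=Interval(j, j + arm),
        orientation=orientation,
        spacer_len=spacer,
        left_seq=seq[i:i + arm],
        right_seq=seq[j:j + arm],
    )


def _find_inverted(seq: str, comp: str, min_arm: int, max_arm: int,
                   min_spacer: int, max_spacer: int) -> list[RepeatPair]:
    n = len(seq)
    k = min(min_arm, _SEED_CAP)
    index = _kmer_index(seq, k)
    covered: dict[int, list[tuple[int, int]]] = {}
    out: list[RepeatPair] = []
    for i in range(n - k + 1):
        key = comp[i:i + k][::-1]  # reverse complement of the left-arm seed
        hits = index.get(key)
        if not hits:
            continue
        for j in hits:
            if j < i:
                continue
            d = i + j + k - 1
            runs = covered.setdefault(d, [])
            if _covered(runs, i):
                continue
            p0, p1 = _inverted_run(seq, comp, d, i)
            runs.append((p0, p1))
            p1c = min(p1, (d - 1) // 2)  # arms must not overlap
            if p1c < p0:
                continue
            arm = p1c - p0 + 1
            spacer = d - 2 * p1c - 1
            if min_arm <= arm <= max_arm and min_spacer <= spacer <= max_spacer:
                out.append(_make_pair(seq, INVERTED, p0, d - p1c, arm, spacer))
    return out


def _find_direct(seq: str, min_arm: int, max_arm: int,
                 min_spacer: int, max_spacer: int) -> list[RepeatPair]:
    n = len(seq)
    k = min(min_arm, _SEED_CAP)
    index = _kmer_index(seq, k)
    covered: dict[int, list[tuple[int, int]]] = {}
    out: list[RepeatPair] = []
    for i in range(n - k + 1):
        hits = index.get(seq[i:i + k])
        if not hits:
            continue
        for j in hits:
            if j <= i:
                continue
            c = j - i
            runs = covered.setdefault(c, [])
            if _covered(runs, i):
                continue
            p0, p1 = _direct_run(seq, c, i)
            runs.append((p0, p1))
            run_len = p1 - p0 + 1
            if run_len <= c:
                arm, spacer = run_len, c - run_len
                if min_arm <= arm <= max_arm and min_spacer <= spacer <= max_spacer:
                    out.append(_make_pair(seq, DIRECT, p0, p0 + c, arm, spacer))
            else:
                # tandem-style run: every spacer-0 placement of a c-long arm
                # inside the run is maximal
                if min_arm <= c <= max_arm and min_spacer <= 0 <= max_spacer:
                    for a in range(p0, p1 - c + 2):
                        out.append(_make_pair(seq, DIRECT, a, a + c, c, 0))
    return out


def _annotate_equivalents(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Count, per pair, the equal-length same-orientation placements whose
    arms overlap it (homopolymer sliding ambiguity)."""
    out = []
    for p in pairs:
        count = sum(
            1
            for q in pairs
            if q.orientation == p.orientation
            and q.arm_len == p.arm_len
            and q.left_arm.overlaps(p.left_arm)
            and q.right_arm.overlaps(p.right_arm)
        )
        out.append(replace(p, n_equivalent_placements=count))
    return out


def find_repeat_pairs(
    seq: str,
    min_arm: int = 8,
    max_arm: Optional[int] = None,
    min_spacer: int = 0,
    max_spacer: int = 10_000,
    orientation: str = "both",
) -> list[RepeatPair]:
    """All maximal repeat pairs with arm length in [min_arm, max_arm] and
    spacer in [min_spacer, max_spacer], sorted by (left arm start, spacer).

    ``min_arm`` below 4 is rejected (spurious-match regime).
    """
    seq = seq.upper()
    if not seq:
        return []
    _check_alphabet(seq)
    if min_arm < MIN_SUPPORTED_ARM:
        raise ValueError(f"min_arm must be >= {MIN_SUPPORTED_ARM}")
    n = len(seq)
    if max_arm is None:
        max_arm = n
    if min_arm > max_arm:
        raise ValueError("min_arm exceeds max_arm")
    if min_spacer < 0 or min_spacer > max_spacer:
        raise ValueError("require 0 <= min_spacer <= max_spacer")
    if orientation not in (INVERTED, DIRECT, "both"):
        raise ValueError(f"unknown orientation {orientation!r}")

    comp = seq.translate(_COMPLEMENT)
    pairs: list[RepeatPair] = []
    if orientation in (INVERTED, "both"):
        pairs.extend(_find_inverted(seq, comp, min_arm, max_arm, min_spacer, max_spacer))
    if orientation in (DIRECT, "both"):
        pairs.extend(_find_direct(seq, min_arm, max_arm, min_spacer, max_spacer))
    # distinct seeds can rediscover a pair after clamping; dedupe defensively
    seen: dict[tuple, RepeatPair] = {}
    for p in pairs:
        seen.setdefault(p.key(), p)
    pairs = _annotate_equivalents(list(seen.values()))
    pairs.sort(key=lambda p: (p.left_arm.start, p.spacer_len, p.orientation))
    return pairs


def maximalize(pair: RepeatPair, seq: str) -> RepeatPair:
    """Extend the arms of ``pair`` outward then inward as far as the
    orientation relation holds.  Idempotent; for direct tandem runs the
    leftmost equal-length placement is returned."""
    seq = seq.upper()
    _check_alphabet(seq)
    comp = seq.translate(_COMPLEMENT)
    i = pair.left_arm.start
    if pair.orientation == INVERTED:
        d = pair.left_arm.start + pair.right_arm.end - 1
        p0, p1 = _inverted_run(seq, comp, d, i)
        p1c = min(p1, (d - 1) // 2)
        arm = p1c - p0 + 1
        return _make_pair(seq, INVERTED, p0, d - p1c, arm, d - 2 * p1c - 1)
    c = pair.right_arm.start - pair.left_arm.start
    p0, p1 = _direct_run(seq, c, i)
    run_len = p1 - p0 + 1
    arm = min(run_len, c)
    return _make_pair(seq, DIRECT, p0, p0 + c, arm, c - arm)


# ---------------------------------------------------------------------------
# reports

_TSV_HEADER = (
    "arm_len\tleft_start_1based\tleft_end\tright_start\tright_end\t"
    "orientation\tspacer_len\tleft_seq\tn_equivalent_placements"
)


def pair_to_dict(pair: RepeatPair) -> dict:
    return {
        "arm_len": pair.arm_len,
        "left_start_1based": pair.left_arm.start + 1,
        "left_end": pair.left_arm.end,
        "right_start": pair.right_arm.start + 1,
        "right_end": pair.right_arm.end,
        "orientation": pair.orientation,
        "spacer_len": pair.spacer_len,
        "left_seq": pair.left_seq,
        "right_seq": pair.right_seq,
        "n_equivalent_placements": pair.n_equivalent_placements,
    }


def write_repeat_tsv(pairs: Iterable[RepeatPair], path) -> None:
    lines = [_TSV_HEADER]
    for p in pairs:
        d = pair_to_dict(p)
        lines.append("\t".join(str(d[c]) for c in _TSV_HEADER.split("\t")))
    Path(path).write_text("\n".join(lines) + "\n")


def write_repeat_json(pairs: Iterable[RepeatPair], path) -> None:
    Path(path).write_text(json.dumps([pair_to_dict(p) for p in pairs], indent=2) + "\n")
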