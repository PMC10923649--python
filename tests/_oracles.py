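"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the seed-and-extend machinery of the package: the
repeat oracle enumerates every (left, right, arm-length) triple with string
slicing and checks the maximality conditions directly.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_repeat_pairs(seq: str, min_arm: int, max_arm: int | None = None,
                             min_spacer: int = 0, max_spacer: int | None = None,
                             orientation: str = "both") -> set:
    """All maximal repeat pairs by exhaustive enumeration.

    Returns a set of (orientation, left_start, right_start, arm_len, spacer)
    tuples.  A pair is maximal when neither the outward nor the inward
    coupled arm extension preserves the orientation relation.
    """
    n = len(seq)
    if max_arm is None:
        max_arm = n
    if max_spacer is None:
        max_spacer = n
    comp = seq.translate(_COMP)
    out = set()

    if orientation in ("inverted", "both"):
        for i in range(n):
            for j in range(i + 1, n):
                top = min(j - i, n - j, max_arm)
                for L in range(min_arm, top + 1):
                    if seq[j] != comp[i + L - 1]:  # cheap prefilter
                        continue
                    if seq[j:j + L] != _rc(seq[i:i + L]):
                        continue
                    sp = j - i - L
                    if not (min_spacer <= sp <= max_spacer):
                        continue
                    outward = i > 0 and j + L < n and seq[i - 1] == comp[j + L]
                    inward = sp >= 2 and seq[i + L] == comp[j - 1]
                    if not outward and not inward:
                        out.add(("inverted", i, j, L, sp))

    if orientation in ("direct", "both"):
        for i in range(n):
            for j in range(i + 1, n):
                top = min(j - i, n - j, max_arm)
                for L in range(min_arm, top + 1):
                    if seq[j:j + L] != seq[i:i + L]:
                        continue
                    sp = j - i - L
                    if not (min_spacer <= sp <= max_spacer):
                        continue
                    left_ext = i > 0 and sp >= 1 and seq[i - 1] == seq[j - 1]
                    right_ext = j + L < n and sp >= 1 and seq[i + L] == seq[j + L]
                    if not left_ext and not right_ext:
                        out.add(("direct", i, j, L, sp))
    return out


def pairs_as_tuples(pairs) -> set:
    """find_repeat_pairs output in the oracle's tuple form."""
    return {
        (p.orientation, p.left_arm.start, p.right_arm.start, p.arm_len, p.spacer_len)
        for p in pairs
    }
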