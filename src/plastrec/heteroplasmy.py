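"""Depth-arithmetic heteroplasmy estimation.

With reads mapped to the parent (G-type) reference, area C is present only
in the parent conformer while the SSC is present in both, so:

    depth(G-type) = mean depth over area C
    depth(A-type) = mean depth over SSC - depth(G-type)

Depth is attributed by region means (area B is excluded throughout: its
observed depth is biased by hairpin formation, which is not modelled).  Ends
of each region are trimmed to dodge mapping edge effects.  Standard errors
use block means to account for the read-length autocorrelation of per-base
depth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .genome_model import Interval, PlastomeStructure, reverse_complement
from .recombinator import SegmentPartition

DEFAULT_TRIM = 50
DEFAULT_BLOCK = 150


@dataclass
class DepthProfile:
    """Per-position read depth over a reference (0-based internally)."""

    name: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class RegionDepth:
    mean: float
    sd: float
    n: int
    se: float  # block-mean standard error


@dataclass(frozen=True)
class HeteroplasmyEstimate:
    depth_g: float
    depth_a: float
    prop_g: float
    prop_a: float
    depth_a_raw: float
    depth_a_se: float
    z_a: float
    regions_used: dict
    dispersion: dict
    floored: bool
    inconsistent: bool


def region_depth(profile: DepthProfile, region: Interval, trim: int = 0,
                 block: int = DEFAULT_BLOCK) -> RegionDepth:
    """Mean and sd of per-position depth over ``region`` after trimming
    ``trim`` bp from each end."""
    if region.end > profile.length or region.start < 0:
        raise ValueError("region outside the reference")
    if trim < 0 or 2 * trim >= len(region):
        raise ValueError("region empty after trimming")
    vals = profile.depth[region.start + trim:region.end - trim]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    nb = max(1, vals.size // block)
    blocks = np.array_split(vals[: nb * block], nb) if vals.size >= block else [vals]
    bm = np.array([b.mean() for b in blocks], dtype=float)
    se = float(bm.std(ddof=1) / math.sqrt(len(bm))) if len(bm) > 1 else sd
    return RegionDepth(mean=mean, sd=sd, n=int(vals.size), se=se)


def _auto_trim(region: Interval, trim: int) -> int:
    return min(trim, max(0, (len(region) - 1) // 2))


def estimate_heteroplasmy(
    profile: DepthProfile,
    partition: SegmentPartition,
    structure: PlastomeStructure,
    trim: int = DEFAULT_TRIM,
) -> HeteroplasmyEstimate:
    """Estimate G-/A-type depths and proportions from a depth profile
    computed against the parent reference."""
    if profile.length != structure.sequence.length:
        raise ValueError("depth profile length differs from the reference length")
    c_trim = _auto_trim(partition.area_c, trim)
    s_trim = _auto_trim(structure.ssc, trim)
    c_stats = region_depth(profile, partition.area_c, trim=c_trim)
    s_stats = region_depth(profile, structure.ssc, trim=s_trim)

    depth_g = c_stats.mean
    depth_a_raw = s_stats.mean - depth_g
    se = math.sqrt(c_stats.se ** 2 + s_stats.se ** 2)
    z_a = depth_a_raw / se if se > 0 else (0.0 if depth_a_raw == 0 else math.inf)
    floored = depth_a_raw < 0
    depth_a = max(0.0, depth_a_raw)
    pooled_sd = math.sqrt(c_stats.sd ** 2 + s_stats.sd ** 2)
    inconsistent = depth_g - s_stats.mean > 3 * pooled_sd

    total = depth_g + depth_a
    if total > 0:
        prop_g, prop_a = depth_g / total, depth_a / total
    else:
        prop_g = prop_a = float("nan")

    return HeteroplasmyEstimate(
        depth_g=depth_g,
        depth_a=depth_a,
        prop_g=prop_g,
        prop_a=prop_a,
        depth_a_raw=depth_a_raw,
        depth_a_se=se,
        z_a=z_a,
        regions_used={
            "area_c": (partition.area_c.start, partition.area_c.end, c_trim),
            "ssc": (structure.ssc.start, structure.ssc.end, s_trim),
        },
        dispersion={"area_c_sd": c_stats.sd, "ssc_sd": s_stats.sd,
                    "area_c_se": c_stats.se, "ssc_se": s_stats.se},
        floored=floored,
        inconsistent=inconsistent,
    )


# ---------------------------------------------------------------------------
# presence calls


@dataclass(frozen=True)
class PresenceCall:
    conformer: str
    present: bool
    depth_evidence: float
    read_evidence: int
    threshold_depth: float
    threshold_reads: int


def detect_presence(
    estimate: Optional[HeteroplasmyEstimate] = None,
    support: Optional[dict] = None,
    threshold_depth: Optional[float] = None,
    threshold_reads: int = 1,
) -> dict[str, PresenceCall]:
    """Call each conformer present or absent.

    A conformer is present when its diagnostic depth reaches the depth
    threshold OR its diagnostic junction has at least ``threshold_reads``
    spanning reads.  When ``threshold_depth`` is None an adaptive threshold
    of 4 standard errors of the depth estimate is used, so pure-parent noise
    (|z| < 4) is called absent.  Both evidence values are always reported.
    """
    if threshold_reads < 0 or (threshold_depth is not None and threshold_depth < 0):
        raise ValueError("thresholds must be non-negative")
    support = support or {}

    def n_span(label: str) -> int:
        sc = support.get(label)
        return sc.n_spanning if sc is not None else 0

    calls = {}
    if estimate is not None:
        thr_a = threshold_depth if threshold_depth is not None else 4 * estimate.depth_a_se
        thr_g = threshold_depth if threshold_depth is not None else 4 * estimate.depth_a_se
        depth_g, depth_a = estimate.depth_g, estimate.depth_a
    else:
        thr_a = thr_g = threshold_depth if threshold_depth is not None else math.inf
        depth_g = depth_a = 0.0
    calls["G-type"] = PresenceCall(
        "G-type",
        depth_g >= thr_g or n_span("G-type") >= max(threshold_reads, 1),
        depth_g, n_span("G-type"), thr_g, threshold_reads,
    )
    calls["A-type"] = PresenceCall(
        "A-type",
        depth_a >= thr_a or n_span("A-type") >= max(threshold_reads, 1),
        depth_a, n_span("A-type"), thr_a, threshold_reads,
    )
    return calls


# ---------------------------------------------------------------------------
# lightweight read mapper (depth from raw reads, no external aligner)

_MAP_K = 21


def depth_from_reads(
    reads,
    reference: Union[str, PlastomeStructure],
    max_mismatch: int = 5,
    name: Optional[str] = None,
) -> DepthProfile:
    """Per-position depth by ungapped, k-mer-anchored mapping of reads to a
    circular reference.

    Each read (or its reverse complement) is placed at the anchor-compatible
    position with the fewest mismatches; ties go to the lowest coordinate, so
    reads from either large-IR copy pile onto the first copy (document: the
    depth arithmetic only consumes single-copy regions).  Junction-spanning
    reads fail to place and are dropped.
    """
    if isinstance(reference, PlastomeStructure):
        ref = reference.sequence.residues
        name = name or reference.sequence.name
    else:
        ref = str(reference).upper()
        name = name or "reference"
    n = len(ref)
    sd = ref + ref
    index: dict[str, list[int]] = {}
    for i in range(len(sd) - _MAP_K + 1):
        index.setdefault(sd[i:i + _MAP_K], []).append(i)

    depth = np.zeros(n, dtype=np.int64)
    seqs = reads.sequences() if hasattr(reads, "sequences") else reads
    for read in seqs:
        read = str(read).upper()
        if len(read) < _MAP_K or len(read) > n:
            continue
        best = None  # (mismatches, start)
        for r in (read, reverse_complement(read)):
            anchors = [0, len(r) // 2, len(r) - _MAP_K]
            cands = set()
            for q in anchors:
                for rp in index.get(r[q:q + _MAP_K], ()):
                    cands.add((rp - q) % n)
            for start in sorted(cands):
                window = sd[start:start + len(r)]
                mism = sum(1 for x, y in zip(r, window) if x != y)
                if mism <= max_mismatch and (best is None or (mism, start) < best[:2]):
                    best = (mism, start, len(r))
        if best is None:
            continue
        _, start, ln = best
        end = start + ln
        if end <= n:
            depth[start:end] += 1
        else:
            depth[start:] += 1
            depth[:end - n] += 1
    return DepthProfile(name, depth)


# ---------------------------------------------------------------------------
# I/O


def read_depth_table(path, reference_length: Optional[int] = None,
                     reference_name: Optional[str] = None) -> DepthProfile:
    """Three-column depth table (reference, 1-based position, depth), as
    produced by standard depth utilities; absent positions are depth 0."""
    name = reference_name
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            ref, pos, dp = parts[0], parts[1], parts[2]
            if name is None:
                name = ref
            elif ref != name:
                if reference_name is not None:
                    raise ValueError(
                        f"{path}:{lineno}: reference {ref!r} does not match "
                        f"expected {reference_name!r}"
                    )
                raise ValueError(f"{path}:{lineno}: multiple references in table")
            try:
                rows.append((int(pos), int(dp)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: empty depth table")
    length = reference_length or max(p for p, _ in rows)
    depth = np.zeros(length, dtype=np.int64)
    for pos, dp in rows:
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside reference of length {length}")
        depth[pos - 1] = dp
    return DepthProfile(name or "reference", depth)


def write_depth_table(profile: DepthProfile, path) -> None:
    with open(path, "w") as fh:
        for i, dp in enumerate(profile.depth, 1):
            fh.write(f"{profile.name}\t{i}\t{int(dp)}\n")


def estimate_to_dict(est: HeteroplasmyEstimate) -> dict:
    return {
        "depth_g": est.depth_g,
        "depth_a": est.depth_a,
        "prop_g": est.prop_g,
        "prop_a": est.prop_a,
        "depth_a_raw": est.depth_a_raw,
        "depth_a_se": est.depth_a_se,
        "z_a": est.z_a,
        "regions_used": est.regions_used,
        "dispersion": est.dispersion,
        "floored": est.floored,
        "inconsistent": est.inconsistent,
    }


def write_estimate_json(est: HeteroplasmyEstimate, path) -> None:
    Path(path).write_text(json.dumps(estimate_to_dict(est), indent=2) + "\n")


def write_estimate_tsv(est: HeteroplasmyEstimate, path) -> None:
    d = estimate_to_dict(est)
    keys = ["depth_g", "depth_a", "prop_g", "prop_a", "depth_a_raw",
            "depth_a_se", "z_a", "floored", "inconsistent"]
    lines = ["\t".join(keys), "\t".join(str(d[k]) for k in keys)]
    Path(path).write_text("\n".join(lines) + "\n")
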