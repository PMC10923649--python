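"""Command-line interface and end-to-end pipeline composition.

Stages run in order structure -> repeats -> partition -> conformers -> gene
changes -> junctions -> heteroplasmy, skipping stages whose inputs are
absent.  All results go into a machine-readable run report (JSON); the
rendered text report contains nothing that is not in the run report, and
re-running with the same config and seed reproduces both byte-identically.
Logging goes to standard error; results only to files/standard output.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import click
import yaml

from . import __version__
from .genome_model import (
    AmbiguousStructureError,
    NoQuadripartiteError,
    compute_metrics,
    detect_quadripartite,
    read_fasta,
    structure_report,
    write_fasta,
    write_structure_bed,
    write_structure_json,
)
from .heteroplasmy import (
    depth_from_reads,
    detect_presence,
    estimate_heteroplasmy,
    estimate_to_dict,
    read_depth_table,
    write_estimate_json,
    write_estimate_tsv,
)
from .junction_support import (
    build_junction_refs,
    read_fastq_pair,
    support_table,
    write_junction_fasta,
    write_support_tsv,
)
from .recombinator import (
    conformer_to_dict,
    enumerate_conformers,
    partition_lsc,
    predict_gene_changes,
    read_annotation,
    write_conformer_fasta,
    write_event_log,
    write_gene_change_tsv,
)
from .repeat_finder import find_repeat_pairs, pair_to_dict, write_repeat_json, write_repeat_tsv
from .synthetic_data import (
    ToySpec,
    make_toy_plastome,
    simulate_reads,
    write_fastq_pair,
    write_truth_tsv,
)


@dataclass
class RunConfig:
    """Validated parameters for an end-to-end run."""

    reference: str = ""
    annotation: Optional[str] = None
    reads1: Optional[str] = None
    reads2: Optional[str] = None
    depth_table: Optional[str] = None
    outdir: str = "plastrec_out"
    min_ir_len: int = 1000
    allow_mismatch: int = 0
    min_arm: int = 8
    max_arm: Optional[int] = None
    min_spacer: int = 0
    max_spacer: int = 10_000
    flank_len: int = 300
    min_overhang: Optional[int] = None  # None: per-junction recommended value
    max_mismatch: int = 0
    trim: int = 50
    threshold_depth: Optional[float] = None
    threshold_reads: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not self.reference:
            raise ValueError("a reference FASTA is required")
        if self.min_ir_len < 50:
            raise ValueError("min_ir_len must be >= 50")
        if self.min_arm < 4:
            raise ValueError("min_arm must be >= 4")
        if self.min_spacer < 0 or self.min_spacer > self.max_spacer:
            raise ValueError("require 0 <= min_spacer <= max_spacer")
        if self.flank_len < 1:
            raise ValueError("flank_len must be positive")
        if self.min_overhang is not None and self.min_overhang > self.flank_len:
            raise ValueError("min_overhang cannot exceed flank_len")
        if self.trim < 0:
            raise ValueError("trim must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _log(msg: str) -> None:
    print(f"[plastrec] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline described by ``config`` and return the run
    report; outputs are also written under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "notices": [],
    }

    _log(f"reading reference {config.reference}")
    records = read_fasta(config.reference)
    if len(records) > 1:
        report["notices"].append(f"using first of {len(records)} FASTA records")
    ref = records[0]

    # -- structure ---------------------------------------------------------
    structure = detect_quadripartite(ref, min_ir_len=config.min_ir_len,
                                     allow_mismatch=config.allow_mismatch)
    metrics = compute_metrics(structure)
    report["stages"]["structure"] = structure_report(structure, metrics)
    write_structure_json(structure, outdir / "structure.json", metrics)
    write_structure_bed(structure, outdir / "structure.bed")
    _log(f"structure: LSC {metrics.lsc_size} / IR {metrics.ir_size} "
         f"/ SSC {metrics.ssc_size}")

    # -- repeats -----------------------------------------------------------
    lsc_seq = structure.region_seq("lsc")
    pairs = find_repeat_pairs(
        lsc_seq, min_arm=config.min_arm, max_arm=config.max_arm,
        min_spacer=config.min_spacer, max_spacer=config.max_spacer,
        orientation="inverted",
    )
    report["stages"]["repeats"] = {"n_pairs": len(pairs),
                                   "pairs": [pair_to_dict(p) for p in pairs]}
    write_repeat_tsv(pairs, outdir / "repeats.tsv")
    write_repeat_json(pairs, outdir / "repeats.json")
    _log(f"repeats: {len(pairs)} inverted pair(s) in the LSC")
    if not pairs:
        report["notices"].append("no inverted repeat pair in the LSC; "
                                 "recombination stages skipped")
        _finish(report, outdir)
        return report
    repeat = pairs[0]

    # -- partition & conformers -------------------------------------------
    partition = partition_lsc(structure, repeat)
    report["stages"]["partition"] = {
        "len_a": partition.len_a, "len_b": partition.len_b,
        "len_c": partition.len_c,
        "arm_len": repeat.arm_len,
    }
    conformers = enumerate_conformers(structure, partition)
    report["stages"]["conformers"] = [conformer_to_dict(c) for c in conformers]
    write_conformer_fasta(conformers, outdir / "conformers.fasta")
    write_event_log(conformers, outdir / "events.json")
    _log(f"conformers: {', '.join(c.label for c in conformers)}")

    # -- gene changes ------------------------------------------------------
    if config.annotation:
        genes = read_annotation(config.annotation)
        reports = [
            predict_gene_changes(partition, label, genes,
                                 genome_length=structure.sequence.length)
            for label in ("A-type", "reciprocal")
        ]
        report["stages"]["gene_changes"] = [
            {
                "conformer": r.label,
                "deleted": [g.name for g in r.deleted],
                "duplicated": [g.name for g in r.duplicated],
                "disrupted": [g.name for g in r.disrupted],
                "unchanged_count": r.unchanged_count,
                "unique_before": r.unique_before,
                "unique_after": r.unique_after,
            }
            for r in reports
        ]
        write_gene_change_tsv(reports, outdir / "gene_changes.tsv")
        _log("gene changes computed from annotation")
    else:
        report["notices"].append("no annotation provided; gene-change stage skipped")

    # -- junctions ---------------------------------------------------------
    reads = read_ids = None
    if config.reads1:
        read_ids, reads = read_fastq_pair(config.reads1, config.reads2)
    refs = build_junction_refs(structure, partition, conformers,
                               flank_len=config.flank_len)
    write_junction_fasta(refs, outdir / "junction_refs.fasta")
    if reads is not None:
        counts = support_table(refs, reads, min_overhang=config.min_overhang,
                               max_mismatch=config.max_mismatch)
        report["stages"]["junctions"] = [
            {
                "junction": sc.junction, "n_spanning": sc.n_spanning,
                "n_partial": sc.n_partial, "min_overhang": sc.min_overhang,
                "max_mismatch": sc.max_mismatch, "cross_match": sc.cross_match,
            }
            for sc in counts
        ]
        write_support_tsv(counts, outdir / "junction_support.tsv")
        _log("junction support counted")
    else:
        counts = None
        report["notices"].append("no reads provided; junction stage skipped")

    # -- heteroplasmy ------------------------------------------------------
    profile = None
    if config.depth_table:
        profile = read_depth_table(config.depth_table,
                                   reference_length=structure.sequence.length)
        if profile.name != structure.sequence.name:
            raise ValueError(
                f"depth table reference {profile.name!r} does not match the "
                f"FASTA record {structure.sequence.name!r}"
            )
    elif reads is not None:
        _log("computing depth by internal read mapping")
        profile = depth_from_reads(reads, structure)
    if profile is not None:
        estimate = estimate_heteroplasmy(profile, partition, structure,
                                         trim=config.trim)
        support = {sc.junction: sc for sc in counts} if counts else None
        calls = detect_presence(estimate, support,
                                threshold_depth=config.threshold_depth,
                                threshold_reads=config.threshold_reads)
        report["stages"]["heteroplasmy"] = estimate_to_dict(estimate)
        report["stages"]["presence"] = {
            k: {"present": v.present, "depth_evidence": v.depth_evidence,
                "read_evidence": v.read_evidence}
            for k, v in calls.items()
        }
        write_estimate_json(estimate, outdir / "heteroplasmy.json")
        write_estimate_tsv(estimate, outdir / "heteroplasmy.tsv")
        _log(f"heteroplasmy: prop_a = {estimate.prop_a:.3f}")
    else:
        report["notices"].append("no reads or depth table; heteroplasmy stage skipped")

    _finish(report, outdir)
    return report


def _finish(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True) + "\n")
    (outdir / "report.txt").write_text(render_report(report))


def render_report(report: dict) -> str:
    """Human-readable summary; every number is traceable to a run-report
    field and regeneration from the same report is byte-identical."""
    lines = [f"plastrec run report (v{report.get('version', '?')})", ""]
    stages = report.get("stages", {})

    st = stages.get("structure")
    if st:
        lines.append(f"Reference: {st['name']}  ({st['genome_size']} bp, "
                     f"GC {_pct(st['gc_total'])})")
        for r in st["regions"]:
            lines.append(f"  {r['region']:<4} {r['start_1based']:>9}-{r['end_1based']:<9}"
                         f" {r['length']:>9} bp  GC {_pct(r['gc'])}")
        lines.append("")

    part = stages.get("partition")
    if part:
        lines.append(f"LSC partition: |A| {part['len_a']}  |B| {part['len_b']}"
                     f"  |C| {part['len_c']}  (arm {part['arm_len']} bp)")
        lines.append("")

    confs = stages.get("conformers")
    if confs:
        parent_size = stages["structure"]["genome_size"] if st else None
        lines.append("Conformer predictions (parent vs products):")
        header = f"  {'conformer':<18}{'size':>10}{'IR':>10}{'LSC':>10}{'SSC':>10}"
        lines.append(header)
        if st:
            sizes = {r['region']: r['length'] for r in st['regions']}
            lines.append(f"  {'parent':<18}{st['genome_size']:>10}"
                         f"{sizes['IRB']:>10}{sizes['LSC']:>10}{sizes['SSC']:>10}")
        for c in confs:
            pm = c.get("predicted_metrics")
            if pm:
                lines.append(f"  {c['label']:<18}{pm['genome_size']:>10}"
                             f"{pm['ir_size']:>10}{pm['lsc_size']:>10}{pm['ssc_size']:>10}")
            else:
                lines.append(f"  {c['label']:<18}{c['size']:>10}"
                             f"{'-':>10}{'-':>10}{'-':>10}")
        lines.append("")

    gch = stages.get("gene_changes")
    if gch:
        for r in gch:
            lines.append(f"Gene changes ({r['conformer']}): "
                         f"deleted {', '.join(r['deleted']) or 'none'}; "
                         f"duplicated {len(r['duplicated'])}; "
                         f"disrupted {len(r['disrupted'])}")
            ub, ua = r["unique_before"], r["unique_after"]
            lines.append(f"  unique genes: protein {ub['protein']} -> {ua['protein']},"
                         f" tRNA {ub['tRNA']} -> {ua['tRNA']},"
                         f" rRNA {ub['rRNA']} -> {ua['rRNA']}")
        lines.append("")

    jn = stages.get("junctions")
    if jn:
        lines.append("Junction support:")
        for sc in jn:
            cross = " (cross-match)" if sc["cross_match"] else ""
            lines.append(f"  {sc['junction']:<14} spanning {sc['n_spanning']:>6}"
                         f"  partial {sc['n_partial']:>6}"
                         f"  overhang {sc['min_overhang']}{cross}")
        lines.append("")

    het = stages.get("heteroplasmy")
    if het:
        lines.append(f"Heteroplasmy: depth_G {het['depth_g']:.1f}x  "
                     f"depth_A {het['depth_a']:.1f}x  "
                     f"prop_A {het['prop_a']:.3f}")
        pres = stages.get("presence", {})
        for k in sorted(pres):
            v = pres[k]
            lines.append(f"  {k}: {'present' if v['present'] else 'absent'} "
                         f"(depth {v['depth_evidence']:.1f}, "
                         f"junction reads {v['read_evidence']})")
        lines.append("")

    for note in report.get("notices", []):
        lines.append(f"note: {note}")
    return "\n".join(lines).rstrip() + "\n"


def _pct(x) -> str:
    return "n/a" if x is None else f"{100 * x:.1f}%"


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.version_option(__version__)
def main():
    """Plastome structural-variation toolkit: quadripartite structure,
    short-repeat discovery, recombination conformers, junction support and
    heteroplasmy estimation."""


@main.command()
@click.argument("fasta", type=click.Path(exists=True))
@click.option("--min-ir-len", default=1000, show_default=True)
@click.option("--allow-mismatch", default=0, show_default=True)
@click.option("-o", "--outdir", default="plastrec_out", show_default=True)
def structure(fasta, min_ir_len, allow_mismatch, outdir):
    """Detect the quadripartite structure of a plastome FASTA."""
    ref = read_fasta(fasta)[0]
    st = detect_quadripartite(ref, min_ir_len=min_ir_len,
                              allow_mismatch=allow_mismatch)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_structure_json(st, out / "structure.json")
    write_structure_bed(st, out / "structure.bed")
    click.echo(json.dumps(structure_report(st), indent=2))


@main.command()
@click.argument("fasta", type=click.Path(exists=True))
@click.option("--region", default="lsc", show_default=True,
              type=click.Choice(["lsc", "ssc", "whole"]))
@click.option("--min-ir-len", default=1000, show_default=True)
@click.option("--min-arm", default=8, show_default=True)
@click.option("--max-arm", default=None, type=int)
@click.option("--min-spacer", default=0, show_default=True)
@click.option("--max-spacer", default=10_000, show_default=True)
@click.option("--orientation", default="both", show_default=True,
              type=click.Choice(["inverted", "direct", "both"]))
@click.option("-o", "--outdir", default="plastrec_out", show_default=True)
def repeats(fasta, region, min_ir_len, min_arm, max_arm, min_spacer,
            max_spacer, orientation, outdir):
    """Find short repeat pairs in a plastome region."""
    ref = read_fasta(fasta)[0]
    if region == "whole":
        seq = ref.residues
    else:
        st = detect_quadripartite(ref, min_ir_len=min_ir_len)
        seq = st.region_seq(region)
    pairs = find_repeat_pairs(seq, min_arm=min_arm, max_arm=max_arm,
                              min_spacer=min_spacer, max_spacer=max_spacer,
                              orientation=orientation)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_repeat_tsv(pairs, out / "repeats.tsv")
    write_repeat_json(pairs, out / "repeats.json")
    click.echo(f"{len(pairs)} pair(s) written to {out / 'repeats.tsv'}")


@main.command()
@click.argument("fasta", type=click.Path(exists=True))
@click.option("--annotation", type=click.Path(exists=True))
@click.option("--min-ir-len", default=1000, show_default=True)
@click.option("--min-arm", default=8, show_default=True)
@click.option("--min-spacer", default=0, show_default=True)
@click.option("--max-spacer", default=10_000, show_default=True)
@click.option("-o", "--outdir", default="plastrec_out", show_default=True)
def conformers(fasta, annotation, min_ir_len, min_arm, min_spacer, max_spacer, outdir):
    """Enumerate recombination conformers of a plastome."""
    cfg = RunConfig(reference=fasta, annotation=annotation, outdir=outdir,
                    min_ir_len=min_ir_len, min_arm=min_arm,
                    min_spacer=min_spacer, max_spacer=max_spacer)
    report = run_pipeline(cfg)
    click.echo(render_report(report))


@main.command()
@click.argument("fasta", type=click.Path(exists=True))
@click.argument("reads1", type=click.Path(exists=True))
@click.option("--reads2", type=click.Path(exists=True))
@click.option("--min-ir-len", default=1000, show_default=True)
@click.option("--min-arm", default=8, show_default=True)
@click.option("--flank-len", default=300, show_default=True)
@click.option("--min-overhang", default=None, type=int,
              help="spanning overhang; default: 20 bp (11 bp for the inversion test)")
@click.option("--max-mismatch", default=0, show_default=True)
@click.option("-o", "--outdir", default="plastrec_out", show_default=True)
def junctions(fasta, reads1, reads2, min_ir_len, min_arm, flank_len,
              min_overhang, max_mismatch, outdir):
    """Count junction-spanning reads for each conformer hypothesis."""
    cfg = RunConfig(reference=fasta, reads1=reads1, reads2=reads2,
                    outdir=outdir, min_ir_len=min_ir_len, min_arm=min_arm,
                    flank_len=flank_len, min_overhang=min_overhang,
                    max_mismatch=max_mismatch, depth_table=None)
    report = run_pipeline(cfg)
    click.echo(render_report(report))


@main.command()
@click.argument("fasta", type=click.Path(exists=True))
@click.option("--depth-table", type=click.Path(exists=True))
@click.option("--reads1", type=click.Path(exists=True))
@click.option("--reads2", type=click.Path(exists=True))
@click.option("--min-ir-len", default=1000, show_default=True)
@click.option("--min-arm", default=8, show_default=True)
@click.option("--trim", default=50, show_default=True)
@click.option("-o", "--outdir", default="plastrec_out", show_default=True)
def heteroplasmy(fasta, depth_table, reads1, reads2, min_ir_len, min_arm,
                 trim, outdir):
    """Estimate conformer heteroplasmy from depth over area C and the SSC."""
    cfg = RunConfig(reference=fasta, depth_table=depth_table, reads1=reads1,
                    reads2=reads2, outdir=outdir, min_ir_len=min_ir_len,
                    min_arm=min_arm, trim=trim)
    report = run_pipeline(cfg)
    click.echo(render_report(report))


@main.command()
@click.option("--spec-json", type=click.Path(exists=True),
              help="ToySpec fields as JSON; defaults used otherwise")
@click.option("--prop-a", default=0.0, show_default=True,
              help="A-type molecule proportion in the simulated mixture")
@click.option("--depth", default=50.0, show_default=True)
@click.option("--read-len", default=150, show_default=True)
@click.option("--error-rate", default=0.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("-o", "--outdir", default="plastrec_sim", show_default=True)
def simulate(spec_json, prop_a, depth, read_len, error_rate, seed, outdir):
    """Generate a toy plastome, its conformers and simulated reads."""
    from .synthetic_data import splice_conformer

    fields = json.loads(Path(spec_json).read_text()) if spec_json else {}
    fields.setdefault("seed", seed)
    spec = ToySpec(**fields)
    toy = make_toy_plastome(spec)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    parent = toy.structure.sequence
    write_fasta([parent], out / "parent.fasta")
    atype = splice_conformer(parent.residues, toy.partition, "A-type",
                             ir_len=spec.len_ir)
    conformer_seqs = {"G-type": parent.residues, "A-type": atype}
    reads = simulate_reads(conformer_seqs,
                           {"G-type": 1 - prop_a, "A-type": prop_a},
                           read_len=read_len, depth=depth,
                           error_rate=error_rate, seed=seed)
    write_fastq_pair(reads, out / "reads_1.fastq", out / "reads_2.fastq")
    write_truth_tsv(reads, out / "truth.tsv")
    (out / "spec.json").write_text(spec.to_json() + "\n")
    click.echo(f"simulated {len(reads.reads)} reads into {out}")


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              help="YAML config; flags below override nothing when given")
@click.option("--reference", type=click.Path(exists=True))
@click.option("--annotation", type=click.Path(exists=True))
@click.option("--reads1", type=click.Path(exists=True))
@click.option("--reads2", type=click.Path(exists=True))
@click.option("--depth-table", type=click.Path(exists=True))
@click.option("--min-ir-len", default=1000, show_default=True)
@click.option("--min-arm", default=8, show_default=True)
@click.option("--min-spacer", default=0, show_default=True)
@click.option("--max-spacer", default=10_000, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("-o", "--outdir", default="plastrec_out", show_default=True)
def run(config_path, reference, annotation, reads1, reads2, depth_table,
        min_ir_len, min_arm, min_spacer, max_spacer, seed, outdir):
    """Run the full pipeline end to end."""
    if config_path:
        cfg = RunConfig.from_yaml(config_path)
    else:
        cfg = RunConfig(reference=reference or "", annotation=annotation,
                        reads1=reads1, reads2=reads2, depth_table=depth_table,
                        min_ir_len=min_ir_len, min_arm=min_arm,
                        min_spacer=min_spacer, max_spacer=max_spacer,
                        seed=seed, outdir=outdir)
    report = run_pipeline(cfg)
    click.echo(render_report(report))


@main.command()
@click.argument("report_json", type=click.Path(exists=True))
def report(report_json):
    """Re-render the text summary from a run report."""
    click.echo(render_report(json.loads(Path(report_json).read_text())), nl=False)


if __name__ == "__main__":
    main()
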