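"""End-to-end orchestration on synthetic inputs.

``run_pipeline`` chains the stages — simulate tag libraries and annotation,
scan for differential-acetylation regions, classify genes and genomic
context, profile acetylated SINEs, test motif over-representation — writing
every tabular output plus a machine-readable run manifest (parameters, seed,
SHA-256 digests of all outputs).  Reruns with an identical configuration are
bit-identical; the manifest carries no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as sfio
from .config import PipelineConfig
from .context import (
    acetylated_sines,
    classify_genes,
    classify_regions_context,
    repeat_enrichment,
    sample_background,
    sine_density_profile,
)
from .motif import default_bbox_pwm, motif_overrepresentation
from .synthetic import (
    AnnotationSimSpec,
    SequenceSimSpec,
    TagSimSpec,
    gen_annotation,
    gen_sequences,
    gen_tag_libraries,
)
from .track import write_changes_track
from .windowscan import estimate_fdr, merge_significant, regions_to_frame, scan_genome

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, rng):
    tag_spec = TagSimSpec(
        chrom_sizes={"chr1": 2_600_000},
        background_per_window=20.0,
        window=config.scan.window,
        spikes=[("chr1", s, s + config.scan.window, 3.0)
                for s in range(100_000, 2_500_000, 200_000)],
    )
    lib_a, lib_b, tag_truth = gen_tag_libraries(tag_spec, rng)
    ann_spec = AnnotationSimSpec(
        chrom_sizes={"chr1": 2_600_000},
        genes_per_group={"NI": 3, "CE": 3, "CS": 2, "NR": 2},
        spacing=180_000, margin=130_000,
    )
    genes, repeats, expr, ann_truth = gen_annotation(ann_spec, rng)
    pwm = default_bbox_pwm()
    seqs, seq_truth = gen_sequences(
        SequenceSimSpec(n_sequences=60, length=300, plant_fraction=0.5), pwm, rng
    )
    return {
        "lib_a": lib_a, "lib_b": lib_b, "genes": genes, "repeats": repeats,
        "expr": expr, "seqs": seqs, "pwm": pwm,
        "truth": {"tags": tag_truth, "annotation": ann_truth, "sequences": seq_truth},
        "chrom_sizes": {"chr1": 2_600_000},
    }


@_stage("scan")
def _scan(config: PipelineConfig, data, out: Path):
    windows = scan_genome(data["lib_a"], data["lib_b"], config.scan)
    regions = merge_significant(windows, config.scan)
    fdr = estimate_fdr(windows, config.scan.alpha)
    sfio.write_regions_bed(regions, out / "regions.bed")
    write_changes_track(regions, out / "changes.wig", alpha=config.scan.alpha)
    frame = regions_to_frame(regions)
    summary = []
    for direction in ("+dAc", "-dAc"):
        sel = frame[frame["direction"] == direction]
        summary.append({
            "direction": direction, "n_regions": len(sel),
            "min_width": int(sel["width"].min()) if len(sel) else 0,
            "max_width": int(sel["width"].max()) if len(sel) else 0,
            "fdr": fdr.value,
        })
    import pandas as pd

    pd.DataFrame(summary).to_csv(out / "scan_summary.tsv", sep="\t", index=False, float_format="%.6g")
    return windows, regions, fdr


@_stage("context")
def _context(config: PipelineConfig, data, regions, out: Path, rng):
    groups = classify_genes(
        data["expr"], config.grouping.fold_threshold, config.grouping.p_threshold
    )
    for g in data["genes"]:
        g.group = groups.get(g.gene_id, "unassigned")
    ctx = classify_regions_context(regions, data["genes"])
    plus = [r for r in regions if r.direction == "+dAc"]
    ac = acetylated_sines(plus, data["repeats"])
    sfio.write_repeats_tsv(ac, out / "acetylated_sines.tsv")
    genes_by_group = {}
    for g in data["genes"]:
        genes_by_group.setdefault(g.group, []).append(g)
    profile = sine_density_profile(
        ac, {k: v for k, v in genes_by_group.items() if k in ("NI", "CE")},
        data["chrom_sizes"], config.sine_profile,
    )
    profile.to_csv(out / "sine_profile.tsv", sep="\t", index=False, float_format="%.6g")
    if plus:
        bg = sample_background(
            data["chrom_sizes"], [r.width for r in plus], rng=rng
        )
        enrich = repeat_enrichment(plus, data["repeats"], bg)
        enrich.to_csv(out / "repeat_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    ctx.value_counts().rename_axis("context").to_frame("n_regions").to_csv(
        out / "region_context.tsv", sep="\t"
    )
    return groups, ac


@_stage("motif")
def _motif(config: PipelineConfig, data, out: Path, rng):
    pwm = data["pwm"]
    n = len(data["seqs"])
    ids = sorted(data["seqs"])
    planted = set(data["truth"]["sequences"]["planted"])
    targets = {i: data["seqs"][i] for i in ids if i in planted}
    background = {i: data["seqs"][i] for i in ids if i not in planted}
    res = motif_overrepresentation(
        pwm, targets, background,
        threshold_bits=config.motif.threshold_fraction * pwm.max_score,
    )
    with open(out / "motif_enrichment.tsv", "w") as fh:
        fh.write("n_target\tn_target_hit\tn_background\tn_background_hit\tfisher_p\n")
        fh.write(
            f"{res.n_target}\t{res.n_target_hit}\t{res.n_background}\t"
            f"{res.n_background_hit}\t{res.fisher_p:.6g}\n"
        )
    return res


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate -> scan -> context -> motif and write a manifest.

    Returns the manifest dict (also written as ``manifest.json``): schema
    version, seed, stage parameters and SHA-256 digests of every output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    data = _simulate(config, rng)
    windows, regions, fdr = _scan(config, data, out)
    _context(config, data, regions, out, rng)
    _motif(config, data, out, rng)
    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "schema_version": config.schema_version,
        "seed": config.seed,
        "parameters": {
            "window": config.scan.window, "step": config.scan.step,
            "alpha": config.scan.alpha,
            "fold_threshold": config.grouping.fold_threshold,
            "coloc_threshold_nm": config.imaging.coloc_threshold_nm,
        },
        "n_regions": len(regions),
        "fdr": fdr.value,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
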