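"""Shared parsing and serialization for the pipeline's text formats.

Genes travel as BED6 (name = gene id; TSS derived from strand), repeats as a
RepeatMasker-style TSV (chrom, start, end, strand, name, family, class),
expression tables as TSV, sequences as FASTA (Biopython), image stacks as
multi-channel TIFF with a JSON sidecar carrying channel names and voxel
sizes.  All genomic coordinates are 0-based half-open in every text format
except WIG serialization (handled in :mod:`sinefactory.track`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .context import ExpressionRecord, GeneRecord, RepeatElement
from .tags import TagLibrary
from .windowscan import DifferentialRegion

__all__ = [
    "write_tags_bed",
    "write_regions_bed",
    "read_regions_bed",
    "write_genes_bed",
    "read_genes_bed",
    "write_repeats_tsv",
    "read_repeats_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_fasta",
    "read_fasta",
    "write_image_stack",
    "read_image_stack",
    "write_chrom_sizes",
]


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def write_tags_bed(lib: TagLibrary, path, mapq: int = 60) -> None:
    """Serialize a tag library as 6-column BED (score = mapping quality).

    Each tag becomes a 1-bp interval at its 5' position; the loader
    recovers the identical library.
    """
    with open(path, "w") as fh:
        for chrom in sorted(lib.tags):
            pos, strand = lib.tags[chrom]
            for p, s in zip(pos, strand):
                fh.write(
                    f"{chrom}\t{p}\t{p + 1}\ttag\t{mapq}\t{'+' if s > 0 else '-'}\n"
                )


def write_regions_bed(regions: list[DifferentialRegion], path) -> None:
    """BED6 of differential regions: name = direction, score =
    round(100 * peak -log10(p)), strand '.'."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t"
                f"{round(100 * r.peak_score)}\t.\n"
            )


def read_regions_bed(path) -> list[DifferentialRegion]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: line {i}: expected >= 5 BED columns")
            out.append(
                DifferentialRegion(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    direction=parts[3], peak_score=float(parts[4]) / 100.0,
                    n_windows=0,
                )
            )
    return out


def write_genes_bed(genes: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.body[0])):
            fh.write(
                f"{g.chrom}\t{g.body[0]}\t{g.body[1]}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_genes_bed(path, groups: dict[str, str] | None = None) -> list[GeneRecord]:
    """Read genes from BED6; the TSS is the 5' body end per strand.  An
    optional gene_id -> group mapping assigns expression groups."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {i}: expected 6 BED columns")
            chrom, start, end, gid, _, strand = parts[:6]
            start, end = int(start), int(end)
            tss = start if strand == "+" else end - 1
            out.append(
                GeneRecord(
                    gene_id=gid, chrom=chrom, strand=strand, tss=tss,
                    body=(start, end),
                    group=(groups or {}).get(gid, "unassigned"),
                )
            )
    return out


_REPEAT_COLS = ["chrom", "start", "end", "strand", "name", "family", "repeat_class"]


def write_repeats_tsv(repeats: list[RepeatElement], path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "strand": r.strand, "name": r.name, "family": r.family,
                "repeat_class": r.repeat_class,
            }
            for r in repeats
        ],
        columns=_REPEAT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_repeats_tsv(path) -> list[RepeatElement]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REPEAT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing repeat columns {missing}")
    return [
        RepeatElement(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            strand=row.strand, name=row.name, family=row.family,
            repeat_class=row.repeat_class,
        )
        for row in df.itertuples()
    ]


_EXPR_COLS = ["gene_id", "detected_ctrl", "detected_stim", "fold_change", "adj_p"]


def write_expression_tsv(records: list[ExpressionRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "detected_ctrl": int(r.detected_ctrl),
                "detected_stim": int(r.detected_stim),
                "fold_change": r.fold_change,
                "adj_p": r.adj_p,
            }
            for r in records
        ],
        columns=_EXPR_COLS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_expression_tsv(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXPR_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    return [
        ExpressionRecord(
            gene_id=row.gene_id,
            detected_ctrl=bool(row.detected_ctrl),
            detected_stim=bool(row.detected_stim),
            fold_change=float(row.fold_change),
            adj_p=float(row.adj_p),
        )
        for row in df.itertuples()
    ]


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}


def write_image_stack(stack, path, sidecar_path=None) -> None:
    """Write channels as a (C, Z, Y, X) TIFF plus a JSON sidecar with channel
    names and voxel sizes (nm)."""
    import tifffile

    path = Path(path)
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)
    tifffile.imwrite(str(path), data)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"channels": names, "voxel_nm": list(stack.voxel_nm)}, fh, indent=2
        )
        fh.write("\n")


def read_image_stack(path, sidecar_path=None):
    import tifffile

    from .imaging import ImageStack

    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        data = data[None]
    if data.shape[0] != len(meta["channels"]):
        raise ValueError(
            f"{path}: {data.shape[0]} planes but {len(meta['channels'])} channel names"
        )
    return ImageStack(
        channels={n: data[i] for i, n in enumerate(meta["channels"])},
        voxel_nm=tuple(meta["voxel_nm"]),
    )
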