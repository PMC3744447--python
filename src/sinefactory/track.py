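"""Signed -log10(p) acetylation-changes track (WIG/bedGraph).

Regions of significant acetylation increase are serialized as positive
columns whose height is -log10(p); decreases as negative columns (log10(p)).
The writer emits bedGraph data lines inside a ``track type=wiggle_0``
container (browser-loadable, 0-based half-open per the bedGraph standard);
the reader additionally accepts fixedStep and variableStep dialects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windowscan import DifferentialRegion

__all__ = ["TrackSummary", "write_changes_track", "read_changes_track"]


@dataclass
class TrackSummary:
    direction: str
    count: int
    min_width: int
    max_width: int


def write_changes_track(
    regions: list[DifferentialRegion],
    path,
    name: str = "H3K9K14ac_changes",
    alpha: float = 1e-3,
) -> None:
    """Write regions as a signed bedGraph changes track.

    The column height is +peak_score (= -log10 p) for +dAc regions and
    -peak_score for -dAc.  Regions whose peak p-value does not fall strictly
    below ``alpha`` are excluded, matching the calling threshold.
    """
    min_height = -np.log10(alpha)
    with open(path, "w") as fh:
        fh.write(
            f'track type=wiggle_0 name="{name}" '
            f'description="signed -log10(p) of differential acetylation"\n'
        )
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            if not r.peak_score > min_height:
                continue
            height = r.peak_score if r.direction == "+dAc" else -r.peak_score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{height:.6g}\n")


def _parse_spans(path):
    """Yield (chrom, start, end, value) spans from bedGraph/fixedStep/variableStep."""
    mode = "bedgraph"
    chrom = None
    pos = step = span = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if fields[0] == "fixedStep":
                kv = dict(f.split("=") for f in fields[1:])
                mode, chrom = "fixed", kv["chrom"]
                pos = int(kv["start"]) - 1  # WIG declaration lines are 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if fields[0] == "variableStep":
                kv = dict(f.split("=") for f in fields[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            if mode == "fixed":
                yield chrom, pos, pos + span, float(fields[0])
                pos += step
            elif mode == "variable":
                start = int(fields[0]) - 1
                yield chrom, start, start + span, float(fields[1])
            else:
                if len(fields) < 4:
                    raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
                yield fields[0], int(fields[1]), int(fields[2]), float(fields[3])


def read_changes_track(path) -> tuple[list[DifferentialRegion], dict[str, TrackSummary]]:
    """Read a signed changes track back into merged regions plus a summary.

    Contiguous or overlapping spans of the same sign are unioned into one
    region (peak = max |height|); overlapping spans of opposite sign are an
    ill-formed track and raise ValueError.  The summary gives per-direction
    region count and min/max width.
    """
    spans = sorted(_parse_spans(path), key=lambda s: (s[0], s[1]))
    regions: list[DifferentialRegion] = []
    cur = None  # [chrom, start, end, sign, peak, n]
    prev_by_chrom: dict[str, tuple[int, int, int]] = {}
    for chrom, start, end, value in spans:
        if value == 0:
            raise ValueError(f"zero-height span at {chrom}:{start}-{end}")
        sign = 1 if value > 0 else -1
        prev = prev_by_chrom.get(chrom)
        if prev is not None and start < prev[1] and sign != prev[2]:
            raise ValueError(
                f"overlapping spans of opposite sign at {chrom}:{start}-{end}"
            )
        prev_by_chrom[chrom] = (start, end, sign)
        if cur is not None and chrom == cur[0] and sign == cur[3] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[4] = max(cur[4], abs(value))
            cur[5] += 1
        else:
            if cur is not None:
                regions.append(_close(cur))
            cur = [chrom, start, end, sign, abs(value), 1]
    if cur is not None:
        regions.append(_close(cur))
    summary: dict[str, TrackSummary] = {}
    for direction in ("+dAc", "-dAc"):
        widths = [r.width for r in regions if r.direction == direction]
        if widths:
            summary[direction] = TrackSummary(direction, len(widths), min(widths), max(widths))
        else:
            summary[direction] = TrackSummary(direction, 0, 0, 0)
    return regions, summary


def _close(cur) -> DifferentialRegion:
    chrom, start, end, sign, peak, n = cur
    return DifferentialRegion(
        chrom=chrom, start=int(start), end=int(end),
        direction="+dAc" if sign > 0 else "-dAc",
        peak_score=float(peak), n_windows=int(n),
    )
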