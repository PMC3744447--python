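"""Mapped-tag libraries for differential ChIP-seq analysis.

A tag is the 5' end of a uniquely mapped sequencing read.  Libraries are
deduplicated so that every retained tag derives from an independent molecule:
at most one tag is kept per (chromosome, position, strand).  Reads below a
mapping-quality floor (default 10) are discarded as potentially ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TagLibrary", "TagParseError", "load_tags", "read_chrom_sizes"]


class TagParseError(ValueError):
    """Raised for a malformed mapped-tag record; names the offending line."""


@dataclass
class TagLibrary:
    """Deduplicated mapped-tag positions per chromosome.

    ``tags`` maps chromosome -> (positions, strands) where ``positions`` is a
    sorted int64 array of 0-based 5'-end coordinates and ``strands`` is an
    aligned int8 array (+1 for '+', -1 for '-').  ``N`` is the total tag count
    after mapq filtering and deduplication.
    """

    name: str
    chrom_sizes: dict[str, int]
    tags: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return int(sum(len(p) for p, _ in self.tags.values()))

    def positions(self, chrom: str) -> np.ndarray:
        if chrom in self.tags:
            return self.tags[chrom][0]
        return np.empty(0, dtype=np.int64)

    def validate(self, check_unique: bool = True) -> None:
        for chrom, (pos, strand) in self.tags.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"tags on unknown chromosome {chrom!r}")
            L = self.chrom_sizes[chrom]
            if len(pos) and (pos.min() < 0 or pos.max() >= L):
                raise ValueError(f"tag position outside [0, {L}) on {chrom}")
            if len(pos) != len(strand):
                raise ValueError(f"position/strand length mismatch on {chrom}")
            if check_unique:
                key = pos * 2 + (strand > 0)
                if len(np.unique(key)) != len(key):
                    raise ValueError(f"duplicate (position, strand) tags on {chrom}")

    @classmethod
    def from_arrays(
        cls,
        name: str,
        chrom_sizes: dict[str, int],
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
        dedup: bool = True,
    ) -> "TagLibrary":
        """Build a library from raw position/strand arrays, sorting and
        (optionally) deduplicating on (position, strand)."""
        tags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, strand) in per_chrom.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            order = np.lexsort((strand, pos))
            pos, strand = pos[order], strand[order]
            if dedup and len(pos):
                key = pos * 2 + (strand > 0)
                keep = np.concatenate([[True], np.diff(key) != 0])
                pos, strand = pos[keep], strand[keep]
            tags[chrom] = (pos, strand)
        lib = cls(name=name, chrom_sizes=dict(chrom_sizes), tags=tags)
        lib.validate(check_unique=dedup)
        return lib


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise TagParseError(f"{path}: line {i}: expected 'chrom length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise TagParseError(f"{path}: line {i}: bad length {parts[1]!r}") from exc
    return sizes


def load_tags(
    path,
    chrom_sizes: dict[str, int],
    mapq_min: int = 10,
    dedup: bool = True,
    name: str | None = None,
    on_unknown_chrom: str = "skip",
) -> TagLibrary:
    """Load a 6-column BED mapped-tag file into a :class:`TagLibrary`.

    Columns: chrom, start, end, name, score (mapping quality), strand.  The
    tag position is the 5' mapped end: ``start`` on the '+' strand, ``end-1``
    on the '-' strand.  Records with score < ``mapq_min`` are dropped; with
    ``dedup`` at most one tag per (chrom, position, strand) is kept.

    ``on_unknown_chrom`` is ``"skip"`` (drop with a warning) or ``"error"``.
    """
    import warnings

    if on_unknown_chrom not in ("skip", "error"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'error'")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    unknown: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise TagParseError(f"{path}: line {i}: expected 6 BED columns, got {len(parts)}")
            chrom, s, e, _, score, strand = parts[:6]
            try:
                start, end, mapq = int(s), int(e), int(float(score))
            except ValueError as exc:
                raise TagParseError(f"{path}: line {i}: non-numeric coordinate or score") from exc
            if strand not in "+-":
                raise TagParseError(f"{path}: line {i}: bad strand {strand!r}")
            if end <= start:
                raise TagParseError(f"{path}: line {i}: empty interval")
            if chrom not in chrom_sizes:
                if on_unknown_chrom == "error":
                    raise TagParseError(f"{path}: line {i}: unknown chromosome {chrom!r}")
                unknown.add(chrom)
                continue
            if mapq < mapq_min:
                continue
            pos = start if strand == "+" else end - 1
            per_chrom.setdefault(chrom, []).append((pos, 1 if strand == "+" else -1))
    if unknown:
        warnings.warn(f"{path}: skipped tags on unknown chromosomes: {sorted(unknown)}")
    arrays = {
        c: (np.array([p for p, _ in v], dtype=np.int64),
            np.array([s for _, s in v], dtype=np.int8))
        for c, v in per_chrom.items()
    }
    return TagLibrary.from_arrays(
        name or str(path), chrom_sizes, arrays, dedup=dedup
    )
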