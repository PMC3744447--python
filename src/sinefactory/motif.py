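"""B-box / ETC position-weight-matrix scanning and over-representation tests.

SINEs carry an internal RNA polymerase III promoter whose B box (~16 bp) is
the recognition sequence of TFIIIC.  This module scores sequences against a
B-box-like PWM in log-odds bits on both strands, bins the best per-element
score into the ordinal +/++/+++/++++ prediction categories, and tests motif
over-representation of a target region set against a background set with a
two-sided Fisher's exact test on per-sequence presence/absence.

The published B-box-like ETC matrix is not reproduced numerically here; the
shipped default is a synthetic stand-in built from a 16-bp consensus whose
informative core is the canonical RNAPIII type-2 B box (GTTCGAANNC), padded
with background-neutral N columns, with a uniform pseudocount of 0.25.  Any
plain-text matrix file can be loaded in its place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import fisher_2x2

__all__ = [
    "PWM",
    "MotifHit",
    "default_bbox_pwm",
    "score_window",
    "scan_sequence",
    "best_score",
    "bbox_category",
    "motif_overrepresentation",
    "split_test_validation",
]

_ALPHABET = "ACGT"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: 16-bp stand-in consensus; core = canonical B box, flanks background-neutral.
DEFAULT_BBOX_CONSENSUS = "NNNGTTCGAANNCNNN"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position-weight matrix over ACGT with uniform-by-default background.

    ``probs`` is (L, 4); each column (row of the array) sums to 1 after
    pseudocount normalization.  Scores are log2 odds against ``background``
    in bits; an N in the scored window contributes 0 (background-neutral).
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, float)
        self.background = np.asarray(self.background, float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be an (L, 4) matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM column must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p / background) in bits."""
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        """A maximal-scoring sequence (ties broken alphabetically; columns
        scoring 0 at best, i.e. background-neutral, render as N)."""
        lo = self.log_odds
        out = []
        for row in lo:
            if np.allclose(row, row[0]):
                out.append("N")
            else:
                out.append(_ALPHABET[int(np.argmax(row))])
        return "".join(out)

    @classmethod
    def from_consensus(cls, consensus: str, name: str = "consensus",
                       pseudocount: float = 0.25) -> "PWM":
        """PWM from an IUPAC consensus: count 1 split over the compatible
        bases per position, plus ``pseudocount`` per base, renormalized."""
        rows = []
        for i, ch in enumerate(consensus.upper()):
            if ch not in _IUPAC:
                raise ValueError(f"bad consensus character {ch!r} at position {i}")
            counts = np.full(4, pseudocount)
            allowed = _IUPAC[ch]
            for b in allowed:
                counts[_ALPHABET.index(b)] += 1.0 / len(allowed)
            rows.append(counts / counts.sum())
        return cls(name=name, probs=np.array(rows))

    @classmethod
    def from_file(cls, path) -> "PWM":
        """Read a whitespace-delimited L x 4 (A C G T) matrix with a one-line
        ``>name`` header.  Rows may be probabilities or counts (normalized)."""
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith(">"):
                raise ValueError(f"{path}: first line must be a '>name' header")
            rows = []
            for lineno, line in enumerate(fh, 2):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: line {lineno}: expected 4 columns (A C G T)")
                rows.append(vals)
        probs = np.array(rows)
        probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(name=header[1:].strip() or "pwm", probs=probs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for row in self.probs:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def default_bbox_pwm() -> PWM:
    """The shipped synthetic stand-in B-box PWM (see module docstring)."""
    return PWM.from_consensus(DEFAULT_BBOX_CONSENSUS, name="Bbox_ETC_standin")


@dataclass
class MotifHit:
    seq_id: str
    offset: int  # 0-based on the forward sequence
    strand: str
    score: float  # log-odds bits

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def _encode(seq: str, what: str = "sequence") -> np.ndarray:
    """Map ACGTN -> 0..3 / 4; error naming the offending position."""
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGTN"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(codes < 0)[0]
    if len(bad):
        raise ValueError(f"bad character {seq[bad[0]]!r} at position {int(bad[0])} in {what}")
    return codes


def score_window(pwm: PWM, subsequence: str) -> float:
    """Log-odds score (bits) of one window; alphabet ACGTN, N scores 0."""
    if len(subsequence) != len(pwm):
        raise ValueError(
            f"window length {len(subsequence)} != PWM length {len(pwm)}"
        )
    codes = _encode(subsequence, "window")
    lo = np.hstack([pwm.log_odds, np.zeros((len(pwm), 1))])  # column 4 = N
    return float(lo[np.arange(len(pwm)), codes].sum())


def _scores_one_strand(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    L = len(pwm)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    lo = np.hstack([pwm.log_odds, np.zeros((L, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo[np.arange(L)[None, :], windows].sum(axis=1)


def scan_sequence(
    pwm: PWM, seq: str, threshold_bits: float, seq_id: str = "seq"
) -> list[MotifHit]:
    """All hits with score >= threshold on both strands.

    Reverse-strand scores come from scanning the reverse complement; a hit at
    offset i on the reverse complement maps to forward offset len - L - i.
    """
    L = len(pwm)
    hits: list[MotifHit] = []
    if len(seq) < L:
        return hits
    fwd = _scores_one_strand(pwm, _encode(seq))
    for i in np.nonzero(fwd >= threshold_bits)[0]:
        hits.append(MotifHit(seq_id, int(i), "+", float(fwd[i])))
    rev = _scores_one_strand(pwm, _encode(reverse_complement(seq)))
    for i in np.nonzero(rev >= threshold_bits)[0]:
        hits.append(MotifHit(seq_id, int(len(seq) - L - i), "-", float(rev[i])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_score(pwm: PWM, seq: str) -> float:
    """Maximal window score over both strands; -inf for too-short sequences."""
    if len(seq) < len(pwm):
        return float("-inf")
    fwd = _scores_one_strand(pwm, _encode(seq))
    rev = _scores_one_strand(pwm, _encode(reverse_complement(seq)))
    return float(max(fwd.max(), rev.max()))


DEFAULT_CATEGORY_EDGES = (0.80, 0.875, 0.95)


def bbox_category(
    best_score_bits: float,
    max_score: float,
    category_edges: tuple[float, float, float] = DEFAULT_CATEGORY_EDGES,
) -> str | None:
    """Ordinal B-box prediction category for the best hit in an element.

    ``category_edges`` are the three interior cut points as fractions of the
    maximal PWM score; a fourth implicit edge sits at the maximum itself.
    Bins are right-closed into the higher category (a score exactly on an
    edge takes the higher bin): no call < e1 <= '+' < e2 <= '++' < e3 <=
    '+++' < max <= '++++'.  Returns None below the lowest edge.
    """
    e1, e2, e3 = category_edges
    if not e1 < e2 < e3:
        raise ValueError("category edges must be strictly increasing")
    frac = best_score_bits / max_score
    if frac >= 1.0 - 1e-9:
        return "++++"
    if frac >= e3:
        return "+++"
    if frac >= e2:
        return "++"
    if frac >= e1:
        return "+"
    return None


@dataclass
class OverrepresentationResult:
    n_target: int
    n_target_hit: int
    n_background: int
    n_background_hit: int
    fisher_p: float

    @property
    def target_fraction(self) -> float:
        return self.n_target_hit / self.n_target

    @property
    def background_fraction(self) -> float:
        return self.n_background_hit / self.n_background


def motif_overrepresentation(
    pwm: PWM,
    target_seqs: dict[str, str] | list[str],
    background_seqs: dict[str, str] | list[str],
    threshold_bits: float | None = None,
) -> OverrepresentationResult:
    """Motif presence in targets vs background, two-sided Fisher's exact.

    Each sequence is scored as containing >= 1 hit at ``threshold_bits``
    (default 80% of the maximal PWM score) on either strand; the 2x2 table
    (contains vs not x sequence set) is tested exactly.
    """
    if len(target_seqs) == 0 or len(background_seqs) == 0:
        raise ValueError("both sequence sets must be non-empty")
    if threshold_bits is None:
        threshold_bits = 0.80 * pwm.max_score
    tgt = list(target_seqs.values()) if isinstance(target_seqs, dict) else list(target_seqs)
    bg = list(background_seqs.values()) if isinstance(background_seqs, dict) else list(background_seqs)
    a = sum(best_score(pwm, s) >= threshold_bits for s in tgt)
    b = sum(best_score(pwm, s) >= threshold_bits for s in bg)
    p = fisher_2x2([[a, len(tgt) - a], [b, len(bg) - b]])
    return OverrepresentationResult(len(tgt), a, len(bg), b, p)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"seq_id": h.seq_id, "offset": h.offset, "strand": h.strand, "score": h.score}
         for h in hits],
        columns=["seq_id", "offset", "strand", "score"],
    )


def split_test_validation(
    items: list, rng: np.random.Generator | int | None = None
) -> tuple[list, list]:
    """Seeded 50/50 split of a region/sequence set into test and validation
    halves (the odd element, if any, goes to the test half)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = rng.permutation(len(items))
    half = (len(items) + 1) // 2
    test = [items[i] for i in sorted(idx[:half])]
    val = [items[i] for i in sorted(idx[half:])]
    return test, val
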