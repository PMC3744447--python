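"""Sliding-window differential acetylation caller.

Tags from two ChIP libraries are counted in 2-kb windows slid along each
chromosome at a 500-bp step.  Each window is tested against a binomial null:
conditional on the window total n = k_a + k_b, the count from library *a*
is Binomial(n, p0) with p0 = N_a / (N_a + N_b), the libraries' relative
sequencing depth.  One-sided tail p-values are computed in each direction
(tails include the observed count, so the discrete test is conservative),
windows with p below a threshold (default 1e-3) are called significant, and
overlapping-or-abutting significant windows of the same direction are merged
into differential regions (+dAc / -dAc).

An expected-false-discovery estimate accompanies each scan: the sum over
tested windows of the exact null probability of crossing the threshold
(discreteness-aware, conditional on each window's n), divided by the number
of observed discoveries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .tags import TagLibrary

__all__ = [
    "ScanConfig",
    "WindowTest",
    "DifferentialRegion",
    "FdrEstimate",
    "count_window",
    "binomial_window_test",
    "scan_genome",
    "merge_significant",
    "estimate_fdr",
]

INCREASE = "increase"
DECREASE = "decrease"
NONE = "none"


@dataclass(frozen=True)
class ScanConfig:
    """Window-scan parameters.

    window: window width in bp. step: stride between window starts.
    alpha: per-window one-sided p-value threshold (calls use strict p < alpha).
    direction_convention: which library is the stimulated "condition"; when
    "a", an upper-tail excess in library a is an increase.
    two_sided: score min(p_inc, p_dec)*2 instead of independent one-sided
    tails (non-default alternative).
    include_truncated: admit flagged partial chromosome-edge windows into
    region calling (excluded by default).
    """

    window: int = 2000
    step: int = 500
    alpha: float = 1e-3
    direction_convention: str = "a"
    two_sided: bool = False
    include_truncated: bool = False

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not 0 < self.step <= self.window:
            raise ValueError("step must satisfy 0 < step <= window")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.direction_convention not in ("a", "b"):
            raise ValueError("direction_convention must be 'a' or 'b'")


@dataclass
class WindowTest:
    chrom: str
    start: int
    end: int
    k_a: int
    k_b: int
    p0: float
    p_inc: float
    p_dec: float
    direction: str
    truncated: bool = False

    @property
    def n(self) -> int:
        return self.k_a + self.k_b


@dataclass
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    direction: str  # "+dAc" or "-dAc"
    peak_score: float  # max -log10(p) over member windows
    n_windows: int

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class FdrEstimate:
    """Expected-false-positives / observed-positives FDR estimate.

    ``value`` is NaN when no window passes the threshold; ``defined`` flags
    that case explicitly.
    """

    value: float
    expected_false: float
    n_significant: int
    n_windows_tested: int

    @property
    def defined(self) -> bool:
        return self.n_significant > 0


def count_window(lib: TagLibrary, chrom: str, start: int, width: int) -> int:
    """Number of tags whose 5' position falls in [start, start + width)."""
    pos = lib.positions(chrom)
    return int(np.searchsorted(pos, start + width) - np.searchsorted(pos, start))


def _tail_pvalues(k_a, n, p0):
    """Vectorized one-sided tails including the observed value."""
    k_a = np.asarray(k_a)
    n = np.asarray(n)
    p_inc = np.where(n > 0, binom.sf(k_a - 1, np.maximum(n, 1), p0), 1.0)
    p_dec = np.where(n > 0, binom.cdf(k_a, np.maximum(n, 1), p0), 1.0)
    return p_inc, p_dec


def binomial_window_test(
    k_a: int,
    k_b: int,
    N_a: int,
    N_b: int,
    alpha: float = 1e-3,
    chrom: str = "",
    start: int = 0,
    width: int = 2000,
) -> WindowTest:
    """Test one window's counts against the binomial depth null.

    p_inc = P(X >= k_a) and p_dec = P(X <= k_a) for X ~ Binomial(k_a + k_b,
    N_a / (N_a + N_b)).  The direction is the tail falling strictly below
    ``alpha`` ("none" if neither; both cannot for alpha < 0.5 since the
    tails share the observed point mass and sum to >= 1).
    """
    if N_a <= 0 or N_b <= 0:
        raise ValueError("library sizes must be positive")
    if k_a < 0 or k_b < 0:
        raise ValueError("window counts must be non-negative")
    p0 = N_a / (N_a + N_b)
    n = k_a + k_b
    if n == 0:
        p_inc = p_dec = 1.0
    else:
        p_inc = float(binom.sf(k_a - 1, n, p0))
        p_dec = float(binom.cdf(k_a, n, p0))
    direction = NONE
    if p_inc < alpha and p_inc < p_dec:
        direction = INCREASE
    elif p_dec < alpha and p_dec < p_inc:
        direction = DECREASE
    return WindowTest(
        chrom=chrom, start=start, end=start + width, k_a=k_a, k_b=k_b,
        p0=p0, p_inc=p_inc, p_dec=p_dec, direction=direction,
    )


def _window_starts(length: int, cfg: ScanConfig) -> tuple[np.ndarray, np.ndarray]:
    """Window starts and a truncation flag per window.

    Full windows tile [0, length - window] at the configured step; if the
    chromosome tail is not covered, one final truncated window is emitted and
    flagged.  A chromosome shorter than one window yields a single truncated
    window spanning it entirely.
    """
    w, s = cfg.window, cfg.step
    if length < w:
        return np.array([0], dtype=np.int64), np.array([True])
    last_full = (length - w) // s * s
    starts = np.arange(0, last_full + 1, s, dtype=np.int64)
    trunc = np.zeros(len(starts), dtype=bool)
    if last_full + w < length:
        starts = np.append(starts, last_full + s)
        trunc = np.append(trunc, True)
    return starts, trunc


def scan_genome(lib_a: TagLibrary, lib_b: TagLibrary, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Test every window of the genome; one row per window.

    Returns a DataFrame ordered by (chrom, start) with columns chrom, start,
    end, truncated, k_a, k_b, n, p0, p_inc, p_dec, direction.
    """
    cfg = cfg or ScanConfig()
    if lib_a.chrom_sizes != lib_b.chrom_sizes:
        raise ValueError("libraries disagree on chromosome sizes")
    N_a, N_b = lib_a.N, lib_b.N
    if N_a <= 0 or N_b <= 0:
        raise ValueError("both libraries must contain tags")
    p0 = N_a / (N_a + N_b)
    frames = []
    for chrom in sorted(lib_a.chrom_sizes):
        length = lib_a.chrom_sizes[chrom]
        starts, trunc = _window_starts(length, cfg)
        ends = np.minimum(starts + cfg.window, length)
        pa = lib_a.positions(chrom)
        pb = lib_b.positions(chrom)
        k_a = np.searchsorted(pa, ends) - np.searchsorted(pa, starts)
        k_b = np.searchsorted(pb, ends) - np.searchsorted(pb, starts)
        n = k_a + k_b
        p_inc, p_dec = _tail_pvalues(k_a, n, p0)
        if cfg.two_sided:
            two = np.minimum(2.0 * np.minimum(p_inc, p_dec), 1.0)
            sig_inc = (two < cfg.alpha) & (p_inc < p_dec)
            sig_dec = (two < cfg.alpha) & (p_dec < p_inc)
        else:
            sig_inc = (p_inc < cfg.alpha) & (p_inc < p_dec)
            sig_dec = (p_dec < cfg.alpha) & (p_dec < p_inc)
        direction = np.where(sig_inc, INCREASE, np.where(sig_dec, DECREASE, NONE))
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "truncated": trunc,
            "k_a": k_a, "k_b": k_b, "n": n, "p0": p0,
            "p_inc": p_inc, "p_dec": p_dec, "direction": direction,
        }))
    df = pd.concat(frames, ignore_index=True)
    if cfg.direction_convention == "b":
        df["p_inc"], df["p_dec"] = df["p_dec"].to_numpy(), df["p_inc"].to_numpy()
        df["k_a"], df["k_b"] = df["k_b"].to_numpy(), df["k_a"].to_numpy()
        df["p0"] = 1.0 - df["p0"]
        df["direction"] = df["direction"].map(
            {INCREASE: DECREASE, DECREASE: INCREASE, NONE: NONE}
        )
    return df


def merge_significant(windows: pd.DataFrame, cfg: ScanConfig | None = None) -> list[DifferentialRegion]:
    """Merge significant windows into maximal same-direction regions.

    Overlapping-or-abutting significant windows of one direction are unioned;
    the region score is the maximum -log10(p) over member windows.  Truncated
    chromosome-edge windows are excluded unless the config admits them.
    """
    cfg = cfg or ScanConfig()
    sig = windows[windows["direction"] != NONE]
    if not cfg.include_truncated:
        sig = sig[~sig["truncated"]]
    regions: list[DifferentialRegion] = []
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=True):
        grp = grp.sort_values("start")
        p = np.where(grp["direction"] == INCREASE, grp["p_inc"], grp["p_dec"])
        score = -np.log10(np.maximum(p, 1e-300))
        cur_start = cur_end = None
        cur_peak = 0.0
        cur_n = 0
        label = "+dAc" if direction == INCREASE else "-dAc"
        for start, end, sc in zip(grp["start"], grp["end"], score):
            if cur_start is None or start > cur_end:
                if cur_start is not None:
                    regions.append(DifferentialRegion(chrom, int(cur_start), int(cur_end), label, float(cur_peak), cur_n))
                cur_start, cur_end, cur_peak, cur_n = start, end, sc, 1
            else:
                cur_end = max(cur_end, end)
                cur_peak = max(cur_peak, sc)
                cur_n += 1
        if cur_start is not None:
            regions.append(DifferentialRegion(chrom, int(cur_start), int(cur_end), label, float(cur_peak), cur_n))
    regions.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return regions


def regions_to_frame(regions: list[DifferentialRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "direction": r.direction, "peak_score": r.peak_score,
             "n_windows": r.n_windows, "width": r.width}
            for r in regions
        ],
        columns=["chrom", "start", "end", "direction", "peak_score", "n_windows", "width"],
    )


def _null_rejection_prob(n: int, p0: float, alpha: float) -> float:
    """Exact P(either one-sided tail p < alpha) for K ~ Binomial(n, p0).

    p_inc(k) is non-increasing in k, p_dec(k) non-decreasing; the rejection
    region is the union of an upper and a lower run of k, located by direct
    evaluation of the discrete tails.
    """
    if n == 0:
        return 0.0
    k = np.arange(n + 1)
    p_inc = binom.sf(k - 1, n, p0)
    p_dec = binom.cdf(k, n, p0)
    prob = 0.0
    up = np.nonzero(p_inc < alpha)[0]
    if len(up):
        prob += float(binom.sf(up[0] - 1, n, p0))
    dn = np.nonzero(p_dec < alpha)[0]
    if len(dn):
        prob += float(binom.cdf(dn[-1], n, p0))
    return min(prob, 1.0)


def estimate_fdr(windows: pd.DataFrame, alpha: float = 1e-3) -> FdrEstimate:
    """Discreteness-aware expected-false-positives FDR estimate.

    For each tested window (n > 0), the exact null probability of a p-value
    below ``alpha`` in either direction is accumulated; the estimate is that
    sum divided by the observed number of significant windows.  Windows with
    n = 0 can never be significant and are excluded from the accounting.
    """
    tested = windows[windows["n"] > 0]
    if len(tested) == 0:
        return FdrEstimate(float("nan"), 0.0, 0, 0)
    p0 = float(tested["p0"].iloc[0])
    expected = 0.0
    counts = tested["n"].value_counts()
    for n, cnt in counts.items():
        expected += cnt * _null_rejection_prob(int(n), p0, alpha)
    n_sig = int((np.minimum(tested["p_inc"], tested["p_dec"]) < alpha).sum())
    # an FDR is a proportion; the ratio estimator is capped at 1
    value = min(expected / n_sig, 1.0) if n_sig else float("nan")
    return FdrEstimate(value, expected, n_sig, len(tested))
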