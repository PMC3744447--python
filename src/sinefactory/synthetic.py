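"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure of the data the pipeline
analyses —
two tag libraries with Poisson-like background and spiked enrichment
windows, gene cohorts (CS/CE/NI/NR) with group-dependent acetylated-SINE
placement around TSSs, random sequences with planted B-box consensus
instances, and 3D confocal stacks with an ellipsoid DAPI nucleus, Gaussian
RNAPII foci and FISH spots at controlled physical distances under
anisotropic voxels — and returns ground-truth records alongside the data so
every downstream stage can be tested against what was planted.

All randomness flows through one ``numpy.random.Generator`` passed
explicitly (or created from an integer seed); a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .context import ExpressionRecord, GeneRecord, RepeatElement
from .tags import TagLibrary

__all__ = [
    "TagSimSpec",
    "SinePlacementRule",
    "AnnotationSimSpec",
    "SequenceSimSpec",
    "ImageSimSpec",
    "gen_tag_libraries",
    "gen_annotation",
    "gen_sequences",
    "gen_image_stack",
]


def _rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# tag libraries


@dataclass
class TagSimSpec:
    """Two-library tag simulation.

    Background tags are uniform over the genome in both libraries (the
    caller's null is count-based, not sequence-based); ``spikes`` are
    (chrom, start, end, ratio) intervals whose per-bp rate is multiplied by
    ``ratio`` in library *a* only.  ``background_per_window`` expresses depth
    as the expected background tag count per library per ``window`` bp; the
    default of 20 gives the spike-recovery study's operating point.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000})
    background_per_window: float = 20.0
    window: int = 2000
    spikes: list[tuple[str, int, int, float]] = field(default_factory=list)
    N_a: int | None = None  # override computed library sizes
    N_b: int | None = None

    @property
    def rate_per_bp(self) -> float:
        return self.background_per_window / self.window

    def library_size(self) -> int:
        return int(round(self.rate_per_bp * sum(self.chrom_sizes.values())))

    def validate(self):
        for chrom, start, end, ratio in self.spikes:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"spike on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_sizes[chrom]):
                raise ValueError(f"spike {chrom}:{start}-{end} outside genome")
            if ratio <= 0:
                raise ValueError("spike enrichment ratio must be > 0")


def _sample_positions(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    n: int,
    spikes: list[tuple[str, int, int, float]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """n distinct (chrom, position, strand) tags, density proportional to 1
    plus the spike excess (ratio - 1) inside spiked intervals."""
    chroms = sorted(chrom_sizes)
    comps: list[tuple[str, int, int, float]] = [
        (c, 0, chrom_sizes[c], float(chrom_sizes[c])) for c in chroms
    ]
    for chrom, start, end, ratio in spikes:
        if ratio != 1.0:
            comps.append((chrom, start, end, (ratio - 1.0) * (end - start)))
    weights = np.array([w for *_, w in comps])
    probs = weights / weights.sum()
    available = 2 * sum(chrom_sizes.values())
    if n > available:
        raise ValueError(
            f"requested {n} tags but only {available} distinct (position, strand) "
            "slots exist"
        )
    chosen: set[tuple[str, int, int]] = set()
    guard = 0
    while len(chosen) < n:
        guard += 1
        if guard > 200:
            raise RuntimeError("tag sampling failed to converge")
        # whole batches only: truncating mid-batch would bias against
        # later-listed components (the spikes)
        counts = rng.multinomial(n - len(chosen), probs)
        for (chrom, start, end, _), cnt in zip(comps, counts):
            if cnt == 0:
                continue
            pos = rng.integers(start, end, size=cnt)
            strands = rng.integers(0, 2, size=cnt) * 2 - 1
            for p, s in zip(pos, strands):
                chosen.add((chrom, int(p), int(s)))
    per_chrom: dict[str, tuple[list, list]] = {c: ([], []) for c in chroms}
    for chrom, p, s in sorted(chosen):
        per_chrom[chrom][0].append(p)
        per_chrom[chrom][1].append(s)
    return {
        c: (np.array(p, dtype=np.int64), np.array(s, dtype=np.int8))
        for c, (p, s) in per_chrom.items()
    }


def gen_tag_libraries(
    spec: TagSimSpec, rng: np.random.Generator | int | None = None
) -> tuple[TagLibrary, TagLibrary, dict]:
    """Simulate the (condition, control) tag libraries plus ground truth.

    Library *a* carries the spiked enrichment; both share the uniform
    background.  Ground truth records the spiked intervals with their
    realized per-library tag counts.
    """
    rng = _rng(rng)
    spec.validate()
    n_a = spec.N_a if spec.N_a is not None else spec.library_size()
    n_b = spec.N_b if spec.N_b is not None else spec.library_size()
    # the stated size IS the realized library size: spiked intervals
    # redistribute sequencing depth (as sampling a library to fixed depth
    # does), they do not add to it
    arrays_a = _sample_positions(rng, spec.chrom_sizes, n_a, spec.spikes)
    arrays_b = _sample_positions(rng, spec.chrom_sizes, n_b, [])
    lib_a = TagLibrary.from_arrays("condition", spec.chrom_sizes, arrays_a)
    lib_b = TagLibrary.from_arrays("control", spec.chrom_sizes, arrays_b)
    truth_spikes = []
    for chrom, start, end, ratio in spec.spikes:
        pa = lib_a.positions(chrom)
        pb = lib_b.positions(chrom)
        truth_spikes.append({
            "chrom": chrom, "start": start, "end": end, "ratio": ratio,
            "k_a": int(np.searchsorted(pa, end) - np.searchsorted(pa, start)),
            "k_b": int(np.searchsorted(pb, end) - np.searchsorted(pb, start)),
        })
    truth = {
        "spikes": truth_spikes,
        "N_a": lib_a.N,
        "N_b": lib_b.N,
        "background_per_window": spec.background_per_window,
    }
    return lib_a, lib_b, truth


# ---------------------------------------------------------------------------
# annotation


@dataclass
class SinePlacementRule:
    """Acetylated-SINE placement around the TSSs of one gene group.

    ``band`` is the strand-oriented offset interval (bp, downstream positive)
    in which surplus elements are planted; ``n_mean`` the Poisson mean of the
    surplus count per gene (0 disables the surplus).
    """

    band: tuple[int, int] = (20_000, 75_000)
    n_mean: float = 0.0


@dataclass
class AnnotationSimSpec:
    """Gene cohorts, repeats and a matching expression table.

    Genes are laid out at ``spacing`` bp with ``margin`` bp clear of
    chromosome ends so profile windows are never truncated; every group
    shares a uniform baseline of acetylated SINEs (``baseline_mean`` per gene
    over +-``baseline_extent``) on top of which group rules plant a surplus.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 61_000_000})
    genes_per_group: dict[str, int] = field(
        default_factory=lambda: {"NI": 100, "CE": 100}
    )
    spacing: int = 300_000
    margin: int = 150_000
    body_length: int = 20_000
    sine_length: int = 150
    baseline_mean: float = 2.0
    baseline_extent: int = 125_000
    rules: dict[str, SinePlacementRule] = field(
        default_factory=lambda: {"NI": SinePlacementRule(n_mean=3.0)}
    )
    fold_threshold: float = 1.24
    sine_names: tuple[str, ...] = ("B1_Mus1", "B1F", "B2_Mm1t", "B3", "RSINE1", "ID4")
    sine_families: tuple[str, ...] = ("Alu/B1", "Alu/B1", "B2", "B2", "B4", "ID")


def gen_annotation(
    spec: AnnotationSimSpec, rng: np.random.Generator | int | None = None
) -> tuple[list[GeneRecord], list[RepeatElement], list[ExpressionRecord], dict]:
    """Simulate genes (with group labels), acetylated SINEs and an expression
    table consistent with the labels.

    The expression table is constructed so :func:`~sinefactory.context.classify_genes`
    reproduces the planted groups exactly (NI: fold >= threshold with adjusted
    p < 0.05; NR: reciprocal; CE: detected in both; CS: in neither).
    """
    rng = _rng(rng)
    total_needed = spec.margin * 2 + spec.spacing * sum(spec.genes_per_group.values())
    if total_needed > sum(spec.chrom_sizes.values()):
        raise ValueError("gene cohorts do not fit in the genome at the given spacing")
    chroms = sorted(spec.chrom_sizes)
    genes: list[GeneRecord] = []
    repeats: list[RepeatElement] = []
    expr: list[ExpressionRecord] = []
    truth: dict = {"genes": {}, "sine_offsets": {}}
    ci = 0
    cursor = spec.margin
    idx = 0
    for group in sorted(spec.genes_per_group):
        for _ in range(spec.genes_per_group[group]):
            while cursor + spec.spacing + spec.margin > spec.chrom_sizes[chroms[ci]]:
                ci += 1
                if ci >= len(chroms):
                    raise ValueError("ran out of genome while placing genes")
                cursor = spec.margin
            chrom = chroms[ci]
            strand = "+" if rng.integers(0, 2) else "-"
            # keep the TSS centred in the gene's slot
            tss = cursor + spec.spacing // 2
            if strand == "+":
                body = (tss, tss + spec.body_length)
            else:
                body = (tss - spec.body_length + 1, tss + 1)
            gid = f"gene{idx:05d}"
            genes.append(GeneRecord(gid, chrom, strand, tss, body, group=group))
            truth["genes"][gid] = group
            # expression record consistent with the planted group
            if group == "NI":
                fold = float(spec.fold_threshold + rng.uniform(0.06, 2.0))
                rec = ExpressionRecord(gid, True, True, fold, float(rng.uniform(1e-5, 0.01)))
            elif group == "NR":
                fold = float(1.0 / (spec.fold_threshold + rng.uniform(0.06, 2.0)))
                rec = ExpressionRecord(gid, True, True, fold, float(rng.uniform(1e-5, 0.01)))
            elif group == "CE":
                rec = ExpressionRecord(gid, True, True, float(rng.uniform(0.95, 1.05)), float(rng.uniform(0.5, 1.0)))
            else:  # CS
                rec = ExpressionRecord(gid, False, False, 1.0, 1.0)
            expr.append(rec)
            # baseline acetylated SINEs, uniform around the TSS in every group
            offsets = []
            n_base = rng.poisson(spec.baseline_mean)
            if n_base:
                offsets.extend(
                    rng.integers(-spec.baseline_extent, spec.baseline_extent + 1, n_base).tolist()
                )
            rule = spec.rules.get(group)
            if rule is not None and rule.n_mean > 0:
                n_sur = rng.poisson(rule.n_mean)
                lo, hi = rule.band
                if n_sur:
                    offsets.extend(rng.integers(lo, hi + 1, n_sur).tolist())
            truth["sine_offsets"][gid] = sorted(int(o) for o in offsets)
            for off in offsets:
                mid = tss + off if strand == "+" else tss - off
                start = int(mid - spec.sine_length // 2)
                j = int(rng.integers(0, len(spec.sine_names)))
                repeats.append(
                    RepeatElement(
                        chrom=chrom, start=start, end=start + spec.sine_length,
                        strand="+" if rng.integers(0, 2) else "-",
                        name=spec.sine_names[j], family=spec.sine_families[j],
                        repeat_class="SINE",
                    )
                )
            cursor += spec.spacing
            idx += 1
    repeats.sort(key=lambda r: (r.chrom, r.start))
    return genes, repeats, expr, truth


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceSimSpec:
    n_sequences: int = 200
    length: int = 400
    plant_fraction: float = 0.5
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def validate(self):
        if not 0.0 <= self.plant_fraction <= 1.0:
            raise ValueError("plant_fraction must be in [0, 1]")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")


def gen_sequences(
    spec: SequenceSimSpec, pwm, rng: np.random.Generator | int | None = None
) -> tuple[dict[str, str], dict]:
    """Random background sequences with the PWM consensus planted in the
    first ``plant_fraction`` of them at recorded offsets.

    Background-neutral (N) consensus positions are realized as random bases,
    which leaves the planted window maximal-scoring.  Ground truth maps each
    planted sequence id to its offset.
    """
    rng = _rng(rng)
    spec.validate()
    bases = np.array(list("ACGT"))
    L = len(pwm)
    if spec.length < L:
        raise ValueError("sequences shorter than the PWM cannot carry a plant")
    consensus = pwm.consensus()
    n_plant = int(round(spec.plant_fraction * spec.n_sequences))
    seqs: dict[str, str] = {}
    truth: dict = {"planted": {}}
    for i in range(spec.n_sequences):
        arr = rng.choice(bases, size=spec.length, p=list(spec.composition))
        sid = f"seq{i:04d}"
        if i < n_plant:
            off = int(rng.integers(0, spec.length - L + 1))
            planted = [
                c if c != "N" else str(rng.choice(bases)) for c in consensus
            ]
            arr[off:off + L] = planted
            truth["planted"][sid] = off
        seqs[sid] = "".join(arr)
    return seqs, truth


# ---------------------------------------------------------------------------
# image stacks


@dataclass
class ImageSimSpec:
    """Synthetic immuno-DNA FISH field: one ellipsoid nucleus, ``n_foci``
    Gaussian RNAPII foci, and FISH spots at the given true distances (nm)
    from their nearest focus.

    The point-spread function is approximated by an isotropic-in-nm Gaussian
    (``focus_sigma_nm``); voxels are anisotropic (dz defaults to the 200-nm
    confocal z-step).  ``min_separation_nm`` keeps foci resolvable.
    """

    shape: tuple[int, int, int] = (20, 64, 64)  # (z, y, x)
    voxel_nm: tuple[float, float, float] = (100.0, 100.0, 200.0)  # (dx, dy, dz)
    nucleus_semiaxes_nm: tuple[float, float, float] | None = None  # (x, y, z)
    n_foci: int = 30
    focus_amplitude: float = 300.0
    focus_sigma_nm: float = 60.0
    spot_amplitude: float = 300.0
    spot_sigma_nm: float = 60.0
    spot_distances_nm: tuple[float, ...] = (100.0,)
    background: float = 10.0
    noise_sd: float = 2.0
    dapi_level: float = 120.0
    min_separation_nm: float = 700.0

    def semiaxes(self) -> tuple[float, float, float]:
        if self.nucleus_semiaxes_nm is not None:
            return self.nucleus_semiaxes_nm
        nz, ny, nx = self.shape
        dx, dy, dz = self.voxel_nm
        return (0.42 * nx * dx, 0.42 * ny * dy, 0.42 * nz * dz)


def _inside_ellipsoid(p_nm, center_nm, semi_nm, shrink=1.0) -> bool:
    return (
        ((p_nm[0] - center_nm[0]) / (semi_nm[0] * shrink)) ** 2
        + ((p_nm[1] - center_nm[1]) / (semi_nm[1] * shrink)) ** 2
        + ((p_nm[2] - center_nm[2]) / (semi_nm[2] * shrink)) ** 2
    ) <= 1.0


def _add_gaussian(img, center_nm, amplitude, sigma_nm, voxel_nm):
    """Add an isotropic (in nm) Gaussian blob, rendered on a local patch."""
    dx, dy, dz = voxel_nm
    nz, ny, nx = img.shape
    cx, cy, cz = center_nm
    rx, ry, rz = (int(np.ceil(4 * sigma_nm / d)) for d in (dx, dy, dz))
    ix, iy, iz = int(cx / dx), int(cy / dy), int(cz / dz)
    z0, z1 = max(iz - rz, 0), min(iz + rz + 1, nz)
    y0, y1 = max(iy - ry, 0), min(iy + ry + 1, ny)
    x0, x1 = max(ix - rx, 0), min(ix + rx + 1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        raise ValueError("blob placement outside the stack")
    zc = (np.arange(z0, z1) + 0.5) * dz - cz
    yc = (np.arange(y0, y1) + 0.5) * dy - cy
    xc = (np.arange(x0, x1) + 0.5) * dx - cx
    r2 = (
        zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
    )
    img[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-r2 / (2.0 * sigma_nm**2))


def gen_image_stack(
    spec: ImageSimSpec, rng: np.random.Generator | int | None = None
):
    """Render one synthetic field: returns (ImageStack, ground truth).

    Ground truth holds focus centers, spot centers and each spot's true
    distance to its nearest focus (exactly the requested distance: other foci
    are kept at least that far away).
    """
    from .imaging import ImageStack

    rng = _rng(rng)
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.voxel_nm
    center = (nx * dx / 2.0, ny * dy / 2.0, nz * dz / 2.0)
    semi = spec.semiaxes()
    # nucleus mask / DAPI channel
    zc = (np.arange(nz) + 0.5) * dz
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx
    ell = (
        ((xc[None, None, :] - center[0]) / semi[0]) ** 2
        + ((yc[None, :, None] - center[1]) / semi[1]) ** 2
        + ((zc[:, None, None] - center[2]) / semi[2]) ** 2
    ) <= 1.0
    dapi = np.full(spec.shape, 2.0) + spec.dapi_level * ell

    # place foci inside the (slightly shrunken) nucleus with min separation
    foci: list[tuple[float, float, float]] = []
    for _ in range(200000):
        if len(foci) >= spec.n_foci:
            break
        cand = (
            center[0] + rng.uniform(-semi[0], semi[0]),
            center[1] + rng.uniform(-semi[1], semi[1]),
            center[2] + rng.uniform(-semi[2], semi[2]),
        )
        if not _inside_ellipsoid(cand, center, semi, shrink=0.85):
            continue
        if any(
            sum((a - b) ** 2 for a, b in zip(cand, f)) < spec.min_separation_nm**2
            for f in foci
        ):
            continue
        foci.append(cand)
    if len(foci) < spec.n_foci:
        raise ValueError("could not place the requested number of foci")

    rnap = np.full(spec.shape, spec.background, dtype=float)
    for f in foci:
        _add_gaussian(rnap, f, spec.focus_amplitude, spec.focus_sigma_nm, spec.voxel_nm)

    # FISH spots at controlled distances from their nearest focus
    foci_arr = np.array(foci)
    spots: list[tuple[float, float, float]] = []
    true_d: list[float] = []
    fish = np.full(spec.shape, spec.background, dtype=float)
    for d in spec.spot_distances_nm:
        placed = False
        for _ in range(200000):
            anchor = foci[int(rng.integers(0, len(foci)))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = tuple(np.array(anchor) + d * u)
            if not _inside_ellipsoid(cand, center, semi, shrink=0.85):
                continue
            dists = np.sqrt(((foci_arr - np.array(cand)) ** 2).sum(axis=1))
            if abs(dists.min() - d) > 1e-6 * max(d, 1.0):
                continue  # another focus would be nearer; the planted distance must be the minimum
            spots.append(cand)
            true_d.append(float(d))
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place a spot at distance {d} nm")
        _add_gaussian(fish, spots[-1], spec.spot_amplitude, spec.spot_sigma_nm, spec.voxel_nm)

    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0, spec.noise_sd, spec.shape)
        rnap = rnap + rng.normal(0, spec.noise_sd, spec.shape)
        fish = fish + rng.normal(0, spec.noise_sd, spec.shape)
    stack = ImageStack(
        channels={
            "dapi": np.clip(dapi, 0, None).astype(np.float32),
            "rnap": np.clip(rnap, 0, None).astype(np.float32),
            "fish": np.clip(fish, 0, None).astype(np.float32),
        },
        voxel_nm=spec.voxel_nm,
    )
    truth = {
        "foci_nm": [list(f) for f in foci],
        "spots_nm": [list(s) for s in spots],
        "true_distances_nm": true_d,
        "nucleus_center_nm": list(center),
        "nucleus_semiaxes_nm": list(semi),
    }
    return stack, truth
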