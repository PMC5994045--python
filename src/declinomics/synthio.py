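"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of input the analysis consumes, under a
model simple enough that the truth is known in closed form:

* structured diploid genotypes under the Balding-Nichols model, whose F
  parameter is the expected Weir-Cockerham F_ST;
* physically linked variant pairs with a tunable copy-error rate, to
  exercise r-squared pruning;
* heterozygous-site tracts from a pairwise (n=2) coalescent under a
  piecewise-constant Ne history, whose constant-Ne expectation is the
  classic 4*N*mu per site;
* coverage-style variant dropout at a planted false-negative rate;
* mock PSMC output files built by inverting the scaling equations, so that
  parse -> scale round-trips the generating history;
* occurrence points and habitat polygons of known area.

All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box

from .variants import VariantTable


@dataclass(frozen=True)
class StructuredGenotypeSpec:
    """Parameters of a Balding-Nichols structured-genotype draw.

    ``fst_target`` is the Balding-Nichols F: per-deme allele frequencies are
    Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral frequency p drawn
    uniformly from ``ancestral_freq_range``.
    """

    n_demes: int = 2
    n_per_deme: int = 50
    n_sites: int = 5_000
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    fst_target: float = 0.15
    seed: int = 0
    pos_stride: int = 1_000  # bp between consecutive synthetic sites

    def validate(self) -> None:
        lo, hi = self.ancestral_freq_range
        if self.n_demes < 2:
            raise ValueError("n_demes must be >= 2")
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError("fst_target must be in (0, 1)")
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        if self.n_per_deme < 1 or self.n_sites < 1:
            raise ValueError("n_per_deme and n_sites must be positive")


@dataclass(frozen=True)
class DropoutSpec:
    """Coverage-style dropout: each variant lost with probability fnr_true."""

    fnr_true: float
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.fnr_true < 1.0):
            raise ValueError("fnr_true must be in [0, 1)")


@dataclass
class NeHistory:
    """Piecewise-constant effective-size history.

    ``epochs`` is an ordered list of (start_time_years, ne) steps, start
    times strictly increasing from 0 (most recent epoch first). ``mu`` is
    the per-site per-generation mutation rate; ``gen_time`` years per
    generation.
    """

    epochs: list[tuple[float, float]]
    mu: float
    gen_time: float = 10.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("history needs at least one epoch")
        starts = [t for t, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all ne must be positive")
        if self.mu <= 0 or self.gen_time <= 0:
            raise ValueError("mu and gen_time must be positive")

    def ne_at_generation(self, g: float) -> float:
        """Ne of the epoch containing generation g before present."""
        ne = self.epochs[0][1]
        for start_years, n in self.epochs:
            if g >= start_years / self.gen_time:
                ne = n
            else:
                break
        return ne


@dataclass
class SyntheticTruth:
    """Generating parameters for a synthetic dataset, for estimator checks."""

    fst: float | None = None
    grouping: dict = field(default_factory=dict)
    ancestral_freqs: np.ndarray | None = None
    deme_freqs: np.ndarray | None = None
    ne_history: NeHistory | None = None
    fnr: float | None = None
    areas_km2: dict = field(default_factory=dict)


def gen_structured_genotypes(
    spec: StructuredGenotypeSpec,
) -> tuple[VariantTable, SyntheticTruth]:
    """Draw a multi-deme diploid genotype matrix under Balding-Nichols.

    Per site: ancestral frequency p ~ U(range); per-deme frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F); per-individual genotype
    ~ Binomial(2, deme frequency). Sites are placed on one contig at a
    fixed position stride. Returns the table and the generating truth
    (F, sample->deme grouping, frequencies).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    F = spec.fst_target
    lo, hi = spec.ancestral_freq_range
    p = rng.uniform(lo, hi, size=spec.n_sites)
    scale = (1.0 - F) / F
    deme_freq = rng.beta(
        np.outer(p, np.ones(spec.n_demes)) * scale,
        np.outer(1.0 - p, np.ones(spec.n_demes)) * scale,
    )  # (n_sites, n_demes)
    gt = np.empty((spec.n_sites, spec.n_demes * spec.n_per_deme), dtype=np.int8)
    samples: list[str] = []
    grouping: dict[str, str] = {}
    for d in range(spec.n_demes):
        cols = slice(d * spec.n_per_deme, (d + 1) * spec.n_per_deme)
        gt[:, cols] = rng.binomial(
            2, deme_freq[:, d][:, None], size=(spec.n_sites, spec.n_per_deme)
        ).astype(np.int8)
        for i in range(spec.n_per_deme):
            name = f"d{d}_s{i}"
            samples.append(name)
            grouping[name] = f"deme{d}"
    pos = (np.arange(spec.n_sites, dtype=np.int64) * spec.pos_stride) + 1
    table = VariantTable(
        contigs=np.array(["chr1"] * spec.n_sites, dtype=object),
        pos=pos,
        ref=np.array(["A"] * spec.n_sites, dtype=object),
        alt=np.array(["C"] * spec.n_sites, dtype=object),
        genotypes=gt,
        samples=samples,
    )
    truth = SyntheticTruth(
        fst=F, grouping=grouping, ancestral_freqs=p, deme_freqs=deme_freq
    )
    return table, truth


def gen_linked_pair(
    base_genotypes: np.ndarray, copy_error_rate: float, seed: int = 0
) -> np.ndarray:
    """Copy a genotype vector, redrawing each entry with the given error rate.

    Redraws come from Binomial(2, p-hat) with p-hat the base site's alternate
    allele frequency, so error 1 yields an independent site with the same
    frequency and error 0 an exact copy (r-squared 1).
    """
    if not (0.0 <= copy_error_rate <= 1.0):
        raise ValueError("copy_error_rate must be in [0, 1]")
    base = np.asarray(base_genotypes)
    called = base[base >= 0]
    if called.size == 0 or np.all(called == called[0]):
        raise ValueError("base site must be polymorphic")
    rng = np.random.default_rng(seed)
    p_hat = float(called.mean()) / 2.0
    out = base.copy()
    flip = rng.random(base.size) < copy_error_rate
    redraw = rng.binomial(2, p_hat, size=base.size).astype(base.dtype)
    out[flip & (base >= 0)] = redraw[flip & (base >= 0)]
    return out


def _draw_coalescent_times(
    history: NeHistory, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Pairwise coalescent times (generations) under the epoch race.

    Within an epoch of size Ne the pair coalesces at rate 1/(2*Ne) per
    generation; the draw races through epochs until one wins (the oldest
    epoch extends to infinity).
    """
    bounds_gen = [t / history.gen_time for t, _ in history.epochs] + [np.inf]
    times = np.full(n, np.nan)
    pending = np.arange(n)
    for e, (_, ne) in enumerate(history.epochs):
        if pending.size == 0:
            break
        start, end = bounds_gen[e], bounds_gen[e + 1]
        draw = start + rng.exponential(2.0 * ne, size=pending.size)
        done = draw < end
        times[pending[done]] = draw[done]
        pending = pending[~done]
    # anything still pending coalesces in the oldest epoch (end == inf above
    # guarantees this branch is unreachable, but guard against fp edge cases)
    if pending.size:
        _, ne = history.epochs[-1]
        times[pending] = bounds_gen[-2] + rng.exponential(2.0 * ne, size=pending.size)
    return times


def gen_het_tracts(
    history: NeHistory, n_blocks: int, block_len: int, seed: int = 0
) -> list[np.ndarray]:
    """Heterozygous-site positions per independent block of a diploid genome.

    Per block a pairwise coalescent time T (generations) is drawn from the
    piecewise-constant history; Poisson(2*mu*T*block_len) heterozygous sites
    are then placed uniformly (without replacement) in the block. Under
    constant Ne the per-site heterozygosity converges to 4*N*mu.
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    rng = np.random.default_rng(seed)
    T = _draw_coalescent_times(history, n_blocks, rng)
    blocks: list[np.ndarray] = []
    for t in T:
        k = rng.poisson(2.0 * history.mu * t * block_len)
        k = min(int(k), block_len)
        pos = rng.choice(block_len, size=k, replace=False) + 1
        blocks.append(np.sort(pos).astype(np.int64))
    return blocks


def apply_dropout(table: VariantTable, spec: DropoutSpec) -> VariantTable:
    """Remove each variant independently with probability ``fnr_true``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    keep = rng.random(table.n_sites) >= spec.fnr_true
    return table.take(keep)


def dropout_retained_count(n_variants: int, spec: DropoutSpec) -> int:
    """Number of variants surviving dropout, without materializing a table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    return int(np.sum(rng.random(n_variants) >= spec.fnr_true))


def gen_mock_psmc_file(
    history: NeHistory,
    n_intervals: int = 64,
    theta0: float = 0.05,
    s: int = 100,
    rho: float = 0.01,
) -> str:
    """Emit PSMC-format output text whose scaled parameters encode a history.

    The scaling equations are inverted: N0 = theta0/(4*mu*s), epoch start
    times become exact scaled-time knots t = years/(2*N0*gen_time), and
    each knot carries lambda = ne/N0. Padding knots (same lambda) are
    inserted within epochs to reach ``n_intervals``, so parse -> scale
    reproduces the step function exactly. Test-fixture behavior, not an
    emulation of PSMC inference.
    """
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    n0 = theta0 / (4.0 * history.mu * s)
    bounds = [t / (2.0 * n0 * history.gen_time) for t, _ in history.epochs]
    lambdas_b = [ne / n0 for _, ne in history.epochs]
    if n_intervals < len(bounds):
        raise ValueError("n_intervals smaller than number of epochs")

    knots: list[tuple[float, float]] = []
    n_extra = n_intervals - len(bounds)
    per_epoch = np.zeros(len(bounds), dtype=int)
    for i in range(n_extra):
        per_epoch[i % len(bounds)] += 1
    for e, (t_start, lam) in enumerate(zip(bounds, lambdas_b)):
        knots.append((t_start, lam))
        t_end = bounds[e + 1] if e + 1 < len(bounds) else (bounds[-1] * 2.0 + 1.0)
        for j in range(per_epoch[e]):
            frac = (j + 1) / (per_epoch[e] + 1)
            knots.append((t_start + frac * (t_end - t_start), lam))

    lines = ["RD\t0", f"TR\t{theta0:.6f}\t{rho:.6f}"]
    for k, (t, lam) in enumerate(knots):
        lines.append(f"RS\t{k}\t{float(t)!r}\t{float(lam)!r}\t0\t0")
    lines.append("//")
    return "\n".join(lines) + "\n"


@dataclass
class RangeFixture:
    """Occurrence points and habitat polygons with known areas (meters)."""

    points: list[tuple[float, float]]
    labels: list[str]
    habitat: Polygon
    truth: SyntheticTruth


def gen_range_fixture(
    seed: int = 0,
    width_m: float = 200_000.0,
    height_m: float = 100_000.0,
    n_interior: int = 20,
) -> RangeFixture:
    """Points whose hull is a known rectangle, plus a half-rectangle habitat.

    The four rectangle corners are in the point set, so the minimum convex
    polygon is the full rectangle (area width*height); the habitat is the
    left half, so the clipped area is exactly half the hull area. Interior
    points get cycled occurrence labels (subfossil / museum / modern).
    """
    rng = np.random.default_rng(seed)
    corners = [(0.0, 0.0), (width_m, 0.0), (width_m, height_m), (0.0, height_m)]
    interior = [
        (float(rng.uniform(0, width_m)), float(rng.uniform(0, height_m)))
        for _ in range(n_interior)
    ]
    points = corners + interior
    labels = ["subfossil", "subfossil", "museum", "modern"] + [
        ("subfossil", "museum", "modern")[i % 3] for i in range(n_interior)
    ]
    habitat = box(0.0, 0.0, width_m / 2.0, height_m)
    hull_km2 = width_m * height_m / 1e6
    truth = SyntheticTruth(
        areas_km2={
            "mcp": hull_km2,
            "habitat": hull_km2 / 2.0,
            "clipped": hull_km2 / 2.0,
        }
    )
    return RangeFixture(points=points, labels=labels, habitat=habitat, truth=truth)
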