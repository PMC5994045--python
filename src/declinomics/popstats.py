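"""Population statistics: Weir-Cockerham F_ST, heterozygosity, windowed pi,
genotype PCA and pairwise sequence distance.

The F_ST estimator is the Weir & Cockerham (1984) variance-components form
for diploid data without inbreeding structure beyond populations: per site,
variance is partitioned into components a (among populations), b (among
individuals within populations) and c (within individuals), and the
"weighted" multi-locus estimate is the ratio of sums sum(a) / sum(a+b+c) —
the figure vcftools prints as "weighted Fst".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable


class FstUndefinedError(ValueError):
    """Raised when the multi-locus F_ST denominator is zero (no variation)."""


@dataclass(frozen=True)
class HetSummary:
    """Genome-wide heterozygosity: variant count over genome length."""

    n_variants: int
    genome_length: int
    gwh: float


@dataclass(frozen=True)
class PDistance:
    """Pairwise p-distance between two aligned sequences."""

    n_substitutions: int
    n_compared: int
    distance: float


def _groups_as_indices(
    samples: Sequence[str], grouping: Mapping[str, str] | Sequence[str]
) -> dict[str, np.ndarray]:
    """Map group label -> column indices; grouping is sample->label or a
    label sequence aligned to the sample order."""
    if isinstance(grouping, Mapping):
        labels = [grouping[s] for s in samples]
    else:
        if len(grouping) != len(samples):
            raise ValueError("grouping length does not match number of samples")
        labels = list(grouping)
    out: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(labels):  # preserve first-seen order
        out[g] = np.array([i for i, l in enumerate(labels) if l == g], dtype=int)
    if len(out) < 2:
        raise ValueError("F_ST requires at least two groups")
    return out


def wc_site_components(
    genotypes: np.ndarray, group_cols: Sequence[np.ndarray]
) -> tuple[float, float, float] | None:
    """Weir-Cockerham (1984) a, b, c for one biallelic site.

    ``genotypes`` is the 0/1/2/missing dosage row; ``group_cols`` the column
    indices of each population. Returns None when fewer than two populations
    have called genotypes (site unusable).
    """
    n_i, p_i, h_i = [], [], []
    for cols in group_cols:
        g = genotypes[cols]
        g = g[g != MISSING]
        if g.size == 0:
            continue
        n_i.append(g.size)
        p_i.append(float(np.sum(g)) / (2 * g.size))
        h_i.append(float(np.sum(g == 1)) / g.size)
    r = len(n_i)
    if r < 2:
        return None
    n_arr = np.array(n_i, dtype=float)
    p_arr = np.array(p_i)
    h_arr = np.array(h_i)

    n_bar = n_arr.mean()
    if n_bar <= 1:
        return None
    n_total = n_arr.sum()
    n_c = (n_total - np.sum(n_arr**2) / n_total) / (r - 1)
    p_bar = float(np.sum(n_arr * p_arr) / n_total)
    s2 = float(np.sum(n_arr * (p_arr - p_bar) ** 2) / ((r - 1) * n_bar))
    h_bar = float(np.sum(n_arr * h_arr) / n_total)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def weir_cockerham_fst(
    table: VariantTable, grouping: Mapping[str, str] | Sequence[str]
) -> tuple[float, pd.DataFrame]:
    """Weighted (ratio-of-sums) Weir-Cockerham F_ST across all sites.

    Returns the multi-locus estimate and a per-site component table with
    columns contig, pos, a, b, c. Sites where fewer than two groups have
    calls are skipped. The estimate can be negative (no differentiation).

    Raises
    ------
    FstUndefinedError
        If sum(a+b+c) over all usable sites is zero (e.g. all monomorphic).
    """
    groups = _groups_as_indices(table.samples, grouping)
    cols = list(groups.values())
    gt = table.genotypes

    # per-group sample sizes, alt-allele and heterozygote frequencies, per site
    n = np.empty((table.n_sites, len(cols)))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, c in enumerate(cols):
        sub = gt[:, c]
        called = sub != MISSING
        n[:, k] = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.where(sub != MISSING, sub, 0).sum(axis=1) / (2 * n[:, k])
            h[:, k] = (sub == 1).sum(axis=1) / n[:, k]
    p = np.nan_to_num(p)
    h = np.nan_to_num(h)

    r = (n > 0).sum(axis=1).astype(float)
    n_total = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_total / r
        n_c = (n_total - (n**2).sum(axis=1) / n_total) / (r - 1)
        p_bar = (n * p).sum(axis=1) / n_total
        s2 = (n * (p - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=1) / n_total
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2

    usable = (r >= 2) & (n_bar > 1)
    frame = pd.DataFrame(
        {
            "contig": table.contigs[usable],
            "pos": table.pos[usable],
            "a": a[usable],
            "b": b[usable],
            "c": c[usable],
        }
    )
    denom = float(frame[["a", "b", "c"]].to_numpy().sum()) if len(frame) else 0.0
    if denom == 0.0:
        raise FstUndefinedError("F_ST undefined: zero total variance (monomorphic data?)")
    fst = float(frame["a"].sum()) / denom
    return fst, frame


def genome_wide_het(n_variants: int, genome_length: int) -> HetSummary:
    """Heterozygous-variant count divided by genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    return HetSummary(int(n_variants), int(genome_length), n_variants / genome_length)


def site_pi(genotypes: np.ndarray) -> float:
    """Per-site nucleotide diversity from called diploid genotypes.

    Mean pairwise difference among the called alleles: with n called alleles
    of which k are the alternate, pi = k(n-k)/C(n,2) — the unbiased
    2*p*(1-p)*n/(n-1) form.
    """
    g = genotypes[genotypes != MISSING]
    n = 2 * g.size
    if n < 2:
        return 0.0
    k = int(np.sum(g))
    return k * (n - k) / (n * (n - 1) / 2)


def windowed_pi(table: VariantTable, window: int = 100_000) -> pd.DataFrame:
    """Nucleotide diversity averaged over fixed, tiling windows.

    Windows tile each contig half-open from base 1: [1, window+1), ... .
    Window pi is the sum of per-site pi over the window length, so empty
    windows between the first and last variant of a contig report 0.

    Returns a frame with columns contig, start, end (1-based inclusive), pi.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    table.require_sorted()
    acc: dict[tuple, float] = {}
    max_pos: dict = {}
    for i in range(table.n_sites):
        c = table.contigs[i]
        w = (int(table.pos[i]) - 1) // window
        acc[(c, w)] = acc.get((c, w), 0.0) + site_pi(table.genotypes[i])
        max_pos[c] = max(max_pos.get(c, 0), w)
    rows = []
    for c in dict.fromkeys(table.contigs):
        for w in range(max_pos[c] + 1):
            rows.append(
                (c, w * window + 1, (w + 1) * window, acc.get((c, w), 0.0) / window)
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "pi"])


def genotype_pca(
    table: VariantTable, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples on mean-centered genotype dosages.

    Missing calls are imputed to the site mean (so they contribute nothing
    after centering). Returns (coordinates, variance_fractions): coordinates
    are the sample projections on the principal axes, shape
    ``(n_samples, k)`` with ``k = min(n_samples, n_sites)``; fractions are
    each axis's share of total variance, non-increasing, summing to <= 1.
    With ``scale=True`` columns are standardized to unit variance first.
    """
    if table.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    d = table.dosages().T  # samples x sites
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    d = d - d.mean(axis=0)
    if scale:
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        d = d / sd
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    coords = u * s
    total = float(np.sum(d * d))
    if total == 0.0:
        fractions = np.zeros(s.size)
    else:
        fractions = s**2 / total
    return coords, fractions


_UNAMBIGUOUS = frozenset("ACGT")


def pairwise_p_distance(seq_a, seq_b) -> PDistance:
    """Uncorrected p-distance between two aligned sequences.

    Positions where either sequence has a gap or an ambiguous base (anything
    outside A/C/G/T, case-insensitive) are excluded from both numerator and
    denominator.
    """
    a = str(seq_a).upper()
    b = str(seq_b).upper()
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    n_comp = 0
    n_diff = 0
    for x, y in zip(a, b):
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS:
            n_comp += 1
            if x != y:
                n_diff += 1
    dist = n_diff / n_comp if n_comp else 0.0
    return PDistance(n_diff, n_comp, dist)
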