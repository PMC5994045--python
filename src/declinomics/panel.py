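"""SNV panel construction: the shared -> spaced -> LD-pruned -> variable ladder.

The ladder mirrors the marker-design workflow used for genotyping panels in
conservation genomics: start from variants genotyped in every individual and
polymorphic across the sample set, enforce a minimum physical spacing to
reduce linkage, prune residual linkage by genotype r-squared, and finally
keep only highly variable sites (both homozygote classes observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

DEFAULT_MIN_GAP = 50_000  # bp between retained sites
DEFAULT_R2_MAX = 0.2
DEFAULT_WINDOW = 1_000_000  # bp; pairs farther apart are never compared

#: r-squared report bins: exact 1, then half-open intervals, then exact 0.
R2_BINS = ("r2=1", "(0.75,1)", "(0.5,0.75]", "(0.25,0.5]", "(0.1,0.25]", "(0,0.1]", "r2=0")

_EPS = 1e-12  # tolerance for the exact-0 / exact-1 singleton bins


class UndefinedR2Error(ValueError):
    """Raised when genotype r-squared is undefined (zero dosage variance)."""


@dataclass
class FilterLadderReport:
    """Retained-site counts per ladder stage, in application order."""

    stages: list[str] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)

    def add(self, stage: str, count: int) -> None:
        if self.counts and count > self.counts[-1]:
            raise ValueError(
                f"ladder counts must be non-increasing: {stage}={count} after {self.counts[-1]}"
            )
        self.stages.append(stage)
        self.counts.append(int(count))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": self.stages, "retained": self.counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_shared_polymorphic(table: VariantTable) -> VariantTable:
    """Keep sites genotyped in every sample and polymorphic across the set.

    A site is polymorphic when both the reference and the alternate allele are
    observed among the calls (any het counts for both).
    """
    gt = table.genotypes
    called_everywhere = np.all(gt != MISSING, axis=1)
    has_ref = np.any((gt == 0) | (gt == 1), axis=1)
    has_alt = np.any((gt == 1) | (gt == 2), axis=1)
    return table.take(called_everywhere & has_ref & has_alt)


def thin_by_spacing(table: VariantTable, min_gap: int = DEFAULT_MIN_GAP) -> VariantTable:
    """Greedy left-to-right spacing filter, independently per contig.

    The first site on each contig is kept; every later site is kept iff its
    position is at least ``min_gap`` beyond the last kept position.
    """
    table.require_sorted()
    keep = np.zeros(table.n_sites, dtype=bool)
    last_pos: dict = {}
    for i in range(table.n_sites):
        c = table.contigs[i]
        if c not in last_pos or table.pos[i] - last_pos[c] >= min_gap:
            keep[i] = True
            last_pos[c] = table.pos[i]
    return table.take(keep)


def genotype_r2(site_a: np.ndarray, site_b: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype-dosage vectors.

    Computed over samples with non-missing calls at both sites (complete
    pairs); this is the unphased genotype r-squared of vcftools --geno-r2.

    Raises
    ------
    UndefinedR2Error
        If fewer than two complete pairs remain or either dosage vector has
        zero variance over the intersection.
    """
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    ok = (np.asarray(site_a) != MISSING) & (np.asarray(site_b) != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise UndefinedR2Error("fewer than two samples called at both sites")
    a = a - a.mean()
    b = b - b.mean()
    va = float(a @ a)
    vb = float(b @ b)
    if va == 0.0 or vb == 0.0:
        raise UndefinedR2Error("zero dosage variance at one of the sites")
    cov = float(a @ b)
    return cov * cov / (va * vb)


def prune_by_ld(
    table: VariantTable,
    r2_max: float = DEFAULT_R2_MAX,
    window: int = DEFAULT_WINDOW,
) -> VariantTable:
    """Left-to-right LD pruning against previously retained sites.

    A candidate is retained iff its genotype r-squared against every already
    retained site within ``window`` bp on the same contig is below ``r2_max``.
    Pairs with undefined r-squared never block retention.
    """
    table.require_sorted()
    keep = np.zeros(table.n_sites, dtype=bool)
    kept_idx: dict = {}  # contig -> list of retained site indices
    for i in range(table.n_sites):
        c = table.contigs[i]
        retained = kept_idx.setdefault(c, [])
        ok = True
        for j in reversed(retained):
            if table.pos[i] - table.pos[j] > window:
                break
            try:
                r2 = genotype_r2(table.genotypes[i], table.genotypes[j])
            except UndefinedR2Error:
                continue
            if r2 >= r2_max:
                ok = False
                break
        if ok:
            keep[i] = True
            retained.append(i)
    return table.take(keep)


def variability_filter(table: VariantTable, require_het: bool = False) -> VariantTable:
    """Keep sites with at least one hom-ref and one hom-alt individual.

    With ``require_het=True`` a heterozygote must additionally be present
    (all three genotype classes observed).
    """
    gt = table.genotypes
    keep = np.any(gt == 0, axis=1) & np.any(gt == 2, axis=1)
    if require_het:
        keep &= np.any(gt == 1, axis=1)
    return table.take(keep)


def r2_bin_report(
    table: VariantTable,
    window: int | None = DEFAULT_WINDOW,
    per_site_max: bool = True,
) -> dict[str, int]:
    """Classify linkage into the standard r-squared bins.

    By default each site contributes its maximum r-squared against any other
    site (within ``window`` bp, same contig), so the bin counts sum to the
    number of classifiable sites. With ``per_site_max=False`` every site pair
    is classified instead. ``window=None`` compares all same-contig pairs.
    """
    table.require_sorted()
    values: list[float] = []
    if per_site_max:
        best = np.full(table.n_sites, np.nan)
        for i, j, r2 in _iter_pairs(table, window):
            if np.isnan(best[i]) or r2 > best[i]:
                best[i] = r2
            if np.isnan(best[j]) or r2 > best[j]:
                best[j] = r2
        values = [v for v in best if not np.isnan(v)]
    else:
        values = [r2 for _, _, r2 in _iter_pairs(table, window)]

    counts = dict.fromkeys(R2_BINS, 0)
    for r2 in values:
        counts[_classify(r2)] += 1
    return counts


def _iter_pairs(table: VariantTable, window: int | None):
    for i in range(table.n_sites):
        for j in range(i + 1, table.n_sites):
            if table.contigs[j] != table.contigs[i]:
                break
            if window is not None and table.pos[j] - table.pos[i] > window:
                break
            try:
                yield i, j, genotype_r2(table.genotypes[i], table.genotypes[j])
            except UndefinedR2Error:
                continue


def _classify(r2: float) -> str:
    if r2 >= 1.0 - _EPS:
        return "r2=1"
    if r2 > 0.75:
        return "(0.75,1)"
    if r2 > 0.5:
        return "(0.5,0.75]"
    if r2 > 0.25:
        return "(0.25,0.5]"
    if r2 > 0.1:
        return "(0.1,0.25]"
    if r2 > _EPS:
        return "(0,0.1]"
    return "r2=0"


def build_panel(
    table: VariantTable,
    min_gap: int = DEFAULT_MIN_GAP,
    r2_max: float = DEFAULT_R2_MAX,
    window: int = DEFAULT_WINDOW,
) -> tuple[VariantTable, FilterLadderReport]:
    """Run the full filter ladder and report per-stage retained counts."""
    report = FilterLadderReport()
    report.add("input", table.n_sites)
    t = select_shared_polymorphic(table)
    report.add("shared_polymorphic", t.n_sites)
    t = thin_by_spacing(t, min_gap=min_gap)
    report.add(f"spaced_{min_gap}bp", t.n_sites)
    t = prune_by_ld(t, r2_max=r2_max, window=window)
    report.add(f"ld_pruned_r2<{r2_max}", t.n_sites)
    t = variability_filter(t)
    report.add("both_homozygotes", t.n_sites)
    return t, report
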