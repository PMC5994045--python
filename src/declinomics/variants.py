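"""Genotype table container shared by the panel and population-statistics modules.

A :class:`VariantTable` holds biallelic SNVs as an ordered list of sites
(contig, 1-based position, ref allele, alt allele) and a sites x samples
matrix of diploid genotype dosages: 0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: genotype code for a missing call
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


class VariantTableError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class VariantTable:
    """Biallelic SNVs with diploid genotype dosages.

    Parameters
    ----------
    contigs
        Contig identifier per site, shape ``(n_sites,)``.
    pos
        1-based base position per site, strictly increasing within a contig.
    ref, alt
        Single-base reference and alternate alleles per site.
    genotypes
        ``(n_sites, n_samples)`` integer matrix with codes {0, 1, 2, -1}.
    samples
        Sample identifiers, one per genotype column.
    """

    contigs: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise VariantTableError("genotypes must be a 2-D sites x samples matrix")
        n = self.genotypes.shape[0]
        if not (len(self.contigs) == len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise VariantTableError("site arrays and genotype rows disagree in length")
        if self.samples and len(self.samples) != self.genotypes.shape[1]:
            raise VariantTableError("sample names and genotype columns disagree in length")
        if not self.samples:
            self.samples = [f"s{i}" for i in range(self.genotypes.shape[1])]
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise VariantTableError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def is_sorted(self) -> bool:
        """True if positions are strictly increasing within every contig run."""
        for i in range(1, self.n_sites):
            if self.contigs[i] == self.contigs[i - 1] and self.pos[i] <= self.pos[i - 1]:
                return False
        return True

    def require_sorted(self) -> None:
        if not self.is_sorted():
            raise VariantTableError(
                "table must be position-sorted (strictly increasing within contigs)"
            )

    def take(self, idx) -> "VariantTable":
        """Subset of sites by integer or boolean index, preserving order."""
        idx = np.asarray(idx)
        return VariantTable(
            contigs=self.contigs[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[idx],
            samples=list(self.samples),
        )

    def dosages(self) -> np.ndarray:
        """Genotype matrix as float with missing calls set to NaN."""
        d = self.genotypes.astype(float)
        d[self.genotypes == MISSING] = np.nan
        return d

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, VariantTable):
            return NotImplemented
        return (
            list(self.contigs) == list(other.contigs)
            and np.array_equal(self.pos, other.pos)
            and list(self.ref) == list(other.ref)
            and list(self.alt) == list(other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
            and self.samples == other.samples
        )
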