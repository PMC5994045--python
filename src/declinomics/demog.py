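"""Demographic post-processing around PSMC.

PSMC (pairwise sequentially Markovian coalescent) infers scaled population
parameters from a single diploid genome's heterozygosity pattern. This
module covers the measurable arithmetic around a PSMC run:

* false-negative-rate (FNR) estimation from a doubled-input remapping,
* encoding binned heterozygosity into the psmcfa input format,
* parsing PSMC output text (TR / RS records of the final EM round),
* converting scaled output (theta0, t_k, lambda_k) to an effective-size
  trajectory in individuals and years, with the FNR correction
  theta_corr = theta0 / (1 - FNR) applied before scaling,
* decline percentages between trajectory points.

The PSMC HMM/EM itself is out of scope; inputs are encoded for it and its
outputs are consumed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN = 100  # bases summarized per psmcfa symbol
DEFAULT_GEN_TIME = 10.0  # years per generation


class PsmcFormatError(ValueError):
    """Raised on malformed PSMC output text."""


@dataclass(frozen=True)
class FnrEstimate:
    """False negative rate from a doubled-input variant recount.

    ``n_high`` variants found with doubled read input, ``n_low`` with the
    standard input; fnr = (n_high - n_low) / n_high.
    """

    n_high: int
    n_low: int
    fnr: float


@dataclass
class PsmcRaw:
    """Final-round scaled parameters read from a PSMC output file.

    theta0 is the per-bin scaled mutation parameter from the TR record;
    times (in 2*N0 units, strictly increasing from 0) and lambdas (relative
    sizes N_k/N0) come from the RS records.
    """

    theta0: float
    times: np.ndarray
    lambdas: np.ndarray
    round_index: int = -1
    rho: float | None = None


@dataclass
class NeTrajectory:
    """Step function of effective population size vs. time in years.

    Step k covers [times_years[k], times_years[k+1]) — right-continuous —
    with the last step extending to infinity. n0 is the most recent
    effective size theta_corr / (4 * mu * s).
    """

    times_years: np.ndarray
    ne: np.ndarray
    n0: float
    mu: float
    s: int
    gen_time: float
    fnr: float = 0.0

    def __post_init__(self) -> None:
        self.times_years = np.asarray(self.times_years, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if self.times_years.size != self.ne.size:
            raise ValueError("times and ne must have equal length")
        if np.any(np.diff(self.times_years) <= 0):
            raise ValueError("step times must be strictly increasing")
        if np.any(self.ne <= 0):
            raise ValueError("effective sizes must be positive")


def estimate_fnr(n_high: int, n_low: int) -> FnrEstimate:
    """FNR = (n_high - n_low) / n_high from a doubled-input recount."""
    if n_high <= 0:
        raise ValueError("n_high must be positive")
    if n_low > n_high:
        raise ValueError(f"n_low ({n_low}) exceeds n_high ({n_high})")
    if n_low < 0:
        raise ValueError("n_low must be non-negative")
    return FnrEstimate(int(n_high), int(n_low), (n_high - n_low) / n_high)


def encode_psmcfa(
    het_positions: Mapping[str, Iterable[int]],
    contig_lengths: Mapping[str, int],
    mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    bin_size: int = DEFAULT_BIN,
    missing_frac: float = 0.5,
    line_width: int = 60,
) -> str:
    """Encode per-contig heterozygous-site positions as psmcfa text.

    Each ``bin_size``-base bin becomes one symbol: 'K' if it contains at
    least one heterozygous site, 'T' otherwise, or 'N' if more than
    ``missing_frac`` of its bases fall in a masked interval. Mask intervals
    are 1-based inclusive (start, end) pairs per contig. Output is
    FASTA-like, ``line_width`` symbols per line.
    """
    out = []
    for contig, length in contig_lengths.items():
        length = int(length)
        n_bins = (length + bin_size - 1) // bin_size
        het_bins = np.zeros(n_bins, dtype=bool)
        for p in het_positions.get(contig, ()):  # 1-based positions
            p = int(p)
            if not (1 <= p <= length):
                raise ValueError(f"position {p} out of bounds for {contig} (len {length})")
            het_bins[(p - 1) // bin_size] = True
        masked_bases = np.zeros(n_bins, dtype=float)
        if mask:
            for start, end in mask.get(contig, ()):  # 1-based inclusive
                start, end = int(start), int(end)
                if start > end:
                    continue
                base = np.zeros(length, dtype=bool)
                base[max(start - 1, 0) : min(end, length)] = True
                for b in range(n_bins):
                    masked_bases[b] += base[b * bin_size : (b + 1) * bin_size].sum()
        symbols = []
        for b in range(n_bins):
            bin_len = min(bin_size, length - b * bin_size)
            if masked_bases[b] / bin_len > missing_frac:
                symbols.append("N")
            elif het_bins[b]:
                symbols.append("K")
            else:
                symbols.append("T")
        seq = "".join(symbols)
        out.append(f">{contig}")
        for i in range(0, len(seq), line_width):
            out.append(seq[i : i + line_width])
    return "\n".join(out) + "\n"


_TR_RE = re.compile(r"^TR\t([0-9.eE+-]+)(?:\t([0-9.eE+-]+))?")


def parse_psmc(text: str, round_index: int = -1) -> PsmcRaw:
    """Read theta0 and the (t_k, lambda_k) knots from PSMC output text.

    PSMC output contains one block per EM round, each with a ``TR`` record
    (theta0, rho) and ``RS`` records (index, t_k, lambda_k, ...). By default
    the final round — the converged estimate — is returned; earlier rounds
    are reachable via ``round_index``.
    """
    blocks: list[dict] = []
    current: dict | None = None
    for line in text.splitlines():
        if line.startswith("RD"):
            current = {"rs": []}
            blocks.append(current)
        elif line.startswith("TR"):
            m = _TR_RE.match(line)
            if not m:
                raise PsmcFormatError(f"unparseable TR record: {line!r}")
            if current is None:
                current = {"rs": []}
                blocks.append(current)
            current["theta0"] = float(m.group(1))
            current["rho"] = float(m.group(2)) if m.group(2) else None
        elif line.startswith("RS"):
            parts = line.split("\t")
            if len(parts) < 4:
                raise PsmcFormatError(f"unparseable RS record: {line!r}")
            if current is None:
                current = {"rs": []}
                blocks.append(current)
            current["rs"].append((float(parts[2]), float(parts[3])))
    blocks = [b for b in blocks if "theta0" in b and b["rs"]]
    if not blocks:
        raise PsmcFormatError("no complete TR/RS block found")
    try:
        block = blocks[round_index]
    except IndexError:
        raise PsmcFormatError(f"round {round_index} not present ({len(blocks)} blocks)")
    times = np.array([t for t, _ in block["rs"]])
    lambdas = np.array([l for _, l in block["rs"]])
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise PsmcFormatError("RS times must start at 0 and be strictly increasing")
    if np.any(lambdas <= 0):
        raise PsmcFormatError("RS lambdas must be positive")
    if block["theta0"] <= 0:
        raise PsmcFormatError("theta0 must be positive")
    idx = round_index if round_index >= 0 else len(blocks) + round_index
    return PsmcRaw(block["theta0"], times, lambdas, round_index=idx, rho=block["rho"])


def scale_psmc_output(
    raw: PsmcRaw,
    mu: float,
    gen_time: float = DEFAULT_GEN_TIME,
    s: int = DEFAULT_BIN,
    fnr: float = 0.0,
) -> NeTrajectory:
    """Convert scaled PSMC output to individuals and years.

    With theta_corr = theta0 / (1 - fnr):

    * N0 = theta_corr / (4 * mu * s)
    * step k: ne = lambda_k * N0, time = 2 * N0 * t_k * gen_time years.

    ``mu`` is the per-site per-generation mutation rate, ``s`` the bin size
    the psmcfa input used, ``gen_time`` the generation time in years.
    """
    if not (0.0 <= fnr < 1.0):
        raise ValueError("fnr must be in [0, 1)")
    if mu <= 0 or gen_time <= 0 or s <= 0:
        raise ValueError("mu, gen_time and s must be positive")
    theta_corr = raw.theta0 / (1.0 - fnr)
    n0 = theta_corr / (4.0 * mu * s)
    times_years = 2.0 * n0 * raw.times * gen_time
    ne = raw.lambdas * n0
    return NeTrajectory(times_years, ne, n0, mu=mu, s=s, gen_time=gen_time, fnr=fnr)


def ne_at(traj: NeTrajectory, time_years: float) -> float:
    """Effective size at a time before present (right-continuous step lookup).

    A query beyond the last knot returns the oldest step's value (logged).
    """
    if time_years < 0:
        raise ValueError("time must be non-negative")
    idx = int(np.searchsorted(traj.times_years, time_years, side="right")) - 1
    if time_years >= traj.times_years[-1]:
        if time_years > traj.times_years[-1]:
            logger.info(
                "query %.0f y beyond last knot %.0f y; using oldest step",
                time_years,
                traj.times_years[-1],
            )
        idx = traj.ne.size - 1
    return float(traj.ne[max(idx, 0)])


def percent_decline(n_from: float, n_to: float) -> float:
    """Percent decline from ``n_from`` to ``n_to``: 100*(n_from-n_to)/n_from."""
    if n_from <= 0:
        raise ValueError("n_from must be positive")
    return 100.0 * (n_from - n_to) / n_from


def mean_decline(pairs: Sequence[tuple[float, float]]) -> float:
    """Arithmetic mean of per-pair percent declines."""
    if not pairs:
        raise ValueError("pairs must be non-empty")
    return float(np.mean([percent_decline(a, b) for a, b in pairs]))


def trajectory_to_frame(traj: NeTrajectory):
    """Trajectory as a (time_years, ne) table ready for step plotting."""
    import pandas as pd

    return pd.DataFrame({"time_years": traj.times_years, "ne": traj.ne})
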