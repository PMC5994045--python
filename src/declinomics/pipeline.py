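"""End-to-end synthetic pipeline: simulate -> panel -> popstats -> demog -> range.

`run_pipeline` chains every stage on synthetic inputs with known truth and
collects the headline numbers into a :class:`RunReport`. It is deterministic
under ``config.seed`` and writes plain-text TSV/JSON reports only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from . import demog, panel, popstats, rangegeo, synthio

#: sub-stream offsets so stages draw from independent seeded generators
_STREAMS = {"genotypes": 1, "dropout": 2, "tracts": 3, "range": 4}


@dataclass
class PipelineConfig:
    """Run parameters. ``mu`` (per-site per-generation mutation rate) has no
    default: it must come from an external estimate for the study organism.
    """

    mu: float
    gen_time: float = 10.0  # years
    bin_size: int = 100  # bases per psmcfa symbol
    min_gap: int = 50_000  # bp spacing filter
    r2_max: float = 0.2
    window: int = 1_000_000  # bp LD comparison window
    pi_window: int = 100_000  # bp diversity window
    census: float = 1_000.0  # modern census size, individuals
    seed: int = 0
    # synthetic-input sizes (study-like defaults: 2 demes, diploid samples)
    n_demes: int = 2
    n_per_deme: int = 50
    n_sites: int = 5_000
    fst_target: float = 0.15
    pos_stride: int = 20_000  # bp between simulated sites
    fnr_true: float = 0.12
    n_dropout_variants: int = 1_000_000
    ne_history: list = field(
        default_factory=lambda: [(0.0, 109_000.0), (60_000.0, 1_000_000.0), (90_000.0, 100_000.0)]
    )
    extant_area_km2: float = 500.0
    buffers_m: tuple = (0.0, 500.0, 1_000.0, 5_000.0)

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_time <= 0:
            raise ValueError("mu and gen_time must be positive")
        if self.min_gap <= 0 or self.bin_size <= 0 or self.pi_window <= 0:
            raise ValueError("lengths must be positive")
        if not (0 <= self.fnr_true < 1):
            raise ValueError("fnr_true must be in [0, 1)")

    def sub_seed(self, stream: str) -> int:
        return (self.seed * 1_000 + _STREAMS[stream]) % (2**31 - 1)


@dataclass
class RunReport:
    """Headline numbers of a pipeline run, traceable to single operations."""

    config: dict
    ladder: pd.DataFrame
    fst_weighted: float
    fst_target: float
    gwh: float
    pca_variance_fractions: list
    fnr_percent: float
    fnr_true_percent: float
    n0: float
    peak_ne: float
    ne_20kybp: float
    decline_peak_to_census_percent: float
    decline_20kybp_to_census_percent: float
    range_table: pd.DataFrame
    version: str = _pkg_version

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k not in ("ladder", "range_table")}
        d["ladder"] = self.ladder.to_dict(orient="list")
        d["range_table"] = self.range_table.to_dict(orient="list")
        return d

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ladder.to_csv(outdir / "filter_ladder.tsv", sep="\t", index=False)
        self.range_table.to_csv(outdir / "range_scenarios.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True, default=float)
        )


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Run every stage on seeded synthetic inputs and collect the results."""
    # --- simulate structured genotypes and build the SNV panel -------------
    spec = synthio.StructuredGenotypeSpec(
        n_demes=config.n_demes,
        n_per_deme=config.n_per_deme,
        n_sites=config.n_sites,
        fst_target=config.fst_target,
        seed=config.sub_seed("genotypes"),
        pos_stride=config.pos_stride,
    )
    table, truth = synthio.gen_structured_genotypes(spec)
    panel_table, ladder = panel.build_panel(
        table, min_gap=config.min_gap, r2_max=config.r2_max, window=config.window
    )

    # --- population statistics --------------------------------------------
    shared = panel.select_shared_polymorphic(table)
    fst, _ = popstats.weir_cockerham_fst(shared, truth.grouping)
    genome_length = config.n_sites * config.pos_stride
    gwh = popstats.genome_wide_het(shared.n_sites, genome_length).gwh
    _, pca_fracs = popstats.genotype_pca(shared)

    # --- demographic history ----------------------------------------------
    drop_spec = synthio.DropoutSpec(config.fnr_true, seed=config.sub_seed("dropout"))
    n_low = synthio.dropout_retained_count(config.n_dropout_variants, drop_spec)
    fnr_est = demog.estimate_fnr(config.n_dropout_variants, n_low)
    history = synthio.NeHistory(
        epochs=[(float(t), float(n)) for t, n in config.ne_history],
        mu=config.mu,
        gen_time=config.gen_time,
    )
    psmc_text = synthio.gen_mock_psmc_file(history, theta0=0.05, s=config.bin_size)
    raw = demog.parse_psmc(psmc_text)
    traj = demog.scale_psmc_output(
        raw, mu=config.mu, gen_time=config.gen_time, s=config.bin_size, fnr=0.0
    )
    peak = float(traj.ne.max())
    ne20k = demog.ne_at(traj, 20_000.0)
    decline_peak = demog.percent_decline(peak, config.census)
    decline_20k = demog.percent_decline(ne20k, config.census)

    # --- historical range ---------------------------------------------------
    fixture = synthio.gen_range_fixture(seed=config.sub_seed("range"))
    scenarios = [
        rangegeo.RangeScenario(
            name=f"buffer_{int(b)}m",
            points=fixture.points,
            habitat=fixture.habitat,
            buffer_distance_m=b,
            extant_area_km2=config.extant_area_km2,
        )
        for b in config.buffers_m
    ]
    range_table = rangegeo.scenario_table(scenarios)

    report = RunReport(
        config=asdict(config),
        ladder=ladder.to_frame(),
        fst_weighted=fst,
        fst_target=config.fst_target,
        gwh=gwh,
        pca_variance_fractions=[float(f) for f in pca_fracs[:10]],
        fnr_percent=100.0 * fnr_est.fnr,
        fnr_true_percent=100.0 * config.fnr_true,
        n0=traj.n0,
        peak_ne=peak,
        ne_20kybp=ne20k,
        decline_peak_to_census_percent=decline_peak,
        decline_20kybp_to_census_percent=decline_20k,
        range_table=range_table,
    )
    if outdir is not None:
        report.write(outdir)
    return report
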