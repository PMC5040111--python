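"""Synthetic inputs with known ground truth for every pipeline stage.

All generators are pure functions of their spec and an explicit seed; a
single pseudo-random stream is drawn per call and no global state is
touched. Block and noise effects are multiplicative lognormal so that
concentrations and signal intensities stay positive, and the interaction
term is injected only into the combined (CW) cell, as a percent deviation
from additivity. In the noiseless limit each generated cell mean
reproduces its specified percent effects exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from warmclip.design import TREATMENT_FLAGS, TREATMENTS, FactorialDesign
from warmclip.geochip_preprocess import PROBE_COLUMNS
from warmclip.teco_inversion import (
    DEFAULT_BOUNDS,
    CarbonState,
    DriverSeries,
    ObservationSet,
    TecoParameters,
    simulate_teco,
)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect structure for one measured variable.

    Percent effects are relative to the control (UU) cell: warming alone
    yields baseline * (1 + warming_pct/100), clipping alone
    baseline * (1 + clipping_pct/100), and the combined cell
    baseline * (1 + (warming_pct + clipping_pct + interaction_pct)/100),
    so ``interaction_pct`` equals the true OE - PE.
    """

    variable: str
    baseline: float
    warming_pct: float = 0.0
    clipping_pct: float = 0.0
    interaction_pct: float = 0.0
    block_sd: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.block_sd < 0 or self.noise_sd < 0:
            raise ValueError("block_sd and noise_sd must be nonnegative")
        effects = (self.warming_pct, self.clipping_pct, self.interaction_pct)
        if self.baseline == 0 and any(e != 0 for e in effects):
            raise ValueError(
                f"variable {self.variable!r}: zero baseline with nonzero "
                "percent effect is undefined (effects are relative)"
            )

    def cell_multiplier(self, treatment: str) -> float:
        warmed, clipped = TREATMENT_FLAGS[treatment]
        pct = self.warming_pct * warmed + self.clipping_pct * clipped
        if warmed and clipped:
            pct += self.interaction_pct
        return 1.0 + pct / 100.0


def generate_factorial_properties(
    design: FactorialDesign,
    specs: list[EffectSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a long-format property table (block, warmed, clipped, vars)."""
    if design.n_blocks < 2:
        raise ValueError("need at least 2 blocks for paired analyses")
    rng = np.random.default_rng(seed)
    rows = []
    for block in design.blocks:
        for trt in TREATMENTS:
            warmed, clipped = TREATMENT_FLAGS[trt]
            rows.append({"block": block, "warmed": warmed, "clipped": clipped})
    table = pd.DataFrame(rows)
    for spec in specs:
        block_mult = {
            b: np.exp(rng.normal(0.0, spec.block_sd)) if spec.block_sd else 1.0
            for b in design.blocks
        }
        values = []
        for row in table.itertuples(index=False):
            trt = ("C" if row.clipped else "U") + ("W" if row.warmed else "U")
            noise = (
                np.exp(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else 1.0
            )
            values.append(
                spec.baseline
                * block_mult[row.block]
                * spec.cell_multiplier(trt)
                * noise
            )
        table[spec.variable] = values
    return table


@dataclass(frozen=True)
class ArrayFixtureSpec:
    """Structure of a synthetic probe-level array fixture.

    ``category_map`` maps gene ids to functional category labels (defaults
    to gene ids G001.. in a single category); ``differential_spec`` maps a
    category to per-treatment multiplicative fold changes, e.g.
    ``{"N_cycling": {"CU": 2.0}}``. Fold 1.0 everywhere makes the
    treatments exchangeable.
    """

    n_genes: int = 20
    probes_per_gene: int = 4
    n_subgrids: int = 2
    category_map: Mapping[str, str] | None = None
    differential_spec: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    flag_rate: float = 0.0
    low_snr_rate: float = 0.0
    signal_scale: float = 1000.0
    probe_sd: float = 0.25
    block_sd: float = 0.05
    n_technical_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("flag_rate", "low_snr_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.signal_scale <= 0:
            raise ValueError("signal_scale must be positive")
        if self.category_map is not None and len(self.category_map) == 0:
            raise ValueError("category_map must not be empty")

    def genes(self) -> dict[str, str]:
        if self.category_map is not None:
            return dict(self.category_map)
        width = len(str(self.n_genes))
        return {f"G{i + 1:0{width}d}": "general" for i in range(self.n_genes)}


def generate_geochip_fixture(
    spec: ArrayFixtureSpec, design: FactorialDesign
) -> pd.DataFrame:
    """Probe-level records for every block x treatment x technical replicate.

    Spot signals are lognormal around gene-level means scaled by the
    treatment fold change of the gene's category; flagged and low-SNR
    spots are injected at the configured rates. Record count equals
    n_genes * probes_per_gene * n_blocks * 4 * n_technical_replicates.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.genes()
    gene_means = {
        g: spec.signal_scale * np.exp(rng.normal(0.0, 0.4)) for g in genes
    }
    rows = []
    for block in design.blocks:
        block_mult = np.exp(rng.normal(0.0, spec.block_sd)) if spec.block_sd else 1.0
        for trt in TREATMENTS:
            sample_id = design.sample_id(block, trt)
            for tech in range(spec.n_technical_replicates):
                slide_id = f"{sample_id}_T{tech + 1}"
                for gene_id, category in genes.items():
                    fold = spec.differential_spec.get(category, {}).get(trt, 1.0)
                    for p in range(spec.probes_per_gene):
                        probe_id = f"{gene_id}_p{p + 1}"
                        background = spec.signal_scale * 0.05 * np.exp(
                            rng.normal(0.0, 0.2)
                        )
                        background_sd = 0.1 * background
                        expr = (
                            gene_means[gene_id]
                            * fold
                            * block_mult
                            * np.exp(rng.normal(0.0, spec.probe_sd))
                        )
                        signal = background + expr
                        flag = 0
                        if spec.flag_rate and rng.uniform() < spec.flag_rate:
                            flag = int(rng.choice([1, 3]))
                        if spec.low_snr_rate and rng.uniform() < spec.low_snr_rate:
                            # SNR strictly below 2 -> removed by QC
                            signal = background + background_sd * rng.uniform(0, 1.9)
                        rows.append(
                            {
                                "slide_id": slide_id,
                                "sample_id": sample_id,
                                "subgrid": (p % spec.n_subgrids) + 1,
                                "probe_id": probe_id,
                                "gene_id": gene_id,
                                "category": category,
                                "signal": signal,
                                "background": background,
                                "background_sd": background_sd,
                                "flag": flag,
                            }
                        )
    return pd.DataFrame(rows, columns=list(PROBE_COLUMNS))


def designed_counts_for(spec: ArrayFixtureSpec) -> dict[str, int]:
    """Designed probe counts matching a generated fixture."""
    return {g: spec.probes_per_gene for g in spec.genes()}


@dataclass(frozen=True)
class TecoDatasetSpec:
    """Ground truth and noise structure for a synthetic inversion dataset."""

    true_params: TecoParameters
    n_days: int = 1095
    temp_mean: float = 16.3  # site mean annual temperature, degC
    temp_amplitude: float = 10.0
    temp_noise_sd: float = 1.0
    c_input_mean: float = 2.0  # g C m^-2 day^-1
    c_input_amplitude: float = 1.0
    obs_noise_sd_rh: float = 0.2
    obs_noise_sd_agb: float = 10.0
    agb_every: int = 30
    initial: CarbonState = field(default_factory=CarbonState)
    temperature_series: np.ndarray | None = None
    c_input_series: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.obs_noise_sd_rh < 0 or self.obs_noise_sd_agb < 0:
            raise ValueError("observation noise sd must be nonnegative")
        self.true_params.validate(DEFAULT_BOUNDS)


def generate_teco_dataset(
    spec: TecoDatasetSpec,
) -> tuple[DriverSeries, ObservationSet]:
    """Drivers plus noisy observations from the forward model at the truth.

    The temperature driver is a seasonal sinusoid around the site mean
    with Gaussian day-to-day noise; carbon input follows a nonnegative
    seasonal cycle. Heterotrophic respiration is observed daily and
    aboveground biomass every ``agb_every`` days, each with independent
    Gaussian noise. At zero noise the observations equal the forward
    simulation exactly.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.arange(spec.n_days)
    phase = 2 * np.pi * (days % 365) / 365.0
    if spec.temperature_series is not None:
        temp = np.asarray(spec.temperature_series, dtype=float)
    else:
        temp = (
            spec.temp_mean
            - spec.temp_amplitude * np.cos(phase)
            + rng.normal(0.0, spec.temp_noise_sd, size=spec.n_days)
        )
    if spec.c_input_series is not None:
        cin = np.asarray(spec.c_input_series, dtype=float)
    else:
        cin = np.maximum(
            spec.c_input_mean - spec.c_input_amplitude * np.cos(phase), 0.0
        )
    drivers = DriverSeries(temperature=temp, c_input=cin)
    traj = simulate_teco(spec.true_params, drivers, initial=spec.initial)

    rh_days = days
    rh_obs = traj.rh + rng.normal(0.0, spec.obs_noise_sd_rh, size=spec.n_days)
    agb_days = days[:: spec.agb_every]
    agb_obs = traj.agb[agb_days] + rng.normal(
        0.0, spec.obs_noise_sd_agb, size=len(agb_days)
    )
    obs = ObservationSet(
        rh_days=rh_days,
        rh_obs=rh_obs,
        rh_sd=max(spec.obs_noise_sd_rh, 1e-6),
        agb_days=agb_days,
        agb_obs=agb_obs,
        agb_sd=max(spec.obs_noise_sd_agb, 1e-6),
    )
    return drivers, obs


def write_series_tsv(days: np.ndarray, values: np.ndarray, path, name: str) -> None:
    pd.DataFrame({"day": days, name: values}).to_csv(path, sep="\t", index=False)


def load_series_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] != 2:
        raise ValueError("series TSV must have exactly two columns")
    return table.iloc[:, 0].to_numpy(), table.iloc[:, 1].to_numpy(dtype=float)
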