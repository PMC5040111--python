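"""Multi-pool soil-carbon forward model and Bayesian Q10 inversion.

The forward model tracks six carbon pools (foliage, fine root, litter,
fast SOM, slow SOM, passive SOM) with donor-controlled first-order
transfers updated daily by explicit (forward-Euler) steps. Litter and SOM
fluxes are multiplied by the temperature scalar q10 ** ((T - Tref) / 10);
heterotrophic respiration is the sum of the respired fractions of those
fluxes. Aboveground biomass is identified with the foliage pool.

Seven parameters (Q10 plus the six pool exit rates) are inverted by
random-walk Metropolis-Hastings against daily heterotrophic-respiration
and periodic aboveground-biomass observations, under independent uniform
priors. The Q10 prior support is [1.5, 5.0].

Model structure not fixed by the estimation problem itself — allocation
fractions (0.45 foliage / 0.55 root), the respired fraction of each
donor flux (0.55, terminal passive flux fully respired), and
Tref = 10 degC — is an implementation default, exposed in the dataclasses
below.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

PARAM_NAMES = (
    "q10", "k_foliage", "k_root", "k_litter", "k_fast", "k_slow", "k_passive",
)
POOL_NAMES = ("foliage", "root", "litter", "fast", "slow", "passive")

Q10_BOUNDS = (1.5, 5.0)

#: Default uniform prior bounds; exit-rate supports span two orders of
#: magnitude around literature-scale turnover times.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "q10": Q10_BOUNDS,
    "k_foliage": (5e-4, 5e-2),
    "k_root": (2e-4, 2e-2),
    "k_litter": (8e-4, 4e-2),
    "k_fast": (1e-4, 1e-2),
    "k_slow": (5e-6, 5e-4),
    "k_passive": (1e-7, 1e-5),
}

DEFAULT_TEMP_REF = 10.0
DEFAULT_RESPIRED_FRACTION = 0.55


def temperature_scalar(q10, temp, temp_ref: float = DEFAULT_TEMP_REF):
    """Multiplicative rate modifier q10 ** ((temp - temp_ref) / 10)."""
    if np.any(np.asarray(q10) <= 0):
        raise ValueError("q10 must be positive")
    return q10 ** ((np.asarray(temp, dtype=float) - temp_ref) / 10.0)


@dataclass(frozen=True)
class TecoParameters:
    """Q10 and the six first-order pool exit rates (day^-1)."""

    q10: float
    k_foliage: float
    k_root: float
    k_litter: float
    k_fast: float
    k_slow: float
    k_passive: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "TecoParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def within(self, bounds: dict[str, tuple[float, float]]) -> bool:
        return all(
            bounds[n][0] <= getattr(self, n) <= bounds[n][1]
            for n in PARAM_NAMES
        )

    def validate(self, bounds: dict[str, tuple[float, float]] | None = None) -> None:
        for name in PARAM_NAMES[1:]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")
        if bounds is not None and not self.within(bounds):
            raise ValueError("parameters outside prior bounds")


@dataclass(frozen=True)
class CarbonState:
    """Pool sizes in g C m^-2."""

    foliage: float = 150.0
    root: float = 300.0
    litter: float = 200.0
    fast: float = 300.0
    slow: float = 1500.0
    passive: float = 1000.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in POOL_NAMES], dtype=float)


@dataclass(frozen=True)
class DriverSeries:
    """Daily forcing: temperature (degC) and carbon input (g C m^-2 day^-1)."""

    temperature: np.ndarray
    c_input: np.ndarray
    alloc_foliage: float = 0.45
    alloc_root: float = 0.55

    def __post_init__(self):
        object.__setattr__(
            self, "temperature", np.asarray(self.temperature, dtype=float)
        )
        object.__setattr__(self, "c_input", np.asarray(self.c_input, dtype=float))
        if len(self.temperature) != len(self.c_input):
            raise ValueError("temperature and c_input must have equal length")
        if abs(self.alloc_foliage + self.alloc_root - 1.0) > 1e-12:
            raise ValueError("allocation fractions must sum to 1")

    @property
    def n_days(self) -> int:
        return len(self.temperature)


@dataclass(frozen=True)
class ObservationSet:
    """Dated observations of heterotrophic respiration and aboveground biomass."""

    rh_days: np.ndarray
    rh_obs: np.ndarray
    rh_sd: float
    agb_days: np.ndarray
    agb_obs: np.ndarray
    agb_sd: float

    def __post_init__(self):
        for name in ("rh_days", "rh_obs", "agb_days", "agb_obs"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if len(self.rh_days) != len(self.rh_obs):
            raise ValueError("rh_days and rh_obs length mismatch")
        if len(self.agb_days) != len(self.agb_obs):
            raise ValueError("agb_days and agb_obs length mismatch")

    @property
    def empty(self) -> bool:
        return len(self.rh_obs) == 0 and len(self.agb_obs) == 0


@dataclass
class TecoTrajectory:
    pools: np.ndarray  # (n_days, 6), state after each daily step
    rh: np.ndarray  # (n_days,)
    agb: np.ndarray  # (n_days,) == pools[:, 0]
    initial: np.ndarray  # (6,)


def _simulate_core(q10, ks, temp, cin, alloc_f, alloc_r, tref, rf, x0):
    n = temp.shape[0]
    pools = np.empty((n, 6))
    rh = np.empty(n)
    x = x0.copy()
    ok = True
    for t in range(n):
        xi = q10 ** ((temp[t] - tref) / 10.0)
        f_fol = ks[0] * x[0]
        f_root = ks[1] * x[1]
        f_lit = ks[2] * xi * x[2]
        f_fast = ks[3] * xi * x[3]
        f_slow = ks[4] * xi * x[4]
        f_pass = ks[5] * xi * x[5]
        x[0] += alloc_f * cin[t] - f_fol
        x[1] += alloc_r * cin[t] - f_root
        x[2] += f_fol + f_root - f_lit
        x[3] += (1.0 - rf) * f_lit - f_fast
        x[4] += (1.0 - rf) * f_fast - f_slow
        x[5] += (1.0 - rf) * f_slow - f_pass
        rh[t] = rf * (f_lit + f_fast + f_slow) + f_pass
        for j in range(6):
            if x[j] < 0.0:
                ok = False
            pools[t, j] = x[j]
        if not ok:
            break
    return pools, rh, ok


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _simulate_core = numba.njit(cache=True)(_simulate_core)
except ImportError:  # pragma: no cover
    logger.warning("numba unavailable; forward simulation runs in pure Python")


class SimulationError(ValueError):
    """A pool went negative (step too large or rates invalid)."""


def simulate_teco(
    params: TecoParameters,
    drivers: DriverSeries,
    initial: CarbonState | None = None,
    temp_ref: float = DEFAULT_TEMP_REF,
    respired_fraction: float = DEFAULT_RESPIRED_FRACTION,
) -> TecoTrajectory:
    """Run the daily six-pool forward model.

    Raises :class:`SimulationError` if any pool goes negative. Mass balance
    (total input minus total respiration equals storage change) holds
    exactly by construction of the update.
    """
    if initial is None:
        initial = CarbonState()
    x0 = initial.as_array()
    if np.any(x0 < 0):
        raise ValueError("initial pools must be nonnegative")
    ks = params.as_array()[1:]
    pools, rh, ok = _simulate_core(
        params.q10, ks, drivers.temperature, drivers.c_input,
        drivers.alloc_foliage, drivers.alloc_root, temp_ref,
        respired_fraction, x0,
    )
    if not ok:
        raise SimulationError(
            "negative pool during simulation; daily step too large for the "
            "given rates and temperatures"
        )
    return TecoTrajectory(pools=pools, rh=rh, agb=pools[:, 0], initial=x0)


def log_likelihood(
    params: TecoParameters,
    drivers: DriverSeries,
    obs: ObservationSet,
    initial: CarbonState | None = None,
    temp_ref: float = DEFAULT_TEMP_REF,
    respired_fraction: float = DEFAULT_RESPIRED_FRACTION,
) -> float:
    """Gaussian log-likelihood of the observation streams; -inf if unstable."""
    if obs.empty:
        return 0.0
    try:
        traj = simulate_teco(
            params, drivers, initial=initial, temp_ref=temp_ref,
            respired_fraction=respired_fraction,
        )
    except SimulationError:
        return -np.inf
    ll = 0.0
    if len(obs.rh_obs):
        r = obs.rh_obs - traj.rh[obs.rh_days]
        ll += float(
            -0.5 * np.sum((r / obs.rh_sd) ** 2)
            - len(r) * (np.log(obs.rh_sd) + 0.5 * np.log(2 * np.pi))
        )
    if len(obs.agb_obs):
        r = obs.agb_obs - traj.agb[obs.agb_days]
        ll += float(
            -0.5 * np.sum((r / obs.agb_sd) ** 2)
            - len(r) * (np.log(obs.agb_sd) + 0.5 * np.log(2 * np.pi))
        )
    return ll


def log_posterior(
    params: TecoParameters,
    drivers: DriverSeries,
    obs: ObservationSet,
    bounds: dict[str, tuple[float, float]] | None = None,
    initial: CarbonState | None = None,
    temp_ref: float = DEFAULT_TEMP_REF,
    respired_fraction: float = DEFAULT_RESPIRED_FRACTION,
) -> float:
    """Uniform log-prior within ``bounds`` plus the Gaussian log-likelihood."""
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if not params.within(bounds):
        return -np.inf
    return log_likelihood(
        params, drivers, obs, initial=initial, temp_ref=temp_ref,
        respired_fraction=respired_fraction,
    )


@dataclass
class McmcConfig:
    n_steps: int = 20_000
    burn_in: int = 5_000
    proposal_scale: float = 0.02  # fraction of each prior-bound width
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    init: TecoParameters | None = None

    def __post_init__(self):
        if self.n_steps <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")


@dataclass
class McmcResult:
    samples: np.ndarray  # (n_steps, n_params)
    param_names: tuple[str, ...]
    log_posteriors: np.ndarray
    acceptance_rate: float
    burn_in: int
    seed: int

    def posterior_samples(self, parameter: str) -> np.ndarray:
        j = self.param_names.index(parameter)
        return self.samples[self.burn_in:, j]


def metropolis_hastings(
    log_post,
    bounds: np.ndarray,
    config: McmcConfig,
    init: np.ndarray | None = None,
) -> McmcResult:
    """Generic random-scan random-walk M-H sampler on a box support.

    ``log_post`` maps a parameter vector to a log density (-inf rejects).
    Each step perturbs one randomly chosen coordinate with a Gaussian step
    whose scale is ``proposal_scale`` times that coordinate's bound width.
    """
    bounds = np.asarray(bounds, dtype=float)
    n_par = bounds.shape[0]
    rng = np.random.default_rng(config.seed)
    if init is None:
        init = bounds[:, 0] + rng.uniform(size=n_par) * (bounds[:, 1] - bounds[:, 0])
    x = np.asarray(init, dtype=float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    scales = config.proposal_scale * (bounds[:, 1] - bounds[:, 0])
    samples = np.empty((config.n_steps, n_par))
    lps = np.empty(config.n_steps)
    accepted = 0
    for i in range(config.n_steps):
        j = rng.integers(n_par)
        prop = x.copy()
        prop[j] += rng.normal(0.0, scales[j])
        if bounds[j, 0] <= prop[j] <= bounds[j, 1]:
            lp_prop = log_post(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted += 1
        samples[i] = x
        lps[i] = lp
    rate = accepted / config.n_steps
    if rate == 0:
        warnings.warn(
            "no proposals accepted; proposal scale is likely pathological",
            RuntimeWarning,
        )
    return McmcResult(
        samples=samples,
        param_names=tuple(f"p{i}" for i in range(n_par)),
        log_posteriors=lps,
        acceptance_rate=rate,
        burn_in=config.burn_in,
        seed=config.seed,
    )


def run_mh_chain(
    drivers: DriverSeries,
    obs: ObservationSet,
    config: McmcConfig | None = None,
    initial_state: CarbonState | None = None,
    temp_ref: float = DEFAULT_TEMP_REF,
    respired_fraction: float = DEFAULT_RESPIRED_FRACTION,
) -> McmcResult:
    """Invert the seven model parameters by Metropolis-Hastings."""
    if config is None:
        config = McmcConfig()
    bounds = np.array([config.bounds[n] for n in PARAM_NAMES])

    def _lp(vec: np.ndarray) -> float:
        return log_posterior(
            TecoParameters.from_array(vec), drivers, obs,
            bounds=config.bounds, initial=initial_state,
            temp_ref=temp_ref, respired_fraction=respired_fraction,
        )

    init = config.init.as_array() if config.init is not None else None
    result = metropolis_hastings(_lp, bounds, config, init=init)
    result.param_names = PARAM_NAMES
    return result


@dataclass
class PosteriorSummary:
    parameter: str
    mode: float
    mean: float
    ci_low: float
    ci_high: float
    n_samples: int


def summarize_posterior(
    result: McmcResult, parameter: str, bins: int = 50
) -> PosteriorSummary:
    """Histogram-mode, mean, and central 95% interval of one parameter."""
    samples = result.posterior_samples(parameter)
    if len(samples) < 100:
        raise ValueError(
            f"need >= 100 post-burn-in samples, have {len(samples)}"
        )
    if samples.min() == samples.max():
        v = float(samples[0])
        return PosteriorSummary(parameter, v, v, v, v, len(samples))
    counts, edges = np.histogram(samples, bins=bins)
    peak = int(np.argmax(counts))
    mode = float(0.5 * (edges[peak] + edges[peak + 1]))
    lo, hi = np.quantile(samples, [0.025, 0.975])
    return PosteriorSummary(
        parameter, mode, float(samples.mean()), float(lo), float(hi),
        len(samples),
    )


def write_chain_tsv(result: McmcResult, path) -> None:
    import pandas as pd

    frame = pd.DataFrame(result.samples, columns=list(result.param_names))
    frame["log_posterior"] = result.log_posteriors
    frame.to_csv(path, sep="\t", index=False)
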