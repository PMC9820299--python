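"""Synthetic river-monitoring data with planted pollution-source structure.

The generator emulates a multi-year monthly monitoring campaign at a small
number of stations ordered upstream to downstream.  Concentrations of the
"mass" parameters are produced by a latent mixture

    X = G @ F  (then multiplicative lognormal measurement noise)

where ``F`` (p x m) holds nonnegative source profiles (species loadings)
and ``G`` (n x p) per-sample source activities built from a per-source base
level, a seasonal sinusoid, a per-station gradient multiplier (modelling
downstream deterioration), and per-sample lognormal variability.  pH and
water temperature are not source-mass species, so they are simulated by
separate bounded baseline-plus-seasonal processes and simply appear as two
further columns.

Every dataset carries its ground truth (the source model and the realized
activity matrix ``G``), so factor-recovery and feature-selection stages can
be scored without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SourceModel",
    "MonitoringDataset",
    "NON_MASS_PARAMETERS",
    "generate_source_model",
    "simulate_monitoring",
    "apply_detection_limits",
    "default_config",
    "default_source_model",
]

#: parameters that are not generated by the source-mass mixture
NON_MASS_PARAMETERS: tuple[str, ...] = ("pH", "WT")


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable settings of the synthetic monitoring-campaign generator."""

    n_stations: int = 4
    #: per-source planted loadings: source index -> {species: share of row}
    dominance: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    #: Dirichlet concentration for the non-planted remainder of each profile
    profile_sparsity: float = 0.4
    #: per-source seasonal amplitude in [0, 1), scalar or sequence
    seasonal_amplitude: float | Sequence[float] = 0.3
    #: per-source seasonal phase offset in months
    seasonal_phase: float | Sequence[float] = 0.0
    #: per-source per-station activity multipliers; None -> all ones
    station_gradient: Mapping[int, Sequence[float]] | None = None
    #: per-source mean activity level
    base_levels: float | Sequence[float] = 1.0
    #: lognormal CV of per-sample source activity, scalar or per-source
    contribution_cv: float | Sequence[float] = 0.35
    #: lognormal CV of multiplicative measurement noise
    noise_cv: float = 0.1
    #: per-species long-run mean concentrations to calibrate to (optional)
    target_means: Mapping[str, float] | None = None
    #: missing-at-random station-month dropout rate
    missing_rate: float = 0.0
    # bounded AR(1)-plus-seasonal processes for the non-mass parameters
    ph_mean: float = 6.95
    ph_ar: float = 0.6
    ph_sd: float = 0.18
    ph_bounds: tuple[float, float] = (6.47, 7.6)
    wt_mean: float = 20.0
    wt_amplitude: float = 7.5
    wt_sd: float = 1.2
    wt_bounds: tuple[float, float] = (6.0, 34.0)
    start: str = "2011-10-01"


@dataclass(frozen=True)
class SourceModel:
    """Planted generative source structure (the ground truth)."""

    n_sources: int
    species: tuple[str, ...]          # mass species (profile columns)
    parameters: tuple[str, ...]       # full parameter list incl. pH/WT
    profiles: np.ndarray              # (p, m_mass), nonnegative
    seasonal_amplitude: np.ndarray    # (p,)
    seasonal_phase: np.ndarray        # (p,)
    station_gradient: np.ndarray      # (p, n_stations), > 0
    base_levels: np.ndarray           # (p,)
    contribution_cv: np.ndarray       # (p,)
    noise_cv: float
    seed: int
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if np.any(self.profiles < 0):
            raise ValueError("profiles must be nonnegative")
        if np.any(self.profiles.sum(axis=1) <= 0):
            raise ValueError("every profile row needs a positive entry")
        if np.any(self.station_gradient <= 0):
            raise ValueError("station gradients must be positive")
        if np.any((self.seasonal_amplitude < 0) | (self.seasonal_amplitude >= 1)):
            raise ValueError("seasonal amplitudes must lie in [0, 1)")

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles,
            index=[f"S{j + 1}" for j in range(self.n_sources)],
            columns=list(self.species),
        )


@dataclass
class MonitoringDataset:
    """Station/date-indexed matrix of parameter concentrations.

    ``values`` is indexed by (station, date) with one column per parameter;
    ``censored`` is a same-shape boolean mask marking below-detection
    entries (which carry the substituted value, not the raw draw).
    Synthetic datasets keep their ground truth: the source model and the
    realized activity matrix ``G``.
    """

    stations: tuple[str, ...]
    values: pd.DataFrame
    censored: pd.DataFrame
    truth_model: SourceModel | None = None
    truth_contributions: pd.DataFrame | None = None

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def true_contribution_matrix(self) -> pd.DataFrame:
        """Column-normalized share of each mass species owed to each true source."""
        if self.truth_model is None or self.truth_contributions is None:
            raise ValueError("dataset carries no ground truth")
        g = self.truth_contributions.to_numpy()
        f = self.truth_model.profiles
        mass = g.sum(axis=0)[:, None] * f  # (p, m_mass)
        c = mass / mass.sum(axis=0, keepdims=True)
        return pd.DataFrame(
            c, index=self.truth_contributions.columns, columns=list(self.truth_model.species)
        )


def _per_source(value: float | Sequence[float], p: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(p, float(arr))
    if arr.shape != (p,):
        raise ValueError(f"{name} must be scalar or length-{p}")
    return arr


def generate_source_model(
    p: int,
    parameters: Sequence[str],
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> SourceModel:
    """Draw a planted source model over the given parameter list.

    Profiles are sparse-ish: each source is dominated by the species planted
    via ``config.dominance`` (shares of the unit row sum), with the
    remainder spread over the other species by a low-concentration
    Dirichlet draw.  If ``config.target_means`` is set, profile columns are
    rescaled so the expected long-run mean of each species matches the
    target (given the base levels and station gradients).
    """
    if p < 1:
        raise ValueError("need at least one source")
    parameters = tuple(parameters)
    if not parameters:
        raise ValueError("parameter list must be non-empty")
    config = config or GeneratorConfig()
    species = tuple(q for q in parameters if q not in NON_MASS_PARAMETERS)
    if not species:
        raise ValueError("parameter list contains no source-mass species")
    m = len(species)
    rng = np.random.default_rng(seed)

    profiles = np.zeros((p, m))
    for j in range(p):
        planted = dict(config.dominance.get(j, {}))
        unknown = set(planted) - set(species)
        if unknown:
            raise ValueError(f"dominance for source {j} names unknown species {sorted(unknown)}")
        total = sum(planted.values())
        if total > 1.0 + 1e-12:
            raise ValueError(f"dominance shares for source {j} exceed 1")
        rest = [i for i, s in enumerate(species) if s not in planted]
        for s, share in planted.items():
            profiles[j, species.index(s)] = share
        if rest:
            remainder = max(0.0, 1.0 - total)
            profiles[j, rest] = remainder * rng.dirichlet(np.full(len(rest), config.profile_sparsity))

    amp = _per_source(config.seasonal_amplitude, p, "seasonal_amplitude")
    phase = _per_source(config.seasonal_phase, p, "seasonal_phase")
    base = _per_source(config.base_levels, p, "base_levels")
    gradient = np.ones((p, config.n_stations))
    if config.station_gradient is not None:
        for j, multipliers in config.station_gradient.items():
            g = np.asarray(multipliers, dtype=float)
            if g.shape != (config.n_stations,):
                raise ValueError(f"station gradient for source {j} must have {config.n_stations} entries")
            gradient[j] = g

    if config.target_means:
        # expected species mean = sum_j base_j * mean_k(gradient_jk) * F_ji
        # (seasonal and noise factors average to one)
        expected = (base * gradient.mean(axis=1)) @ profiles
        for i, s in enumerate(species):
            if s in config.target_means:
                if expected[i] <= 0:
                    raise ValueError(f"cannot calibrate {s}: no source loads on it")
                profiles[:, i] *= config.target_means[s] / expected[i]

    return SourceModel(
        n_sources=p,
        species=species,
        parameters=parameters,
        profiles=profiles,
        seasonal_amplitude=amp,
        seasonal_phase=phase,
        station_gradient=gradient,
        base_levels=base,
        contribution_cv=_per_source(config.contribution_cv, p, "contribution_cv"),
        noise_cv=config.noise_cv,
        seed=seed,
        config=config,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with the given CV (CV=0 -> exactly 1)."""
    if cv == 0.0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def simulate_monitoring(
    model: SourceModel,
    n_stations: int | None = None,
    n_months: int = 107,
    seed: int = 0,
) -> MonitoringDataset:
    """Simulate a monthly monitoring campaign from a planted source model.

    Samples are ordered station-major (upstream first), each station
    carrying the full monthly date range.  The realized activity matrix and
    the model are stored as ground truth.
    """
    cfg = model.config
    if n_stations is None:
        n_stations = model.station_gradient.shape[1]
    if n_stations < 1 or n_months < 1:
        raise ValueError("need at least one station and one month")
    if n_stations != model.station_gradient.shape[1]:
        raise ValueError(
            f"model was built for {model.station_gradient.shape[1]} stations, got {n_stations}"
        )
    rng = np.random.default_rng(seed)
    p, m = model.profiles.shape
    stations = tuple(f"ST{k + 1}" for k in range(n_stations))
    dates = pd.date_range(cfg.start, periods=n_months, freq="MS")
    index = pd.MultiIndex.from_product([stations, dates], names=["station", "date"])
    n = n_stations * n_months

    t = np.arange(n_months)
    seasonal = 1.0 + model.seasonal_amplitude[:, None] * np.sin(
        2.0 * np.pi * (t[None, :] + model.seasonal_phase[:, None]) / 12.0
    )  # (p, n_months)

    g = np.empty((n, p))
    for k in range(n_stations):
        block = model.base_levels[:, None] * model.station_gradient[:, k : k + 1] * seasonal
        g[k * n_months : (k + 1) * n_months] = block.T
    for j in range(p):
        g[:, j] *= _lognormal_factors(rng, float(model.contribution_cv[j]), (n,))

    x_mass = g @ model.profiles
    x_mass = x_mass * _lognormal_factors(rng, model.noise_cv, (n, m))

    values = pd.DataFrame(index=index, columns=list(model.parameters), dtype=float)
    for i, s in enumerate(model.species):
        values[s] = x_mass[:, i]

    if "pH" in model.parameters:
        ph = np.empty(n)
        for k in range(n_stations):
            level = cfg.ph_mean
            for tt in range(n_months):
                level = cfg.ph_mean + cfg.ph_ar * (level - cfg.ph_mean) + rng.normal(0.0, cfg.ph_sd)
                ph[k * n_months + tt] = level
        values["pH"] = np.clip(ph, *cfg.ph_bounds)
    if "WT" in model.parameters:
        months = np.tile(dates.month.to_numpy(), n_stations)
        wt = cfg.wt_mean + cfg.wt_amplitude * np.sin(2.0 * np.pi * (months - 4) / 12.0)
        wt = wt + rng.normal(0.0, cfg.wt_sd, size=n)
        values["WT"] = np.clip(wt, *cfg.wt_bounds)

    contributions = pd.DataFrame(g, index=index, columns=[f"S{j + 1}" for j in range(p)])

    if cfg.missing_rate > 0.0:
        keep = rng.random(n) >= cfg.missing_rate
        values = values.loc[keep]
        contributions = contributions.loc[keep]

    censored = pd.DataFrame(False, index=values.index, columns=values.columns)
    return MonitoringDataset(
        stations=stations,
        values=values,
        censored=censored,
        truth_model=model,
        truth_contributions=contributions,
    )


def apply_detection_limits(
    dataset: MonitoringDataset, mdl: Mapping[str, float]
) -> MonitoringDataset:
    """Censor below-detection entries: flag them and substitute MDL/2."""
    for name, limit in mdl.items():
        if limit < 0:
            raise ValueError(f"negative detection limit for {name}")
    values = dataset.values.copy()
    censored = dataset.censored.copy()
    for name, limit in mdl.items():
        if name not in values.columns or limit == 0:
            continue
        below = values[name] < limit
        values.loc[below, name] = limit / 2.0
        censored.loc[below, name] = True
    return MonitoringDataset(
        stations=dataset.stations,
        values=values,
        censored=censored,
        truth_model=dataset.truth_model,
        truth_contributions=dataset.truth_contributions,
    )


# ---------------------------------------------------------------------------
# Study-condition defaults: a five-source structure over the 14 routinely
# monitored parameters, with signatures chosen to emulate the classic river
# pollution mix — a microbial (faecal) source, diffuse agricultural runoff,
# a natural/seasonal background carrying DO and organics, an urban nutrient
# source, and a heavy-metal source growing downstream.

DEFAULT_TARGET_MEANS: dict[str, float] = {
    "DO": 8.0,
    "TN": 1.54,
    "NH3-N": 0.25,
    "NO3-N": 0.9,
    "TP": 0.08,
    "CODMn": 2.2,
    "Cl": 12.0,
    "SO4": 15.0,
    "F.coli": 9000.0,
    "Fe": 2.0,
    "Mn": 0.6,
    "F": 0.25,
}

DEFAULT_DOMINANCE: dict[int, dict[str, float]] = {
    0: {"F.coli": 0.87},                                                        # microbial
    1: {"TN": 0.25, "NO3-N": 0.18, "SO4": 0.18, "Cl": 0.18, "F": 0.12},         # agricultural
    2: {"DO": 0.45, "CODMn": 0.25, "TN": 0.12},                                 # natural/seasonal
    3: {"TP": 0.65, "NH3-N": 0.20},                                             # nutrient
    4: {"Fe": 0.45, "Mn": 0.45},                                                # heavy metal
}

DEFAULT_STATION_GRADIENT: dict[int, tuple[float, ...]] = {
    0: (0.60, 0.75, 1.25, 1.60),
    1: (1.10, 1.05, 0.95, 0.90),
    2: (1.00, 1.00, 1.00, 1.00),
    3: (0.80, 0.90, 1.15, 1.30),
    4: (0.55, 0.70, 1.35, 1.80),
}


def _resample_gradient(gradient: Mapping[int, Sequence[float]], n_stations: int,
                       ) -> dict[int, tuple[float, ...]]:
    """Interpolate per-source gradients onto a different station count,
    preserving the upstream-to-downstream pattern."""
    out = {}
    for j, g in gradient.items():
        g = np.asarray(g, dtype=float)
        pos = np.linspace(0.0, 1.0, len(g))
        new = np.linspace(0.0, 1.0, n_stations) if n_stations > 1 else np.array([0.5])
        out[j] = tuple(np.interp(new, pos, g))
    return out


def default_config(**overrides) -> GeneratorConfig:
    """Study-condition generator settings: 4 stations, 5 planted sources."""
    n_stations = int(overrides.get("n_stations", 4))
    if "station_gradient" not in overrides and n_stations != 4:
        overrides["station_gradient"] = _resample_gradient(DEFAULT_STATION_GRADIENT, n_stations)
    cfg = GeneratorConfig(
        n_stations=4,
        dominance=DEFAULT_DOMINANCE,
        profile_sparsity=0.15,
        seasonal_amplitude=(0.15, 0.45, 0.65, 0.25, 0.10),
        seasonal_phase=(0.0, 2.0, 6.0, 1.0, 9.0),
        station_gradient=DEFAULT_STATION_GRADIENT,
        base_levels=1.0,
        # activity variability per source: faecal inputs are episodic (large
        # CV), the agricultural ion mix and natural background are stable
        contribution_cv=(0.9, 0.3, 0.25, 0.45, 0.5),
        noise_cv=0.1,
        target_means=DEFAULT_TARGET_MEANS,
    )
    return replace(cfg, **overrides) if overrides else cfg


def default_source_model(seed: int = 0, config: GeneratorConfig | None = None) -> SourceModel:
    """Five-source study-condition model over the 14 default parameters."""
    from .wqi import DEFAULT_PARAMETERS

    return generate_source_model(5, DEFAULT_PARAMETERS, config or default_config(), seed=seed)
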