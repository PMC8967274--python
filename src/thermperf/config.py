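"""Configuration objects for simulation, MCMC sampling, and derivation.

All stochastic stages draw from named substreams of a single integer seed so
that a run is reproducible end-to-end from its configuration file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError

#: Day/night chamber regimes used in the growth experiment (degrees C).
DEFAULT_REGIMES: tuple[tuple[float, float], ...] = (
    (10.0, 0.0),
    (20.0, 10.0),
    (25.0, 15.0),
    (30.0, 20.0),
    (40.0, 30.0),
    (45.0, 35.0),
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for a named substream of ``seed``.

    Stage names ("design", "obs", ...) are hashed with CRC-32 so that adding a
    stage never perturbs the streams of existing stages.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


@dataclass
class ClimateGeoConfig:
    """Geography of the simulated localities.

    Native populations span a wide latitudinal band with mean annual
    temperature (MAT) falling toward the pole; invasive populations occupy a
    narrow, cool-temperate band. Temperature seasonality (TS, the standard
    deviation of mean monthly temperature) rises with latitude in the native
    band and falls with latitude in the invasive band.
    """

    native_lat_range: tuple[float, float] = (33.0, 61.0)
    invasive_lat_range: tuple[float, float] = (50.0, 58.0)
    native_mat_intercept: float = 29.0  # MAT (degC) extrapolated to latitude 0
    native_mat_lat_slope: float = -0.45  # degC per degree latitude
    invasive_mat_intercept: float = 17.0
    invasive_mat_lat_slope: float = -0.15
    mat_noise_sd: float = 0.8
    native_ts_intercept: float = 2.0
    native_ts_lat_slope: float = 0.09
    invasive_ts_intercept: float = 9.0
    invasive_ts_lat_slope: float = -0.07
    ts_noise_sd: float = 0.4


@dataclass
class TrueCurveConfig:
    """Shared ground-truth curve from which population truths are built.

    Defaults describe a plant growing between roughly -5 and 50 degC with a
    thermal optimum in the mid-20s and peak relative growth rate (RGR) of
    0.15 per day, in line with week-long clonal growth assays.
    """

    lower: float = -5.0
    upper: float = 50.0
    shape_a: float = 2.5
    shape_b: float = 3.5
    stretch: float = 0.15  # peak RGR, per day


@dataclass
class SimConfig:
    """Complete description of one simulated clone-growth experiment."""

    n_native_pops: int = 18
    n_invasive_pops: int = 13
    genotypes_per_pop: int = 3
    clones_per_genotype_per_regime: int = 2
    regimes: tuple[tuple[float, float], ...] = DEFAULT_REGIMES
    # extra clone replicates for particular regimes, e.g. {(45, 35): 2}
    extra_regime_replicates: dict = field(default_factory=lambda: {(45.0, 35.0): 2})
    p_establish_fail: float = 25.0 / 1302.0
    p_damage: float = 26.0 / 1277.0
    noise_sd: float = 0.02  # residual sd of RGR, per day
    truth_mode: str = "fixed"  # "fixed" or "cline"
    cline_slope_topt_mat: float = 0.15  # degC T_opt per degC MAT (cline mode)
    cline_slope_breadth_seasonality: float = 0.5  # degC T_breadth per degC TS
    pop_scatter_topt_sd: float = 0.8  # seeded population scatter of T_opt, degC
    pop_scatter_breadth_sd: float = 0.0  # seeded population scatter of T_breadth, degC
    days: int = 7
    stem_in_mean: float = 3.0  # cm, initial cutting size
    stem_in_log_sd: float = 0.15
    # fixture mode: pin exact failure/damage counts (hypergeometric assignment)
    pin_establish_fail: Optional[int] = None
    pin_damage: Optional[int] = None
    seed: int = 0
    climate: ClimateGeoConfig = field(default_factory=ClimateGeoConfig)
    truth: TrueCurveConfig = field(default_factory=TrueCurveConfig)

    def __post_init__(self) -> None:
        self.regimes = tuple((float(d), float(n)) for d, n in self.regimes)
        self.extra_regime_replicates = {
            (float(k[0]), float(k[1])): int(v)
            for k, v in self.extra_regime_replicates.items()
        }
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_native_pops": self.n_native_pops,
            "n_invasive_pops": self.n_invasive_pops,
            "genotypes_per_pop": self.genotypes_per_pop,
            "clones_per_genotype_per_regime": self.clones_per_genotype_per_regime,
            "days": self.days,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.n_native_pops + self.n_invasive_pops < 1:
            raise ConfigError("at least one population is required")
        for name in ("p_establish_fail", "p_damage"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.regimes:
            raise ConfigError("regimes must be nonempty")
        if self.truth_mode not in ("fixed", "cline"):
            raise ConfigError(f"truth_mode must be 'fixed' or 'cline', got {self.truth_mode!r}")
        for regime in self.extra_regime_replicates:
            if regime not in self.regimes:
                raise ConfigError(f"extra replicates given for unknown regime {regime}")

    @property
    def n_pops(self) -> int:
        return self.n_native_pops + self.n_invasive_pops

    def replicates_for(self, regime: tuple[float, float]) -> int:
        return self.clones_per_genotype_per_regime + self.extra_regime_replicates.get(
            regime, 0
        )

    @property
    def n_records(self) -> int:
        """Exact design size: sum of replicates over all design cells."""
        per_genotype = sum(self.replicates_for(r) for r in self.regimes)
        return self.n_pops * self.genotypes_per_pop * per_genotype


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``max_tree_depth`` is reserved for tree-based samplers and is recorded but
    not used by the Metropolis-within-Gibbs backend.
    """

    chains: int = 4
    iterations_per_chain: int = 4000
    warmup_fraction: float = 0.5
    max_tree_depth: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ConfigError(f"chains must be >= 1, got {self.chains}")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ConfigError(
                f"warmup_fraction must lie in (0, 1), got {self.warmup_fraction}"
            )
        if self.iterations_per_chain < 2:
            raise ConfigError("iterations_per_chain must be >= 2")

    @property
    def n_warmup(self) -> int:
        return int(round(self.iterations_per_chain * self.warmup_fraction))

    @property
    def n_retained(self) -> int:
        """Total post-warmup draws across chains."""
        return self.chains * (self.iterations_per_chain - self.n_warmup)


@dataclass
class DeriveConfig:
    level: float = 0.5  # fraction of maximum performance defining breadth
    grid_n: int = 100
    refine: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ConfigError(f"level must lie in (0, 1), got {self.level}")
        if self.grid_n < 10:
            raise ConfigError(f"grid_n must be >= 10, got {self.grid_n}")


# ---------------------------------------------------------------------------
# YAML round-trip


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {
            (f"{k[0]}/{k[1]}" if isinstance(k, tuple) else k): _to_plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def sim_config_to_dict(cfg: SimConfig) -> dict:
    return _to_plain(cfg)


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "climate" in d and isinstance(d["climate"], dict):
        d["climate"] = ClimateGeoConfig(**d["climate"])
    if "truth" in d and isinstance(d["truth"], dict):
        d["truth"] = TrueCurveConfig(**d["truth"])
    if "regimes" in d:
        d["regimes"] = tuple(tuple(r) for r in d["regimes"])
    if "extra_regime_replicates" in d:
        extras = {}
        for k, v in d["extra_regime_replicates"].items():
            if isinstance(k, str):
                day, night = k.split("/")
                k = (float(day), float(night))
            extras[tuple(k)] = int(v)
        d["extra_regime_replicates"] = extras
    return SimConfig(**d)


@dataclass
class RunConfig:
    """Top-level pipeline configuration (YAML file contents)."""

    sim: SimConfig = field(default_factory=SimConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    derive: DeriveConfig = field(default_factory=DeriveConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = sim_config_from_dict(raw.get("sim", {}))
        mcmc = MCMCConfig(**raw.get("mcmc", {}))
        derive = DeriveConfig(**raw.get("derive", {}))
        return cls(sim=sim, mcmc=mcmc, derive=derive)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return {
            "sim": _to_plain(self.sim),
            "mcmc": _to_plain(self.mcmc),
            "derive": _to_plain(self.derive),
        }

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        sim = dataclasses.replace(self.sim, seed=int(seed))
        mcmc = dataclasses.replace(self.mcmc, seed=int(seed))
        return RunConfig(sim=sim, mcmc=mcmc, derive=self.derive)
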