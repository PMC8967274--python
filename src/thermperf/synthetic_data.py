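"""Seeded simulation of the clone-growth thermal performance experiment.

The generator emulates the study design the analysis assumes: populations
from a wide-latitude native range and a narrow-latitude invasive range, a few
genotypes per population, clone replicates grown under day/night temperature
regimes for a week, with establishment failure, accidental damage, and
dieback (negative growth) at temperature extremes.

Ground-truth curves can be shared by all populations (``truth_mode="fixed"``)
or carry linear clines of the thermal optimum on mean annual temperature and
of breadth on temperature seasonality (``truth_mode="cline"``), plus seeded
population scatter. Cline construction is exact: shifting both critical
limits moves T_opt one-for-one, and scaling the support width about T_opt
scales breadth one-for-one, so noiseless truths regress on climate with
exactly the configured slopes.

Observation noise is additive on the RGR scale: for an established cutting,
``stem_out = stem_in * (1 + days * (P(day_temp) + eps))`` with
``eps ~ Normal(0, noise_sd)``, so the implied RGR is ``P + eps``. Outside the
curve's support the expectation is zero and negative draws become dieback
records. Damaged cuttings receive an arbitrary negative implied RGR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .config import SimConfig, substream
from .errors import ConfigError, DataError
from .tpc_model import TPCParams, performance_curve_array
from .tpc_derive import thermal_breadth, thermal_optimum

TRUTH_COLUMNS = (
    "population_id",
    "range_label",
    "lower",
    "upper",
    "shape_a",
    "shape_b",
    "stretch",
    "t_opt",
    "t_breadth",
    "noise_sd",
)


def _population_ids(config: SimConfig) -> tuple[list, list]:
    native = [f"NAT{i + 1:02d}" for i in range(config.n_native_pops)]
    invasive = [f"INV{i + 1:02d}" for i in range(config.n_invasive_pops)]
    return native, invasive


def gen_climate(config: SimConfig) -> pd.DataFrame:
    """Per-population latitude, mean annual temperature, and seasonality."""
    if config.n_pops < 1:
        raise ConfigError("at least one population is required")
    rng = substream(config.seed, "climate")
    geo = config.climate
    rows = []
    for label, ids, lat_range, mat0, mat_sl, ts0, ts_sl in (
        (
            "native",
            _population_ids(config)[0],
            geo.native_lat_range,
            geo.native_mat_intercept,
            geo.native_mat_lat_slope,
            geo.native_ts_intercept,
            geo.native_ts_lat_slope,
        ),
        (
            "invasive",
            _population_ids(config)[1],
            geo.invasive_lat_range,
            geo.invasive_mat_intercept,
            geo.invasive_mat_lat_slope,
            geo.invasive_ts_intercept,
            geo.invasive_ts_lat_slope,
        ),
    ):
        n = len(ids)
        if n == 0:
            continue
        span = lat_range[1] - lat_range[0]
        lats = np.linspace(*lat_range, n) if n > 1 else np.array([np.mean(lat_range)])
        lats = lats + rng.uniform(-0.02, 0.02, size=n) * span
        mat = mat0 + mat_sl * lats + rng.normal(0.0, geo.mat_noise_sd, size=n)
        ts = ts0 + ts_sl * lats + rng.normal(0.0, geo.ts_noise_sd, size=n)
        for pid, la, m, t in zip(ids, lats, mat, ts):
            rows.append(
                {
                    "population_id": pid,
                    "range_label": label,
                    "latitude": float(la),
                    "mat": float(m),
                    "seasonality": float(max(t, 0.1)),
                }
            )
    return pd.DataFrame(rows)


def gen_true_tpcs(config: SimConfig, climate: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth curve parameters per population (one row each)."""
    native, invasive = _population_ids(config)
    pops = native + invasive
    missing = set(pops) - set(climate["population_id"])
    if missing:
        raise DataError(f"climate table missing populations: {sorted(missing)}")
    climate = climate.set_index("population_id").loc[pops]

    base = TPCParams(
        lower=config.truth.lower,
        upper=config.truth.upper,
        shape_a=config.truth.shape_a,
        shape_b=config.truth.shape_b,
        stretch=config.truth.stretch,
    )
    base.validate()
    base_topt = thermal_optimum(base)
    base_breadth, _, _ = thermal_breadth(base, refine=True)

    rng = substream(config.seed, "truth")
    n = len(pops)
    if config.truth_mode == "fixed":
        d_topt = np.zeros(n)
        scale = np.ones(n)
    else:
        mat = climate["mat"].to_numpy(dtype=float)
        ts = climate["seasonality"].to_numpy(dtype=float)
        d_topt = config.cline_slope_topt_mat * (mat - mat.mean())
        d_topt = d_topt + rng.normal(0.0, config.pop_scatter_topt_sd, size=n)
        breadth = base_breadth + config.cline_slope_breadth_seasonality * (ts - ts.mean())
        breadth = breadth + rng.normal(0.0, config.pop_scatter_breadth_sd, size=n)
        scale = breadth / base_breadth
        if np.any(scale <= 0):
            raise ConfigError(
                "configured breadth cline collapses the support (upper <= lower) "
                "for at least one population"
            )

    rows = []
    for pid, dt, s in zip(pops, d_topt, scale):
        topt = base_topt + dt
        lower = topt + (base.lower - base_topt) * s
        upper = topt + (base.upper - base_topt) * s
        rows.append(
            {
                "population_id": pid,
                "range_label": "native" if pid in native else "invasive",
                "lower": lower,
                "upper": upper,
                "shape_a": base.shape_a,
                "shape_b": base.shape_b,
                "stretch": base.stretch,
                "t_opt": topt,
                "t_breadth": base_breadth * s,
                "noise_sd": config.noise_sd,
            }
        )
    return pd.DataFrame(rows)


def gen_design(config: SimConfig) -> pd.DataFrame:
    """Experiment layout with establishment/damage flags, measurements empty.

    With ``pin_establish_fail``/``pin_damage`` set, exactly that many records
    are flagged (sampled without replacement), reproducing fixed filter
    bookkeeping; otherwise flags are Bernoulli with the configured rates.
    """
    rng = substream(config.seed, "design")
    native, invasive = _population_ids(config)
    rows = []
    for pid in native + invasive:
        label = "native" if pid in native else "invasive"
        for g in range(1, config.genotypes_per_pop + 1):
            gid = f"{pid}-g{g}"
            for day, night in config.regimes:
                for clone in range(1, config.replicates_for((day, night)) + 1):
                    rows.append(
                        {
                            "population_id": pid,
                            "range_label": label,
                            "genotype_id": gid,
                            "clone_id": clone,
                            "day_temp": day,
                            "night_temp": night,
                            "stem_in": np.nan,
                            "stem_out": np.nan,
                            "days": config.days,
                        }
                    )
    df = pd.DataFrame(rows)
    n = len(df)
    assert n == config.n_records

    established = np.ones(n, dtype=bool)
    damaged = np.zeros(n, dtype=bool)
    if config.pin_establish_fail is not None:
        fail_idx = rng.choice(n, size=config.pin_establish_fail, replace=False)
        established[fail_idx] = False
    else:
        established = rng.random(n) >= config.p_establish_fail
    est_idx = np.flatnonzero(established)
    if config.pin_damage is not None:
        dmg = rng.choice(len(est_idx), size=config.pin_damage, replace=False)
        damaged[est_idx[dmg]] = True
    else:
        damaged[est_idx] = rng.random(len(est_idx)) < config.p_damage
    df["established"] = established
    df["damaged"] = damaged
    return df


def gen_observations(
    design: pd.DataFrame, truths: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Fill stem measurements by forward-simulating growth from the truths."""
    missing = set(design["population_id"]) - set(truths["population_id"])
    if missing:
        raise DataError(f"no truth entry for populations: {sorted(missing)}")
    t = truths.set_index("population_id")
    rng = substream(config.seed, "obs")
    df = design.copy()
    n = len(df)

    pop = df["population_id"].to_numpy()
    pvals = performance_curve_array(
        df["day_temp"].to_numpy(dtype=float),
        t.loc[pop, "lower"].to_numpy(dtype=float),
        t.loc[pop, "upper"].to_numpy(dtype=float),
        t.loc[pop, "shape_a"].to_numpy(dtype=float),
        t.loc[pop, "shape_b"].to_numpy(dtype=float),
        t.loc[pop, "stretch"].to_numpy(dtype=float),
    )
    stem_in = config.stem_in_mean * np.exp(
        config.stem_in_log_sd * rng.standard_normal(n)
    )
    rgr = pvals + config.noise_sd * rng.standard_normal(n)
    dmg = df["damaged"].to_numpy(dtype=bool)
    rgr[dmg] = -rng.uniform(0.01, 0.08, size=int(dmg.sum()))
    stem_out = stem_in * (1.0 + df["days"].to_numpy(dtype=float) * rgr)

    est = df["established"].to_numpy(dtype=bool)
    df["stem_in"] = stem_in
    df["stem_out"] = np.where(est, stem_out, np.nan)
    return df


def simulate_experiment(config: SimConfig):
    """Convenience: (climate, truths, records) for one seeded experiment."""
    climate = gen_climate(config)
    truths = gen_true_tpcs(config, climate)
    records = gen_observations(gen_design(config), truths, config)
    return climate, truths, records


def gen_model_family_means(config: SimConfig):
    """Genotype-mean RGR drawn directly from the model's likelihood family.

    Each genotype x daytime-temperature cell receives one zero-truncated
    Normal(P(day_temp), noise_sd) draw. Used to check posterior predictive
    calibration under a well-specified model.
    """
    climate = gen_climate(config)
    truths = gen_true_tpcs(config, climate)
    t = truths.set_index("population_id")
    rng = substream(config.seed, "model-family")
    rows = []
    for pid in truths["population_id"]:
        for g in range(1, config.genotypes_per_pop + 1):
            for day, _night in config.regimes:
                rows.append((pid, t.loc[pid, "range_label"], f"{pid}-g{g}", day))
    df = pd.DataFrame(rows, columns=["population_id", "range_label", "genotype_id", "day_temp"])
    mu = performance_curve_array(
        df["day_temp"].to_numpy(dtype=float),
        t.loc[df["population_id"], "lower"].to_numpy(dtype=float),
        t.loc[df["population_id"], "upper"].to_numpy(dtype=float),
        t.loc[df["population_id"], "shape_a"].to_numpy(dtype=float),
        t.loc[df["population_id"], "shape_b"].to_numpy(dtype=float),
        t.loc[df["population_id"], "stretch"].to_numpy(dtype=float),
    )
    sd = config.noise_sd
    lo = ndtr(-mu / sd)
    u = lo + (1.0 - lo) * rng.random(len(df))
    df["mean_rgr"] = mu + sd * ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))
    return climate, truths, df
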