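"""Thermal optimum and performance breadth, derived per posterior draw.

The thermal optimum has a closed form under peak normalization,
``T_opt = lower + (upper - lower) * z*`` with ``z*`` the Kumaraswamy kernel
mode. Thermal performance breadth is the span between the temperatures, one
on each side of the optimum, whose performance is closest to ``level`` (by
default 50%) of the maximum among ``grid_n`` equally spaced points covering
the curve's support. Endpoints snap to grid points; an optional ``refine``
flag replaces them by root-finding, off by default.

Summaries (posterior mean and equal-tailed 95% credible interval) are always
computed from the per-draw derived values, never from summarized parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import DeriveConfig
from .errors import ConfigError, DataError
from .tpc_model import (
    PosteriorDraws,
    TPCParams,
    _kernel,
    kumaraswamy_mode,
)

#: derived quantities exported per population
DERIVED_NAMES = ("t_opt", "t_breadth", "breadth_lo", "breadth_hi", "p_max", "lower", "upper")


def thermal_optimum(params: TPCParams) -> float:
    """Temperature of maximum performance (analytic kernel mode)."""
    if params.shape_a <= 1.0 or params.shape_b <= 1.0:
        raise ConfigError("thermal optimum requires shape_a > 1 and shape_b > 1")
    z = kumaraswamy_mode(params.shape_a, params.shape_b)
    return params.lower + (params.upper - params.lower) * z


def thermal_breadth(
    params: TPCParams,
    level: float = 0.5,
    grid_n: int = 100,
    refine: bool = False,
):
    """(t_breadth, breadth_lo, breadth_hi) at ``level`` of maximum performance."""
    if grid_n < 10:
        raise ConfigError(f"grid_n must be >= 10, got {grid_n}")
    if not 0.0 < level < 1.0:
        raise ConfigError(f"level must lie in (0, 1), got {level}")
    params.validate()
    lo, hi = _breadth_z(
        np.array([params.shape_a]),
        np.array([params.shape_b]),
        level,
        grid_n,
        refine,
    )
    width = params.upper - params.lower
    b_lo = params.lower + lo[0] * width
    b_hi = params.lower + hi[0] * width
    return b_hi - b_lo, b_lo, b_hi


def _breadth_z(shape_a, shape_b, level, grid_n, refine):
    """Breadth endpoints in the unit z-coordinate, vectorized over draws."""
    zstar = kumaraswamy_mode(shape_a, shape_b)
    peak = _kernel(zstar, shape_a, shape_b)
    # interior grid; the support endpoints have zero performance and are not
    # candidates, keeping breadth_lo/hi strictly inside (lower, upper)
    z = np.linspace(0.0, 1.0, grid_n)[1:-1]
    g = _kernel(z[None, :], shape_a[:, None], shape_b[:, None]) / peak[:, None]
    dist = np.abs(g - level)
    below = z[None, :] < zstar[:, None]
    lo_idx = np.where(below, dist, np.inf).argmin(axis=1)
    hi_idx = np.where(~below, dist, np.inf).argmin(axis=1)
    z_lo, z_hi = z[lo_idx], z[hi_idx]
    if refine:
        z_lo = z_lo.copy()
        z_hi = z_hi.copy()
        for i in range(len(zstar)):
            a, b, zs, pk = shape_a[i], shape_b[i], zstar[i], peak[i]
            f = lambda zz: _kernel(zz, a, b) / pk - level  # noqa: E731
            z_lo[i] = brentq(f, 1e-12, zs, xtol=1e-12)
            z_hi[i] = brentq(f, zs, 1.0 - 1e-12, xtol=1e-12)
    return z_lo, z_hi


def derive_draws(draws: PosteriorDraws, cfg: DeriveConfig | None = None) -> pd.DataFrame:
    """Per-draw, per-population derived quantities (long DataFrame)."""
    cfg = cfg or DeriveConfig()
    n_d, n_p, _ = draws.params.shape
    frames = []
    for k in range(n_p):
        p = draws.params[:, k, :]
        lower, upper, a, b, stretch = (p[:, j] for j in range(5))
        width = upper - lower
        zstar = kumaraswamy_mode(a, b)
        t_opt = lower + width * zstar
        z_lo, z_hi = _breadth_z(a, b, cfg.level, cfg.grid_n, cfg.refine)
        frames.append(
            pd.DataFrame(
                {
                    "draw": np.arange(n_d),
                    "population_id": draws.populations[k],
                    "range_label": draws.range_labels[k],
                    "t_opt": t_opt,
                    "t_breadth": (z_hi - z_lo) * width,
                    "breadth_lo": lower + z_lo * width,
                    "breadth_hi": lower + z_hi * width,
                    "p_max": stretch,
                    "lower": lower,
                    "upper": upper,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class DerivedSummary:
    """Posterior mean and 95% CrI per population per derived quantity."""

    table: pd.DataFrame  # population_id, range_label, parameter, mean, cri_lo, cri_hi


def summarize_derived(
    draws: PosteriorDraws,
    cfg: DeriveConfig | None = None,
    per_draw: pd.DataFrame | None = None,
) -> DerivedSummary:
    """Summarize per-draw derived values (derivation happens before summary)."""
    if draws.n_draws < 100:
        raise DataError(f"need >= 100 draws to summarize, got {draws.n_draws}")
    if per_draw is None:
        per_draw = derive_draws(draws, cfg)
    rows = []
    for (pop, label), grp in per_draw.groupby(["population_id", "range_label"], sort=True):
        for name in DERIVED_NAMES:
            v = grp[name].to_numpy(dtype=float)
            lo, hi = np.percentile(v, [2.5, 97.5])
            rows.append(
                {
                    "population_id": pop,
                    "range_label": label,
                    "parameter": name,
                    "mean": float(v.mean()),
                    "cri_lo": float(lo),
                    "cri_hi": float(hi),
                }
            )
    return DerivedSummary(table=pd.DataFrame(rows))
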