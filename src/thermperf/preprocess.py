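"""Relative growth rate, quality filters, genotype aggregation, and scaling.

Relative growth rate (RGR) of a cutting is the change in total stem-plus-
branch length per unit initial length per day:

    rgr = (stem_out - stem_in) / (stem_in * days)

Filtering follows the experiment's stated rules, in order: drop cuttings that
failed to establish; drop cuttings flagged as accidentally damaged (whose
negative RGR reflects handling, not temperature); truncate remaining negative
RGR — dieback at temperature extremes — to zero. Truncation is applied to
individual cuttings before genotype averaging.

The model consumes genotype-level mean RGR per daytime temperature, scaled by
the grand mean RGR and with temperature centered on the unweighted mean of the
distinct daytime treatment temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: columns required of an experiment record table
RECORD_COLUMNS = (
    "population_id",
    "range_label",
    "genotype_id",
    "clone_id",
    "day_temp",
    "night_temp",
    "stem_in",
    "stem_out",
    "days",
    "established",
    "damaged",
)


@dataclass(frozen=True)
class FilterReport:
    """Auditable record counts at each filtering stage."""

    n_total: int
    n_failed_establish: int
    n_after_establish: int
    n_damaged_excluded: int
    n_final: int
    n_dieback_truncated: int

    def __post_init__(self):
        assert self.n_after_establish == self.n_total - self.n_failed_establish
        assert self.n_final == self.n_after_establish - self.n_damaged_excluded

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_rgr(stem_in, stem_out, days):
    """Per-day relative growth rate; may be negative before truncation."""
    stem_in = np.asarray(stem_in, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(stem_in <= 0):
        raise DataError("stem_in must be > 0 for established records")
    if np.any(days <= 0):
        raise DataError("days must be > 0")
    return (np.asarray(stem_out, dtype=float) - stem_in) / (stem_in * days)


def apply_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply establishment/damage exclusions and dieback truncation.

    Returns the clean records (with an ``rgr`` column) and a
    :class:`FilterReport`. Damaged and non-established records are excluded
    regardless of the sign of their RGR.
    """
    n_total = len(records)
    established = records[records["established"].astype(bool)]
    n_failed = n_total - len(established)
    clean = established[~established["damaged"].astype(bool)].copy()
    n_damaged = len(established) - len(clean)

    if len(clean) == 0:
        logger.warning("all %d records removed by filters", n_total)
        clean["rgr"] = pd.Series(dtype=float)
    else:
        rgr = compute_rgr(clean["stem_in"], clean["stem_out"], clean["days"])
        n_trunc = int((rgr < 0).sum())
        clean["rgr"] = np.maximum(rgr, 0.0)
    report = FilterReport(
        n_total=n_total,
        n_failed_establish=n_failed,
        n_after_establish=len(established),
        n_damaged_excluded=n_damaged,
        n_final=len(clean),
        n_dieback_truncated=0 if len(clean) == 0 else n_trunc,
    )
    logger.info(
        "filters: %d total -> %d established -> %d final (%d dieback truncations)",
        report.n_total,
        report.n_after_establish,
        report.n_final,
        report.n_dieback_truncated,
    )
    return clean, report


def genotype_means(clean: pd.DataFrame) -> pd.DataFrame:
    """Mean RGR over clone replicates within genotype x daytime temperature."""
    grouped = (
        clean.groupby(
            ["population_id", "range_label", "genotype_id", "day_temp"],
            as_index=False,
            sort=True,
        )["rgr"]
        .mean()
        .rename(columns={"rgr": "mean_rgr"})
    )
    return grouped


@dataclass
class ScaledDataset:
    """Genotype means scaled for modelling, with constants to invert the maps.

    ``scaled_rgr = mean_rgr / grand_mean_rgr`` (so the grand mean of the
    scaled response is 1) and ``centered_temp = day_temp - temp_center``.
    """

    df: pd.DataFrame  # pop_index, population_id, range_label, genotype_id,
    #                   day_temp, centered_temp, scaled_rgr
    grand_mean_rgr: float
    temp_center: float
    populations: list
    range_labels: list


def scale_dataset(means: pd.DataFrame) -> ScaledDataset:
    if len(means) == 0:
        raise DataError("cannot scale an empty genotype-means table")
    grand = float(means["mean_rgr"].mean())
    if grand <= 0:
        raise DataError("grand mean RGR is not positive; cannot scale")
    center = float(np.mean(np.unique(means["day_temp"].to_numpy(dtype=float))))

    pops = sorted(means["population_id"].unique())
    pop_index = {p: i for i, p in enumerate(pops)}
    labels = (
        means.drop_duplicates("population_id")
        .set_index("population_id")["range_label"]
        .to_dict()
    )
    df = means.copy()
    df["pop_index"] = df["population_id"].map(pop_index)
    df["centered_temp"] = df["day_temp"].astype(float) - center
    df["scaled_rgr"] = df["mean_rgr"].astype(float) / grand
    return ScaledDataset(
        df=df,
        grand_mean_rgr=grand,
        temp_center=center,
        populations=pops,
        range_labels=[labels[p] for p in pops],
    )


def unscale_rgr(scaled, dataset: ScaledDataset):
    return np.asarray(scaled, dtype=float) * dataset.grand_mean_rgr


def unscale_temperature(centered, dataset: ScaledDataset):
    return np.asarray(centered, dtype=float) + dataset.temp_center


def preprocess(records: pd.DataFrame):
    """Full stage: filters -> genotype means -> scaling.

    Returns (clean records, FilterReport, genotype means, ScaledDataset).
    """
    clean, report = apply_filters(records)
    means = genotype_means(clean)
    scaled = scale_dataset(means)
    return clean, report, means, scaled
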