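"""Range contrasts and climatic cline regressions.

Two questions are answered downstream of the curve fit. First, do the native
and invasive ranges differ in thermal optimum or breadth? For every posterior
draw the invasive among-population average is subtracted from the native
average; the contrast is summarized by its posterior mean and equal-tailed
95% credible interval, and called significant when the interval excludes
zero. Second, do curve parameters show clines on latitude or climate? The
population posterior means are regressed on a predictor, a range indicator
(native is the reference level; the indicator is 1 for invasive), and
optionally their interaction; the model with and without the interaction are
compared by AIC (strict minimum, ties resolved toward fewer parameters), and
per-range sub-models dissect where any cline lives.

AIC uses the Gaussian log-likelihood with its constant and counts the
residual-variance parameter, matching mainstream statistical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, ModelError

#: cline model families: (response, predictor) pairs
CLINE_FAMILIES = (
    ("t_opt", "latitude"),
    ("t_opt", "mat"),
    ("t_breadth", "latitude"),
    ("t_breadth", "seasonality"),
)


@dataclass
class RangeContrast:
    parameter: str
    mean_diff: float
    cri_lo: float
    cri_hi: float
    significant: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def range_contrast(per_draw: pd.DataFrame, parameter: str) -> RangeContrast:
    """Posterior contrast of a derived parameter: native mean - invasive mean."""
    if parameter not in per_draw.columns:
        raise DataError(f"unknown parameter {parameter!r}")
    for label in ("native", "invasive"):
        if not (per_draw["range_label"] == label).any():
            raise DataError(f"no populations labelled {label!r}")
    means = per_draw.pivot_table(
        index="draw", columns="range_label", values=parameter, aggfunc="mean"
    )
    diff = (means["native"] - means["invasive"]).to_numpy(dtype=float)
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return RangeContrast(
        parameter=parameter,
        mean_diff=float(diff.mean()),
        cri_lo=float(lo),
        cri_hi=float(hi),
        significant=not (lo <= 0.0 <= hi),
    )


@dataclass
class ClineModelResult:
    response: str
    predictor: str
    coef_names: list
    coefficients: np.ndarray
    pvalues: np.ndarray
    aic: float
    adj_r2: float
    n: int
    has_interaction: bool

    @property
    def beta1(self) -> float:
        """Main effect of the predictor."""
        return float(self.coefficients[1])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.coef_names.index(name)])

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "predictor": self.predictor,
            "aic": self.aic,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "has_interaction": self.has_interaction,
        }
        for name, c, p in zip(self.coef_names, self.coefficients, self.pvalues):
            d[f"coef_{name}"] = float(c)
            d[f"p_{name}"] = float(p)
        return d


def fit_ols(
    y,
    X: np.ndarray,
    coef_names: list,
    response: str = "y",
    predictor: str = "x",
    has_interaction: bool = False,
) -> ClineModelResult:
    """Ordinary least squares with R-style AIC and adjusted R^2.

    ``X`` must include the intercept column. Raises :class:`ModelError`
    naming the collinear columns on rank deficiency.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ModelError(f"need more observations ({n}) than columns ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # flag columns whose removal restores full rank
        bad = [
            coef_names[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ModelError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    aic = -2.0 * fit.llf + 2.0 * (k + 1)  # + 1 counts the variance parameter
    coef = np.asarray(fit.params, dtype=float)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0.0 else 1.0 - rss / tss
    k_slopes = k - 1  # intercept column excluded
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k_slopes - 1)
    pvalues = np.asarray(fit.pvalues, dtype=float)
    pvalues = np.where(np.isfinite(pvalues), pvalues, 1.0)  # degenerate response
    return ClineModelResult(
        response=response,
        predictor=predictor,
        coef_names=list(coef_names),
        coefficients=coef,
        pvalues=pvalues,
        aic=float(aic),
        adj_r2=float(adj_r2),
        n=int(n),
        has_interaction=has_interaction,
    )


def aic_select(full: ClineModelResult, reduced: ClineModelResult) -> ClineModelResult:
    """Strict-minimum-AIC choice between the interaction and main-effect models.

    Ties go to the reduced (fewer-parameter) model. Attaches an
    ``interpretation`` entry when converted to a report.
    """
    if full.n != reduced.n:
        raise ModelError(f"model sample sizes differ: {full.n} vs {reduced.n}")
    return full if full.aic < reduced.aic else reduced


def interpret(chosen: ClineModelResult, alpha: float = 0.05) -> str:
    if chosen.has_interaction and chosen.pvalue("interaction") < alpha:
        return "divergent clines"
    if chosen.pvalue(chosen.predictor) < alpha:
        return "parallel cline"
    return "no cline"


@dataclass
class SubModelResult:
    range_label: str
    slope: float
    pvalue: float
    adj_r2: float
    n: int


@dataclass
class ClineFamilyReport:
    response: str
    predictor: str
    full: ClineModelResult
    reduced: ClineModelResult
    final: ClineModelResult
    interpretation: str
    sub_models: dict = field(default_factory=dict)  # range_label -> SubModelResult


@dataclass
class ClineReport:
    families: list  # of ClineFamilyReport
    contrasts: Optional[list] = None

    def to_frame(self) -> pd.DataFrame:
        """Flat table of all fitted models (one row per model), final flagged."""
        rows = []
        for fam in self.families:
            for tag, model in (("full", fam.full), ("reduced", fam.reduced)):
                d = model.to_dict()
                d["model"] = tag
                d["final"] = model is fam.final
                d["interpretation"] = fam.interpretation if d["final"] else ""
                rows.append(d)
            for label, sub in fam.sub_models.items():
                rows.append(
                    {
                        "response": fam.response,
                        "predictor": fam.predictor,
                        "model": f"within-{label}",
                        "final": False,
                        f"coef_{fam.predictor}": sub.slope,
                        f"p_{fam.predictor}": sub.pvalue,
                        "adj_r2": sub.adj_r2,
                        "n": sub.n,
                        "interpretation": "",
                    }
                )
        return pd.DataFrame(rows)


def _family_design(df: pd.DataFrame, predictor: str):
    x = df[predictor].to_numpy(dtype=float)
    r = (df["range_label"] == "invasive").to_numpy(dtype=float)
    intercept = np.ones(len(df))
    X_full = np.column_stack([intercept, x, r, x * r])
    X_red = np.column_stack([intercept, x, r])
    names_full = ["intercept", predictor, "range", "interaction"]
    names_red = ["intercept", predictor, "range"]
    return (X_full, names_full), (X_red, names_red)


def cline_analysis(
    derived_means: pd.DataFrame, climate: pd.DataFrame
) -> ClineReport:
    """Fit the four cline model families and per-range sub-models.

    ``derived_means`` holds one row per population with columns ``t_opt`` and
    ``t_breadth`` (population posterior means) and ``range_label``.
    """
    missing = set(derived_means["population_id"]) - set(climate["population_id"])
    if missing:
        raise DataError(f"climate missing for populations: {sorted(missing)}")
    df = derived_means.merge(
        climate[["population_id", "latitude", "mat", "seasonality"]],
        on="population_id",
        validate="one_to_one",
    )
    families = []
    for response, predictor in CLINE_FAMILIES:
        y = df[response].to_numpy(dtype=float)
        (X_f, names_f), (X_r, names_r) = _family_design(df, predictor)
        full = fit_ols(y, X_f, names_f, response, predictor, has_interaction=True)
        reduced = fit_ols(y, X_r, names_r, response, predictor)
        final = aic_select(full, reduced)
        subs = {}
        for label in ("native", "invasive"):
            sel = df[df["range_label"] == label]
            ys = sel[response].to_numpy(dtype=float)
            Xs = np.column_stack([np.ones(len(sel)), sel[predictor].to_numpy(dtype=float)])
            m = fit_ols(ys, Xs, ["intercept", predictor], response, predictor)
            subs[label] = SubModelResult(
                range_label=label,
                slope=m.beta1,
                pvalue=m.pvalue(predictor),
                adj_r2=m.adj_r2,
                n=m.n,
            )
        families.append(
            ClineFamilyReport(
                response=response,
                predictor=predictor,
                full=full,
                reduced=reduced,
                final=final,
                interpretation=interpret(final),
                sub_models=subs,
            )
        )
    return ClineReport(families=families)
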