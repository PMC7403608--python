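"""Mutation-rate estimation per cell division and per meter of growth.

Linear apical growth converts directly between length and divisions: a
mycelium of length *L* meters built from apical cells of length *l* µm
has undergone ``D = L / (l × 10⁻⁶)`` divisions along any hyphal lineage.
With *n* mutations accumulated over *D* divisions across *G* callable
sites, the per-cell-division rate is ``μ = n / (G × D)`` and the
per-meter rate is ``μ / (l × 10⁻⁶)``.

Group estimates average per-line rates; the confidence interval is a
two-sided Student-t interval by default, with a BCa bootstrap
alternative.  Factorial comparisons (founder genotype × tube size, with
optional length and coverage covariates) use an ordinary linear model
with type-II sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf


def divisions_from_length(length_m: float, cell_length_um: float) -> float:
    """Number of cell divisions represented by ``length_m`` of growth."""
    if cell_length_um <= 0:
        raise ValueError("cell_length_um must be positive")
    if length_m < 0:
        raise ValueError("length_m must be >= 0")
    return length_m / (cell_length_um * 1e-6)


def rate_per_division(n_mut: float, callable_sites: float,
                      divisions: float) -> float:
    """Mutations per nucleotide per cell division."""
    if callable_sites <= 0 or divisions <= 0:
        raise ValueError("callable_sites and divisions must be positive")
    return n_mut / (callable_sites * divisions)


def rate_per_meter(rate_per_div: float, cell_length_um: float) -> float:
    """Convert a per-cell-division rate to a per-meter-of-growth rate."""
    if cell_length_um <= 0:
        raise ValueError("cell_length_um must be positive")
    return rate_per_div / (cell_length_um * 1e-6)


@dataclass(frozen=True)
class LineRecord:
    """Final mutation tally and geometry for one experimental line."""

    line_id: str
    founder: str
    tube: str
    replicate: int
    final_length_m: float
    n_reached: int
    callable_sites: float
    mean_coverage: float = float("nan")

    def __post_init__(self):
        if self.final_length_m <= 0:
            raise ValueError("final_length_m must be positive")
        if self.n_reached < 0:
            raise ValueError("n_reached must be >= 0")


@dataclass(frozen=True)
class RateEstimate:
    rate_per_division: float
    rate_per_meter: float
    ci95: tuple[float, float]        # per-division scale
    ci95_per_meter: tuple[float, float]
    n_lines: int
    cell_length_um: float
    mean_divisions: float
    per_line_rates: tuple[float, ...]


def line_rate(line: LineRecord, cell_length_um: float) -> float:
    d = divisions_from_length(line.final_length_m, cell_length_um)
    return rate_per_division(line.n_reached, line.callable_sites, d)


def group_rate_with_ci(lines: list[LineRecord], cell_length_um: float,
                       ci_method: str = "t_interval", confidence: float = 0.95,
                       n_resamples: int = 9999, seed: int = 0,
                       pooled: bool = False) -> RateEstimate:
    """Group mutation rate with a confidence interval.

    The point estimate is the mean of per-line rates (``pooled=True``
    instead divides the pooled mutation count by the pooled site-division
    denominator).  ``ci_method`` is ``"t_interval"`` (two-sided Student t
    on per-line rates) or ``"bootstrap_bca"``.
    """
    if len(lines) < 2:
        raise ValueError("need at least two lines for a dispersion estimate")
    rates = np.array([line_rate(ln, cell_length_um) for ln in lines])
    divisions = np.array([
        divisions_from_length(ln.final_length_m, cell_length_um) for ln in lines
    ])
    if pooled:
        point = float(
            sum(ln.n_reached for ln in lines)
            / sum(ln.callable_sites * d for ln, d in zip(lines, divisions))
        )
    else:
        point = float(rates.mean())

    if ci_method == "t_interval":
        sem = stats.sem(rates)
        if sem == 0:
            ci = (point, point)
        else:
            ci = stats.t.interval(confidence, len(rates) - 1,
                                  loc=rates.mean(), scale=sem)
    elif ci_method == "bootstrap_bca":
        res = stats.bootstrap(
            (rates,), np.mean, confidence_level=confidence,
            n_resamples=n_resamples, method="BCa",
            rng=np.random.default_rng(seed),
        )
        ci = (float(res.confidence_interval.low),
              float(res.confidence_interval.high))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    to_m = 1.0 / (cell_length_um * 1e-6)
    return RateEstimate(
        rate_per_division=point,
        rate_per_meter=point * to_m,
        ci95=(float(ci[0]), float(ci[1])),
        ci95_per_meter=(float(ci[0]) * to_m, float(ci[1]) * to_m),
        n_lines=len(lines),
        cell_length_um=cell_length_um,
        mean_divisions=float(divisions.mean()),
        per_line_rates=tuple(float(r) for r in rates),
    )


def lines_to_frame(lines: list[LineRecord],
                   cell_length_by_tube: dict[str, float]) -> pd.DataFrame:
    rows = []
    for ln in lines:
        cl = cell_length_by_tube[ln.tube]
        rows.append({
            "line_id": ln.line_id, "founder": ln.founder, "tube": ln.tube,
            "replicate": ln.replicate, "final_length_m": ln.final_length_m,
            "n_reached": ln.n_reached,
            "rate": line_rate(ln, cl),
            "mean_coverage": ln.mean_coverage,
        })
    return pd.DataFrame(rows)


def anova_rates(frame: pd.DataFrame, length_covariate: bool = False,
                coverage_covariate: bool = False):
    """Two-way fixed-effects model of per-line rate on founder and tube.

    Fits ``rate ~ C(founder) + C(tube)`` by OLS, optionally adding the
    final mycelium length and/or the mean sample coverage as continuous
    covariates, and returns the type-II ANOVA table alongside the fitted
    model.
    """
    for term in ("founder", "tube"):
        if frame[term].nunique() < 2:
            raise ValueError(f"factor {term!r} needs at least two levels")
    formula = "rate ~ C(founder) + C(tube)"
    if length_covariate:
        formula += " + final_length_m"
    if coverage_covariate:
        if frame["mean_coverage"].isna().any():
            raise ValueError("mean_coverage covariate requested but missing")
        formula += " + mean_coverage"
    model = smf.ols(formula, data=frame).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear terms)")
    table = sm.stats.anova_lm(model, typ=2)
    return table, model
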