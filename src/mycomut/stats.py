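"""Cell-length statistics, growth-rate regressions, and counting dN/dS.

The dN/dS here is the classic counting approximation: mutational
opportunity is tallied by enumerating all nine single-base changes of
every CDS codon under equal rates (changes creating a stop codon count
as nonsynonymous opportunity), and the ratio is
``(nN / sitesN) / (nS / sitesS)``.  It is not a codon-model maximum
likelihood estimate; for the neutral and purifying-selection contrasts
simulated here the counting form is sufficient and transparent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf

from .genome import BASES, GenomeModel, translate_codon


@dataclass(frozen=True)
class CellLengthSample:
    """Apical cell length measurements (µm) for one tube type."""

    tube: str
    measurements: tuple[float, ...]

    def __post_init__(self):
        if any(m <= 0 for m in self.measurements):
            raise ValueError("cell length measurements must be positive")


def cell_length_stats(sample: CellLengthSample,
                      confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean apical cell length with a two-sided t confidence interval."""
    x = np.asarray(sample.measurements, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two measurements")
    mean = float(x.mean())
    sem = sps.sem(x)
    if sem == 0:
        return mean, mean, mean
    lo, hi = sps.t.interval(confidence, len(x) - 1, loc=mean, scale=sem)
    return mean, float(lo), float(hi)


@dataclass(frozen=True)
class GrowthRecord:
    """Cumulative length observations (mm) for one line over time (days)."""

    line_id: str
    days: tuple[float, ...]
    lengths_mm: tuple[float, ...]

    def __post_init__(self):
        if len(self.days) != len(self.lengths_mm):
            raise ValueError("days and lengths differ in size")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(b < a for a, b in zip(self.lengths_mm, self.lengths_mm[1:])):
            raise ValueError("cumulative lengths must be non-decreasing")


@dataclass
class GrowthFit:
    intervals: pd.DataFrame      # midpoint_day, rate_mm_per_day, line_id
    mean_rate_mm_per_day: float
    slope: float                 # change of rate per day
    r2_adj: float
    p_value: float


def growth_rate_regression(records: list[GrowthRecord]) -> GrowthFit:
    """Per-interval growth rates regressed on time.

    Each consecutive observation pair yields an interval rate
    Δlength/Δday at the interval's midpoint day; an OLS fit of rate on
    midpoint tests for a change of growth rate over the experiment.
    Reports the slope, adjusted R², and the two-sided p-value for
    slope = 0.
    """
    rows = []
    for rec in records:
        for (d0, d1), (l0, l1) in zip(
            zip(rec.days, rec.days[1:]), zip(rec.lengths_mm, rec.lengths_mm[1:])
        ):
            if d1 == d0:
                raise ValueError(f"zero-length time interval in {rec.line_id}")
            rows.append({
                "line_id": rec.line_id,
                "midpoint_day": 0.5 * (d0 + d1),
                "rate_mm_per_day": (l1 - l0) / (d1 - d0),
            })
    intervals = pd.DataFrame(rows)
    if len(intervals) < 3:
        raise ValueError("need at least three growth intervals")
    rates = intervals["rate_mm_per_day"].to_numpy()
    if np.ptp(rates) == 0.0:
        # perfectly constant rate: the F test is 0/0; report the only
        # sensible answer rather than numerical noise
        return GrowthFit(intervals=intervals,
                         mean_rate_mm_per_day=float(rates.mean()),
                         slope=0.0, r2_adj=float("nan"), p_value=1.0)
    fit = smf.ols("rate_mm_per_day ~ midpoint_day", data=intervals).fit()
    return GrowthFit(
        intervals=intervals,
        mean_rate_mm_per_day=float(intervals["rate_mm_per_day"].mean()),
        slope=float(fit.params["midpoint_day"]),
        r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.pvalues["midpoint_day"]),
    )


@dataclass(frozen=True)
class EffectTally:
    group: str
    n_nonsyn: int
    n_syn: int
    sites_nonsyn: float
    sites_syn: float
    dn_ds: float | None  # None when undefined (no synonymous hits or sites)


@lru_cache(maxsize=None)
def _codon_opportunity(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site fractions of one codon.

    Each of the nine single-base changes contributes 1/3 of a site;
    changes to or from stop codons count as nonsynonymous.
    """
    aa = translate_codon(codon)
    n_sites = s_sites = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if translate_codon(alt) == aa:
                s_sites += 1.0 / 3.0
            else:
                n_sites += 1.0 / 3.0
    return n_sites, s_sites


def coding_site_opportunity(genome: GenomeModel) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) site counts over all CDS."""
    if not genome.genes:
        raise ValueError("genome has no annotated CDS")
    n_tot = s_tot = 0.0
    for gene in genome.genes:
        cds = genome.spliced_cds(gene)
        for i in range(0, len(cds) - 2, 3):
            n, s = _codon_opportunity(cds[i:i + 3])
            n_tot += n
            s_tot += s
    return n_tot, s_tot


def dnds_counting(effects, genome: GenomeModel,
                  group: str = "all") -> EffectTally:
    """Opportunity-corrected dN/dS from classified mutation effects.

    ``effects`` is an iterable of effect labels; nonsense changes count
    toward the nonsynonymous numerator (they are amino-acid-altering).
    The ratio is undefined (``None``) when no synonymous mutations were
    observed or the genome offers no synonymous sites.
    """
    sites_n, sites_s = coding_site_opportunity(genome)
    effects = list(effects)
    n_nonsyn = sum(1 for e in effects if e in ("nonsynonymous", "nonsense"))
    n_syn = sum(1 for e in effects if e == "synonymous")
    if n_syn == 0 or sites_s == 0 or sites_n == 0:
        dn_ds = None
    else:
        dn_ds = (n_nonsyn / sites_n) / (n_syn / sites_s)
    return EffectTally(group=group, n_nonsyn=n_nonsyn, n_syn=n_syn,
                       sites_nonsyn=sites_n, sites_syn=sites_s, dn_ds=dn_ds)
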