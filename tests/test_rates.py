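"""Length-to-division conversion, rate arithmetic, CIs, and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mycomut.rates import (LineRecord, anova_rates, divisions_from_length,
                           group_rate_with_ci, rate_per_division,
                           rate_per_meter)


def make_line(n_reached, length=1.98, tube="thick", founder="sh01",
              line_id="L", replicate=1, G=3.85e7):
    return LineRecord(line_id=line_id, founder=founder, tube=tube,
                      replicate=replicate, final_length_m=length,
                      n_reached=n_reached, callable_sites=G)


class TestConversions:
    def test_mean_narrow_length_is_about_4800_divisions(self):
        d = divisions_from_length(0.78, 163.0)
        assert d == pytest.approx(4785.28, abs=0.01)
        assert round(d / 100) * 100 == 4800

    def test_mean_thick_length_is_12000_divisions(self):
        assert divisions_from_length(1.98, 165.0) == pytest.approx(12_000)

    def test_zero_length_zero_divisions(self):
        assert divisions_from_length(0.0, 163.0) == 0.0

    def test_nonpositive_cell_length_rejected(self):
        with pytest.raises(ValueError):
            divisions_from_length(1.0, 0.0)

    @pytest.mark.parametrize("n,G,D,expected", [
        (10, 3.85e7, 12_000, 2.1645e-11),
        (0, 3.85e7, 12_000, 0.0),
        (9.4, 3.85e7, 12_000, 2.0346e-11),
    ])
    def test_rate_per_division_formula(self, n, G, D, expected):
        assert rate_per_division(n, G, D) == pytest.approx(expected, rel=1e-3)

    def test_rate_per_division_zero_denominator(self):
        with pytest.raises(ValueError):
            rate_per_division(1, 0, 100)

    def test_rate_per_meter_thick_tube_headline(self):
        assert rate_per_meter(2.04e-11, 165.0) == pytest.approx(1.236e-7, rel=1e-3)

    def test_per_generation_rate_over_10_cm(self):
        # a generation spanning ~10 cm of growth: 2e-8 per generation
        # translates to 2e-7 per meter
        assert rate_per_meter(2e-8, 0.10 * 1e6) == pytest.approx(2e-7)

    def test_dimensional_round_trip_is_exact(self):
        r = rate_per_division(7, 3.85e7, 4785.0)
        assert rate_per_meter(r, 163.0) * (163.0 * 1e-6) == r


class TestGroupRate:
    def test_identical_lines_zero_width_interval(self):
        lines = [make_line(8, line_id=f"L{i}") for i in range(3)]
        est = group_rate_with_ci(lines, 165.0)
        assert est.ci95[0] == est.ci95[1] == est.rate_per_division

    def test_t_interval_matches_textbook_formula(self):
        """Mean and bounds agree with the closed-form Student-t interval."""
        # choose counts so per-line rates are (1, 2, 3) x 1e-11
        G, L, cell = 1e7, 1.0, 100.0
        D = divisions_from_length(L, cell)
        lines = [make_line(n, length=L, G=G, line_id=f"L{n}")
                 for n in (1, 2, 3)]
        est = group_rate_with_ci(lines, cell)
        rates = np.array([n / (G * D) for n in (1, 2, 3)])
        assert est.rate_per_division == pytest.approx(rates.mean(), rel=1e-12)
        half = sps.t.ppf(0.975, 2) * rates.std(ddof=1) / np.sqrt(3)
        assert est.ci95[0] == pytest.approx(rates.mean() - half, rel=1e-9)
        assert est.ci95[1] == pytest.approx(rates.mean() + half, rel=1e-9)

    def test_doubling_counts_doubles_estimate(self):
        lines = [make_line(n, line_id=f"L{n}") for n in (3, 6, 9)]
        doubled = [make_line(2 * n, line_id=f"L{n}") for n in (3, 6, 9)]
        e1 = group_rate_with_ci(lines, 165.0)
        e2 = group_rate_with_ci(doubled, 165.0)
        assert e2.rate_per_division == pytest.approx(2 * e1.rate_per_division)

    def test_fewer_than_two_lines_rejected(self):
        with pytest.raises(ValueError, match="two lines"):
            group_rate_with_ci([make_line(5)], 165.0)

    def test_bootstrap_ci_brackets_point(self):
        rng = np.random.default_rng(0)
        lines = [make_line(int(n), line_id=f"L{i}")
                 for i, n in enumerate(rng.poisson(9, size=12))]
        est = group_rate_with_ci(lines, 165.0, ci_method="bootstrap_bca")
        assert est.ci95[0] <= est.rate_per_division <= est.ci95[1]

    def test_t_interval_coverage_on_poisson_counts(self):
        """Nominal 95% intervals cover the generating rate ~95% of the time
        for Poisson-distributed per-line mutation counts."""
        mu, G, cell, L = 2.04e-11, 3.85e7, 165.0, 1.98
        D = divisions_from_length(L, cell)
        lam = mu * G * D
        rng = np.random.default_rng(12)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            counts = rng.poisson(lam, size=12)
            lines = [make_line(int(n), line_id=f"L{i}")
                     for i, n in enumerate(counts)]
            est = group_rate_with_ci(lines, cell)
            if est.ci95[0] <= mu <= est.ci95[1]:
                hits += 1
        assert 0.88 <= hits / n_rep <= 0.99

    def test_pooled_mode_uses_pooled_denominator(self):
        lines = [make_line(5, length=1.0, line_id="a"),
                 make_line(10, length=2.0, line_id="b")]
        est = group_rate_with_ci(lines, 100.0, pooled=True)
        G = 3.85e7
        d1 = divisions_from_length(1.0, 100.0)
        d2 = divisions_from_length(2.0, 100.0)
        assert est.rate_per_division == pytest.approx(15 / (G * (d1 + d2)))


class TestAnova:
    def _frame(self, tube_shift=0.0, noise=1.0, seed=0, n_rep=3):
        rng = np.random.default_rng(seed)
        rows = []
        for tube in ("narrow", "thick"):
            for founder in ("sh01", "sh02", "sh03", "sh04"):
                for rep in range(n_rep):
                    rate = 10 + (tube_shift if tube == "thick" else 0.0)
                    rows.append({
                        "founder": founder, "tube": tube,
                        "rate": rate + noise * rng.normal(),
                        "final_length_m": 1.0 + 0.2 * rng.random(),
                        "mean_coverage": 135.0 + rng.normal(),
                    })
        return pd.DataFrame(rows)

    def test_identical_group_means_give_null_f(self):
        # identical per-tube values with real within-group spread
        rows = []
        for tube in ("narrow", "thick"):
            for founder in ("sh01", "sh02"):
                for r, rate in enumerate((1.0, 2.0, 3.0)):
                    rows.append({"founder": founder, "tube": tube,
                                 "rate": rate})
        table, _ = anova_rates(pd.DataFrame(rows))
        assert table.loc["C(tube)", "F"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["C(tube)", "PR(>F)"] > 0.99

    def test_injected_tube_effect_detected(self):
        """A large tube effect reaches p < 0.01 in nearly all seeded runs."""
        hits = 0
        for seed in range(40):
            table, _ = anova_rates(self._frame(tube_shift=5.0, seed=seed))
            if table.loc["C(tube)", "PR(>F)"] < 0.01:
                hits += 1
        assert hits >= 38

    def test_matches_independent_least_squares_oracle(self):
        """Type-II F statistics agree with a hand-rolled projection fit."""
        frame = self._frame(tube_shift=2.0, seed=3)
        table, model = anova_rates(frame)

        y = frame["rate"].to_numpy()
        founders = sorted(frame["founder"].unique())
        x_founder = np.column_stack([
            (frame["founder"] == f).to_numpy(float) for f in founders[1:]
        ])
        x_tube = (frame["tube"] == "thick").to_numpy(float)[:, None]
        ones = np.ones((len(frame), 1))

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        full = np.hstack([ones, x_founder, x_tube])
        rss_full = rss(full)
        df_resid = len(frame) - full.shape[1]
        for term, x_drop, df_term in [
            ("C(founder)", np.hstack([ones, x_tube]), len(founders) - 1),
            ("C(tube)", np.hstack([ones, x_founder]), 1),
        ]:
            f_oracle = ((rss(x_drop) - rss_full) / df_term) / (rss_full / df_resid)
            assert table.loc[term, "F"] == pytest.approx(f_oracle, rel=1e-10)

    def test_single_level_factor_rejected(self):
        frame = self._frame()
        with pytest.raises(ValueError, match="tube"):
            anova_rates(frame[frame["tube"] == "thick"])

    def test_covariates_extend_model(self):
        frame = self._frame(tube_shift=3.0, seed=5)
        table, _ = anova_rates(frame, length_covariate=True,
                               coverage_covariate=True)
        assert "final_length_m" in table.index
        assert "mean_coverage" in table.index
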