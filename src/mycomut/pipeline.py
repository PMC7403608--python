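"""End-to-end orchestration: simulate → call → fates → rates.

Seeding: one master seed governs a whole experiment; the seed for line
*i* is ``SeedSequence((master_seed, i)).generate_state(1)[0] % 2**31``,
so individual lines can be re-simulated in isolation and partial re-runs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import CallerConfig, call_variants
from .counts import SampleCounts, write_counts_table
from .fates import (FateConfig, accumulation_curve, classify_fate,
                    trajectories_from_calls)
from .io import RunManifest, calls_to_frame, write_truth, write_vcf
from .rates import (LineRecord, RateEstimate, group_rate_with_ci,
                    anova_rates, lines_to_frame)
from .simulate import (SimulationConfig, narrow_tube_default, simulate_line,
                       thick_tube_default)

TUBE_DEFAULTS = {"thick": thick_tube_default, "narrow": narrow_tube_default}


def derive_line_seed(master_seed: int, index: int) -> int:
    """Deterministic per-line sub-seed (< 2**31) from the master seed."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class LineResult:
    config: SimulationConfig
    truth: list
    samples: list[SampleCounts]
    calls: list
    fate_calls: list
    curve: pd.DataFrame

    @property
    def n_reached_final(self) -> int:
        return int(self.curve["n_reached"].iloc[-1]) if len(self.curve) else 0

    def to_line_record(self) -> LineRecord:
        cfg = self.config
        depths = [float(s.table["depth"].mean()) for s in self.samples]
        return LineRecord(
            line_id=cfg.line_id, founder=cfg.founder, tube=cfg.tube,
            replicate=1, final_length_m=cfg.sampling_lengths_m[-1],
            n_reached=self.n_reached_final,
            callable_sites=cfg.n_callable_sites,
            mean_coverage=float(np.mean(depths)),
        )


def process_line(config: SimulationConfig,
                 caller_config: CallerConfig | None = None,
                 fate_config: FateConfig | None = None) -> LineResult:
    """Simulate one line and run it through calling and fate tracking."""
    fate_config = fate_config or FateConfig()
    truth, samples = simulate_line(config)
    founder = next(s for s in samples if s.length_m == 0.0)
    derived = [s for s in samples if s is not founder]
    _, calls = call_variants(derived, founder, caller_config)
    trajectories = trajectories_from_calls(calls, line_id=config.line_id)
    fate_calls = [classify_fate(t, fate_config) for t in trajectories]
    curve = accumulation_curve(trajectories, fate_config)
    return LineResult(config=config, truth=truth, samples=samples,
                      calls=calls, fate_calls=fate_calls, curve=curve)


def simulate_tube_lines(tube: str, n_lines: int, master_seed: int,
                        caller_config: CallerConfig | None = None,
                        fate_config: FateConfig | None = None,
                        **overrides) -> list[LineResult]:
    """Simulate and process ``n_lines`` lines of one tube type."""
    factory = TUBE_DEFAULTS[tube]
    founders = ("sh01", "sh02", "sh03", "sh04")
    results = []
    for i in range(n_lines):
        cfg = factory(
            seed=derive_line_seed(master_seed, i),
            line_id=f"{tube}{i + 1:02d}",
            founder=founders[i % len(founders)],
            **overrides,
        )
        results.append(process_line(cfg, caller_config, fate_config))
    return results


def estimate_tube_rate(tube: str, n_lines: int, master_seed: int,
                       ci_method: str = "t_interval",
                       **overrides) -> tuple[RateEstimate, list[LineResult]]:
    """Full pipeline estimate of the per-division rate for one tube type."""
    results = simulate_tube_lines(tube, n_lines, master_seed, **overrides)
    records = [r.to_line_record() for r in results]
    cell_length = results[0].config.cell_length_um
    est = group_rate_with_ci(records, cell_length, ci_method=ci_method)
    return est, results


@dataclass
class ExperimentConfig:
    """A full factorial experiment: founders × tube sizes × replicates."""

    founders: tuple[str, ...] = ("sh01", "sh02", "sh03", "sh04")
    tubes: tuple[str, ...] = ("narrow", "thick")
    n_replicates: int = 3
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # applied to every line

    def line_configs(self) -> list[SimulationConfig]:
        configs = []
        i = 0
        for tube in self.tubes:
            for founder in self.founders:
                for rep in range(1, self.n_replicates + 1):
                    configs.append(TUBE_DEFAULTS[tube](
                        seed=derive_line_seed(self.seed, i),
                        line_id=f"{tube}-{founder}-r{rep}",
                        founder=founder,
                        **self.overrides,
                    ))
                    i += 1
        return configs


def simulation_config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.pop("genome") is not None:
        raise ValueError("configs with in-memory genomes cannot be serialised")
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("sampling_lengths_m", "replicate_samples"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        return simulation_config_from_dict(yaml.safe_load(fh))


def save_simulation_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(simulation_config_to_dict(cfg), fh, sort_keys=True)


def run_pipeline(exp: ExperimentConfig, outdir,
                 caller_config: CallerConfig | None = None,
                 fate_config: FateConfig | None = None) -> RunManifest:
    """Run the whole experiment and write every artifact plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fate_config = fate_config or FateConfig()
    manifest = RunManifest(
        config={
            "founders": list(exp.founders), "tubes": list(exp.tubes),
            "n_replicates": exp.n_replicates, "overrides": exp.overrides,
        },
        seed=exp.seed,
    )

    results: list[LineResult] = []
    for cfg in exp.line_configs():
        manifest.stage_seeds[cfg.line_id] = cfg.seed
        try:
            res = process_line(cfg, caller_config, fate_config)
        except Exception as err:  # preserve partial outputs, name the stage
            manifest.config["failed_line"] = cfg.line_id
            manifest.write(outdir / "manifest.json")
            raise RuntimeError(f"pipeline failed at line {cfg.line_id}: {err}") from err
        results.append(res)
        ldir = outdir / cfg.line_id
        ldir.mkdir(exist_ok=True)
        write_counts_table(res.samples, ldir / "counts.tsv")
        write_truth(res.truth, ldir / "truth.tsv", ldir / "truth_freqs.json")
        write_vcf(res.calls, ldir / "calls.vcf",
                  contig_length=cfg.n_callable_sites)
        calls_to_frame(res.calls).to_csv(
            ldir / "calls.tsv", sep="\t", index=False, lineterminator="\n")
        res.curve.to_csv(ldir / "accumulation.tsv", sep="\t", index=False,
                         lineterminator="\n")
        pd.DataFrame([
            {"mutation_id": f.mutation_id, "fate": f.fate,
             "first_reach_index": f.first_reach_index,
             "unresolved": f.unresolved}
            for f in res.fate_calls
        ]).to_csv(ldir / "fates.tsv", sep="\t", index=False, lineterminator="\n")
        for name in ("counts.tsv", "truth.tsv", "truth_freqs.json", "calls.vcf",
                     "calls.tsv", "accumulation.tsv", "fates.tsv"):
            manifest.add_output(ldir / name)

    records = [r.to_line_record() for r in results]
    report: dict = {"tubes": {}}
    for tube in exp.tubes:
        tube_records = [r for r in records if r.tube == tube]
        if len(tube_records) >= 2:
            cell_length = next(r.config.cell_length_um for r in results
                               if r.config.tube == tube)
            est = group_rate_with_ci(tube_records, cell_length)
            report["tubes"][tube] = {
                "rate_per_division": est.rate_per_division,
                "rate_per_meter": est.rate_per_meter,
                "ci95_per_division": list(est.ci95),
                "n_lines": est.n_lines,
                "per_line_rates": list(est.per_line_rates),
            }
    if len(exp.tubes) >= 2 and len(exp.founders) >= 2:
        cell_by_tube = {
            tube: next(r.config.cell_length_um for r in results
                       if r.config.tube == tube)
            for tube in exp.tubes
        }
        frame = lines_to_frame(records, cell_by_tube)
        table, _ = anova_rates(frame)
        report["anova"] = {
            term: {"F": float(row["F"]), "p": float(row["PR(>F)"])}
            for term, row in table.iterrows() if term != "Residual"
        }
    with open(outdir / "rates.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    manifest.add_output(outdir / "rates.json")
    manifest.write(outdir / "manifest.json")
    return manifest
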