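"""De novo mutation calling from per-position allele-count tables.

The cascade mirrors pool-sequencing practice for mutation-accumulation
lines:

1. *Candidate listing* — every (position, alternative allele) supported by
   at least one read in at least one non-founder sample.
2. *Stage 1, coverage/frequency filter* — kept if, in at least one sample,
   read depth lies inside a wide coverage window and the alternative
   allele frequency exceeds 30%, **or** depth lies inside a narrower
   window and the frequency exceeds 20%.  Frequency inequalities are
   strict; the coverage windows are, by default, per-sample empirical
   depth quantiles (10–90% and 15–85%), which on realistic coverage
   distributions exclude collapsed repeats and dropouts.
3. *Stage 2, founder-absence filter* — kept only if no founder read
   (``founder_max_support = 0``) supports the allele: de novo means
   absent from the founding culture.

Frequencies of surviving variants are then assessed in every sample, with
double-sequenced sampling points averaged across their two replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import BASE_COLS, SampleCounts

FREQ_MISSING = float("nan")


@dataclass(frozen=True)
class CallerConfig:
    freq_threshold_a: float = 0.30
    cov_window_a: tuple[float, float] = (10.0, 90.0)
    freq_threshold_b: float = 0.20
    cov_window_b: tuple[float, float] = (15.0, 85.0)
    founder_max_support: int = 0
    coverage_window_mode: str = "quantile"  # or "fraction_of_mean"

    def __post_init__(self):
        for thr in (self.freq_threshold_a, self.freq_threshold_b):
            if not 0.0 < thr < 1.0:
                raise ValueError("frequency thresholds must be in (0, 1)")
        for lo, hi in (self.cov_window_a, self.cov_window_b):
            if not lo < hi:
                raise ValueError("coverage window low bound must be below high")
        if self.founder_max_support < 0:
            raise ValueError("founder_max_support must be >= 0")
        if self.coverage_window_mode not in ("quantile", "fraction_of_mean"):
            raise ValueError(f"unknown window mode {self.coverage_window_mode!r}")


@dataclass
class VariantCandidate:
    """One (position, alt allele) candidate with its per-sample evidence."""

    position: int
    ref_allele: str
    alt_allele: str
    depths: np.ndarray          # per non-founder sample, caller order
    alt_counts: np.ndarray
    founder_support: int
    pass_stage1: bool = False
    pass_stage2: bool = False

    @property
    def frequencies(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depths > 0, self.alt_counts / self.depths, np.nan)


def _check_coordinates(samples: list[SampleCounts], founder: SampleCounts):
    ref_pos = founder.positions
    for s in samples:
        pos = s.positions
        if len(pos) != len(ref_pos) or not np.array_equal(pos, ref_pos):
            # name the first discordant position
            a, b = set(ref_pos.tolist()), set(pos.tolist())
            diff = sorted(a.symmetric_difference(b))
            where = diff[0] if diff else "(ordering)"
            raise ValueError(
                f"sample {s.sample_id} coordinate mismatch with founder "
                f"at position {where}"
            )


def coverage_windows(samples: list[SampleCounts], config: CallerConfig):
    """Per-sample inclusive depth bounds for windows A and B.

    ``quantile`` mode takes empirical depth quantiles over all assayed
    positions of each sample; ``fraction_of_mean`` takes the stated
    percentages of the sample's mean depth.
    """
    windows = []
    for s in samples:
        depth = s.table["depth"].to_numpy()
        if len(depth) == 0:
            raise ValueError(f"sample {s.sample_id} has no assayed positions")
        if config.coverage_window_mode == "quantile":
            a = tuple(np.percentile(depth, config.cov_window_a))
            b = tuple(np.percentile(depth, config.cov_window_b))
        else:
            m = depth.mean()
            a = (config.cov_window_a[0] / 100.0 * m, config.cov_window_a[1] / 100.0 * m)
            b = (config.cov_window_b[0] / 100.0 * m, config.cov_window_b[1] / 100.0 * m)
        windows.append((a, b))
    return windows


def collect_candidates(samples: list[SampleCounts],
                       founder: SampleCounts) -> list[VariantCandidate]:
    """List every (position, alt allele) with read support beyond the founder.

    All samples must share the founder's coordinate system.  Multiple
    alternative alleles at one position yield separate candidates; indel
    alleles are candidates in their own right.
    """
    _check_coordinates(samples, founder)
    pos = founder.positions
    refs = founder.table["ref"].to_numpy()
    ref_idx = np.array([BASE_COLS.index(r) for r in refs])
    n_pos = len(pos)

    base_stack = np.stack([s.table[BASE_COLS].to_numpy() for s in samples])
    depth_stack = np.stack([s.table["depth"].to_numpy() for s in samples])
    founder_bases = founder.table[BASE_COLS].to_numpy()

    candidates: list[VariantCandidate] = []
    rows = np.arange(n_pos)
    any_support = base_stack.sum(axis=0)  # (n_pos, 4)
    any_support[rows, ref_idx] = 0
    cand_pos, cand_base = np.nonzero(any_support)
    for i, bi in zip(cand_pos, cand_base):
        candidates.append(VariantCandidate(
            position=int(pos[i]),
            ref_allele=str(refs[i]),
            alt_allele=BASE_COLS[bi],
            depths=depth_stack[:, i].copy(),
            alt_counts=base_stack[:, i, bi].copy(),
            founder_support=int(founder_bases[i, bi]),
        ))

    # indel candidates are sparse: walk the dict columns
    indel_alleles: dict[int, set[str]] = {}
    for s in samples:
        for row_i, d in enumerate(s.table["indels"]):
            for allele, c in d.items():
                if c > 0:
                    indel_alleles.setdefault(row_i, set()).add(allele)
    founder_indels = list(founder.table["indels"])
    sample_indels = [list(s.table["indels"]) for s in samples]
    for row_i, alleles in sorted(indel_alleles.items()):
        for allele in sorted(alleles):
            candidates.append(VariantCandidate(
                position=int(pos[row_i]),
                ref_allele=str(refs[row_i]),
                alt_allele=allele,
                depths=depth_stack[:, row_i].copy(),
                alt_counts=np.array([
                    si[row_i].get(allele, 0) for si in sample_indels
                ]),
                founder_support=int(founder_indels[row_i].get(allele, 0)),
            ))
    candidates.sort(key=lambda c: (c.position, c.alt_allele))
    return candidates


def stage1_filter(candidate: VariantCandidate, samples: list[SampleCounts],
                  config: CallerConfig, windows=None) -> bool:
    """Coverage-window / frequency filter (strict frequency inequalities)."""
    if windows is None:
        windows = coverage_windows(samples, config)
    freqs = candidate.frequencies
    for j, ((a_lo, a_hi), (b_lo, b_hi)) in enumerate(windows):
        d = candidate.depths[j]
        f = freqs[j]
        if d <= 0 or not np.isfinite(f):
            continue
        if a_lo <= d <= a_hi and f > config.freq_threshold_a:
            return True
        if b_lo <= d <= b_hi and f > config.freq_threshold_b:
            return True
    return False


def stage2_founder_filter(candidate: VariantCandidate,
                          config: CallerConfig) -> bool:
    """De novo requires (near-)absence of founder read support."""
    return candidate.founder_support <= config.founder_max_support


@dataclass
class VariantCall:
    """A variant surviving both stages, with replicate-averaged frequencies."""

    position: int
    ref_allele: str
    alt_allele: str
    sampling_lengths_m: list[float]
    frequencies: list[float]  # one per sampling point; NaN where depth 0
    founder_support: int

    @property
    def is_indel(self) -> bool:
        return self.alt_allele.startswith(("I:", "D:"))


def assess_frequencies(candidates: list[VariantCandidate],
                       samples: list[SampleCounts]) -> list[VariantCall]:
    """Per-sampling-point frequencies, averaging double-sequenced replicates.

    Sampling points are identified by ``sample_id``; a point with two
    replicates gets the arithmetic mean of the replicate frequencies
    (replicates with zero depth are dropped from the mean; a point where
    every replicate has zero depth is reported missing, never 0).
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        if s.sample_id not in groups:
            groups[s.sample_id] = []
            order.append(s.sample_id)
        groups[s.sample_id].append(j)
        if len(groups[s.sample_id]) > 2:
            raise ValueError(
                f"sampling point {s.sample_id} has more than two replicates"
            )
    lengths = {sid: samples[groups[sid][0]].length_m for sid in order}
    order.sort(key=lambda sid: lengths[sid])

    calls = []
    for c in candidates:
        freqs = c.frequencies
        point_freqs = []
        for sid in order:
            vals = [freqs[j] for j in groups[sid] if np.isfinite(freqs[j])]
            point_freqs.append(float(np.mean(vals)) if vals else FREQ_MISSING)
        calls.append(VariantCall(
            position=c.position, ref_allele=c.ref_allele,
            alt_allele=c.alt_allele,
            sampling_lengths_m=[lengths[sid] for sid in order],
            frequencies=point_freqs,
            founder_support=c.founder_support,
        ))
    return calls


def call_variants(samples: list[SampleCounts], founder: SampleCounts,
                  config: CallerConfig | None = None):
    """Run the full cascade; returns (candidates, calls).

    ``candidates`` carry their stage flags for auditing; ``calls`` are the
    stage-2 survivors with replicate-averaged per-point frequencies.
    """
    if config is None:
        config = CallerConfig()
    candidates = collect_candidates(samples, founder)
    windows = coverage_windows(samples, config)
    for c in candidates:
        c.pass_stage1 = stage1_filter(c, samples, config, windows=windows)
        c.pass_stage2 = c.pass_stage1 and stage2_founder_filter(c, config)
    survivors = [c for c in candidates if c.pass_stage2]
    calls = assess_frequencies(survivors, samples)
    return candidates, calls
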