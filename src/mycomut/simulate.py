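"""Forward simulation of mutation accumulation in a linearly growing mycelium.

The model: a haploid mycelium advances along a tube as a front of ``n_tips``
concurrently growing apical cells.  One division step extends every tip by
one cell (``cell_length_um``), so the mycelium length at division *t* is
``t × cell_length_um``.  During each division every tip gains new mutations
at rate ``mu`` per callable nucleotide, and with probability ``branch_prob``
each tip branches: the branch of one tip (chosen proportionally to fitness)
overgrows and replaces a uniformly chosen tip, keeping the number of
growing tips constant — a Moran-style update.  A mutation's true frequency
at any moment is the fraction of tips carrying it, always a multiple of
``1/n_tips``; neutral mutations therefore drift to fixation or loss at the
classic rate of ``mu × G`` fixations per division, independent of
``n_tips``.

Sites mutate at most once (infinite-sites approximation): at realistic
settings (~10 mutations over tens of megabases) double hits are
negligible.

Sequencing is emulated at the level of per-position read counts.  Read
depth at a site is Poisson around ``mean_coverage`` times a site-specific
multiplier: callable (mutation) sites are clean, while a configurable
fraction of background sites mimic collapsed repeats (inflated depth) and
low-mappability dropouts (depressed depth), reproducing the broad coverage
distribution that makes percentile-window depth filters meaningful on real
data.  Each read reports the allele of a tip lineage drawn by frequency
and is then miscalled with total probability ``seq_error``, uniformly over
the three other bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import chain
from typing import NamedTuple

import numpy as np
import pandas as pd

from .counts import SampleCounts
from .genome import BASES, DELETERIOUS_EFFECTS, GenomeModel, classify_effect

#: Approximate callable genome size (bp) of the *S. commune* reference;
#: used as the default rate denominator G.
DEFAULT_CALLABLE_SITES = 38_500_000

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
# for each base index, the three other base indices (error targets)
_OTHERS = np.array([[j for j in range(4) if j != i] for i in range(4)])


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one experimental line."""

    mu: float = 2.04e-11
    genome: GenomeModel | None = None
    callable_sites: int | None = None
    n_tips: int = 20
    branch_prob: float = 1.0
    sel_coeff_nonsyn: float = 0.0
    cell_length_um: float = 165.0
    sampling_lengths_m: tuple[float, ...] = (0.33, 0.66, 0.99, 1.32, 1.65, 1.98)
    mean_coverage: float = 135.0
    seq_error: float = 1e-3
    replicate_samples: tuple[int, ...] = (0,)
    seed: int = 0
    indel_prob: float = 0.0
    n_background_sites: int = 5000
    frac_low_coverage: float = 0.10
    frac_high_coverage: float = 0.10
    mutation_cap: float = 1000.0
    line_id: str = "line1"
    founder: str = "sh01"
    tube: str = "thick"

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if not 0.0 <= self.sel_coeff_nonsyn <= 1.0:
            raise ValueError("sel_coeff_nonsyn must be in [0, 1]")
        if self.cell_length_um <= 0:
            raise ValueError("cell_length_um must be positive")
        if self.genome is None and self.callable_sites is None:
            raise ValueError("provide a genome or a callable-site count")
        lengths = self.sampling_lengths_m
        if not lengths or any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("sampling_lengths_m must be strictly increasing")
        if lengths[0] <= 0:
            raise ValueError("sampling lengths must be positive")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if not 0.0 <= self.seq_error < 1.0:
            raise ValueError("seq_error must be in [0, 1)")
        for i in self.replicate_samples:
            if not 0 <= i < len(lengths):
                raise ValueError(f"replicate sample index {i} out of range")
        if not 0 <= self.frac_low_coverage + self.frac_high_coverage <= 1:
            raise ValueError("coverage-class fractions must sum to <= 1")
        if self.mu * self.n_callable_sites > self.mutation_cap:
            raise ValueError(
                "expected mutations per tip per division "
                f"({self.mu * self.n_callable_sites:.3g}) exceeds the cap "
                f"({self.mutation_cap:g}); refusing a pathological configuration"
            )
        self.division_steps()  # validate integerisation eagerly

    @property
    def n_callable_sites(self) -> int:
        if self.genome is not None:
            return self.genome.length
        return int(self.callable_sites)

    def division_steps(self) -> list[int]:
        """Division count at each sampling length (nearest integer)."""
        cell_m = self.cell_length_um * 1e-6
        steps = [int(round(length / cell_m)) for length in self.sampling_lengths_m]
        if steps[0] < 1 or any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError(
                "sampling lengths do not map to distinct positive division "
                f"counts at cell length {self.cell_length_um} um: {steps}"
            )
        return steps


@dataclass
class MutationEvent:
    """One true (or called) de novo mutation with its sampled trajectory."""

    id: int
    position: int
    ref_allele: str
    alt_allele: str  # single base, or "I:<seq>" / "D:<n>"
    origin_division: int
    effect: str
    true_freq_by_sample: list[float] = field(default_factory=list)

    @property
    def is_indel(self) -> bool:
        return self.alt_allele.startswith(("I:", "D:"))


class ReadDraw(NamedTuple):
    depth: int
    ref_count: int
    alt_count: int
    other_count: int


def generate_read_counts(true_freq: float, mean_coverage: float,
                         seq_error: float, seed) -> ReadDraw:
    """Draw read counts for one site.

    Depth is Poisson(``mean_coverage``); each read carries the true allele
    of a lineage drawn by frequency and is miscalled with total
    probability ``seq_error`` (to each other base with probability
    ``seq_error/3``; miscalls landing on neither ref nor alt are reported
    as ``other_count``).
    """
    if not 0.0 <= true_freq <= 1.0:
        raise ValueError("true_freq must be in [0, 1]")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0.0 <= seq_error < 1.0:
        raise ValueError("seq_error must be in [0, 1)")
    rng = np.random.default_rng(seed)
    table = _sample_table(
        rng,
        pos=np.array([0]),
        ref_idx=np.array([0]),
        alt_alleles=["C"],
        alt_idx=np.array([1]),
        is_indel=np.array([False]),
        freq=np.array([true_freq]),
        lam=np.array([mean_coverage]),
        seq_error=seq_error,
    )
    row = table.iloc[0]
    return ReadDraw(
        depth=int(row["depth"]),
        ref_count=int(row["A"]),
        alt_count=int(row["C"]),
        other_count=int(row["G"] + row["T"]),
    )


def _spread_errors(counts, rows, k, targets, rng):
    """Distribute k[i] miscalled reads uniformly over targets[i] (3 bases)."""
    k1 = rng.binomial(k, 1.0 / 3.0)
    k2 = rng.binomial(k - k1, 0.5)
    k3 = k - k1 - k2
    counts[rows, targets[:, 0]] += k1
    counts[rows, targets[:, 1]] += k2
    counts[rows, targets[:, 2]] += k3


def _simulate_demography(cfg: SimulationConfig, rng: np.random.Generator):
    """Run the Moran tip dynamics; return (mutations, freq-by-sample rows).

    ``mutations`` is a list of dicts (position, ref, alt, effect,
    origin_division, fitness); frequencies are fractions of tips at each
    sampling division.
    """
    n = cfg.n_tips
    steps = cfg.division_steps()
    D = steps[-1]
    G = cfg.n_callable_sites
    sample_at = {step: i for i, step in enumerate(steps)}

    m_counts = rng.poisson(cfg.mu * G * n, size=D).tolist()
    if cfg.branch_prob == 1.0:
        k_counts = None  # constant n events per step
        total_events = D * n
    else:
        k_arr = rng.binomial(n, cfg.branch_prob, size=D)
        total_events = int(k_arr.sum())
        k_counts = k_arr.tolist()
    parents = rng.integers(0, n, size=total_events).tolist()
    victims = rng.integers(0, n, size=total_events).tolist()

    genome = cfg.genome
    seq = genome.sequence if genome is not None else None
    used_positions: set[int] = set()
    mutations: list[dict] = []
    s = cfg.sel_coeff_nonsyn

    def new_mutation(t: int) -> tuple[int, float]:
        while True:
            pos = int(rng.integers(G))
            if pos not in used_positions:
                break
        used_positions.add(pos)
        ref = seq[pos] if seq is not None else BASES[int(rng.integers(4))]
        if rng.random() < cfg.indel_prob:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                ins = "".join(BASES[int(b)] for b in rng.integers(0, 4, size=length))
                alt = f"I:{ins}"
            else:
                alt = f"D:{length}"
        else:
            alt = BASES[int(rng.integers(4))]
            while alt == ref:
                alt = BASES[int(rng.integers(4))]
        if genome is not None and seq is not None:
            effect = classify_effect(pos, ref, alt, genome)
        else:
            effect = "other_noncoding"
        fitness = (1.0 - s) if (s > 0 and effect in DELETERIOUS_EFFECTS) else 1.0
        mid = len(mutations)
        mutations.append({
            "id": mid, "position": pos, "ref": ref, "alt": alt,
            "effect": effect, "origin_division": t, "fitness": fitness,
        })
        return mid, fitness

    tips: list[tuple[int, ...]] = [()] * n
    tip_fitness = [1.0] * n
    homogeneous = True
    freq_rows: list[dict[int, float]] = []

    cursor = 0
    for t in range(D):
        m = m_counts[t]
        if m:
            for _ in range(m):
                u = int(rng.integers(n))
                mid, fit = new_mutation(t)
                tips[u] = tips[u] + (mid,)
                if fit < 1.0:
                    tip_fitness[u] *= fit
                    homogeneous = False
        k = n if k_counts is None else k_counts[t]
        if homogeneous:
            end = cursor + k
            while cursor < end:
                tips[victims[cursor]] = tips[parents[cursor]]
                cursor += 1
        else:
            for _ in range(k):
                r = rng.random() * sum(tip_fitness)
                acc = 0.0
                p = n - 1
                for j, w in enumerate(tip_fitness):
                    acc += w
                    if r < acc:
                        p = j
                        break
                v = victims[cursor]
                cursor += 1
                tips[v] = tips[p]
                tip_fitness[v] = tip_fitness[p]
        si = sample_at.get(t + 1)
        if si is not None:
            tally = Counter(chain.from_iterable(tips))
            freq_rows.append({mid: c / n for mid, c in tally.items()})

    return mutations, freq_rows


def simulate_truth(config: SimulationConfig, rng=None):
    """Simulate tip dynamics only; return the truth list of MutationEvents.

    Only mutations segregating or fixed at at least one sampling point are
    reported, each with its true frequency at every sampling point.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    mutations, freq_rows = _simulate_demography(config, rng)
    truth = []
    for m in mutations:
        freqs = [row.get(m["id"], 0.0) for row in freq_rows]
        if any(f > 0 for f in freqs):
            truth.append(MutationEvent(
                id=len(truth), position=m["position"], ref_allele=m["ref"],
                alt_allele=m["alt"], origin_division=m["origin_division"],
                effect=m["effect"], true_freq_by_sample=freqs,
            ))
    return truth


def _background_positions(cfg: SimulationConfig, used: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    G = cfg.n_callable_sites
    want = cfg.n_background_sites
    taken = set(int(p) for p in used)
    out: list[int] = []
    while len(out) < want:
        draw = rng.integers(0, G, size=want - len(out) + 16)
        for p in np.unique(draw):
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == want:
                    break
    return np.array(sorted(out[:want]), dtype=np.int64)


def _sample_table(rng, pos, ref_idx, alt_alleles, alt_idx, is_indel, freq,
                  lam, seq_error) -> pd.DataFrame:
    n = len(pos)
    rows = np.arange(n)
    depth = rng.poisson(lam)
    alt_true = rng.binomial(depth, freq)
    ref_true = depth - alt_true

    counts = np.zeros((n, 4), dtype=np.int64)
    err_ref = rng.binomial(ref_true, seq_error)
    counts[rows, ref_idx] += ref_true - err_ref
    _spread_errors(counts, rows, err_ref, _OTHERS[ref_idx], rng)

    snv = ~is_indel
    if snv.any():
        err_alt = rng.binomial(alt_true[snv], seq_error)
        counts[rows[snv], alt_idx[snv]] += alt_true[snv] - err_alt
        _spread_errors(counts, rows[snv], err_alt, _OTHERS[alt_idx[snv]], rng)

    indels = [{} for _ in range(n)]
    for i in np.flatnonzero(is_indel):
        if alt_true[i] > 0:
            indels[i] = {alt_alleles[i]: int(alt_true[i])}
    # depth of an indel row = its base counts + its indel-supporting reads
    table = pd.DataFrame({
        "pos0": pos,
        "ref": [BASES[i] for i in ref_idx],
        "depth": counts.sum(axis=1) + np.where(is_indel, alt_true, 0),
        "A": counts[:, 0], "C": counts[:, 1],
        "G": counts[:, 2], "T": counts[:, 3],
        "indels": indels,
    })
    return table


def simulate_line(config: SimulationConfig):
    """Simulate one experimental line end to end.

    Returns ``(truth, samples)``: the list of true
    :class:`MutationEvent` s, and the sequenced :class:`SampleCounts`
    — the founder sample first (length 0), then one or two replicates per
    sampling point.  Sub-streams for demography, background-site layout,
    and each sequencing library are derived deterministically from
    ``config.seed`` via ``numpy.random.SeedSequence`` spawning, so any
    stage can be reproduced in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    demo_ss, layout_ss, reads_ss = ss.spawn(3)
    truth = simulate_truth(config, np.random.default_rng(demo_ss))

    layout_rng = np.random.default_rng(layout_ss)
    mut_pos = np.array([m.position for m in truth], dtype=np.int64)
    bg_pos = _background_positions(config, mut_pos, layout_rng)

    seq = config.genome.sequence if config.genome is not None else None
    if seq is not None:
        bg_ref = np.array([_BASE_IDX[seq[p]] for p in bg_pos], dtype=np.int64)
    else:
        bg_ref = layout_rng.integers(0, 4, size=len(bg_pos))

    # coverage class multipliers: background sites may be repeat-like or
    # dropout-like; callable mutation sites are clean by construction
    nb = len(bg_pos)
    mult_bg = np.ones(nb)
    classes = layout_rng.random(nb)
    low = classes < config.frac_low_coverage
    high = classes >= 1.0 - config.frac_high_coverage
    mult_bg[low] = layout_rng.uniform(0.05, 0.4, size=int(low.sum()))
    mult_bg[high] = layout_rng.uniform(1.8, 3.0, size=int(high.sum()))

    pos = np.concatenate([mut_pos, bg_pos])
    ref_idx = np.concatenate([
        np.array([_BASE_IDX[m.ref_allele] for m in truth], dtype=np.int64),
        bg_ref,
    ])
    alt_alleles = [m.alt_allele for m in truth] + [""] * nb
    is_indel = np.array([m.is_indel for m in truth] + [False] * nb)
    alt_idx = np.array(
        [(_BASE_IDX[m.alt_allele] if not m.is_indel else 0) for m in truth]
        + [0] * nb, dtype=np.int64,
    )
    lam = config.mean_coverage * np.concatenate([np.ones(len(truth)), mult_bg])

    order = np.argsort(pos, kind="mergesort")
    pos_o = pos[order]
    ref_o = ref_idx[order]
    alt_al_o = [alt_alleles[i] for i in order]
    indel_o = is_indel[order]
    alt_o = alt_idx[order]
    lam_o = lam[order]

    n_points = len(config.sampling_lengths_m)
    reads_children = reads_ss.spawn(1 + n_points * 2)

    def make_sample(freq_vec, sample_id, replicate_id, length_m, child):
        rng = np.random.default_rng(child)
        table = _sample_table(rng, pos_o, ref_o, alt_al_o, alt_o, indel_o,
                              freq_vec[order], lam_o, config.seq_error)
        return SampleCounts(
            sample_id=sample_id, line_id=config.line_id,
            replicate_id=replicate_id, length_m=length_m, table=table,
        )

    zero_freq = np.zeros(len(pos))
    samples = [make_sample(zero_freq, f"{config.line_id}-founder", 1, 0.0,
                           reads_children[0])]
    for i in range(n_points):
        freq_vec = np.concatenate([
            np.array([m.true_freq_by_sample[i] for m in truth]),
            np.zeros(nb),
        ]) if truth else zero_freq
        sid = f"{config.line_id}-s{i + 1:02d}"
        n_reps = 2 if i in config.replicate_samples else 1
        for r in range(1, n_reps + 1):
            samples.append(make_sample(
                freq_vec, sid, r, config.sampling_lengths_m[i],
                reads_children[1 + 2 * i + (r - 1)],
            ))
    return truth, samples


def thick_tube_default(seed: int = 0, line_id: str = "thick1",
                       founder: str = "sh01", **overrides) -> SimulationConfig:
    """Default thick-tube line: many competing tips, ~12,000 divisions."""
    base = dict(
        mu=2.04e-11, callable_sites=DEFAULT_CALLABLE_SITES, n_tips=20,
        cell_length_um=165.0,
        sampling_lengths_m=(0.33, 0.66, 0.99, 1.32, 1.65, 1.98),
        mean_coverage=135.0, seq_error=1e-3, replicate_samples=(0,),
        seed=seed, line_id=line_id, founder=founder, tube="thick",
    )
    base.update(overrides)
    return SimulationConfig(**base)


def narrow_tube_default(seed: int = 0, line_id: str = "narrow1",
                        founder: str = "sh01", **overrides) -> SimulationConfig:
    """Default narrow-tube line: few competing tips, ~4,800 divisions."""
    base = dict(
        mu=4.99e-11, callable_sites=DEFAULT_CALLABLE_SITES, n_tips=4,
        cell_length_um=163.0,
        sampling_lengths_m=(0.156, 0.312, 0.468, 0.624, 0.78),
        mean_coverage=135.0, seq_error=1e-3, replicate_samples=(0,),
        seed=seed, line_id=line_id, founder=founder, tube="narrow",
    )
    base.update(overrides)
    return SimulationConfig(**base)
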