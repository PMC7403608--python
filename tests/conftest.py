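import pandas as pd
import pytest

from mycomut.counts import SampleCounts
from mycomut.genome import Gene, GenomeModel, random_genome
from mycomut.simulate import SimulationConfig


@pytest.fixture(scope="session")
def tiny_genome():
    """Handcrafted genome: one + strand gene ATG TGG GCT AAA TAA at [4, 19)."""
    cds_seq = "ATGTGGGCTAAATAA"
    seq = "AAAA" + cds_seq + "CCTTTTTGGA"
    gene = Gene(name="g1", strand="+", cds=((4, 19),))
    return GenomeModel(length=len(seq), genes=(gene,),
                       intron_intervals=((21, 25),), sequence=seq, name="tiny")


@pytest.fixture(scope="session")
def annotated_genome():
    """Random multi-gene genome with sequence, introns, both strands."""
    return random_genome(length=30_000, n_genes=10, codons_per_gene=200,
                         intron_prob=0.5, seed=11)


def small_config(**overrides) -> SimulationConfig:
    """Fast line configuration: ~200 divisions, small genome."""
    base = dict(
        mu=2e-6, callable_sites=10_000, n_tips=5, branch_prob=1.0,
        cell_length_um=100.0, sampling_lengths_m=(0.005, 0.01, 0.02),
        mean_coverage=135.0, seq_error=1e-3, replicate_samples=(0,),
        n_background_sites=400, seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def make_config():
    return small_config


def manual_sample(depths, alt_counts, ref="A", alt="C", sample_id="s1",
                  line_id="L", replicate_id=1, length_m=0.1,
                  extra_depths=None) -> SampleCounts:
    """Build a sample whose first positions carry the given depth/alt pairs,
    padded with ref-only positions at the depths in ``extra_depths`` (used
    to pin down the empirical coverage quantiles)."""
    rows = []
    pos = 0
    for d, a in zip(depths, alt_counts):
        counts = {b: 0 for b in "ACGT"}
        counts[ref] = d - a
        counts[alt] = a
        rows.append({"pos0": pos, "ref": ref, "depth": d, **counts, "indels": {}})
        pos += 1
    for d in (extra_depths if extra_depths is not None else []):
        counts = {b: 0 for b in "ACGT"}
        counts[ref] = d
        rows.append({"pos0": pos, "ref": ref, "depth": d, **counts, "indels": {}})
        pos += 1
    cols = ["pos0", "ref", "depth", "A", "C", "G", "T", "indels"]
    return SampleCounts(sample_id=sample_id, line_id=line_id,
                        replicate_id=replicate_id, length_m=length_m,
                        table=pd.DataFrame(rows, columns=cols))
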