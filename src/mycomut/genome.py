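"""Genome models and mutation effect classification.

A :class:`GenomeModel` is the minimal annotation needed downstream: genome
length, CDS intervals grouped into genes (0-based, half-open), intron
intervals, and optionally the nucleotide sequence itself.  When only a
callable-site count is known (the usual case for rate estimation at full
genome scale) the model can be built without sequence; effect
classification then degrades to ``other_noncoding``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

BASES = "ACGT"

#: Effect categories for de novo mutations.
EFFECTS = (
    "nonsense",
    "nonsynonymous",
    "synonymous",
    "frameshift",
    "intronic",
    "other_noncoding",
)

#: Effect classes treated as deleterious by the selection model.
DELETERIOUS_EFFECTS = frozenset({"nonsense", "nonsynonymous", "frameshift"})

_STOPS = frozenset(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)


def translate_codon(codon: str) -> str:
    """Return the amino acid for ``codon``, '*' for a stop codon."""
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    return _CODON_AA[codon]


@dataclass(frozen=True)
class Gene:
    """One protein-coding gene: ordered CDS intervals on one strand."""

    name: str
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        total = sum(e - s for s, e in self.cds)
        if total % 3 != 0:
            raise ValueError(f"gene {self.name}: CDS length {total} not divisible by 3")
        for (s, e) in self.cds:
            if e <= s:
                raise ValueError(f"gene {self.name}: empty CDS interval ({s}, {e})")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GenomeModel:
    """Genome length, gene models, and (optionally) the sequence.

    Coordinates are 0-based half-open throughout; conversion to 1-based
    inclusive happens only at GFF3/VCF emission.
    """

    length: int
    genes: tuple[Gene, ...] = ()
    intron_intervals: tuple[tuple[int, int], ...] = ()
    sequence: str | None = None
    name: str = "genome"
    _cds_lookup: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match genome length")
        prev_end = -1
        for s, e in sorted(iv for g in self.genes for iv in g.cds):
            if s < 0 or e > self.length:
                raise ValueError(f"CDS interval ({s}, {e}) outside genome")
            if s < prev_end:
                raise ValueError(f"overlapping CDS intervals at {s}")
            prev_end = e
        for s, e in self.intron_intervals:
            if s < 0 or e > self.length or e <= s:
                raise ValueError(f"bad intron interval ({s}, {e})")
        self._cds_lookup = sorted(
            (s, e, gene) for gene in self.genes for (s, e) in gene.cds
        )

    @property
    def cds_intervals(self) -> list[tuple[int, int, str]]:
        """Flat sorted list of (start, end, strand)."""
        return [(s, e, g.strand) for s, e, g in self._cds_lookup]

    def gene_at(self, position: int) -> Gene | None:
        for s, e, gene in self._cds_lookup:
            if s <= position < e:
                return gene
            if s > position:
                break
        return None

    def in_intron(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.intron_intervals)

    def coding_offset(self, gene: Gene, position: int) -> int:
        """0-based position within the spliced CDS, in translation order."""
        off = 0
        for s, e in gene.cds:
            if s <= position < e:
                off += position - s
                break
            off += e - s
        else:
            raise ValueError(f"position {position} not in CDS of {gene.name}")
        if gene.strand == "-":
            off = gene.cds_length - 1 - off
        return off

    def spliced_cds(self, gene: Gene) -> str:
        """CDS sequence in translation order (reverse-complemented for '-')."""
        if self.sequence is None:
            raise ValueError("genome has no sequence")
        seq = "".join(self.sequence[s:e] for s, e in gene.cds)
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def classify_effect(position: int, ref_allele: str, alt_allele: str,
                    genome: GenomeModel) -> str:
    """Classify a variant's coding effect.

    ``alt_allele`` is a single base for substitutions, or an indel
    descriptor ``"I:<seq>"`` (insertion after ``position``) /
    ``"D:<n>"`` (deletion of *n* bases starting at ``position``).

    Substitutions inside a CDS are translated with and without the change
    under the standard nuclear code; indels inside a CDS whose length is
    not a multiple of 3 shift the reading frame; in-frame coding indels
    are reported as nonsynonymous.  Positions in annotated introns are
    intronic; everything else is other noncoding.
    """
    if not 0 <= position < genome.length:
        raise ValueError(f"position {position} outside genome [0, {genome.length})")

    is_indel = alt_allele.startswith(("I:", "D:"))
    gene = genome.gene_at(position)

    if gene is None:
        return "intronic" if genome.in_intron(position) else "other_noncoding"

    if is_indel:
        if alt_allele.startswith("I:"):
            indel_len = len(alt_allele[2:])
        else:
            indel_len = int(alt_allele[2:])
        return "frameshift" if indel_len % 3 != 0 else "nonsynonymous"

    if genome.sequence is not None and genome.sequence[position] != ref_allele:
        raise ValueError(
            f"ref allele mismatch at position {position}: "
            f"genome has {genome.sequence[position]!r}, got {ref_allele!r}"
        )
    if genome.sequence is None:
        # Without sequence context a coding substitution cannot be resolved
        # to a codon change; the caller should not rely on CDS effects here.
        return "other_noncoding"

    off = genome.coding_offset(gene, position)
    cds = genome.spliced_cds(gene)
    codon_i = off // 3
    codon_pos = off % 3
    codon = cds[codon_i * 3:codon_i * 3 + 3]

    base = alt_allele
    if gene.strand == "-":
        base = str(Seq(base).complement())
    new_codon = codon[:codon_pos] + base + codon[codon_pos + 1:]

    aa_old, aa_new = translate_codon(codon), translate_codon(new_codon)
    if aa_new == "*" and aa_old != "*":
        return "nonsense"
    if aa_new == aa_old:
        return "synonymous"
    return "nonsynonymous"


def random_genome(length: int = 30_000, n_genes: int = 10,
                  codons_per_gene: int = 200, intron_prob: float = 0.5,
                  intron_len: int = 60, seed: int = 0,
                  name: str = "synthetic") -> GenomeModel:
    """Generate a random annotated genome with sequence.

    Genes are placed non-overlapping on alternating strands; each CDS is a
    start codon, random sense codons, and a stop codon, optionally split
    by one intron.  Intended for tests and for small-genome simulations
    where coding effects matter.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(BASES), size=length))

    sense_codons = [c for c in _CODON_AA]
    genes, introns = [], []
    gene_span = codons_per_gene * 3 + intron_len + 40
    n_fit = max(0, (length - 100) // gene_span)
    n_genes = min(n_genes, n_fit)
    cursor = 50
    for gi in range(n_genes):
        cds_seq = "ATG" + "".join(rng.choice(sense_codons, size=codons_per_gene - 2)) + "TAA"
        strand = "+" if gi % 2 == 0 else "-"
        if strand == "-":
            genomic = str(Seq(cds_seq).reverse_complement())
        else:
            genomic = cds_seq
        if rng.random() < intron_prob:
            # split the genomic CDS span with one intron near its middle
            split = (len(genomic) // 2 // 3) * 3 + 1  # not on codon boundary
            s1 = (cursor, cursor + split)
            intron = (s1[1], s1[1] + intron_len)
            s2 = (intron[1], intron[1] + len(genomic) - split)
            seq[s1[0]:s1[1]] = list(genomic[:split])
            seq[s2[0]:s2[1]] = list(genomic[split:])
            seq[intron[0]:intron[1]] = list(rng.choice(list(BASES), size=intron_len))
            cds = (s1, s2)
            introns.append(intron)
            end = s2[1]
        else:
            cds = ((cursor, cursor + len(genomic)),)
            seq[cursor:cursor + len(genomic)] = list(genomic)
            end = cursor + len(genomic)
        genes.append(Gene(name=f"{name}_g{gi + 1}", strand=strand, cds=cds))
        cursor = end + 40

    return GenomeModel(
        length=length,
        genes=tuple(genes),
        intron_intervals=tuple(introns),
        sequence="".join(seq),
        name=name,
    )
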