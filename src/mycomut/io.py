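"""External formats: FASTA, GFF3, VCF 4.2, truth tables, run manifests.

Internal coordinates are 0-based half-open everywhere; each writer
converts to the target convention (1-based inclusive for GFF3 and VCF)
exactly once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Gene, GenomeModel


def write_fasta(genome: GenomeModel, path) -> None:
    if genome.sequence is None:
        raise ValueError("genome has no sequence to write")
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> tuple[str, str]:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def write_gff3(genome: GenomeModel, path) -> None:
    """Emit gene/CDS/intron features, 1-based inclusive coordinates."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for gene in genome.genes:
            start = min(s for s, _ in gene.cds) + 1
            end = max(e for _, e in gene.cds)
            fh.write("\t".join([
                genome.name, "mycomut", "gene", str(start), str(end), ".",
                gene.strand, ".", f"ID={gene.name}",
            ]) + "\n")
            for i, (s, e) in enumerate(gene.cds):
                fh.write("\t".join([
                    genome.name, "mycomut", "CDS", str(s + 1), str(e), ".",
                    gene.strand, "0" if i == 0 else ".",
                    f"ID={gene.name}.cds{i + 1};Parent={gene.name}",
                ]) + "\n")
        for i, (s, e) in enumerate(genome.intron_intervals):
            fh.write("\t".join([
                genome.name, "mycomut", "intron", str(s + 1), str(e), ".",
                ".", ".", f"ID=intron{i + 1}",
            ]) + "\n")


def read_genome(fasta_path, gff3_path) -> GenomeModel:
    """Rebuild a GenomeModel from the FASTA + GFF3 pair written above."""
    name, seq = read_fasta(fasta_path)
    genes: dict[str, dict] = {}
    introns = []
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            ftype, start, end, strand, attrs = f[2], int(f[3]), int(f[4]), f[6], f[8]
            if ftype == "CDS":
                parent = dict(kv.split("=") for kv in attrs.split(";"))["Parent"]
                g = genes.setdefault(parent, {"strand": strand, "cds": []})
                g["cds"].append((start - 1, end))
            elif ftype == "intron":
                introns.append((start - 1, end))
    gene_objs = tuple(
        Gene(name=n, strand=g["strand"], cds=tuple(sorted(g["cds"])))
        for n, g in genes.items()
    )
    return GenomeModel(length=len(seq), genes=gene_objs,
                       intron_intervals=tuple(introns), sequence=seq, name=name)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mycomut
##contig=<ID={contig},length={length}>
##INFO=<ID=FS,Number=1,Type=Integer,Description="Founder read support">
##INFO=<ID=SF,Number=.,Type=String,Description="Replicate-averaged alt frequency per sampling point (missing as .)">
##INFO=<ID=LM,Number=.,Type=Float,Description="Mycelium length (m) at each sampling point">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _vcf_alleles(call, genome: GenomeModel | None, contig_length: int):
    pos0 = call.position
    ref = call.ref_allele
    alt = call.alt_allele
    if genome is not None and genome.sequence is not None:
        if genome.sequence[pos0] != ref:
            raise ValueError(
                f"ref allele {ref!r} inconsistent with genome at position {pos0}"
            )
    if not alt.startswith(("I:", "D:")):
        return pos0 + 1, ref, alt
    if alt.startswith("I:"):
        return pos0 + 1, ref, ref + alt[2:]
    n_del = int(alt[2:])
    if pos0 + 1 + n_del > contig_length:
        raise ValueError(f"deletion at {pos0} extends past contig end")
    if genome is not None and genome.sequence is not None:
        deleted = genome.sequence[pos0 + 1:pos0 + 1 + n_del]
    else:
        deleted = "N" * n_del
    return pos0 + 1, ref + deleted, ref


def write_vcf(calls, path, genome: GenomeModel | None = None,
              contig: str = "genome", contig_length: int | None = None) -> None:
    """Write stage-2 calls as VCF 4.2 (positions 1-based, indels anchored)."""
    if genome is not None:
        contig = genome.name
        contig_length = genome.length
    if contig_length is None:
        contig_length = (max((c.position for c in calls), default=0) + 2)
    with open(path, "w", newline="\n") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=contig_length))
        for call in sorted(calls, key=lambda c: (c.position, c.alt_allele)):
            pos1, ref, alt = _vcf_alleles(call, genome, contig_length)
            sf = ",".join(
                "." if f != f else f"{f:.6g}" for f in call.frequencies
            )
            lm = ",".join(f"{x:g}" for x in call.sampling_lengths_m)
            info = f"FS={call.founder_support};SF={sf};LM={lm}"
            fh.write("\t".join([
                contig, str(pos1), ".", ref, alt, ".", "PASS", info,
            ]) + "\n")


def calls_to_frame(calls) -> pd.DataFrame:
    """TSV mirror of the VCF: one row per call, one column per point."""
    rows = []
    for c in calls:
        row = {
            "pos0": c.position, "ref": c.ref_allele, "alt": c.alt_allele,
            "founder_support": c.founder_support,
        }
        for length, f in zip(c.sampling_lengths_m, c.frequencies):
            row[f"freq@{length:g}m"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def write_truth(truth, tsv_path, json_path) -> None:
    """True mutations as a VCF-like TSV plus a JSON frequency sidecar."""
    rows = [{
        "id": m.id, "pos0": m.position, "ref": m.ref_allele,
        "alt": m.alt_allele, "origin_division": m.origin_division,
        "effect": m.effect,
    } for m in truth]
    pd.DataFrame(
        rows, columns=["id", "pos0", "ref", "alt", "origin_division", "effect"]
    ).to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    with open(json_path, "w") as fh:
        json.dump({str(m.id): m.true_freq_by_sample for m in truth}, fh, indent=1)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config, seeds, and output file hashes."""

    config: dict
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = "1"

    def add_output(self, path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
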