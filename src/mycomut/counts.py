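"""Per-sample, per-position allele count tables.

This is the pipeline's central exchange format: one record per assayed
genome position holding read depth and counts for the four bases plus any
indel alleles.  Tables are stored as TSV (tab separated, LF newlines, '.'
for an empty indel field) with columns::

    sample_id  line_id  replicate_id  length_m  pos0  ref  depth  A  C  G  T  indel_json

``pos0`` is the 0-based position; ``indel_json`` is a JSON object mapping
indel descriptors (``"I:<seq>"`` or ``"D:<n>"``) to read counts.  The
conservation invariant — base counts plus indel counts sum to depth —
is validated on construction and on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

TSV_COLUMNS = [
    "sample_id", "line_id", "replicate_id", "length_m",
    "pos0", "ref", "depth", "A", "C", "G", "T", "indel_json",
]

BASE_COLS = ["A", "C", "G", "T"]


@dataclass
class SampleCounts:
    """Allele counts for one sequenced sample (one time point, one replicate).

    ``table`` has columns pos0, ref, depth, A, C, G, T, indels (dict), sorted
    by pos0 and unique in pos0.
    """

    sample_id: str
    line_id: str
    replicate_id: int
    length_m: float
    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in ("pos0", "ref", "depth", *BASE_COLS) if c not in t.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        if "indels" not in t.columns:
            t = t.assign(indels=[{} for _ in range(len(t))])
        t = t.sort_values("pos0", kind="mergesort").reset_index(drop=True)
        if t["pos0"].duplicated().any():
            dup = int(t.loc[t["pos0"].duplicated(), "pos0"].iloc[0])
            raise ValueError(f"duplicate position {dup} in sample {self.sample_id}")
        base_sum = t[BASE_COLS].to_numpy().sum(axis=1)
        indel_sum = np.array([sum(d.values()) for d in t["indels"]])
        bad = np.flatnonzero(base_sum + indel_sum != t["depth"].to_numpy())
        if bad.size:
            pos = int(t["pos0"].iloc[bad[0]])
            raise ValueError(
                f"allele counts do not sum to depth at position {pos} "
                f"in sample {self.sample_id}"
            )
        if (t[BASE_COLS].to_numpy() < 0).any() or (t["depth"].to_numpy() < 0).any():
            raise ValueError(f"negative counts in sample {self.sample_id}")
        self.table = t

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos0"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def to_long_frame(samples: list[SampleCounts]) -> pd.DataFrame:
    """Concatenate samples into the long TSV layout."""
    frames = []
    for s in samples:
        f = s.table.copy()
        f.insert(0, "sample_id", s.sample_id)
        f.insert(1, "line_id", s.line_id)
        f.insert(2, "replicate_id", s.replicate_id)
        f.insert(3, "length_m", s.length_m)
        f["indel_json"] = [
            json.dumps(d, sort_keys=True) if d else "." for d in f.pop("indels")
        ]
        frames.append(f[TSV_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def write_counts_table(samples: list[SampleCounts], path) -> None:
    to_long_frame(samples).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_counts_table(path) -> list[SampleCounts]:
    """Read a counts TSV back into per-sample records.

    Schema violations raise ``ValueError`` naming the offending TSV line
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "line_id": str, "ref": str,
                               "indel_json": str},
        keep_default_na=False, na_values=[],
    )
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    def _int_col(col):
        try:
            return df[col].astype(np.int64)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = int(coerced.isna().idxmax())
            raise ValueError(
                f"{path}: malformed {col!r} field at line {bad + 2}"
            ) from None

    for col in ("replicate_id", "pos0", "depth", *BASE_COLS):
        df[col] = _int_col(col)
    df["length_m"] = pd.to_numeric(df["length_m"])

    def _parse_indels(s, lineno):
        if s == "." or s == "":
            return {}
        try:
            d = json.loads(s)
        except json.JSONDecodeError:
            raise ValueError(f"{path}: malformed indel_json at line {lineno}") from None
        return {str(k): int(v) for k, v in d.items()}

    df["indels"] = [
        _parse_indels(s, i + 2) for i, s in enumerate(df["indel_json"])
    ]

    key_cols = ["sample_id", "line_id", "replicate_id", "length_m"]
    dup = df.duplicated(subset=["sample_id", "replicate_id", "pos0"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (sample, replicate, position) row at line "
            f"{int(dup.idxmax()) + 2}"
        )
    samples = []
    for (sid, lid, rid, lm), grp in df.groupby(key_cols, sort=False):
        table = grp[["pos0", "ref", "depth", *BASE_COLS, "indels"]].reset_index(drop=True)
        samples.append(SampleCounts(
            sample_id=sid, line_id=lid, replicate_id=int(rid),
            length_m=float(lm), table=table,
        ))
    return samples


def _parse_pileup_bases(bases: str, ref: str) -> tuple[dict, dict]:
    """Tokenise one mpileup read-base column into base and indel counts."""
    base_counts = {b: 0 for b in BASE_COLS}
    indels: dict[str, int] = {}
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":            # read start: skip mapping-quality char
            i += 2
            continue
        if c == "$":            # read end marker
            i += 1
            continue
        if c in "+-":           # indel attached to the preceding base
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            length = int(bases[i + 1:j])
            seq = bases[j:j + length].upper()
            key = f"I:{seq}" if c == "+" else f"D:{length}"
            indels[key] = indels.get(key, 0) + 1
            i = j + length
            continue
        if c in ".,":
            base_counts[ref.upper()] += 1
        elif c.upper() in base_counts:
            base_counts[c.upper()] += 1
        # '*' (deleted base placeholder) and anything else add no allele
        i += 1
    return base_counts, indels


def pileup_to_sample_counts(path, sample_id: str, line_id: str,
                            replicate_id: int = 1,
                            length_m: float = 0.0) -> SampleCounts:
    """Adapt ``samtools mpileup`` text output to the counts schema.

    Indel-supporting reads are counted as indel alleles in addition to
    the base they report, so depth is recomputed as the allele-count sum
    rather than taken from the pileup depth column (which also counts
    deletion placeholders).  Upstream read filters (mapping quality,
    proper pairs, deduplication) are the caller's responsibility.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}: malformed pileup line {lineno}")
            pos1, ref, bases = int(f[1]), f[2].upper(), f[4]
            if ref not in BASE_COLS:
                continue  # skip N/ambiguous reference positions
            base_counts, indels = _parse_pileup_bases(bases, ref)
            depth = sum(base_counts.values()) + sum(indels.values())
            rows.append({
                "pos0": pos1 - 1, "ref": ref, "depth": depth,
                **base_counts, "indels": indels,
            })
    table = pd.DataFrame(rows, columns=["pos0", "ref", "depth", *BASE_COLS,
                                        "indels"])
    return SampleCounts(sample_id=sample_id, line_id=line_id,
                        replicate_id=replicate_id, length_m=length_m,
                        table=table)
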