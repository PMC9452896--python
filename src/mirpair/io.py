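"""Readers and writers for the formats the pipeline touches.

Covers miRBase-style GFF3 mature-miR annotations, SAM alignments with
UMI-bearing read names, TSV count matrices and sample sheets, GMT-like
pathway→miR set files, and TSV results tables.

Coordinates are 1-based inclusive throughout (the native GFF3/SAM
convention); any half-open arithmetic is internal to a function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

__all__ = [
    "MatureMirRecord",
    "AlignedRead",
    "MirCountMatrix",
    "read_mirbase_gff",
    "read_alignments",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "read_gmt",
    "write_results_table",
]

COMPARTMENTS = ("MB", "EV")
TREATMENTS = ("CTL", "CLFS", "IHFS")

#: mature positions 2–8 from the 5' end — the canonical seed definition
SEED_OFFSET_START = 1
SEED_OFFSET_END = 7

#: default UMI convention: last "_"-delimited token of the read name
DEFAULT_UMI_PATTERN = r"_([A-Za-z]+)$"


@dataclass(frozen=True)
class MatureMirRecord:
    """One annotated mature miRNA locus.

    ``seed_start``/``seed_end`` are the genomic coordinates of mature
    positions 2–8 (the target-recognition seed), derived from the locus
    span and strand.
    """

    mir_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    seed_start: int
    seed_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.mir_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.mir_id}: start {self.start} > end {self.end}")
        length = self.end - self.start + 1
        if not 15 <= length <= 30:
            raise ValueError(
                f"{self.mir_id}: mature length {length} outside the 15–30 nt range"
            )
        if not (self.start <= self.seed_start <= self.seed_end <= self.end):
            raise ValueError(f"{self.mir_id}: seed interval not contained in locus span")

    @classmethod
    def from_locus(cls, mir_id: str, chrom: str, strand: str, start: int, end: int) -> "MatureMirRecord":
        """Build a record, deriving seed coordinates from span and strand."""
        if strand == "+":
            seed = (start + SEED_OFFSET_START, start + SEED_OFFSET_END)
        else:
            seed = (end - SEED_OFFSET_END, end - SEED_OFFSET_START)
        return cls(mir_id, chrom, strand, start, end, seed[0], seed[1])

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the mature 5' terminus."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class AlignedRead:
    """One aligned small-RNA read with its extracted UMI."""

    read_id: str
    umi: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive aligned span
    end: int
    n_hits: int  # number of genomic locations this read maps to

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.read_id}: start {self.start} > end {self.end}")
        if not self.umi:
            raise ValueError(f"{self.read_id}: empty UMI")
        if self.n_hits < 1:
            raise ValueError(f"{self.read_id}: n_hits must be >= 1")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


class MirCountMatrix:
    """Deduplicated integer miR × sample counts plus sample metadata.

    ``counts`` is a DataFrame indexed by mir_id with one column per
    sample; ``samples`` is indexed by sample_id with columns
    ``subject``, ``compartment`` (MB/EV) and ``treatment``.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.copy()
        samples = samples.copy()
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miR ids: {dups}")
        if list(counts.columns) != list(samples.index):
            missing = sorted(set(counts.columns) ^ set(samples.index))
            raise ValueError(
                f"count-matrix columns and sample sheet disagree; offending ids: {missing or 'order mismatch'}"
            )
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype("int64", copy=False)
        self.samples = samples

    @property
    def mir_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "MirCountMatrix":
        ids = list(sample_ids)
        return MirCountMatrix(self.counts[ids], self.samples.loc[ids])

    def subset_mirs(self, mir_ids: Iterable[str]) -> "MirCountMatrix":
        return MirCountMatrix(self.counts.loc[list(mir_ids)], self.samples)

    def select(self, **criteria: object) -> "MirCountMatrix":
        """Subset samples by metadata equality, e.g. ``select(compartment="MB")``."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            vals = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            mask &= self.samples[col].isin(list(vals))
        return self.subset_samples(self.samples.index[mask])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MirCountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.samples.equals(other.samples)

    def __repr__(self) -> str:
        return f"MirCountMatrix({len(self.counts)} miRs x {self.counts.shape[1]} samples)"


def read_mirbase_gff(
    path: str | Path,
    feature_type: str = "miRNA",
    name_attr: str = "Name",
) -> list[MatureMirRecord]:
    """Parse a miRBase-style GFF3 and return mature-miR records in file order.

    Only features of ``feature_type`` (mature miRNAs; primary transcripts
    are skipped) are returned, with seed coordinates derived from the
    span and strand.
    """
    records: list[MatureMirRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: non-integer coordinates") from exc
            attributes = _parse_gff_attributes(attrs)
            if name_attr not in attributes:
                raise ValueError(
                    f"{path}: line {lineno}: feature lacks the {name_attr!r} attribute"
                )
            records.append(
                MatureMirRecord.from_locus(attributes[name_attr], chrom, strand, start, end)
            )
    return records


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def extract_umi(read_name: str, umi_pattern: str = DEFAULT_UMI_PATTERN) -> str:
    """Pull the UMI out of a read name; by default the last ``_`` token."""
    m = re.search(umi_pattern, read_name)
    if not m or not m.group(m.lastindex or 0):
        raise ValueError(f"read {read_name!r}: no UMI token matching {umi_pattern!r}")
    return m.group(m.lastindex or 0)


def read_alignments(
    path: str | Path,
    umi_pattern: str = DEFAULT_UMI_PATTERN,
) -> list[AlignedRead]:
    """Read mapped records from a SAM file as :class:`AlignedRead`.

    Unmapped records are skipped. Multiplicity (``n_hits``) is taken from
    the NH tag when present; otherwise a preliminary pass counts how many
    alignment records share each read id.
    """
    path = str(path)
    # preliminary pass: read-id multiplicity, used only when NH is absent
    multiplicity: dict[str, int] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NH"):
                multiplicity[rec.query_name] = multiplicity.get(rec.query_name, 0) + 1

    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            umi = extract_umi(rec.query_name, umi_pattern)
            n_hits = (
                int(rec.get_tag("NH"))
                if rec.has_tag("NH")
                else multiplicity[rec.query_name]
            )
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    umi=umi,
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    start=rec.reference_start + 1,
                    end=rec.reference_end,  # 0-based exclusive == 1-based inclusive
                    n_hits=n_hits,
                )
            )
    return reads


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV count matrix (first column ``mir_id``, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate miR ids: {dups}")
    return df


def write_count_matrix(counts: pd.DataFrame | MirCountMatrix, path: str | Path) -> None:
    df = counts.counts if isinstance(counts, MirCountMatrix) else counts
    df.to_csv(path, sep="\t", index_label="mir_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample_id, subject, compartment, treatment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "subject", "compartment", "treatment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    df = df.set_index("sample_id")
    return validate_sample_sheet(df)


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    if samples.index.duplicated().any():
        raise ValueError("duplicate sample_ids in sample sheet")
    bad_comp = sorted(set(samples["compartment"]) - set(COMPARTMENTS))
    if bad_comp:
        raise ValueError(f"unknown compartments {bad_comp}; expected {COMPARTMENTS}")
    combos = samples[["subject", "compartment", "treatment"]]
    if combos.duplicated().any():
        dup = combos[combos.duplicated()].iloc[0].tolist()
        raise ValueError(f"(subject, compartment, treatment) combination repeated: {dup}")
    return samples


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT-like TSV: pathway name, description, then member miR ids."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected name, description and >=1 member")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: pathway {name!r} has no members")
            if name in pathways:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway {name!r}")
            pathways[name] = set(members)
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")


def write_results_table(table: pd.DataFrame, path: str | Path, index_label: str = "mir_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)
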