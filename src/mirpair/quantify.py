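"""Read-to-miR quantification: multimap filtering, seed-anchored
assignment with 3'-end tolerance, and UMI deduplication.

The counting rules are:

* a read is retained only if it maps to at most ``max_hits`` genomic
  locations (default 13);
* a retained alignment is assigned to a mature miR when strands agree,
  the read's 5' terminus coincides exactly with the annotated mature 5'
  terminus — pinning mature positions 2–8 (the seed) to the annotated
  seed coordinates — and its 3' terminus differs from the annotated 3'
  terminus by at most ``max_3p_var`` nt (default 2);
* molecules are counted as distinct (chrom, strand, start, end, UMI)
  tuples per miR, removing PCR duplicates.

``seed_mode="cover"`` relaxes the 5' anchor to mere coverage of the
seed interval (the 3' rule still applies).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .io import (
    AlignedRead,
    MatureMirRecord,
    MirCountMatrix,
    DEFAULT_UMI_PATTERN,
    read_alignments,
    validate_sample_sheet,
)

__all__ = [
    "MatchDecision",
    "QuantifyConfig",
    "filter_multimappers",
    "assign_read",
    "deduplicate",
    "quantify_sample",
    "quantify_dataset",
]

REASONS = ("ok", "too_many_hits", "strand_mismatch", "seed_mismatch", "three_prime_excess", "no_overlap")


@dataclass(frozen=True)
class MatchDecision:
    """Outcome of matching one read against one mature-miR record."""

    accepted: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.accepted != (self.reason == "ok"):
            raise ValueError("accepted must hold exactly when reason == 'ok'")


OK = MatchDecision(True, "ok")


@dataclass
class QuantifyConfig:
    max_hits: int = 13
    max_3p_var: int = 2
    seed_mode: str = "anchor"  # "anchor" (strict 5'-terminus) or "cover"
    umi_pattern: str = DEFAULT_UMI_PATTERN

    def __post_init__(self) -> None:
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.max_3p_var < 0:
            raise ValueError("max_3p_var must be >= 0")
        if self.seed_mode not in ("anchor", "cover"):
            raise ValueError("seed_mode must be 'anchor' or 'cover'")


def filter_multimappers(
    reads: Iterable[AlignedRead], max_hits: int = 13
) -> Iterator[AlignedRead]:
    """Retain reads mapping to at most ``max_hits`` genomic locations."""
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    return (r for r in reads if r.n_hits <= max_hits)


def assign_read(
    read: AlignedRead,
    mir: MatureMirRecord,
    max_3p_var: int = 2,
    seed_mode: str = "anchor",
) -> MatchDecision:
    """Decide whether ``read`` reports a molecule of mature miR ``mir``."""
    if read.strand != mir.strand:
        return MatchDecision(False, "strand_mismatch")
    if read.end < mir.start or read.start > mir.end:
        return MatchDecision(False, "no_overlap")
    if seed_mode == "anchor":
        if read.five_prime != mir.five_prime:
            return MatchDecision(False, "seed_mismatch")
    else:  # cover: read must span the annotated seed interval
        if not (read.start <= mir.seed_start and mir.seed_end <= read.end):
            return MatchDecision(False, "seed_mismatch")
    if abs(read.three_prime - mir.three_prime) > max_3p_var:
        return MatchDecision(False, "three_prime_excess")
    return OK


def deduplicate(assigned: Iterable[tuple[str, AlignedRead]]) -> dict[str, int]:
    """Collapse PCR duplicates: one molecule per distinct
    (chrom, strand, start, end, UMI) tuple within each miR."""
    molecules: dict[str, set[tuple]] = defaultdict(set)
    for mir_id, read in assigned:
        molecules[mir_id].add((read.chrom, read.strand, read.start, read.end, read.umi))
    return {mir_id: len(tuples) for mir_id, tuples in molecules.items()}


class _AnnotationIndex:
    """Per-(chrom, strand) interval lookup over mature records."""

    def __init__(self, annotations: Sequence[MatureMirRecord]):
        self._by_key: dict[tuple[str, str], list[MatureMirRecord]] = defaultdict(list)
        for rec in annotations:
            self._by_key[(rec.chrom, rec.strand)].append(rec)

    def candidates(self, read: AlignedRead) -> list[MatureMirRecord]:
        recs = self._by_key.get((read.chrom, read.strand), [])
        return [m for m in recs if read.start <= m.end and m.start <= read.end]


@dataclass
class QuantifyStats:
    """Per-sample retention statistics through the counting stages."""

    n_input: int = 0
    n_multimap_dropped: int = 0
    n_assigned: int = 0
    n_molecules: int = 0


def quantify_sample(
    reads: Iterable[AlignedRead],
    annotations: Sequence[MatureMirRecord],
    config: QuantifyConfig | None = None,
) -> tuple[pd.Series, QuantifyStats]:
    """Count deduplicated molecules per mature miR for one sample.

    Returns a Series indexed by mir_id (annotation order; zeros included)
    and the stage-by-stage retention statistics.
    """
    config = config or QuantifyConfig()
    index = _AnnotationIndex(annotations)
    stats = QuantifyStats()
    assigned: list[tuple[str, AlignedRead]] = []
    for read in reads:
        stats.n_input += 1
        if read.n_hits > config.max_hits:
            stats.n_multimap_dropped += 1
            continue
        for mir in index.candidates(read):
            if assign_read(read, mir, config.max_3p_var, config.seed_mode).accepted:
                assigned.append((mir.mir_id, read))
                stats.n_assigned += 1
    counts = deduplicate(assigned)
    stats.n_molecules = sum(counts.values())
    mir_ids = [m.mir_id for m in annotations]
    col = pd.Series([counts.get(mid, 0) for mid in mir_ids], index=mir_ids, dtype="int64")
    return col, stats


def quantify_dataset(
    sam_paths: Mapping[str, str | Path],
    annotations: Sequence[MatureMirRecord],
    samples: pd.DataFrame,
    config: QuantifyConfig | None = None,
) -> tuple[MirCountMatrix, dict[str, QuantifyStats]]:
    """Quantify every sample in the sheet; columns follow sheet order.

    ``sam_paths`` maps sample_id → SAM file. A sample present in the
    sheet but absent from ``sam_paths`` is an error.
    """
    config = config or QuantifyConfig()
    validate_sample_sheet(samples)
    missing = [
        sid
        for sid in samples.index
        if sid not in sam_paths or not Path(sam_paths[sid]).exists()
    ]
    if missing:
        raise ValueError(f"no alignment file for samples: {missing}")
    columns: dict[str, pd.Series] = {}
    stats: dict[str, QuantifyStats] = {}
    for sample_id in samples.index:
        reads = read_alignments(sam_paths[sample_id], config.umi_pattern)
        columns[sample_id], stats[sample_id] = quantify_sample(reads, annotations, config)
    counts = pd.DataFrame(columns)[list(samples.index)]
    return MirCountMatrix(counts, samples), stats
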