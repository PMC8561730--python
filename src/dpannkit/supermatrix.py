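"""Phylogenomic marker selection and supermatrix/partition construction.

Marker selection follows the two-criterion ribosomal-protein rule: a marker is
suitable for concatenated phylogenomics when it is (i) present in at least 80%
of the reference genomes and (ii) close to single-copy, measured as a standard
deviation of copy number below 1.25 *among the genomes that contain it*. The
SD convention (sample, n-1, vs population, n) is configurable because the two
disagree near the cutoff; sample SD is the default.

For an existing per-marker alignment set, markers present in fewer than half
of the genomes are eliminated before concatenation (a sparsity guard for
partitioned analyses). Concatenation itself is deterministic: markers in
lexicographic order, each genome's missing markers gap-filled, and a 1-based
inclusive partition table mapping every marker to its column range, written in
RAxML style (``PROT, marker = start-end``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import CopyNumberMatrix, marker_prevalence

__all__ = [
    "PhyloSelectionConfig",
    "PartitionTable",
    "Supermatrix",
    "select_phylo_markers",
    "selection_report",
    "eliminate_rare_markers",
    "concatenate",
    "write_partition_file",
    "read_alignment_dir",
    "read_alignment_fasta",
]

# marker -> ordered (genome_id, aligned sequence) pairs; duplicates allowed
AlignmentSet = Mapping[str, Sequence[tuple[str, str]]]


@dataclass
class PhyloSelectionConfig:
    min_prevalence: float = 0.80
    max_copy_sd: float = 1.25
    sd_convention: str = "sample"  # "sample" (n-1) or "population" (n)

    def __post_init__(self) -> None:
        if not (0.0 < self.min_prevalence <= 1.0):
            raise ValidationError("min_prevalence must be in (0, 1]")
        if not (self.max_copy_sd > 0):
            raise ValidationError("max_copy_sd must be positive")
        if self.sd_convention not in ("sample", "population"):
            raise ValidationError("sd_convention must be 'sample' or 'population'")


def copy_number_sd(copies: Sequence[int], convention: str = "sample") -> float:
    """SD of copy number over genomes containing the marker; 0 for a single genome."""
    vals = np.asarray(copies, dtype=float)
    if vals.size <= 1:
        return 0.0
    ddof = 1 if convention == "sample" else 0
    return float(np.std(vals, ddof=ddof))


def selection_report(
    matrix: CopyNumberMatrix, config: PhyloSelectionConfig | None = None
) -> pd.DataFrame:
    """Per-marker prevalence, copy-number SD, and selection decision."""
    cfg = config or PhyloSelectionConfig()
    prev = marker_prevalence(matrix)
    rows = []
    for j, m in enumerate(matrix.marker_ids):
        col = matrix.counts[:, j]
        carriers = col[col >= 1]
        sd = copy_number_sd(carriers, cfg.sd_convention)
        selected = bool(prev[m] >= cfg.min_prevalence and sd < cfg.max_copy_sd)
        rows.append({"marker": m, "prevalence": float(prev[m]), "copy_sd": sd, "selected": selected})
    return pd.DataFrame(rows, columns=["marker", "prevalence", "copy_sd", "selected"])


def select_phylo_markers(
    matrix: CopyNumberMatrix, config: PhyloSelectionConfig | None = None
) -> list[str]:
    """Markers passing prevalence >= min_prevalence and copy-number SD < max_copy_sd."""
    rep = selection_report(matrix, config)
    return rep.loc[rep["selected"], "marker"].tolist()


def eliminate_rare_markers(
    alignments: AlignmentSet,
    genome_ids: Sequence[str],
    min_frac: float = 0.5,
) -> list[str]:
    """Retain markers whose alignments cover >= ``min_frac`` of the genomes.

    A marker covered by fewer than ``min_frac`` of the genome set is
    eliminated; exactly at the boundary it is retained.
    """
    if not (0.0 <= min_frac <= 1.0):
        raise ValidationError("min_frac must be in [0, 1]")
    known = set(genome_ids)
    if not known:
        raise ValidationError("genome_ids is empty")
    retained = []
    for marker in sorted(alignments):
        genomes = {g for g, _ in alignments[marker]}
        unknown = genomes - known
        if unknown:
            raise ValidationError(
                f"alignment {marker!r} names genomes outside the genome set: {sorted(unknown)}"
            )
        if len(genomes) / len(known) >= min_frac:
            retained.append(marker)
    return retained


@dataclass
class PartitionTable:
    """Ordered (marker, start, end) ranges, 1-based inclusive and contiguous."""

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        expected_start = 1
        for marker, start, end in self.entries:
            if start != expected_start:
                raise ValidationError(
                    f"partition {marker!r} starts at {start}, expected {expected_start}"
                )
            if end < start:
                raise ValidationError(f"partition {marker!r} has end {end} < start {start}")
            expected_start = end + 1

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    @property
    def length_range(self) -> tuple[int, int]:
        lengths = [end - start + 1 for _, start, end in self.entries]
        return (min(lengths), max(lengths))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Supermatrix:
    """Concatenated alignment plus its partition table."""

    genome_ids: list[str]
    sequences: dict[str, str]
    partition_table: PartitionTable

    def __post_init__(self) -> None:
        n = self.partition_table.total_length
        for g in self.genome_ids:
            if len(self.sequences[g]) != n:
                raise ValidationError(
                    f"sequence for {g!r} has length {len(self.sequences[g])}, expected {n}"
                )

    @property
    def alignment_length(self) -> int:
        return self.partition_table.total_length

    def write_fasta(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for g in self.genome_ids:
                fh.write(f">{g}\n")
                seq = self.sequences[g]
                for start in range(0, len(seq), 60):
                    fh.write(seq[start : start + 60] + "\n")


def _resolve_duplicates(
    marker: str, pairs: Sequence[tuple[str, str]], policy: str
) -> dict[str, str]:
    by_genome: dict[str, list[str]] = {}
    for g, seq in pairs:
        by_genome.setdefault(g, []).append(seq)
    out: dict[str, str] = {}
    for g, seqs in by_genome.items():
        if len(seqs) == 1:
            out[g] = seqs[0]
        elif policy == "error":
            raise ValidationError(f"genome {g!r} has {len(seqs)} sequences for marker {marker!r}")
        elif policy == "longest":
            # most non-gap residues; ties keep the first occurrence
            out[g] = max(seqs, key=lambda s: len(s) - s.count("-"))
        elif policy == "gap":
            continue  # drop the genome for this marker; it will be gap-filled
        else:
            raise ValidationError(f"unknown duplicate_policy {policy!r}")
    return out


def concatenate(
    alignments: AlignmentSet,
    genome_ids: Sequence[str],
    duplicate_policy: str = "gap",
) -> Supermatrix:
    """Concatenate per-marker alignments into a gap-filled supermatrix.

    Markers enter in lexicographic order. A genome missing a marker (or
    dropped by ``duplicate_policy='gap'`` because it has several copies)
    receives all-gap columns across that partition.
    """
    genome_ids = list(genome_ids)
    known = set(genome_ids)
    markers = sorted(alignments)
    if not markers:
        raise ValidationError("no alignments to concatenate")
    parts: dict[str, list[str]] = {g: [] for g in genome_ids}
    entries: list[tuple[str, int, int]] = []
    cursor = 1
    for marker in markers:
        pairs = alignments[marker]
        unknown = {g for g, _ in pairs} - known
        if unknown:
            raise ValidationError(
                f"alignment {marker!r} names genomes outside the genome set: {sorted(unknown)}"
            )
        lengths = {len(s) for _, s in pairs}
        if len(lengths) > 1:
            raise ValidationError(f"alignment {marker!r} has unequal sequence lengths {sorted(lengths)}")
        if not pairs:
            raise ValidationError(f"alignment {marker!r} is empty")
        width = lengths.pop()
        chosen = _resolve_duplicates(marker, pairs, duplicate_policy)
        gap = "-" * width
        for g in genome_ids:
            parts[g].append(chosen.get(g, gap))
        entries.append((marker, cursor, cursor + width - 1))
        cursor += width
    return Supermatrix(
        genome_ids=genome_ids,
        sequences={g: "".join(parts[g]) for g in genome_ids},
        partition_table=PartitionTable(entries=entries),
    )


def write_partition_file(table: PartitionTable, path: str | Path) -> tuple[int, int]:
    """Write RAxML-style partition lines; returns the (min, max) partition length."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for marker, start, end in table.entries:
            fh.write(f"PROT, {marker} = {start}-{end}\n")
    return table.length_range


# -- FASTA ingestion -------------------------------------------------------

def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read one aligned FASTA; returns (sequence id, sequence) pairs in file order."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_alignment_dir(
    directory: str | Path, suffixes: Sequence[str] = (".fasta", ".faa", ".fa", ".aln")
) -> dict[str, list[tuple[str, str]]]:
    """Load every per-marker alignment in a directory; marker id = file stem."""
    directory = Path(directory)
    out: dict[str, list[tuple[str, str]]] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in suffixes:
            out[path.stem] = read_alignment_fasta(path)
    if not out:
        raise ValidationError(f"no alignment files found in {directory}")
    return out
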