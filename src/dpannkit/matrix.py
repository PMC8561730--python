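"""Genome x marker copy-number matrices and HMMER hit ingestion.

The central container is :class:`CopyNumberMatrix`: an ordered genome x marker
table of non-negative integer gene-copy counts, optionally annotated with a
lineage label per genome and a prior completeness estimate per genome (e.g.
from a general-purpose marker tool) used only for tier filtering.

Copy counts can be ingested from a plain TSV or collapsed from HMMER tabular
domain-hit files: a count is the number of distinct query proteins of a genome
hitting a profile at or below an e-value threshold, so a protein carrying two
domains of one profile still counts as one gene copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "CopyNumberMatrix",
    "HitRecord",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "matrix_from_hits",
    "read_domtbl_hits",
    "marker_prevalence",
    "read_two_column_tsv",
]


@dataclass
class CopyNumberMatrix:
    """Genome x marker copy counts with optional per-genome annotations.

    Parameters
    ----------
    genome_ids, marker_ids:
        Ordered, unique identifiers for rows and columns.
    counts:
        Integer array of shape ``(n_genomes, n_markers)``, all entries >= 0.
    lineage:
        Optional mapping genome -> lineage label; when given it must cover
        every genome.
    prior_completeness:
        Optional mapping genome -> completeness percentage from an external
        estimator, consumed only by tier filtering.
    """

    genome_ids: list[str]
    marker_ids: list[str]
    counts: np.ndarray
    lineage: dict[str, str] | None = None
    prior_completeness: dict[str, float] | None = None
    _gidx: dict[str, int] = field(init=False, repr=False)
    _midx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.genome_ids = [str(g) for g in self.genome_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValidationError("genome_ids contain duplicates")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("marker_ids contain duplicates")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genome_ids), len(self.marker_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.marker_ids)} markers"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.lineage is not None:
            missing = [g for g in self.genome_ids if g not in self.lineage]
            if missing:
                raise ValidationError(f"lineage labels missing for genomes: {missing}")
        self._gidx = {g: i for i, g in enumerate(self.genome_ids)}
        self._midx = {m: j for j, m in enumerate(self.marker_ids)}

    # -- indexing helpers -------------------------------------------------
    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def genome_index(self, genome: str) -> int:
        try:
            return self._gidx[genome]
        except KeyError:
            raise ValidationError(f"unknown genome id: {genome!r}") from None

    def marker_index(self, marker: str) -> int:
        try:
            return self._midx[marker]
        except KeyError:
            raise ValidationError(f"unknown marker id: {marker!r}") from None

    def count(self, genome: str, marker: str) -> int:
        return int(self.counts[self.genome_index(genome), self.marker_index(marker)])

    def subset_genomes(self, genomes: Sequence[str]) -> "CopyNumberMatrix":
        rows = [self.genome_index(g) for g in genomes]
        return CopyNumberMatrix(
            genome_ids=list(genomes),
            marker_ids=list(self.marker_ids),
            counts=self.counts[rows, :],
            lineage=({g: self.lineage[g] for g in genomes} if self.lineage else None),
            prior_completeness=(
                {g: self.prior_completeness[g] for g in genomes if g in self.prior_completeness}
                if self.prior_completeness
                else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genome_ids, columns=self.marker_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopyNumberMatrix):
            return NotImplemented
        return (
            self.genome_ids == other.genome_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class HitRecord:
    """One profile-vs-protein hit from a HMMER search."""

    query_protein: str
    profile: str
    full_sequence_evalue: float
    genome: str

    def __post_init__(self) -> None:
        if not (self.full_sequence_evalue > 0) or math.isinf(self.full_sequence_evalue):
            raise ValidationError(
                f"e-value must be a positive finite number, got {self.full_sequence_evalue!r}"
            )


# -- TSV I/O ---------------------------------------------------------------

def read_matrix_tsv(path: str | Path) -> CopyNumberMatrix:
    """Read a copy-number matrix from TSV (header = marker ids, col 1 = genome id)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 1:
            raise ParseError(f"{path}: empty header")
        marker_ids = header[1:]
        if len(set(marker_ids)) != len(marker_ids):
            dup = sorted({m for m in marker_ids if marker_ids.count(m) > 1})
            raise ParseError(f"{path}: duplicated marker column(s): {dup}")
        genome_ids: list[str] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(marker_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(marker_ids) + 1} columns, got {len(cells)}"
                )
            gid = cells[0]
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate genome row {gid!r}")
            seen.add(gid)
            row = []
            for marker, cell in zip(marker_ids, cells[1:]):
                try:
                    row.append(int(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer cell {cell!r} "
                        f"(genome {gid!r}, marker {marker!r})"
                    ) from None
            genome_ids.append(gid)
            rows.append(row)
    counts = np.array(rows, dtype=np.int64).reshape(len(genome_ids), len(marker_ids))
    return CopyNumberMatrix(genome_ids=genome_ids, marker_ids=marker_ids, counts=counts)


def write_matrix_tsv(matrix: CopyNumberMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips losslessly through read_matrix_tsv."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("genome\t" + "\t".join(matrix.marker_ids) + "\n")
        for i, gid in enumerate(matrix.genome_ids):
            fh.write(gid + "\t" + "\t".join(str(int(c)) for c in matrix.counts[i]) + "\n")


def read_two_column_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (key, value) TSV, skipping blank and '#' lines."""
    out: dict[str, str] = {}
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if cells[0] in out:
                raise ParseError(f"{path}:{lineno}: duplicate key {cells[0]!r}")
            out[cells[0]] = cells[1]
    return out


# -- HMMER hit ingestion ----------------------------------------------------

def read_domtbl_hits(
    path: str | Path,
    protein_to_genome: Mapping[str, str] | None = None,
    id_separator: str = "|",
) -> list[HitRecord]:
    """Extract hit records from a HMMER3 per-domain tabular (``--domtblout``) file.

    The genome of each hit is looked up in ``protein_to_genome`` when supplied,
    otherwise taken from a ``genomeID|proteinID`` naming convention on the
    protein identifier (separator configurable).
    """
    from Bio import SearchIO

    records: list[HitRecord] = []
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        profile = qresult.id
        for hit in qresult.hits:
            protein = hit.id
            if protein_to_genome is not None:
                if protein not in protein_to_genome:
                    raise ValidationError(
                        f"protein {protein!r} missing from protein->genome map"
                    )
                genome = protein_to_genome[protein]
            else:
                genome = protein.split(id_separator, 1)[0]
            records.append(
                HitRecord(
                    query_protein=protein,
                    profile=profile,
                    full_sequence_evalue=float(hit.evalue),
                    genome=genome,
                )
            )
    return records


def matrix_from_hits(
    hits: Iterable[HitRecord],
    evalue_max: float,
    genome_ids: Sequence[str] | None = None,
    marker_ids: Sequence[str] | None = None,
    profile_evalue_max: Mapping[str, float] | None = None,
) -> CopyNumberMatrix:
    """Collapse hits into gene-copy counts.

    ``counts[g, m]`` is the number of *distinct* query proteins of genome ``g``
    hitting profile ``m`` with full-sequence e-value <= the threshold
    (``profile_evalue_max[m]`` when present, else ``evalue_max``). Genomes and
    markers listed but absent from the hits appear as zero rows/columns —
    absence is signal for completeness estimation.
    """
    if not (evalue_max > 0):
        raise ValidationError(f"evalue_max must be positive, got {evalue_max!r}")
    hits = list(hits)
    accepted: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        thr = evalue_max
        if profile_evalue_max is not None and h.profile in profile_evalue_max:
            thr = profile_evalue_max[h.profile]
        if h.full_sequence_evalue <= thr:
            accepted.setdefault((h.genome, h.profile), set()).add(h.query_protein)

    def _ordered(listed: Sequence[str] | None, observed: Iterable[str]) -> list[str]:
        if listed is not None:
            out = list(listed)
            known = set(out)
            extra = sorted({x for x in observed if x not in known})
            return out + extra
        return sorted(set(observed))

    gids = _ordered(genome_ids, (h.genome for h in hits))
    mids = _ordered(marker_ids, (h.profile for h in hits))
    counts = np.zeros((len(gids), len(mids)), dtype=np.int64)
    gpos = {g: i for i, g in enumerate(gids)}
    mpos = {m: j for j, m in enumerate(mids)}
    for (g, m), proteins in accepted.items():
        counts[gpos[g], mpos[m]] = len(proteins)
    return CopyNumberMatrix(genome_ids=gids, marker_ids=mids, counts=counts)


def marker_prevalence(
    matrix: CopyNumberMatrix, genome_subset: Sequence[str] | None = None
) -> pd.Series:
    """Fraction of genomes (in the subset) carrying >= 1 copy of each marker.

    Prevalence is a presence statistic: copy counts beyond one do not change it.
    """
    if genome_subset is None:
        rows = np.arange(matrix.n_genomes)
    else:
        subset = list(genome_subset)
        if not subset:
            raise ValidationError("genome_subset must be non-empty")
        rows = np.array([matrix.genome_index(g) for g in subset])
    present = matrix.counts[rows, :] >= 1
    return pd.Series(present.mean(axis=0), index=matrix.marker_ids, name="prevalence")
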