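"""Lineage-tailored single-copy-gene curation and MAG quality assessment.

Universal single-copy-gene (SCG) collections over-penalize reduced genomes:
lineages such as the DPANN archaea genuinely lack many "universal" markers, so
completeness estimated against a universal set is biased low. The remedy
implemented here curates a lineage-tailored collection from a reference set of
genomes: a marker is kept only if it is prevalent across the whole genome set
(>= 75% by default) *and* sufficiently prevalent within every "classic"
(well-sampled, trusted) lineage (> 50% by default, strict). Reference genomes
are first tier-filtered on an external prior completeness estimate (50% and
75% tiers by default) so that marker absence reflects biology, not assembly
gaps.

Completeness and redundancy are then simple presence fractions against the
curated collection:

    completeness% = 100 * |{m : c(g, m) >= 1}| / |collection|
    redundancy%   = 100 * |{m : c(g, m) >= 2}| / |collection|

Redundancy counts multi-copy markers (a contamination proxy), not excess
copies — the convention under which reported values are k/collection-size
fractions.

Two quality gates are provided: a reporting gate (completeness >= 50% and
redundancy <= 10%) and a stricter candidate-species gate (completeness >= 90%,
redundancy < 10%, >= 18 tRNAs, 16S rRNA >= 1000 bp). Boundary semantics are
exactly as stated: the reporting gate is inclusive at 10% redundancy, the
species gate exclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import CopyNumberMatrix, marker_prevalence

__all__ = [
    "CurationConfig",
    "CuratedCollection",
    "CompletenessReport",
    "QualityGateConfig",
    "GateVerdict",
    "filter_genomes_by_tier",
    "curate_collection",
    "compare_collections",
    "estimate_completeness",
    "reports_to_frame",
    "apply_quality_gates",
]


@dataclass
class CurationConfig:
    """Thresholds for lineage-tailored collection curation."""

    tier_completeness_cutoffs: tuple[float, ...] = (50.0, 75.0)
    min_prevalence_overall: float = 0.75
    min_prevalence_per_lineage: float = 0.50  # strict inequality
    classic_lineages: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for c in self.tier_completeness_cutoffs:
            if not (0.0 < c <= 100.0):
                raise ValidationError(f"tier cutoff {c} outside (0, 100]")
        for name, v in (
            ("min_prevalence_overall", self.min_prevalence_overall),
            ("min_prevalence_per_lineage", self.min_prevalence_per_lineage),
        ):
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        self.classic_lineages = frozenset(self.classic_lineages)


@dataclass
class CuratedCollection:
    """An ordered marker set surviving curation, with provenance."""

    marker_ids: list[str]
    source_collection: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValidationError("curated collection is empty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("curated collection has duplicate markers")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def write(self, path) -> None:
        """One marker per line, preceded by a JSON provenance header comment."""
        import json
        from pathlib import Path

        with Path(path).open("w", encoding="utf-8") as fh:
            header = {"source_collection": self.source_collection, **self.provenance}
            fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
            for m in self.marker_ids:
                fh.write(m + "\n")

    @classmethod
    def read(cls, path) -> "CuratedCollection":
        import json
        from pathlib import Path

        provenance: dict = {}
        markers: list[str] = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    try:
                        provenance = json.loads(line.lstrip("# "))
                    except ValueError:
                        pass
                    continue
                markers.append(line)
        source = provenance.pop("source_collection", "")
        return cls(marker_ids=markers, source_collection=source, provenance=provenance)


@dataclass
class CompletenessReport:
    genome_id: str
    completeness_pct: float
    redundancy_pct: float
    n_markers_present: int
    n_markers_multicopy: int
    collection_size: int


@dataclass
class GateVerdict:
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


@dataclass
class QualityGateConfig:
    """MAG reporting and candidate-species gates (percent scale)."""

    report_min_completeness: float = 50.0  # inclusive
    report_max_redundancy: float = 10.0  # inclusive
    species_min_completeness: float = 90.0  # inclusive
    species_max_redundancy: float = 10.0  # exclusive
    species_min_trna: int = 18  # inclusive
    species_min_16s_bp: int = 1000  # inclusive


def filter_genomes_by_tier(matrix: CopyNumberMatrix, cutoff_pct: float) -> list[str]:
    """Genomes whose prior completeness estimate is >= ``cutoff_pct`` (inclusive)."""
    if matrix.prior_completeness is None:
        raise ValidationError(
            f"prior_completeness missing for all genomes: {matrix.genome_ids}"
        )
    missing = [g for g in matrix.genome_ids if g not in matrix.prior_completeness]
    if missing:
        raise ValidationError(f"prior_completeness missing for genomes: {missing}")
    kept = [g for g in matrix.genome_ids if matrix.prior_completeness[g] >= cutoff_pct]
    if not kept:
        warnings.warn(
            f"tier cutoff {cutoff_pct}%C retains no genomes", stacklevel=2
        )
    return kept


def curate_collection(
    matrix: CopyNumberMatrix,
    config: CurationConfig,
    genome_subset: Sequence[str] | None = None,
    source_collection: str = "",
) -> CuratedCollection:
    """Retain markers prevalent overall and within every classic lineage.

    A marker m survives iff prevalence(m, subset) >= ``min_prevalence_overall``
    and, for every classic lineage L with at least one genome in the subset,
    prevalence(m, genomes of L) > ``min_prevalence_per_lineage`` (strict). The
    subset is typically a completeness tier from :func:`filter_genomes_by_tier`.
    """
    if matrix.lineage is None:
        raise ValidationError("matrix has no lineage labels")
    if not config.classic_lineages:
        raise ValidationError("classic_lineages must be non-empty")
    genomes = list(genome_subset) if genome_subset is not None else list(matrix.genome_ids)
    if not genomes:
        raise ValidationError("genome subset is empty")
    rows = np.array([matrix.genome_index(g) for g in genomes])
    present = matrix.counts[rows, :] >= 1
    lineages = np.array([matrix.lineage[g] for g in genomes])
    represented = [L for L in sorted(config.classic_lineages) if (lineages == L).any()]
    if not represented:
        raise ValidationError(
            f"no classic lineage {sorted(config.classic_lineages)} represented in subset"
        )
    keep = present.mean(axis=0) >= config.min_prevalence_overall
    lineage_sizes = {}
    for L in represented:
        mask = lineages == L
        lineage_sizes[L] = int(mask.sum())
        keep &= present[mask, :].mean(axis=0) > config.min_prevalence_per_lineage
    markers = [m for m, k in zip(matrix.marker_ids, keep) if k]
    if not markers:
        raise ValidationError("no marker survives curation under these thresholds")
    return CuratedCollection(
        marker_ids=markers,
        source_collection=source_collection,
        provenance={
            "n_genomes": len(genomes),
            "min_prevalence_overall": config.min_prevalence_overall,
            "min_prevalence_per_lineage": config.min_prevalence_per_lineage,
            "classic_lineage_sizes": lineage_sizes,
            "n_markers_in": matrix.n_markers,
            "n_markers_out": len(markers),
        },
    )


def compare_collections(
    matrices: Mapping[str, CopyNumberMatrix],
    equivalence_pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    priority: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pick, per equivalence class, the marker variant with highest prevalence.

    Different source collections may model the same underlying gene with HMM
    profiles of different quality; comparing prevalence across collections
    flags profiles that under-detect. ``equivalence_pairs`` links
    ``(collection, marker)`` entries; classes are their transitive closure.
    Ties break by ``priority`` (a collection order; defaults to the mapping
    order of ``matrices``).
    """
    priority = list(priority) if priority is not None else list(matrices)
    members: set[tuple[str, str]] = set()
    for (a, b) in equivalence_pairs:
        members.update((tuple(a), tuple(b)))
    for coll, marker in sorted(members):
        if coll not in matrices:
            raise ValidationError(f"unknown collection {coll!r} in equivalence map")
        if marker not in matrices[coll].marker_ids:
            raise ValidationError(
                f"marker {marker!r} absent from collection {coll!r}"
            )
    # union-find over (collection, marker) members
    parent: dict[tuple[str, str], tuple[str, str]] = {m: m for m in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b) in equivalence_pairs:
        ra, rb = find(tuple(a)), find(tuple(b))
        if ra != rb:
            parent[ra] = rb

    prevalence = {
        name: marker_prevalence(mat) for name, mat in matrices.items()
    }
    classes: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for m in members:
        classes.setdefault(find(m), []).append(m)

    rank = {name: i for i, name in enumerate(priority)}
    rows = []
    for idx, group in enumerate(sorted(classes.values())):
        scored = [
            (float(prevalence[coll][marker]), coll, marker) for coll, marker in group
        ]
        best = max(scored, key=lambda t: (t[0], -rank.get(t[1], len(rank))))
        for prev, coll, marker in sorted(scored, key=lambda t: (t[1], t[2])):
            rows.append(
                {
                    "class_id": idx,
                    "collection": coll,
                    "marker": marker,
                    "prevalence": prev,
                    "selected": (coll, marker) == (best[1], best[2]),
                }
            )
    return pd.DataFrame(rows, columns=["class_id", "collection", "marker", "prevalence", "selected"])


def estimate_completeness(
    matrix: CopyNumberMatrix, collection: CuratedCollection
) -> list[CompletenessReport]:
    """Per-genome completeness/redundancy percentages against a collection."""
    missing = [m for m in collection.marker_ids if m not in matrix._midx]
    if missing:
        raise ValidationError(f"collection markers absent from matrix: {missing}")
    cols = np.array([matrix.marker_index(m) for m in collection.marker_ids])
    sub = matrix.counts[:, cols]
    size = len(collection)
    reports = []
    for i, g in enumerate(matrix.genome_ids):
        present = int((sub[i] >= 1).sum())
        multi = int((sub[i] >= 2).sum())
        reports.append(
            CompletenessReport(
                genome_id=g,
                completeness_pct=100.0 * present / size,
                redundancy_pct=100.0 * multi / size,
                n_markers_present=present,
                n_markers_multicopy=multi,
                collection_size=size,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[CompletenessReport], decimals: int = 1) -> pd.DataFrame:
    """Tabulate reports with percentages rounded to ``decimals`` places."""
    return pd.DataFrame(
        {
            "genome": [r.genome_id for r in reports],
            "completeness_pct": [round(r.completeness_pct, decimals) for r in reports],
            "redundancy_pct": [round(r.redundancy_pct, decimals) for r in reports],
            "n_markers_present": [r.n_markers_present for r in reports],
            "n_markers_multicopy": [r.n_markers_multicopy for r in reports],
            "collection_size": [r.collection_size for r in reports],
        }
    )


def apply_quality_gates(
    report: CompletenessReport,
    n_tRNA: int = 0,
    len_16S_bp: int = 0,
    config: QualityGateConfig | None = None,
) -> dict[str, GateVerdict]:
    """Evaluate the reporting gate and the candidate-species gate.

    ``len_16S_bp`` is the longest 16S rRNA gene length (0 = absent). Returns
    verdicts with the failing criteria spelled out.
    """
    if n_tRNA < 0 or len_16S_bp < 0:
        raise ValidationError("n_tRNA and len_16S_bp must be >= 0")
    cfg = config or QualityGateConfig()
    c, r = report.completeness_pct, report.redundancy_pct

    report_fail = []
    if not (c >= cfg.report_min_completeness):
        report_fail.append(f"completeness {c:.1f}% < {cfg.report_min_completeness:g}%")
    if not (r <= cfg.report_max_redundancy):
        report_fail.append(f"redundancy {r:.1f}% > {cfg.report_max_redundancy:g}%")

    species_fail = []
    if not (c >= cfg.species_min_completeness):
        species_fail.append(f"completeness {c:.1f}% < {cfg.species_min_completeness:g}%")
    if not (r < cfg.species_max_redundancy):
        species_fail.append(f"redundancy {r:.1f}% not < {cfg.species_max_redundancy:g}%")
    if not (n_tRNA >= cfg.species_min_trna):
        species_fail.append(f"tRNA count {n_tRNA} < {cfg.species_min_trna}")
    if not (len_16S_bp >= cfg.species_min_16s_bp):
        species_fail.append(f"16S length {len_16S_bp} bp < {cfg.species_min_16s_bp} bp")

    return {
        "report_gate": GateVerdict(passed=not report_fail, failed_criteria=report_fail),
        "species_gate": GateVerdict(passed=not species_fail, failed_criteria=species_fail),
    }
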