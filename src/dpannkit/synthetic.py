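"""Synthetic inputs with known ground truth.

Every downstream module is exercised against data generated here: marker
presence/absence matrices with controllable per-genome completeness and
duplication, proteomes with a known number of planted heme-binding motifs on a
motif-free background, and rooted bifurcating trees with clade-consistent rank
labels. Each generator is deterministic given its seed.

The duplication model is intentionally minimal: a duplicated marker receives
copy count exactly 2, because redundancy as estimated downstream only
distinguishes multi-copy (>= 2) from single-copy. The heme background alphabet
excludes C and H entirely, so planted-motif recovery is exact rather than
probabilistic. The tree generator joins random pairs coalescent-style with
i.i.d. exponential branch lengths — enough structure for relative-divergence
property tests without modelling sequence evolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import ValidationError
from .matrix import CopyNumberMatrix

__all__ = [
    "MatrixSimulationSpec",
    "HemeSimulationSpec",
    "TreeSimulationSpec",
    "simulate_marker_matrix",
    "simulate_heme_proteome",
    "simulate_labelled_tree",
    "write_proteome_fasta",
    "BACKGROUND_ALPHABET",
]

# The 18 standard amino acids minus C and H: no spurious C-Xn-C-H motif can
# arise from background or spacer residues.
BACKGROUND_ALPHABET = "ADEFGIKLMNPQRSTVWY"

_RANK_PREFIX = {"class": "c", "order": "o", "family": "f", "genus": "g"}


def _as_per_genome(value, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError(f"{name} must be finite fractions in [0, 1]")
    return arr


@dataclass
class MatrixSimulationSpec:
    """Parameters for a genome x marker copy-number simulation.

    ``true_completeness`` and ``duplication_rate`` may be scalars (shared by
    all genomes) or per-genome sequences of fractions in [0, 1].
    """

    n_genomes: int
    marker_ids: Sequence[str]
    true_completeness: float | Sequence[float] = 0.75
    duplication_rate: float | Sequence[float] = 0.05
    lineage_labels: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValidationError("n_genomes must be >= 1")
        self.marker_ids = [str(m) for m in self.marker_ids]
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("marker_ids must be unique")
        if self.lineage_labels is not None and len(self.lineage_labels) != self.n_genomes:
            raise ValidationError("lineage_labels must have one label per genome")


def simulate_marker_matrix(spec: MatrixSimulationSpec) -> tuple[CopyNumberMatrix, dict]:
    """Draw a copy-number matrix with known completeness/duplication truth.

    For genome g and marker m the copy count is 0 with probability
    ``1 - true_completeness[g]``; a present marker is duplicated to count 2
    with probability ``duplication_rate[g]``, else stays at 1.
    """
    f = _as_per_genome(spec.true_completeness, spec.n_genomes, "true_completeness")
    d = _as_per_genome(spec.duplication_rate, spec.n_genomes, "duplication_rate")
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_genomes, len(spec.marker_ids)
    present = rng.random((n, k)) < f[:, None]
    duplicated = rng.random((n, k)) < d[:, None]
    counts = present.astype(np.int64) + (present & duplicated).astype(np.int64)
    width = max(4, len(str(n)))
    genome_ids = [f"G{i + 1:0{width}d}" for i in range(n)]
    lineages = (
        {g: str(l) for g, l in zip(genome_ids, spec.lineage_labels)}
        if spec.lineage_labels is not None
        else {g: "L1" for g in genome_ids}
    )
    matrix = CopyNumberMatrix(
        genome_ids=genome_ids,
        marker_ids=list(spec.marker_ids),
        counts=counts,
        lineage=lineages,
    )
    truth = {
        "seed": spec.seed,
        "true_completeness": {g: float(fi) for g, fi in zip(genome_ids, f)},
        "duplication_rate": {g: float(di) for g, di in zip(genome_ids, d)},
        "lineage": lineages,
    }
    return matrix, truth


@dataclass
class HemeSimulationSpec:
    """Parameters for a proteome with planted C-X(1,4)-C-H motifs.

    ``planted_counts`` and ``background_length`` are per-protein; scalars are
    broadcast. ``background_length`` is the total protein length; planted
    motifs (4-7 residues each) replace stretches of background.
    """

    n_proteins: int
    planted_counts: int | Sequence[int] = 0
    background_length: int | Sequence[int] = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        self._counts = np.broadcast_to(
            np.asarray(self.planted_counts, dtype=np.int64), (self.n_proteins,)
        ).copy()
        self._lengths = np.broadcast_to(
            np.asarray(self.background_length, dtype=np.int64), (self.n_proteins,)
        ).copy()
        if self._counts.min(initial=0) < 0:
            raise ValidationError("planted_counts must be non-negative")
        if self._lengths.min(initial=1) < 1:
            raise ValidationError("background_length must be positive")
        # worst case motif length is 7 (spacer of 4)
        bad = np.nonzero(self._counts * 7 > self._lengths)[0]
        if bad.size:
            raise ValidationError(
                f"planted_counts x 7 exceeds background capacity for proteins "
                f"{[int(i) for i in bad]}"
            )


def simulate_heme_proteome(
    spec: HemeSimulationSpec,
) -> tuple[list[tuple[str, str]], dict]:
    """Build proteins carrying exactly the requested number of heme motifs.

    Returns ``(records, truth)`` where records are ``(protein_id, sequence)``
    pairs and truth maps protein id to planted count and 1-based inclusive
    motif positions. Because background and spacer residues are drawn from the
    C/H-free alphabet, a scanner must recover the planted count exactly.
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.array(list(BACKGROUND_ALPHABET))
    records: list[tuple[str, str]] = []
    truth: dict[str, dict] = {}
    width = max(3, len(str(spec.n_proteins)))
    for i in range(spec.n_proteins):
        k = int(spec._counts[i])
        total = int(spec._lengths[i])
        spacers = rng.integers(1, 5, size=k)  # spacer lengths in [1, 4]
        motif_lens = spacers + 3
        slack = total - int(motif_lens.sum())
        # distribute leftover background uniformly into the k+1 gaps
        gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        parts: list[str] = []
        positions: list[tuple[int, int]] = []
        cursor = 0
        for j in range(k):
            parts.append("".join(rng.choice(bg, size=gaps[j])))
            cursor += int(gaps[j])
            spacer = "".join(rng.choice(bg, size=int(spacers[j])))
            motif = "C" + spacer + "CH"
            parts.append(motif)
            positions.append((cursor + 1, cursor + len(motif)))
            cursor += len(motif)
        parts.append("".join(rng.choice(bg, size=gaps[k])))
        seq = "".join(parts)
        pid = f"SIM|P{i + 1:0{width}d}"
        records.append((pid, seq))
        truth[pid] = {"count": k, "positions": positions}
    return records, {"seed": spec.seed, "proteins": truth}


def write_proteome_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) records as FASTA, 60 columns per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start : start + 60] + "\n")


@dataclass
class TreeSimulationSpec:
    """Parameters for a rooted, bifurcating, rank-labelled random tree."""

    n_leaves: int
    branch_length_scale: float = 0.1
    rank_depths: Mapping[str, float] = field(
        default_factory=lambda: {"class": 0.30, "order": 0.50, "family": 0.70, "genus": 0.90}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValidationError("n_leaves must be >= 2")
        if not (self.branch_length_scale > 0):
            raise ValidationError("branch_length_scale must be positive")
        for rank, depth in self.rank_depths.items():
            if rank not in _RANK_PREFIX:
                raise ValidationError(f"unknown rank {rank!r}")
            if not (0.0 < depth < 1.0):
                raise ValidationError(f"rank depth for {rank!r} must be in (0, 1)")


def simulate_labelled_tree(spec: TreeSimulationSpec) -> dendropy.Tree:
    """Generate a rooted bifurcating tree with rank-labelled internal nodes.

    Topology arises from coalescent-style random pair joins; branch lengths
    are i.i.d. exponential (strictly positive). Each internal non-root node is
    labelled ``r__<Rank><k>`` with the rank whose target depth fraction is
    nearest to the node's relative depth, so every labelled taxon is a clade
    by construction.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(spec.n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)

    def _edge_len() -> float:
        # rejection keeps lengths strictly positive
        while True:
            x = float(rng.exponential(spec.branch_length_scale))
            if x > 0.0:
                return x

    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node(taxon=taxon)
        leaf.edge.length = _edge_len()
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        parent.edge.length = _edge_len()
        nodes.append(parent)
    root = nodes[0]
    root.edge.length = None
    tree.seed_node = root
    tree.is_rooted = True

    # relative depth: position of the node along the deepest root->leaf path
    # passing through it, in (0, 1) for internal non-root nodes
    depth_below: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depth_below[id(node)] = 0.0
        else:
            depth_below[id(node)] = max(
                depth_below[id(ch)] + ch.edge.length for ch in node.child_nodes()
            )
    depth_above: dict[int, float] = {id(root): 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depth_above[id(node)] = depth_above[id(node.parent_node)] + node.edge.length

    ranks = sorted(spec.rank_depths.items(), key=lambda kv: kv[1])
    counters = {rank: 0 for rank, _ in ranks}
    for node in tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        total = depth_above[id(node)] + depth_below[id(node)]
        frac = depth_above[id(node)] / total if total > 0 else 0.0
        rank = min(ranks, key=lambda kv: abs(kv[1] - frac))[0]
        counters[rank] += 1
        node.label = f"{_RANK_PREFIX[rank]}__{rank.capitalize()}{counters[rank]}"
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line rooted Newick string."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    ).strip() + "\n"


def write_truth_json(truth: dict, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
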