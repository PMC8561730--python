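"""Relative evolutionary divergence (RED) and rank circumscription.

RED maps every node of a rooted tree onto [0, 1] — 0 at the root, 1 at every
leaf — so that taxonomic ranks can be compared across clades with very
different substitution rates. For an internal node n with parent RED value P,
branch length a to its parent, and mean path length b from n to its descendant
leaves,

    RED(n) = P + (a / (a + b)) * (1 - P)

computed in a preorder pass (b averages over *all* descendant leaves). With
strictly positive branch lengths RED increases monotonically along every
root-to-leaf path.

Rank medians are taken over the RED values of the labelled taxa of each rank
(class, order, family, genus); a query RED value is circumscribed to the rank
with the nearest median, flagged as inside/outside a +/- 0.05 window, with
ties resolved toward the higher (more inclusive) rank. Species delimitation
uses single-linkage clustering on a pairwise identity matrix (ANI >= 95% is
the conventional conspecificity threshold; AAI with caller-set thresholds
works identically for higher ranks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "REDTable",
    "RankWindowConfig",
    "RankAssignment",
    "compute_red",
    "rank_medians",
    "circumscribe",
    "write_red_scaled_tree",
    "red_scaled_tree",
    "delimit_species",
    "read_identity_matrix",
    "load_rooted_tree",
    "RANK_ORDER",
]

# higher (more inclusive) ranks first
RANK_ORDER = ("class", "order", "family", "genus")
_PREFIX_TO_RANK = {"c": "class", "o": "order", "f": "family", "g": "genus"}


@dataclass
class REDTable:
    """Per-node RED values, keyed by dendropy node objects and by stable labels."""

    values: dict  # dendropy.Node -> float
    labels: dict  # label (leaf name or internal label/N<i>) -> float

    def __getitem__(self, node) -> float:
        if isinstance(node, str):
            return self.labels[node]
        return self.values[node]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.labels), "red": list(self.labels.values())}
        )


def load_rooted_tree(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree, treating it as rooted; internal labels preserved."""
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True
    return tree


def _check_rooted(tree: dendropy.Tree) -> None:
    root = tree.seed_node
    if tree.is_rooted is False or (
        len(root.child_nodes()) > 2 and tree.is_rooted is not True
    ):
        raise ValidationError(
            "tree appears unrooted (basal multifurcation); root it first"
        )


def compute_red(tree: dendropy.Tree) -> REDTable:
    """Relative evolutionary divergence for every node of a rooted tree.

    Negative branch lengths are rejected; missing lengths count as 0, and a
    node whose a + b is 0 inherits its parent's value.
    """
    _check_rooted(tree)
    root = tree.seed_node

    n_leaves: dict[int, int] = {}
    sum_paths: dict[int, float] = {}  # sum over descendant leaves of dist(node, leaf)
    for node in tree.postorder_node_iter():
        if node is not root and node.edge.length is not None and node.edge.length < 0:
            raise ValidationError("negative branch length encountered")
        if node.is_leaf():
            n_leaves[id(node)] = 1
            sum_paths[id(node)] = 0.0
        else:
            n_leaves[id(node)] = sum(n_leaves[id(c)] for c in node.child_nodes())
            sum_paths[id(node)] = sum(
                sum_paths[id(c)] + n_leaves[id(c)] * (c.edge.length or 0.0)
                for c in node.child_nodes()
            )

    values: dict = {}
    labels: dict[str, float] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node is root:
            red = 0.0 if not root.is_leaf() else 1.0
        elif node.is_leaf():
            red = 1.0
        else:
            P = values[node.parent_node]
            a = node.edge.length or 0.0
            b = sum_paths[id(node)] / n_leaves[id(node)]
            red = P if (a + b) == 0 else P + (a / (a + b)) * (1.0 - P)
        values[node] = red
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or f"N{counter}")
        else:
            label = node.label or f"N{counter}"
        counter += 1
        if label in labels:
            label = f"{label}.{counter}"
        labels[label] = red
    return REDTable(values=values, labels=labels)


def _taxa_from_labels(tree: dendropy.Tree) -> dict[str, tuple[str, object]]:
    """Map taxon name -> (rank, node) from GTDB-style ``r__Name`` internal labels."""
    taxa: dict[str, tuple[str, object]] = {}
    for node in tree.preorder_internal_node_iter():
        label = node.label
        if not label:
            continue
        for piece in str(label).split(";"):
            piece = piece.strip().strip("'\"")
            if len(piece) > 3 and piece[1:3] == "__" and piece[0] in _PREFIX_TO_RANK:
                taxa[piece] = (_PREFIX_TO_RANK[piece[0]], node)
    return taxa


def rank_medians(
    tree: dendropy.Tree,
    red_table: REDTable,
    labelled_taxa: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Median RED per rank over the labelled taxa of the tree.

    Taxa are taken from GTDB-style internal labels (``c__``, ``o__``, ``f__``,
    ``g__``); alternatively ``labelled_taxa`` maps ``rank -> leaf names`` sets
    whose most recent common ancestors circumscribe the taxa. The median of an
    even count is the mean of the two central values. Ranks with no taxa are
    absent from the output (with a warning).
    """
    per_rank: dict[str, list[float]] = {r: [] for r in RANK_ORDER}
    if labelled_taxa is None:
        for name, (rank, node) in _taxa_from_labels(tree).items():
            per_rank[rank].append(red_table.values[node])
    else:
        for rank, leaf_sets in labelled_taxa.items():
            if rank not in per_rank:
                raise ValidationError(f"unknown rank {rank!r}")
            for leaves in leaf_sets:
                node = tree.mrca(taxon_labels=list(leaves))
                if node is None:
                    raise ValidationError(f"no MRCA for leaves {leaves!r}")
                per_rank[rank].append(red_table.values[node])
    medians: dict[str, float] = {}
    for rank in RANK_ORDER:
        vals = per_rank[rank]
        if not vals:
            warnings.warn(f"no labelled taxa at rank {rank!r}", stacklevel=2)
            continue
        medians[rank] = float(np.median(vals))
    return medians


@dataclass
class RankWindowConfig:
    """Per-rank RED medians and the half-width of the acceptance window."""

    medians: dict[str, float]
    window: float = 0.05
    ranks: tuple[str, ...] = RANK_ORDER

    def __post_init__(self) -> None:
        if not (self.window > 0):
            raise ValidationError("window must be positive")
        for rank, m in self.medians.items():
            if rank not in self.ranks:
                raise ValidationError(f"unknown rank {rank!r}")
            if not (0.0 <= m <= 1.0):
                raise ValidationError(f"median for {rank!r} outside [0, 1]")
        if not self.medians:
            raise ValidationError("at least one rank median is required")


@dataclass
class RankAssignment:
    rank: str
    median: float
    distance: float
    within_window: bool
    tied_with: str | None = None


def circumscribe(red_value: float, config: RankWindowConfig) -> RankAssignment:
    """Assign the rank whose median RED is nearest to ``red_value``.

    ``within_window`` is true iff the distance is <= the window half-width.
    An exact tie between two ranks resolves toward the higher (more
    inclusive) rank and is flagged via ``tied_with``.
    """
    ordered = [r for r in config.ranks if r in config.medians]
    dists = {r: abs(red_value - config.medians[r]) for r in ordered}
    best = min(dists.values())
    # float-robust tie detection: distances equal to machine precision count as tied
    tied = [r for r in ordered if dists[r] <= best + 1e-12]
    rank = tied[0]  # ranks are ordered most-inclusive first
    return RankAssignment(
        rank=rank,
        median=config.medians[rank],
        distance=best,
        within_window=best <= config.window,
        tied_with=tied[1] if len(tied) > 1 else None,
    )


def red_scaled_tree(tree: dendropy.Tree, red_table: REDTable | None = None) -> dendropy.Tree:
    """Clone of the tree with branch lengths replaced by RED increments.

    In the returned tree the root-to-node path length equals RED(node), so all
    leaves sit at depth 1.
    """
    scaled = tree.clone(depth=1)
    table = compute_red(scaled)
    for node in scaled.preorder_node_iter():
        if node is scaled.seed_node:
            node.edge.length = None
        else:
            node.edge.length = table.values[node] - table.values[node.parent_node]
    return scaled


def write_red_scaled_tree(
    tree: dendropy.Tree, path: str | Path, red_table: REDTable | None = None
) -> None:
    """Write the RED-scaled Newick tree to ``path``."""
    scaled = red_scaled_tree(tree, red_table)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            scaled.as_string(
                schema="newick", suppress_rooting=False, unquoted_underscores=True
            )
        )


# -- identity-based delimitation -------------------------------------------

def read_identity_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square pairwise-identity TSV (ANI or AAI, percent scale)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def delimit_species(
    identity: pd.DataFrame,
    threshold: float = 95.0,
    symmetry_tol: float = 0.1,
) -> list[list[str]]:
    """Single-linkage genome clusters at an identity threshold.

    Two genomes are linked when their identity is >= ``threshold`` (strictly
    below the threshold they are distinct); clusters are the connected
    components, so conspecificity is transitive through chains. The default
    threshold is the conventional 95% ANI species boundary.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    if list(identity.index) != list(identity.columns):
        raise ValidationError("identity matrix rows and columns must match")
    vals = identity.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        raise ValidationError("identity values must lie in [0, 100]")
    if np.max(np.abs(vals - vals.T)) > symmetry_tol:
        raise ValidationError(
            f"identity matrix asymmetric beyond tolerance {symmetry_tol}"
        )
    sym = (vals + vals.T) / 2.0
    adj = csr_matrix(sym >= threshold)
    n_comp, assignment = connected_components(adj, directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for genome, comp in zip(identity.index, assignment):
        clusters[comp].append(str(genome))
    clusters = [sorted(c) for c in clusters]
    return sorted(clusters, key=lambda c: c[0])
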