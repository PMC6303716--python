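"""Taxonomy-as-proxy tree and Brownian-motion covariance for PGLS.

Without a calibrated phylogeny, shared evolutionary history is approximated
from Linnean ranks: two species share ancestry in proportion to the number
of ranks (class, order, family, genus, species) they have in common. The
rank tree is ultrametric with five equal-length edge levels and total depth
1, so under Brownian motion the trait covariance of two species is simply
the depth of their most recent common ancestor: 0 for different classes,
0.2 for same class, up to 0.8 for congeners and 1 on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .species import SpeciesRecord

RANKS = ("class_rank", "order_rank", "family_rank", "genus_rank")
#: depth contributed by each shared rank level (5 levels, total depth 1)
LEVEL_DEPTH = 0.2


@dataclass(frozen=True)
class RankTree:
    """Ultrametric taxonomy tree; tips are species, depth normalized to 1."""

    tree: dendropy.Tree
    tip_ids: tuple[str, ...]


@dataclass(frozen=True)
class BrownianCovariance:
    """Shared-ancestry covariance matrix V aligned to ``species_order``."""

    matrix: np.ndarray
    species_order: tuple[str, ...]

    def subset(self, species_ids: Sequence[str]) -> "BrownianCovariance":
        """Covariance of a subset (or resample with duplicates) of species.

        Because V[i, j] is the MRCA depth, pruning the tree and rebuilding V
        equals slicing the full matrix; duplicated species get off-diagonal
        covariance 1, so resampled matrices need the nugget to stay positive
        definite.
        """
        pos = {s: k for k, s in enumerate(self.species_order)}
        idx = np.array([pos[s] for s in species_ids], dtype=np.intp)
        return BrownianCovariance(
            matrix=self.matrix[np.ix_(idx, idx)],
            species_order=tuple(species_ids),
        )


def build_rank_tree(records: Sequence[SpeciesRecord]) -> RankTree:
    """Build the taxonomy proxy tree from records' rank columns.

    Children at every level are ordered alphabetically, so the tree (and its
    Newick serialization) is deterministic. Each edge has length 0.2; every
    root-to-tip path traverses class, order, family and genus.
    """
    for rec in records:
        for rank in RANKS:
            if not getattr(rec, rank):
                raise ValueError(
                    f"record {rec.species_id!r} (row {rec.row}) lacks {rank}"
                )
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node.edge.length = 0.0

    # nested sorted grouping: class -> order -> family -> genus -> species
    by_path: dict[tuple[str, ...], list[str]] = {}
    for rec in records:
        path = tuple(getattr(rec, rank) for rank in RANKS)
        by_path.setdefault(path, []).append(rec.species_id)

    nodes: dict[tuple[str, ...], dendropy.Node] = {(): tree.seed_node}
    tip_ids: list[str] = []
    for path in sorted(by_path):
        for depth in range(1, len(RANKS) + 1):
            prefix = path[:depth]
            if prefix not in nodes:
                node = dendropy.Node()
                node.label = prefix[-1]
                node.edge.length = LEVEL_DEPTH
                nodes[prefix[:-1]].add_child(node)
                nodes[prefix] = node
        for sid in sorted(set(by_path[path])):
            taxon = taxon_namespace.new_taxon(sid)
            tip = dendropy.Node(taxon=taxon)
            tip.edge.length = LEVEL_DEPTH
            nodes[path].add_child(tip)
            tip_ids.append(sid)
    return RankTree(tree=tree, tip_ids=tuple(tip_ids))


def shared_depth(a: SpeciesRecord, b: SpeciesRecord) -> float:
    """MRCA depth of two records by direct rank comparison."""
    if a.species_id == b.species_id:
        return 1.0
    depth = 0.0
    for rank in RANKS:
        if getattr(a, rank) != getattr(b, rank):
            break
        depth += LEVEL_DEPTH
    return depth


def brownian_covariance(records: Sequence[SpeciesRecord]) -> BrownianCovariance:
    """Brownian trait covariance implied by the rank tree.

    V[i, j] is the fraction of root-to-tip history species i and j share;
    the diagonal is exactly 1. V is a Gram matrix of shared branch lengths
    and hence positive semi-definite by construction.
    """
    n = len(records)
    # vectorized rank comparison: accumulate 0.2 per consecutively shared rank
    v = np.zeros((n, n))
    alive = np.ones((n, n), dtype=bool)
    for rank in RANKS:
        labels = np.array([getattr(r, rank) for r in records], dtype=object)
        same = labels[:, None] == labels[None, :]
        alive &= same
        v += LEVEL_DEPTH * alive
    ids = np.array([r.species_id for r in records], dtype=object)
    v[ids[:, None] == ids[None, :]] = 1.0
    np.fill_diagonal(v, 1.0)
    return BrownianCovariance(
        matrix=v, species_order=tuple(r.species_id for r in records)
    )


def covariance_from_tree(tree: RankTree) -> BrownianCovariance:
    """V via explicit tree traversal (MRCA depth = 1 - half patristic distance).

    Slower than the rank shortcut but independent of it; the two must agree
    exactly, which the test suite asserts.
    """
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(tree.tip_ids)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[tree.tip_ids[i]], taxa[tree.tip_ids[j]])
            v[i, j] = v[j, i] = 1.0 - dist / 2.0
    return BrownianCovariance(matrix=v, species_order=tree.tip_ids)


def write_newick(tree: RankTree, path: str | Path) -> None:
    """Serialize the rank tree as Newick with branch lengths."""
    tree.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
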