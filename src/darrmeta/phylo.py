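"""Phylogenetic correlation and sampling variance-covariance structures.

Two known matrices enter the meta-analytic model.  The species-level
correlation matrix A comes from a rooted tree whose branch lengths are
assigned by Grafen's method: each internal node sits at height
((descendant tips - 1)/(total tips - 1))**rho, tips at 0, the root at 1,
so the tree is ultrametric with unit depth and A[i, j] is the shared
root-to-MRCA path length, 1 - height(MRCA(i, j)).  Polytomies are
resolved at random (seeded) before scaling.

The effect-level sampling VCV V carries each effect's known sampling
variance on the diagonal and, for pairs of effects that reuse the same
treatment group in stepwise comparisons, an off-diagonal covariance
r * sqrt(v_i v_j) with a conservative r = 0.5 by default.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from darrmeta.effects import EffectSize

__all__ = [
    "PhyloCorrelation", "SamplingVCV", "StructureError",
    "read_tree", "resolve_polytomies", "grafen_lengths",
    "phylo_correlation", "build_sampling_vcv", "correlation_from_newick",
]

PSD_RTOL = 1e-8


class StructureError(ValueError):
    """A constructed matrix violates its structural contract."""


@dataclass
class PhyloCorrelation:
    """Species-by-species phylogenetic correlation matrix."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.shape != (len(self.species), len(self.species)):
            raise StructureError("matrix shape does not match species list")
        if not np.allclose(a, a.T, atol=1e-12):
            raise StructureError("correlation matrix not symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-10):
            raise StructureError("correlation matrix diagonal is not 1")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise StructureError("correlation entries outside [0, 1]")
        _check_psd(a, "phylogenetic correlation")
        self.matrix = a

    def submatrix(self, species: Sequence[str]) -> "PhyloCorrelation":
        missing = [s for s in species if s not in self.species]
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(list(species), self.matrix[np.ix_(idx, idx)])


@dataclass
class SamplingVCV:
    """Known sampling (co)variance matrix over ordered effect sizes."""

    effect_ids: list[str]
    matrix: np.ndarray
    r_shared: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.matrix, dtype=float)
        if v.shape != (len(self.effect_ids), len(self.effect_ids)):
            raise StructureError("VCV shape does not match effect list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise StructureError("sampling VCV not symmetric")
        if np.any(np.diag(v) <= 0):
            raise StructureError("sampling variances must be > 0")
        _check_psd(v, "sampling VCV")
        self.matrix = v

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.matrix).copy()


def _check_psd(a: np.ndarray, what: str) -> None:
    ev = np.linalg.eigvalsh(a)
    if ev[0] < -PSD_RTOL * max(ev[-1], 1.0):
        raise StructureError(
            f"{what} is not positive semi-definite (min eigenvalue {ev[0]:.3g})"
        )


def read_tree(path) -> dendropy.Tree:
    """Parse a rooted newick tree, rejecting duplicate tip labels."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise ValueError(
            f"{path}: malformed newick or duplicate tip labels ({exc})"
        ) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Randomly resolve all polytomies into a strictly binary tree.

    The resolution is a deterministic function of (tree, seed); the tip
    set is unchanged and an already-binary tree passes through intact.
    """
    out = tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    return out


def _assert_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise ValueError("tree must be strictly binary; resolve polytomies first")


def grafen_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign Grafen branch lengths to a binary rooted tree.

    Node height = ((descendant tips - 1)/(total tips - 1))**rho; tips at
    height 0, root at height 1; branch length = parent height - child
    height.  The result is ultrametric with total depth 1.
    """
    _assert_binary(tree)
    out = tree.clone(depth=1)
    n_total = len(out.leaf_nodes())
    if n_total < 2:
        raise ValueError("Grafen scaling needs >= 2 tips")
    for node in out.postorder_node_iter():
        if node.is_leaf():
            node._grafen_tips = 1
            node._grafen_height = 0.0
        else:
            tips = sum(c._grafen_tips for c in node.child_nodes())
            node._grafen_tips = tips
            node._grafen_height = ((tips - 1) / (n_total - 1)) ** rho
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node._grafen_height - node._grafen_height
    return out


def phylo_correlation(tree: dendropy.Tree) -> PhyloCorrelation:
    """Correlation matrix from a Grafen-scaled (unit-depth ultrametric) tree.

    A[i, j] is the shared path from the root to the MRCA of tips i and j,
    which for a unit-depth tree equals 1 - height(MRCA).
    """
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    # root-to-node distances; ultrametry check
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depths = np.array([leaf.root_distance for leaf in leaves])
    if not np.allclose(depths, depths[0], atol=1e-8):
        raise ValueError("tree is not ultrametric; apply Grafen scaling first")
    depth = float(depths[0])
    # newick convention: unquoted underscores read as spaces; normalize back
    names = [leaf.taxon.label.replace(" ", "_") for leaf in leaves]
    A = np.eye(n)
    # pairs across the two child subtrees of a node have that node as MRCA
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    for node in tree.postorder_internal_node_iter():
        shared = float(node.root_distance) / depth
        kids = node.child_nodes()
        leaf_sets = [[index[id(l)] for l in c.leaf_iter()] for c in kids]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in leaf_sets[a]:
                    for j in leaf_sets[b]:
                        A[i, j] = A[j, i] = shared
    return PhyloCorrelation(names, A)


def correlation_from_newick(
    path, seed: int, rho: float = 1.0
) -> PhyloCorrelation:
    """Read newick -> resolve polytomies -> Grafen lengths -> correlation."""
    return phylo_correlation(grafen_lengths(resolve_polytomies(read_tree(path), seed), rho))


def build_sampling_vcv(
    effects: Sequence[EffectSize], r_shared: float = 0.5
) -> SamplingVCV:
    """Effect-level sampling VCV with shared-treatment covariances.

    V[i, i] is each effect's sampling variance; V[i, j] is
    r_shared * sqrt(v_i v_j) when effects i and j reuse a common
    treatment group (their shared-group identifier sets intersect), and
    zero otherwise.  Positive semi-definiteness is verified and a
    violation is reported, never silently repaired.
    """
    if not (0 <= r_shared < 1):
        raise ValueError(f"r_shared must be in [0, 1), got {r_shared}")
    k = len(effects)
    v = np.array([e.variance for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    V = np.diag(v)
    if r_shared > 0:
        groups: dict[str, list[int]] = {}
        for i, e in enumerate(effects):
            for gid in e.shared_group_ids:
                groups.setdefault(gid, []).append(i)
        for members in groups.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    i, j = members[a], members[b]
                    V[i, j] = V[j, i] = r_shared * np.sqrt(v[i] * v[j])
    ids = [e.effect_id or str(i) for i, e in enumerate(effects)]
    return SamplingVCV(ids, V, r_shared=r_shared)
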