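"""Rooted phylogenies, patristic distances and trait covariance structure.

The tree is the backbone of every comparative statistic in this package:
under Brownian-motion (BM) trait evolution the expected covariance of two
tip values is the shared root-to-ancestor path length, and the Pagel λ/δ
and Ornstein-Uhlenbeck (OU) models act as transformations of that
covariance matrix.  Newick I/O is delegated to :mod:`dendropy`; the
distance/covariance computations and the model transforms live here.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "cophenetic_distances",
    "phylo_covariance",
    "transform_covariance",
]


class NewickError(ValueError):
    """Malformed Newick input or an invalid tree (duplicate labels, missing lengths)."""


class PhyloTree:
    """A rooted phylogeny with branch lengths, wrapping a :class:`dendropy.Tree`.

    Invariants enforced at construction: unique tip labels and a branch
    length on every node except the root.  Branch lengths may be in any
    additive unit (time or expected substitutions); nothing here assumes
    the tree is ultrametric.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()
        # stable tip order used by every matrix this tree produces
        self._tip_labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"could not parse Newick: {exc}") from exc
        return cls(dtree)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    def _validate(self) -> None:
        if self._tree.seed_node is None:
            raise NewickError("tree has no root")
        labels = []
        for lf in self._tree.leaf_node_iter():
            if lf.taxon is None or not lf.taxon.label:
                raise NewickError("unlabeled tip")
            labels.append(lf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        for nd in self._tree.preorder_node_iter():
            if nd is self._tree.seed_node:
                continue
            if nd.edge.length is None:
                tok = nd.taxon.label if nd.taxon else "<internal>"
                raise NewickError(f"missing branch length at node {tok!r}")
            if nd.edge.length < 0:
                raise NewickError("negative branch length")

    # -- basic accessors ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def __repr__(self) -> str:
        return f"PhyloTree(n_tips={self.n_tips})"

    # -- node depths --------------------------------------------------------

    def _node_depths(self) -> dict:
        """Path length from the root to every node.  The root's own edge
        (if the Newick string carried one) is not counted."""
        depths = {self._tree.seed_node: 0.0}
        for nd in self._tree.preorder_node_iter():
            if nd is self._tree.seed_node:
                continue
            depths[nd] = depths[nd.parent_node] + nd.edge.length
        return depths

    # -- matrices ------------------------------------------------------------

    def cophenetic_distances(self) -> pd.DataFrame:
        """Patristic distance matrix: sum of branch lengths between tip pairs.

        Derived from the covariance structure through the exact identity
        d[i,j] = c[i,i] + c[j,j] − 2·c[i,j]: tip depths minus twice the
        shared root-to-MRCA path leave precisely the unshared path.
        """
        c = self._covariance_array()
        diag = np.diag(c)
        d = diag[:, None] + diag[None, :] - 2.0 * c
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=self._tip_labels, columns=self._tip_labels)

    def _covariance_array(self, depths=None) -> np.ndarray:
        labels = self._tip_labels
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        if depths is None:
            depths = self._node_depths()
        c = np.zeros((n, n))
        below: dict = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                i = idx[nd.taxon.label]
                c[i, i] = depths[nd]
                below[nd] = [i]
                continue
            kids = [below[ch] for ch in nd.child_nodes()]
            h = depths[nd]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            c[i, j] = c[j, i] = h
            merged: list[int] = []
            for k in kids:
                merged.extend(k)
            below[nd] = merged
        return c

    def covariance(self) -> pd.DataFrame:
        """BM trait covariance: C[i,j] = root-to-MRCA path length, C[i,i] = tip depth."""
        c = self._covariance_array()
        return pd.DataFrame(c, index=self._tip_labels, columns=self._tip_labels)

    # -- pruning -------------------------------------------------------------

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Subtree spanning ``labels``; unifurcations are suppressed with
        branch lengths summed, so patristic distances among retained tips
        are unchanged."""
        keep = list(dict.fromkeys(labels))
        missing = set(keep) - set(self._tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to prune to")
        sub = self._tree.clone(depth=1)
        sub.retain_taxa_with_labels(keep)
        sub.seed_node.edge.length = None  # pruning may fold depth into a root edge
        return PhyloTree(sub)


# ---------------------------------------------------------------------------
# module-level conveniences


def parse_newick(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def cophenetic_distances(tree: PhyloTree) -> pd.DataFrame:
    return tree.cophenetic_distances()


def phylo_covariance(tree: PhyloTree) -> pd.DataFrame:
    return tree.covariance()


# ---------------------------------------------------------------------------
# covariance transforms for the trait-evolution models

_BOUNDS = {"lambda": (0.0, 1.0), "delta": (0.0, 10.0), "ou": (0.0, 1000.0)}


def transform_covariance(c: pd.DataFrame, model: str, param: float) -> pd.DataFrame:
    """Apply the λ, δ or OU transformation to a BM covariance matrix.

    * ``lambda``: off-diagonal entries multiplied by λ ∈ [0, 1]; λ = 0 is a
      star phylogeny, λ = 1 leaves the matrix unchanged.
    * ``delta``: shared path lengths raised to the power δ ∈ (0, 10] after
      normalising by the tree height T = max diagonal, then rescaled by T,
      so the transform is well defined on non-ultrametric trees and
      preserves the height.
    * ``ou``: fixed-root Ornstein-Uhlenbeck covariance
      c'[i,j] = (1/2α)·exp(−α·d[i,j])·(1 − exp(−2α·c[i,j])) with d the
      patristic distance (recovered from c); valid on non-ultrametric
      trees.  α = 0 is the BM limit c' = c.
    """
    if model not in _BOUNDS:
        raise ValueError(f"unknown model {model!r}; expected lambda/delta/ou")
    lo, hi = _BOUNDS[model]
    if not (lo <= param <= hi) or (model == "delta" and param == 0.0):
        raise ValueError(f"{model} parameter {param} outside ({lo}, {hi}]")
    a = c.to_numpy(dtype=float, copy=True)
    if model == "lambda":
        diag = np.diag(a).copy()
        a *= param
        np.fill_diagonal(a, diag)
    elif model == "delta":
        t = float(np.max(np.diag(a)))
        if t <= 0:
            raise ValueError("degenerate covariance: zero tree height")
        a = t * np.power(a / t, param)
    else:  # ou
        alpha = param
        if alpha > 1e-9:
            diag = np.diag(a)
            d = diag[:, None] + diag[None, :] - 2.0 * a
            np.fill_diagonal(d, 0.0)
            a = (1.0 / (2.0 * alpha)) * np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * a))
        # α ≈ 0: BM limit, leave a unchanged
    return pd.DataFrame(a, index=c.index, columns=c.columns)
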