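"""Phylogenetic trees: Newick I/O, chronogram assembly, and covariance matrices.

Branch lengths are in millions of years (My) throughout; evolutionary rates
computed downstream are therefore per-My. The phylogenetic covariance of two
tips is the depth of their most recent common ancestor (the shared root-to-MRCA
path length), optionally lambda-transformed: off-diagonal entries are
multiplied by Pagel's lambda while tip variances (root-to-tip distances) are
left unchanged.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from io import StringIO
from typing import Iterator, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "Branch",
    "TreeError",
    "read_newick",
    "write_newick",
    "build_chronogram",
    "vcv",
    "bundled_tree",
    "bundled_node_dates",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass(frozen=True)
class Branch:
    """One edge of a rooted tree, identified by the node it subtends."""

    id: str
    parent: str
    child: str
    length: float
    is_tip: bool


class PhyloTree:
    """A rooted tree with named tips, stable node ids, and lengths in My.

    Thin wrapper around a :class:`dendropy.Tree` that adds the bookkeeping the
    comparative analyses need: stable identifiers for internal nodes (their
    Newick label when present, ``N<k>`` in preorder otherwise), node depths,
    branch iteration, and lambda-transformed covariance matrices.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._assign_ids()
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _assign_ids(self) -> None:
        self._id_of = {}
        k = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("tip without a label")
                self._id_of[node] = node.taxon.label
            elif node.label:
                self._id_of[node] = node.label
            else:
                self._id_of[node] = f"N{k}"
            k += 1
        ids = list(self._id_of.values())
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TreeError(f"duplicate node labels: {dup}")

    def _validate(self) -> None:
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeError(f"missing branch length above node {self._id_of[node]!r}")
            if node.edge.length < 0:
                raise TreeError(
                    f"negative branch length {node.edge.length} above node "
                    f"{self._id_of[node]!r}"
                )
        for tip, depth in zip(self.tips, np.diag(self._shared_path_matrix())):
            if depth <= 0:
                raise TreeError(f"tip {tip!r} has zero root-to-tip distance")

    # -- basic structure ---------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels in Newick file order."""
        return [self._id_of[n] for n in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def root_id(self) -> str:
        return self._id_of[self._tree.seed_node]

    @property
    def node_ids(self) -> list[str]:
        """All node ids, preorder (root first)."""
        return [self._id_of[n] for n in self._tree.preorder_node_iter()]

    def depths(self) -> dict[str, float]:
        """Root-to-node path length for every node (root = 0)."""
        out: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                out[self._id_of[node]] = 0.0
            else:
                out[self._id_of[node]] = (
                    out[self._id_of[node.parent_node]] + node.edge.length
                )
        return out

    def branches(self) -> Iterator[Branch]:
        """Yield every non-root branch, identified by its child node."""
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            cid = self._id_of[node]
            yield Branch(
                id=cid,
                parent=self._id_of[node.parent_node],
                child=cid,
                length=float(node.edge.length),
                is_tip=node.is_leaf(),
            )

    def neighbors(self) -> dict[str, list[tuple[str, float]]]:
        """Adjacency map (node id -> list of (neighbor id, branch length))."""
        adj: dict[str, list[tuple[str, float]]] = {i: [] for i in self.node_ids}
        for br in self.branches():
            adj[br.parent].append((br.child, br.length))
            adj[br.child].append((br.parent, br.length))
        return adj

    def tip_set(self, node_id: str) -> frozenset[str]:
        """Tips descending from (and including) a node."""
        for node in self._tree.preorder_node_iter():
            if self._id_of[node] == node_id:
                return frozenset(
                    self._id_of[leaf] for leaf in node.leaf_iter()
                )
        raise KeyError(node_id)

    def mrca_id(self, tips: list[str]) -> str:
        taxa = set(tips)
        unknown = taxa - set(self.tips)
        if unknown:
            raise KeyError(f"unknown tips: {sorted(unknown)}")
        node = self._tree.mrca(taxon_labels=list(taxa))
        return self._id_of[node]

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.depths()
        tip_depths = [d[t] for t in self.tips]
        return max(tip_depths) - min(tip_depths) <= tol

    # -- covariance --------------------------------------------------------

    def _shared_path_matrix(self) -> np.ndarray:
        # trees are immutable after construction; cache the expensive scan
        cached = getattr(self, "_spm_cache", None)
        if cached is not None:
            return cached
        tips = self.tips
        idx = {t: i for i, t in enumerate(tips)}
        depth = self.depths()
        n = len(tips)
        V = np.zeros((n, n))
        for t in tips:
            V[idx[t], idx[t]] = depth[t]
        # off-diagonals: depth of the MRCA; accumulate over internal nodes,
        # pairing tips that descend through different children
        for node in self._tree.postorder_internal_node_iter():
            d = depth[self._id_of[node]]
            child_tipsets = [
                [idx[self._id_of[l]] for l in ch.leaf_iter()]
                for ch in node.child_nodes()
            ]
            for a in range(len(child_tipsets)):
                for b in range(a + 1, len(child_tipsets)):
                    for i in child_tipsets[a]:
                        for j in child_tipsets[b]:
                            V[i, j] = d
                            V[j, i] = d
        self._spm_cache = V
        return V

    def vcv(self, lam: float = 1.0) -> pd.DataFrame:
        """Phylogenetic covariance matrix with Pagel-lambda transformation.

        Entry (i, j) for i != j is ``lam`` times the shared root-to-MRCA path
        length; the diagonal (root-to-tip distances) is unchanged.
        """
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        V = self._shared_path_matrix().copy()
        diag = np.diag(V).copy()
        V *= lam
        np.fill_diagonal(V, diag)
        return pd.DataFrame(V, index=self.tips, columns=self.tips)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        out = self._tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return out.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required) into a PhyloTree."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def vcv(tree: PhyloTree, lam: float = 1.0) -> pd.DataFrame:
    return tree.vcv(lam)


def build_chronogram(spec: Mapping) -> PhyloTree:
    """Assemble an ultrametric tree from a nested clade/date specification.

    ``spec`` is a nested mapping: internal clades carry ``name``, ``age`` (My
    before present) and ``children``; tips carry only ``name`` (age 0).
    Branch length = parent age - child age; ages must strictly decrease from
    root to tips.
    """

    def render(node: Mapping, parent_age: float | None) -> str:
        name = node["name"]
        age = float(node.get("age", 0.0))
        children = node.get("children")
        if children and age <= 0:
            raise TreeError(f"internal clade {name!r} needs a positive age")
        if parent_age is not None:
            if age >= parent_age:
                raise TreeError(
                    f"date inversion: clade {name!r} (age {age}) is not younger "
                    f"than its parent (age {parent_age})"
                )
            length = f":{parent_age - age:.12g}"
        else:
            length = ""
        if not children:
            return f"{name}{length}"
        inner = ",".join(render(c, age) for c in children)
        return f"({inner}){name}{length}"

    newick = render(spec, None) + ";"
    tree = PhyloTree.from_newick(newick)
    assert tree.is_ultrametric(1e-9)
    return tree


def _resource_text(name: str) -> str:
    return (
        importlib.resources.files("phylolat.resources").joinpath(name).read_text()
    )


def bundled_node_dates() -> dict:
    """The versioned clade/date specification for the anthropoid chronogram."""
    spec = json.loads(_resource_text("anthropoid_node_dates.json"))
    spec.pop("comment", None)
    return spec


def bundled_tree_path():
    """Filesystem path of the versioned chronogram Newick file."""
    return importlib.resources.files("phylolat.resources").joinpath(
        "anthropoid_chronogram.nwk"
    )


def bundled_tree() -> PhyloTree:
    """The bundled 16-species anthropoid chronogram."""
    return PhyloTree.from_newick(_resource_text("anthropoid_chronogram.nwk"))
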