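"""Tree-structured class taxonomies for hierarchical multi-label classification.

A class hierarchy (e.g. the MIPS FunCat protein-function catalogue) is a
rooted tree whose nodes are classes identified by their path from the root:
``12.01.01`` is a subclass of ``12.01`` which is a subclass of the top-level
category ``12``.  A synthetic root joins the top-level categories; it is not a
class, is never predicted, and is not counted in ``|C|``.

Annotation sets must be *closed under ancestors*: whenever a class is
assigned to an instance, every superclass on its root path is assigned too.
This module parses hierarchical labels, builds hierarchies, closes label
sets, and repairs predictions that violate the closure constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ClassNode",
    "ClassHierarchy",
    "HierarchyError",
    "LabelParseError",
    "parse_label",
    "format_label",
    "build_hierarchy",
]

_SEPARATORS = {"dot": ".", "slash": "/"}


class HierarchyError(KeyError):
    """Unknown class id or malformed hierarchy operation."""


class LabelParseError(ValueError):
    """Raised for labels that cannot be tokenized."""


def parse_label(text: str, dialect: str = "dot") -> tuple[str, ...]:
    """Split a hierarchical class label into its path tokens.

    ``"12.01.01"`` (dot dialect) and ``"12/01/01"`` (slash dialect, used by
    Clus ARFF files) both denote the level-3 class whose superclasses are
    ``12.01`` and ``12``.
    """
    try:
        sep = _SEPARATORS[dialect]
    except KeyError:
        raise LabelParseError(f"unknown label dialect {dialect!r}") from None
    if not text:
        raise LabelParseError("empty class label")
    tokens = tuple(text.split(sep))
    if any(not t for t in tokens):
        raise LabelParseError(f"empty token in class label {text!r}")
    return tokens


def format_label(path: Sequence[str], dialect: str = "dot") -> str:
    """Inverse of :func:`parse_label`."""
    try:
        sep = _SEPARATORS[dialect]
    except KeyError:
        raise LabelParseError(f"unknown label dialect {dialect!r}") from None
    return sep.join(path)


@dataclass(frozen=True)
class ClassNode:
    """One class in the taxonomy, identified by its path from the root."""

    path: tuple[str, ...]

    @property
    def id(self) -> str:
        return ".".join(self.path)

    @property
    def level(self) -> int:
        """Depth in the tree; top-level categories are level 1."""
        return len(self.path)

    @property
    def parent_id(self) -> str | None:
        """Id of the parent class, or None for a top-level category."""
        if len(self.path) == 1:
            return None
        return ".".join(self.path[:-1])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ClassNode({self.id})"


class ClassHierarchy:
    """Rooted tree of class nodes with a fixed global class ordering.

    The ordering is lexicographic by path tokens and frozen at build time;
    every vector or matrix over the class set uses it.  ``levels[l]`` lists
    the column indices of the level-``l`` classes (1-based levels).
    """

    def __init__(self, nodes: Iterable[ClassNode]):
        ordered = sorted(set(nodes), key=lambda n: n.path)
        self._nodes: list[ClassNode] = ordered
        self._index: dict[str, int] = {n.id: i for i, n in enumerate(ordered)}
        if len(self._index) != len(ordered):
            raise HierarchyError("duplicate class ids in hierarchy")
        for n in ordered:
            pid = n.parent_id
            if pid is not None and pid not in self._index:
                raise HierarchyError(f"class {n.id!r} lacks parent {pid!r}")
        self.max_depth = max((n.level for n in ordered), default=0)
        self.levels: dict[int, np.ndarray] = {
            l: np.array(
                [i for i, n in enumerate(ordered) if n.level == l], dtype=np.intp
            )
            for l in range(1, self.max_depth + 1)
        }
        # parent column index per class, -1 for top-level categories
        self.parent_index = np.array(
            [
                self._index[n.parent_id] if n.parent_id is not None else -1
                for n in ordered
            ],
            dtype=np.intp,
        )

    # -- basic container protocol ------------------------------------------
    @property
    def class_count(self) -> int:
        return len(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClassHierarchy):
            return NotImplemented
        return [n.path for n in self._nodes] == [n.path for n in other._nodes]

    @property
    def class_ids(self) -> list[str]:
        """All class ids in the global (lexicographic) ordering."""
        return [n.id for n in self._nodes]

    @property
    def nodes(self) -> list[ClassNode]:
        return list(self._nodes)

    def index_of(self, class_id: str) -> int:
        try:
            return self._index[class_id]
        except KeyError:
            raise HierarchyError(f"unknown class id {class_id!r}") from None

    def node(self, class_id: str) -> ClassNode:
        return self._nodes[self.index_of(class_id)]

    def level_sizes(self) -> list[int]:
        return [len(self.levels[l]) for l in range(1, self.max_depth + 1)]

    # -- ancestor machinery -------------------------------------------------
    def ancestors(self, class_id: str) -> list[ClassNode]:
        """Proper ancestors of a class, nearest first, excluding the root."""
        node = self.node(class_id)
        return [
            self._nodes[self.index_of(".".join(node.path[:k]))]
            for k in range(node.level - 1, 0, -1)
        ]

    def close_labels(self, raw: Iterable[str]) -> frozenset[str]:
        """Ancestor closure of a set of class ids (idempotent)."""
        closed: set[str] = set()
        for cid in raw:
            node = self.node(cid)
            for k in range(1, node.level + 1):
                closed.add(".".join(node.path[:k]))
        return frozenset(closed)

    def close_matrix(self, Y: np.ndarray) -> np.ndarray:
        """Ancestor closure applied row-wise to a binary label matrix."""
        Y = np.asarray(Y)
        self._check_width(Y)
        out = Y.astype(bool).copy()
        for l in range(self.max_depth, 1, -1):
            cols = self.levels[l]
            parents = self.parent_index[cols]
            np.logical_or.at(out.T, parents, out.T[cols])
        return out.astype(np.int8)

    def repair_consistency(self, v: np.ndarray) -> np.ndarray:
        """Drop predictions whose superclasses are not predicted.

        The sweep is level-ascending, so removal cascades: once a class is
        dropped, every predicted descendant is dropped too.  Accepts a single
        vector or a matrix of row vectors; output ≤ input elementwise and is
        ancestor-closed.
        """
        v = np.asarray(v)
        single = v.ndim == 1
        V = np.atleast_2d(v)
        self._check_width(V)
        out = V.astype(bool).copy()
        for l in range(2, self.max_depth + 1):
            cols = self.levels[l]
            out[:, cols] &= out[:, self.parent_index[cols]]
        out = out.astype(np.int8)
        return out[0] if single else out

    def min_path_scores(self, scores: np.ndarray) -> np.ndarray:
        """Per-class minimum of the scores along each class's root path.

        Thresholding these transformed scores at any t is equivalent to
        thresholding the raw scores at t followed by cascading consistency
        repair, which makes threshold sweeps cheap.
        """
        S = np.atleast_2d(np.asarray(scores, dtype=float))
        self._check_width(S)
        out = S.copy()
        for l in range(2, self.max_depth + 1):
            cols = self.levels[l]
            out[:, cols] = np.minimum(out[:, cols], out[:, self.parent_index[cols]])
        return out if np.asarray(scores).ndim > 1 else out[0]

    def _check_width(self, arr: np.ndarray) -> None:
        if arr.shape[-1] != self.class_count:
            raise ValueError(
                f"vector width {arr.shape[-1]} != class count {self.class_count}"
            )

    # -- construction and export -------------------------------------------
    def labels_to_matrix(self, label_sets: Sequence[Iterable[str]]) -> np.ndarray:
        """Binary (instances × |C|) matrix from per-instance id sets, closed."""
        Y = np.zeros((len(label_sets), self.class_count), dtype=np.int8)
        for i, labels in enumerate(label_sets):
            for cid in self.close_labels(labels):
                Y[i, self._index[cid]] = 1
        return Y

    def edge_list(self) -> list[tuple[str, str]]:
        """(parent, child) pairs; top-level categories hang off ``<root>``."""
        return [
            (n.parent_id if n.parent_id is not None else "<root>", n.id)
            for n in self._nodes
        ]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ClassHierarchy(|C|={self.class_count}, "
            f"levels={self.level_sizes()})"
        )


def build_hierarchy(paths: Iterable[Sequence[str]]) -> ClassHierarchy:
    """Build a hierarchy from class paths, completing all path prefixes.

    Every prefix of every path becomes a node, so the result is always a
    well-formed tree.  Duplicates are allowed; ordering is deterministic.
    """
    nodes: set[ClassNode] = set()
    for path in paths:
        path = tuple(path)
        for k in range(1, len(path) + 1):
            nodes.add(ClassNode(path[:k]))
    return ClassHierarchy(nodes)
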