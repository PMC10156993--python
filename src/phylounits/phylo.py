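"""Rooted-tree handling: Newick I/O, patristic distances, clade labelling.

The tree's tips correspond one-to-one with sampling sites (one strain per
site), so the site-to-site phylogenetic distance is simply the tip-to-tip
patristic distance: the sum of branch lengths along the path joining two
tips. Clades are delineated by the user as the full descendant set of the
most recent common ancestor (MRCA) of a defining tip pair, mirroring how
clades are read off a drawn tree.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .core import DistanceMatrix

__all__ = ["CladeTree", "read_newick", "patristic_matrix", "assign_clades"]

logger = logging.getLogger(__name__)


class CladeTree:
    """A rooted tree with branch lengths and an optional clade labelling.

    ``clade_map`` maps clade label → frozenset of tip names; clade sets are
    disjoint and each is verified to be monophyletic when assigned via
    :meth:`assign_clades`.
    """

    def __init__(self, tree: dendropy.Tree,
                 clade_map: Mapping[str, frozenset[str]] | None = None):
        self._tree = tree
        names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate tip names: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length} not allowed")
        self.clade_map = {k: frozenset(v) for k, v in (clade_map or {}).items()}
        _check_disjoint(self.clade_map)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def write_newick(self, path=None) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s)
        return s

    def patristic_matrix(self) -> DistanceMatrix:
        return patristic_matrix(self)

    def assign_clades(self, clade_spec: Mapping[str, tuple[str, str]],
                      require_cover: bool = False) -> dict[str, frozenset[str]]:
        self.clade_map = assign_clades(self, clade_spec, require_cover=require_cover)
        return self.clade_map

    def clade_of(self, tip_name: str) -> str:
        for clade, tips in self.clade_map.items():
            if tip_name in tips:
                return clade
        raise KeyError(f"tip {tip_name!r} not covered by any clade")


def _check_disjoint(clade_map: Mapping[str, frozenset[str]]) -> None:
    seen: dict[str, str] = {}
    shared: dict[tuple[str, str], list[str]] = {}
    for clade, tips in clade_map.items():
        for t in tips:
            if t in seen:
                shared.setdefault(tuple(sorted((seen[t], clade))), []).append(t)
            seen[t] = clade
    if shared:
        msgs = [f"{a}/{b}: {sorted(tips)}" for (a, b), tips in shared.items()]
        raise ValueError("overlapping clades share tips — " + "; ".join(msgs))


def read_newick(source: str, clade_spec: Mapping[str, tuple[str, str]] | None = None,
                ) -> CladeTree:
    """Parse a Newick string or file into a :class:`CladeTree`.

    Missing branch lengths default to 0 with a logged warning; negative
    lengths and duplicate tip names are rejected.
    """
    text = source
    if not source.lstrip().startswith("("):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing:
        logger.warning("%d branch length(s) missing in Newick input; set to 0", n_missing)
    ct = CladeTree(tree)
    if clade_spec:
        ct.assign_clades(clade_spec)
    return ct


def patristic_matrix(tree: CladeTree) -> DistanceMatrix:
    """Tip-to-tip patristic distance matrix (sum of branch lengths on path)."""
    dt = tree.tree
    pdm = dt.phylogenetic_distance_matrix()
    names = tree.tip_names
    taxa = {t.label: t for t in dt.taxon_namespace if t.label in set(names)}
    n = len(names)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(names, values)


def assign_clades(tree: CladeTree, clade_spec: Mapping[str, tuple[str, str]],
                  require_cover: bool = False) -> dict[str, frozenset[str]]:
    """Label clades as the descendant tip sets of MRCAs of defining pairs.

    ``clade_spec`` maps clade label → (tip_a, tip_b); the clade is every tip
    descending from MRCA(tip_a, tip_b). Overlapping clades raise an error
    listing the shared tips; with ``require_cover`` every tip must belong to
    some clade.
    """
    dt = tree.tree
    known = set(tree.tip_names)
    clade_map: dict[str, frozenset[str]] = {}
    for clade, pair in clade_spec.items():
        a, b = pair
        for name in (a, b):
            if name not in known:
                raise ValueError(f"clade {clade!r}: unknown tip name {name!r}")
        mrca = dt.mrca(taxon_labels=[a, b])
        tips = frozenset(leaf.taxon.label for leaf in mrca.leaf_iter())
        clade_map[clade] = tips
    _check_disjoint(clade_map)
    if require_cover:
        covered = set().union(*clade_map.values()) if clade_map else set()
        missing = known - covered
        if missing:
            raise ValueError(f"tips not covered by any clade: {sorted(missing)}")
    return clade_map
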